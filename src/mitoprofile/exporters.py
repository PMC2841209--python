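"""The six downstream export formats.

All writers are pure functions of the validated project state and are
deterministic: the same state always yields byte-identical text.

================  ==========================================================
format            shape
================  ==========================================================
empop             one row per haplotype: ID, haplogroup ("?" when unknown),
                  frequency, then the variant tokens, tab-separated
binary_matrix     samples x polymorphisms 0/1 table, tab-separated
tab_delimited     EMPOP columns plus "range" and "tumour profiles"
mtdnamanager      variants partitioned into the control-region ranges
                  [16024-16569], [1-437], [438-576]
network           median-joining network input: polymorphism columns, one
                  base per column per sample (reference base when absent)
fasta             reconstructed sequences over user-chosen ranges
================  ==========================================================
"""

from __future__ import annotations

import io
import warnings
from typing import Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    Profile,
    ReferenceSequence,
    VariantCall,
    VariantKind,
    apply_profile,
    format_variant,
)
from .errors import ExportError, ExportWarning
from .store import ValidatedSample

__all__ = [
    "DEFAULT_MANAGER_RANGES",
    "NETWORK_NAME_LIMIT",
    "export_empop",
    "export_binary_matrix",
    "export_tab_delimited",
    "export_mtdnamanager",
    "export_network",
    "export_fasta",
    "read_binary_matrix",
]

#: Control-region grouping ranges of the mtDNAmanager format, in its
#: printed order: HVS-I, then HVS-II, then HVS-III.
DEFAULT_MANAGER_RANGES: tuple[tuple[int, int], ...] = (
    (16024, 16569),
    (1, 437),
    (438, 576),
)

#: Fluxus Network rejects sample names longer than this.
NETWORK_NAME_LIMIT = 13

_FASTA_WRAP = 70


def _haplotype_key(sample: ValidatedSample) -> str:
    return " ".join(sample.profile.tokens())


def export_empop(
    samples: Sequence[ValidatedSample], collapse_haplotypes: bool = False
) -> str:
    """EMPOP population-database rows: ID, haplogroup, frequency, tokens.

    An unknown haplogroup renders as ``?``.  With ``collapse_haplotypes``
    identical profiles merge into one row whose frequency is their count
    (ID and haplogroup come from the first carrier); otherwise frequency
    is 1 per sample.  Either way the frequencies sum to the sample count.
    """
    rows: list[str] = []
    if collapse_haplotypes:
        groups: dict[str, list[ValidatedSample]] = {}
        for s in samples:
            groups.setdefault(_haplotype_key(s), []).append(s)
        chosen = sorted(groups.values(), key=lambda g: g[0].sample_id)
        for group in chosen:
            first = group[0]
            rows.append(
                "\t".join(
                    [first.sample_id, first.haplogroup or "?", str(len(group))]
                    + list(first.profile.tokens())
                )
            )
    else:
        for s in samples:
            rows.append(
                "\t".join(
                    [s.sample_id, s.haplogroup or "?", "1"]
                    + list(s.profile.tokens())
                )
            )
    return "\n".join(rows) + ("\n" if rows else "")


def _variant_union(samples: Sequence[ValidatedSample]) -> list[VariantCall]:
    union: dict[tuple[int, int, str], VariantCall] = {}
    for s in samples:
        for v in s.profile.variants:
            union[(v.position, v.insertion_index, v.observed)] = v
    return sorted(union.values(), key=lambda v: (v.position, v.insertion_index, v.observed))


def export_binary_matrix(samples: Sequence[ValidatedSample]) -> str:
    """Tab-delimited 0/1 matrix: polymorphisms in the header, samples in rows.

    A cell is 1 when the sample carries exactly that polymorphism (same
    position, insertion index and observed base).
    """
    if not samples:
        raise ExportError("cannot export a binary matrix from an empty project")
    columns = _variant_union(samples)
    header = "\t".join(["ID"] + [format_variant(v) for v in columns])
    lines = [header]
    for s in samples:
        carried = {(v.position, v.insertion_index, v.observed) for v in s.profile.variants}
        cells = [
            "1" if (v.position, v.insertion_index, v.observed) in carried else "0"
            for v in columns
        ]
        lines.append("\t".join([s.sample_id] + cells))
    return "\n".join(lines) + "\n"


def read_binary_matrix(text: str) -> dict[str, set[str]]:
    """Inverse of :func:`export_binary_matrix`: sample ID -> token set."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")[1:]
    out: dict[str, set[str]] = {}
    for line in lines[1:]:
        cells = line.split("\t")
        out[cells[0]] = {
            tok for tok, cell in zip(header, cells[1:]) if cell == "1"
        }
    return out


def export_tab_delimited(
    samples: Sequence[ValidatedSample],
    somatic_strings: dict[str, str] | None = None,
) -> str:
    """EMPOP columns plus "range" and "tumour profiles", with a header row.

    ``somatic_strings`` maps sample ID to its somatic-alteration string
    (tumour projects); other projects leave the column empty.
    """
    somatic_strings = somatic_strings or {}
    lines = ["\t".join(["ID", "haplogroup", "frequency", "range",
                        "tumour profiles", "profile"])]
    for s in samples:
        ranges = s.profile.sequenced_ranges
        range_cell = ";".join(f"{a}-{b}" for a, b in ranges) if ranges else ""
        lines.append(
            "\t".join(
                [
                    s.sample_id,
                    s.haplogroup or "?",
                    "1",
                    range_cell,
                    somatic_strings.get(s.sample_id, ""),
                    " ".join(s.profile.tokens()),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def export_mtdnamanager(
    samples: Sequence[ValidatedSample],
    ranges: Sequence[tuple[int, int]] = DEFAULT_MANAGER_RANGES,
) -> str:
    """Group each profile's variants into the three control-region ranges.

    Variants whose anchor position falls outside all three ranges are
    excluded with a warning.  Output: ID, haplogroup, then one
    space-joined token group per range, tab-separated, in the given
    range order.
    """
    lines = []
    for s in samples:
        groups: list[list[str]] = [[] for _ in ranges]
        for v in s.profile.variants:
            for i, (start, end) in enumerate(ranges):
                if start <= v.position <= end:
                    groups[i].append(format_variant(v))
                    break
            else:
                warnings.warn(
                    f"sample {s.sample_id}: variant {format_variant(v)} outside "
                    f"the grouping ranges; excluded",
                    ExportWarning,
                    stacklevel=2,
                )
        lines.append(
            "\t".join([s.sample_id, s.haplogroup or "?"] + [" ".join(g) for g in groups])
        )
    return "\n".join(lines) + ("\n" if lines else "")


def export_network(
    samples: Sequence[ValidatedSample], ref: ReferenceSequence
) -> str:
    """Input table for the Fluxus Network program.

    The first row lists the polymorphism columns; each sample line gives,
    per column, the sample's observed base if it carries that variant and
    otherwise the reference state (the reference base for substitution
    and deletion columns, ``-`` for insertion columns).  Tokens are
    space-separated and every line has the same width as the header.

    Sample names longer than 13 characters are an error — the downstream
    program truncates, which could silently merge samples.  A run of
    three or more inserted bases at one anchor triggers a warning
    (Network reports duplicated header information for those).
    """
    for s in samples:
        if len(s.sample_id) > NETWORK_NAME_LIMIT:
            raise ExportError(
                f"sample name {s.sample_id!r} exceeds the "
                f"{NETWORK_NAME_LIMIT}-character Network limit"
            )
    columns = _variant_union(samples)
    for s in samples:
        anchors: dict[int, int] = {}
        for v in s.profile.variants:
            if v.kind is VariantKind.INSERTION:
                anchors[v.position] = anchors.get(v.position, 0) + 1
        for pos, count in sorted(anchors.items()):
            if count >= 3:
                warnings.warn(
                    f"sample {s.sample_id}: {count} inserted bases after "
                    f"position {pos}; Network will warn about duplicated "
                    f"header information",
                    ExportWarning,
                    stacklevel=2,
                )
    header = " ".join(["ID"] + [format_variant(v) for v in columns])
    lines = [header]
    for s in samples:
        carried = {(v.position, v.insertion_index, v.observed) for v in s.profile.variants}
        cells = []
        for v in columns:
            if (v.position, v.insertion_index, v.observed) in carried:
                cells.append(v.observed if v.kind is not VariantKind.DELETION else "-")
            elif v.kind is VariantKind.INSERTION:
                cells.append("-")
            else:
                cells.append(ref.base_at(v.position))
        lines.append(" ".join([s.sample_id] + cells))
    return "\n".join(lines) + "\n"


def export_fasta(
    samples: Sequence[ValidatedSample],
    ref: ReferenceSequence,
    ranges: Sequence[tuple[int, int]],
) -> str:
    """One FASTA record per sample over any combination of ranges.

    The sequence is the reference with each sample's variants applied;
    single positions are ranges of length one.
    """
    if not ranges:
        raise ExportError("fasta export needs at least one range")
    records = [
        SeqRecord(
            Seq(apply_profile(ref, s.profile, ranges)),
            id=s.sample_id,
            description="",
        )
        for s in samples
    ]
    buf = io.StringIO()
    writer = SeqIO.FastaIO.FastaWriter(buf, wrap=_FASTA_WRAP)
    writer.write_file(records)
    return buf.getvalue()
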