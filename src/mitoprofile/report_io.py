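"""Reading and writing evaluator mutation-report files.

Two plain-text dialects are supported, distinguished by extension:

``.txt`` — "sequencher" dialect::

    SAMPLE 12334            # optional header
    RANGE 16024-16569       # zero or more sequenced-range lines
    73G
    263G

``.sqs`` — "seqscape" dialect: a tab-separated table whose header row names
``position``, ``reference`` and ``observed`` columns.  Insertions carry a
fractional position (``309.1``); deletions have observed ``del`` or ``-``::

    position<TAB>reference<TAB>observed
    73<TAB>A<TAB>G
    309.1<TAB>-<TAB>C

The sample ID and evaluator initials come from the filename stem split at
its first underscore (``12334_ABC.txt`` -> ID ``12334``, evaluator ``ABC``);
tumour and association projects require the ID to be numeric.

The authentic vendor layouts are not publicly documented; these dialects
are this package's documented equivalents carrying the same fields
(variant tokens plus, for sequencher, the sequenced ranges).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .core import (
    DELETION_MARKER,
    Profile,
    ProjectType,
    SourceProgram,
    VariantCall,
    VariantKind,
    deletion,
    format_variant,
    insertion,
    parse_variant_token,
    substitution,
)
from .errors import ReportFormatError, VariantParseError

__all__ = [
    "MutationReportFile",
    "detect_dialect",
    "extract_identifier",
    "read_report",
    "read_report_batch",
    "write_report",
]

_EXTENSIONS = {".sqs": SourceProgram.SEQSCAPE, ".txt": SourceProgram.SEQUENCHER}


@dataclass(frozen=True)
class MutationReportFile:
    """One parsed evaluator report."""

    filename: str
    dialect: SourceProgram
    sample_id: str
    evaluator: str
    profile: Profile


def detect_dialect(filename: str) -> SourceProgram:
    """Map the file extension to its evaluation program (case-insensitive)."""
    if not filename:
        raise ReportFormatError("empty filename")
    ext = Path(filename).suffix.lower()
    try:
        return _EXTENSIONS[ext]
    except KeyError:
        raise ReportFormatError(
            f"unknown mutation-report extension {ext!r} in {filename!r} "
            f"(expected .sqs or .txt)"
        ) from None


def extract_identifier(
    filename: str, project_type: ProjectType | str
) -> tuple[str, str]:
    """Split the filename stem at its first underscore into (ID, evaluator).

    Tumour and association projects require an all-digit sample ID;
    population projects allow arbitrary text.
    """
    project_type = ProjectType(project_type)
    detect_dialect(filename)  # validates the extension
    stem = Path(filename).stem
    if "_" not in stem:
        raise ReportFormatError(
            f"filename {filename!r} lacks the '_' separating ID from evaluator"
        )
    sample_id, evaluator = stem.split("_", 1)
    if not sample_id or not evaluator:
        raise ReportFormatError(
            f"filename {filename!r} has an empty ID or evaluator part"
        )
    if project_type.requires_numeric_ids and not sample_id.isdigit():
        raise ReportFormatError(
            f"sample ID {sample_id!r} must be numeric for a "
            f"{project_type.value} project (file {filename!r})"
        )
    return sample_id, evaluator


def _parse_sequencher(path: Path, lines: list[str]) -> tuple[list[VariantCall], list[tuple[int, int]]]:
    variants: list[VariantCall] = []
    ranges: list[tuple[int, int]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        upper = line.upper()
        if upper.startswith("SAMPLE"):
            continue
        if upper.startswith("RANGE"):
            body = line.split(None, 1)[1] if len(line.split(None, 1)) > 1 else ""
            try:
                start_s, end_s = body.replace(" ", "").split("-", 1)
                ranges.append((int(start_s), int(end_s)))
            except ValueError:
                raise ReportFormatError(
                    f"{path.name}:{lineno}: malformed RANGE line {line!r}"
                ) from None
            continue
        try:
            variants.append(parse_variant_token(line))
        except VariantParseError as exc:
            raise ReportFormatError(f"{path.name}:{lineno}: {exc}") from exc
    return variants, ranges


def _parse_seqscape(path: Path, lines: list[str]) -> list[VariantCall]:
    header: dict[str, int] | None = None
    variants: list[VariantCall] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cells = line.split("\t")
        if header is None:
            header = {c.strip().lower(): i for i, c in enumerate(cells)}
            for col in ("position", "observed"):
                if col not in header:
                    raise ReportFormatError(
                        f"{path.name}:{lineno}: header lacks {col!r} column"
                    )
            continue
        try:
            pos_text = cells[header["position"]].strip()
            obs = cells[header["observed"]].strip()
        except IndexError:
            raise ReportFormatError(
                f"{path.name}:{lineno}: row has too few columns"
            ) from None
        try:
            if "." in pos_text:
                anchor_s, idx_s = pos_text.split(".", 1)
                variants.append(insertion(int(anchor_s), int(idx_s), obs))
            elif obs.lower() in ("del", DELETION_MARKER):
                variants.append(deletion(int(pos_text)))
            else:
                variants.append(substitution(int(pos_text), obs))
        except (ValueError, VariantParseError) as exc:
            raise ReportFormatError(f"{path.name}:{lineno}: {exc}") from exc
    if header is None:
        raise ReportFormatError(f"{path.name}: empty seqscape report (no header)")
    return variants


def read_report(path: str | Path, project_type: ProjectType | str) -> MutationReportFile:
    """Parse one mutation-report file in the dialect its extension names."""
    path = Path(path)
    dialect = detect_dialect(path.name)
    sample_id, evaluator = extract_identifier(path.name, project_type)
    lines = path.read_text().splitlines()
    if dialect is SourceProgram.SEQUENCHER:
        variants, ranges = _parse_sequencher(path, lines)
    else:
        variants, ranges = _parse_seqscape(path, lines), []
    profile = Profile(
        sample_id=sample_id,
        evaluator=evaluator,
        source_program=dialect,
        variants=tuple(variants),
        sequenced_ranges=tuple(ranges) or None,
    )
    return MutationReportFile(
        filename=path.name,
        dialect=dialect,
        sample_id=sample_id,
        evaluator=evaluator,
        profile=profile,
    )


def read_report_batch(
    paths: Iterable[str | Path], project_type: ProjectType | str
) -> dict[str, list[MutationReportFile]]:
    """Read many reports and group them by sample ID.

    Per-sample lists are ordered by evaluator name.  Two reports from the
    same evaluator for the same sample are rejected; mixing dialects within
    a sample is allowed (evaluators may use different programs).
    """
    grouped: dict[str, list[MutationReportFile]] = {}
    seen: set[tuple[str, str]] = set()
    for p in paths:
        report = read_report(p, project_type)
        key = (report.sample_id, report.evaluator)
        if key in seen:
            raise ReportFormatError(
                f"duplicate report for sample {report.sample_id!r} by "
                f"evaluator {report.evaluator!r}"
            )
        seen.add(key)
        grouped.setdefault(report.sample_id, []).append(report)
    for reports in grouped.values():
        reports.sort(key=lambda r: r.evaluator)
    return grouped


def write_report(path: str | Path, profile: Profile) -> Path:
    """Write a profile as a mutation-report file.

    The dialect follows the extension of *path*; this is the exact inverse
    of :func:`read_report` on (sample_id, evaluator, variants, ranges).
    """
    path = Path(path)
    dialect = detect_dialect(path.name)
    if dialect is SourceProgram.SEQUENCHER:
        lines = [f"SAMPLE {profile.sample_id}"]
        for start, end in profile.sequenced_ranges or ():
            lines.append(f"RANGE {start}-{end}")
        lines.extend(format_variant(v) for v in profile.variants)
    else:
        lines = ["position\treference\tobserved"]
        for v in profile.variants:
            if v.kind is VariantKind.INSERTION:
                lines.append(f"{v.position}.{v.insertion_index}\t-\t{v.observed}")
            elif v.kind is VariantKind.DELETION:
                lines.append(f"{v.position}\t.\tdel")
            else:
                lines.append(f"{v.position}\t.\t{v.observed}")
    path.write_text("\n".join(lines) + "\n")
    return path
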