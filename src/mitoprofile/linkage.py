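"""Phenotype linkage and paired-tissue somatic-mutation detection.

Phenotype tables arrive as delimited text with a user-named ID column and
are joined to samples by that ID; columns flagged sample-specific at
import time sit behind the access guard.  Tumour projects store one
validated profile per tissue (benign, tumour) and somatic alterations are
the key-wise differences between the pair: variants gained in the tumour
and variants lost from the benign profile.  A changed base at one
position counts as one loss plus one gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import Profile, ProjectType, Tissue, VariantCall, format_variant
from .errors import ExportError, MitoprofileError, StoreError
from .store import Store, UserAccount
from .validation import compare_profiles

__all__ = [
    "LinkSummary",
    "SomaticAlteration",
    "import_phenotypes",
    "export_combined",
    "detect_somatic",
    "project_somatic_strings",
]


@dataclass
class LinkSummary:
    n_linked: int = 0
    unmatched: list[str] = field(default_factory=list)
    changes: int = 0


@dataclass(frozen=True)
class SomaticAlteration:
    """Key-wise differences between matched benign and tumour profiles."""

    sample_id: str
    gained: frozenset[VariantCall]  # tumour-only calls
    lost: frozenset[VariantCall]  # benign-only calls

    @property
    def empty(self) -> bool:
        return not self.gained and not self.lost

    def pattern(self) -> str:
        """Render as ``+gain;-loss`` tokens in canonical order."""
        parts = [(v.key, f"+{format_variant(v)}") for v in self.gained]
        parts += [(v.key, f"-{format_variant(v)}") for v in self.lost]
        return ";".join(text for _, text in sorted(parts))


def import_phenotypes(
    store: Store,
    project: str,
    table: pd.DataFrame | str | Path,
    id_column: str,
    sample_specific_columns: Sequence[str] = (),
    employee: str = "system",
) -> LinkSummary:
    """Join a phenotype table to a project's samples by its ID column.

    The table may be a DataFrame or a path to delimited text (separator
    sniffed by pandas).  Unmatched IDs are reported, not fatal; flagged
    columns are stored behind the access guard.  Value changes on
    re-import are history-logged with old and new values.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep=None, engine="python", dtype=str)
    if id_column not in table.columns:
        raise MitoprofileError(
            f"phenotype table lacks the ID column {id_column!r} "
            f"(columns: {list(table.columns)})"
        )
    ids = table[id_column].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise MitoprofileError(f"duplicate IDs in phenotype table: {dupes}")
    unknown_flags = set(sample_specific_columns) - set(table.columns)
    if unknown_flags:
        raise MitoprofileError(
            f"sample-specific columns not in table: {sorted(unknown_flags)}"
        )
    known = {sid for sid, _, _ in store.list_samples(project)}
    summary = LinkSummary()
    rows: dict[str, dict[str, str]] = {}
    value_columns = [c for c in table.columns if c != id_column]
    for _, row in table.iterrows():
        sample_id = str(row[id_column])
        if sample_id not in known:
            summary.unmatched.append(sample_id)
            continue
        rows[sample_id] = {c: str(row[c]) for c in value_columns}
        summary.n_linked += 1
    changes = store.store_phenotypes(
        project, rows, sample_specific_columns=sample_specific_columns,
        employee=employee,
    )
    summary.changes = len(changes)
    return summary


def export_combined(
    store: Store,
    project: str,
    selected_phenotypes: Sequence[str],
    selected_variants: Sequence[str],
    user: UserAccount,
) -> pd.DataFrame:
    """One row per sample: ID, chosen phenotypes, 0/1 variant columns.

    Only association and tumour projects may combine phenotypes with
    mtDNA data.  Columns the access guard denies are silently withheld
    (the denial is history-logged).  Variants are emitted as
    presence/absence so the table loads directly into statistics
    packages.  Rows cover samples having both a validated profile and a
    phenotype row; the export is history-logged.
    """
    ptype = store.project_type(project)
    if ptype is ProjectType.POPULATION:
        raise ExportError("combined export requires association or tumour project")
    if not selected_phenotypes and not selected_variants:
        raise ExportError("combined export needs at least one selected column")
    known_cols = store.phenotype_columns(project)
    missing = set(selected_phenotypes) - set(known_cols)
    if missing:
        raise MitoprofileError(f"unknown phenotype columns: {sorted(missing)}")
    permitted = store.guard_sample_info(user, project, selected_phenotypes)
    pheno_rows = store.phenotype_rows(project, permitted)

    tissue = Tissue.BENIGN if ptype is ProjectType.TUMOUR else None
    samples = store.validated_samples(project, tissue=tissue)
    records = []
    for s in samples:
        if s.sample_id not in pheno_rows:
            continue
        tokens = set(s.profile.tokens())
        record: dict[str, object] = {"ID": s.sample_id}
        for col in permitted:
            record[col] = pheno_rows[s.sample_id].get(col, "")
        for tok in selected_variants:
            record[tok] = int(tok in tokens)
        records.append(record)
    frame = pd.DataFrame.from_records(
        records, columns=["ID"] + list(permitted) + list(selected_variants)
    )
    store.record_history(
        project, user.name,
        f"Export combined: {len(permitted)} phenotypes x "
        f"{len(selected_variants)} polymorphisms",
    )
    return frame


def detect_somatic(benign: Profile, tumour: Profile) -> SomaticAlteration:
    """Somatic alterations between matched benign and tumour profiles.

    gained = tumour \\ benign and lost = benign \\ tumour on
    (position, insertion_index) keys; a key present in both with a
    different observed base contributes one loss (the benign call) and
    one gain (the tumour call).
    """
    if benign.sample_id != tumour.sample_id:
        raise MitoprofileError(
            f"tissue profiles belong to different samples: "
            f"{benign.sample_id!r} vs {tumour.sample_id!r}"
        )
    map_b, map_t = benign.variant_map(), tumour.variant_map()
    gained: set[VariantCall] = set()
    lost: set[VariantCall] = set()
    for key in set(map_b) | set(map_t):
        vb, vt = map_b.get(key), map_t.get(key)
        if vb is None:
            gained.add(vt)
        elif vt is None:
            lost.add(vb)
        elif (vb.observed, vb.kind) != (vt.observed, vt.kind):
            lost.add(vb)
            gained.add(vt)
    return SomaticAlteration(
        sample_id=benign.sample_id,
        gained=frozenset(gained),
        lost=frozenset(lost),
    )


def project_somatic_strings(store: Store, project: str) -> dict[str, str]:
    """Alteration patterns for every sample with both tissues validated.

    Samples lacking either tissue are skipped (they cannot be compared
    yet); the caller may warn about them via the returned dict's absence.
    """
    if store.project_type(project) is not ProjectType.TUMOUR:
        raise MitoprofileError("somatic detection applies to tumour projects only")
    benign = {s.sample_id: s.profile for s in store.validated_samples(project, Tissue.BENIGN)}
    tumour = {s.sample_id: s.profile for s in store.validated_samples(project, Tissue.TUMOUR)}
    out: dict[str, str] = {}
    for sample_id in sorted(set(benign) & set(tumour)):
        out[sample_id] = detect_somatic(benign[sample_id], tumour[sample_id]).pattern()
    return out
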