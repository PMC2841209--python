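"""Double-evaluation comparison and validation.

Every sample is sequenced once but evaluated twice, by independent
scientists; the two resulting mutation reports are compared polymorphism
by polymorphism.  Equal evaluations are stored automatically; unequal
ones are listed as discordances for a validating senior scientist, who
either picks one of the two files or uploads a third evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Mapping, Sequence

from .core import Profile, VariantCall, format_variant
from .errors import ComparisonError, MitoprofileError, StoreError
from .report_io import MutationReportFile

if TYPE_CHECKING:  # pragma: no cover
    from .store import Store

__all__ = [
    "Discordance",
    "ComparisonStatus",
    "ComparisonReport",
    "ValidationResult",
    "BatchSummary",
    "compare_profiles",
    "validate_sample",
    "batch_validate",
]


class ComparisonStatus(str, Enum):
    CONCORDANT = "concordant"
    DISCORDANT = "discordant"


@dataclass(frozen=True)
class Discordance:
    """One per-key difference between two evaluations.

    Exactly one description applies: the key is present only in A, only
    in B, or present in both with a different observed base or kind
    (``conflicting`` — e.g. a C vs Y heteroplasmy-interpretation split).
    """

    key: tuple[int, int]
    in_a_only: VariantCall | None = None
    in_b_only: VariantCall | None = None
    conflicting: bool = False

    def __post_init__(self) -> None:
        one_sided = (self.in_a_only is None) != (self.in_b_only is None)
        both = self.in_a_only is not None and self.in_b_only is not None
        if self.conflicting:
            if not both:
                raise ComparisonError("conflicting discordance needs both calls")
        elif not one_sided:
            raise ComparisonError("one-sided discordance needs exactly one call")

    def describe(self) -> str:
        pos = f"{self.key[0]}.{self.key[1]}" if self.key[1] else str(self.key[0])
        if self.conflicting:
            return (
                f"{pos}: conflict {format_variant(self.in_a_only)} (A) vs "
                f"{format_variant(self.in_b_only)} (B)"
            )
        if self.in_a_only is not None:
            return f"{pos}: {format_variant(self.in_a_only)} only in A"
        return f"{pos}: {format_variant(self.in_b_only)} only in B"

    def swapped(self) -> "Discordance":
        return Discordance(
            key=self.key,
            in_a_only=self.in_b_only,
            in_b_only=self.in_a_only,
            conflicting=self.conflicting,
        )


@dataclass(frozen=True)
class ComparisonReport:
    """Polymorphism-level discordance listing for one sample."""

    sample_id: str
    status: ComparisonStatus
    discordances: tuple[Discordance, ...] = ()
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        empty = not self.discordances
        if (self.status is ComparisonStatus.CONCORDANT) != empty:
            raise ComparisonError("status must reflect the discordance list")

    @property
    def concordant(self) -> bool:
        return self.status is ComparisonStatus.CONCORDANT

    def to_text(self) -> str:
        lines = [f"sample {self.sample_id}: {self.status.value}"]
        lines += [f"  {d.describe()}" for d in self.discordances]
        lines += [f"  note: {n}" for n in self.notes]
        return "\n".join(lines)


def compare_profiles(a: Profile, b: Profile) -> ComparisonReport:
    """Row-by-row (polymorphism-by-polymorphism) comparison of two evaluations.

    Discordances are the per-key symmetric difference; a key present in
    both with a different observed base or kind is a *conflict*.
    Sequenced-range disagreement is surfaced as a note, never a
    discordance: the range is program metadata, not part of the haplotype.
    """
    if a.sample_id != b.sample_id:
        raise ComparisonError(
            f"sample-ID mismatch: {a.sample_id!r} vs {b.sample_id!r}"
        )
    map_a, map_b = a.variant_map(), b.variant_map()
    discordances: list[Discordance] = []
    for key in sorted(set(map_a) | set(map_b)):
        va, vb = map_a.get(key), map_b.get(key)
        if va is not None and vb is None:
            discordances.append(Discordance(key=key, in_a_only=va))
        elif va is None and vb is not None:
            discordances.append(Discordance(key=key, in_b_only=vb))
        elif (va.observed, va.kind) != (vb.observed, vb.kind):
            discordances.append(
                Discordance(key=key, in_a_only=va, in_b_only=vb, conflicting=True)
            )
    notes: tuple[str, ...] = ()
    if (
        a.sequenced_ranges is not None
        and b.sequenced_ranges is not None
        and a.sequenced_ranges != b.sequenced_ranges
    ):
        notes = (
            f"sequenced ranges differ: {a.sequenced_ranges} vs {b.sequenced_ranges}",
        )
    status = (
        ComparisonStatus.CONCORDANT if not discordances else ComparisonStatus.DISCORDANT
    )
    return ComparisonReport(
        sample_id=a.sample_id,
        status=status,
        discordances=tuple(discordances),
        notes=notes,
    )


@dataclass(frozen=True)
class ValidationResult:
    sample_id: str
    status: str  # "validated" | "pending"
    stored_profile: Profile | None = None
    report: ComparisonReport | None = None
    reason: str | None = None


@dataclass
class BatchSummary:
    n_validated: int = 0
    n_pending: int = 0
    results: dict[str, ValidationResult] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.n_validated + self.n_pending


def _pick_resolution(
    reports: Sequence[MutationReportFile], resolution: str
) -> MutationReportFile:
    if resolution.upper() == "A":
        return reports[0]
    if resolution.upper() == "B":
        if len(reports) < 2:
            raise MitoprofileError("resolution 'B' but only one report present")
        return reports[1]
    for r in reports:
        if r.filename == resolution or r.evaluator == resolution:
            return r
    raise MitoprofileError(
        f"resolution {resolution!r} names no uploaded report "
        f"(have {[r.filename for r in reports]})"
    )


def validate_sample(
    store: "Store",
    project: str,
    sample_id: str,
    reports: Sequence[MutationReportFile],
    *,
    resolution: str | None = None,
    employee: str = "system",
    tissue: str | None = None,
    force: bool = False,
) -> ValidationResult:
    """Validate one sample from its two (or three) evaluation reports.

    A concordant pair stores the lexicographically first evaluator's file
    automatically, recording the other filename as provenance.  A
    discordant pair without a resolution stays pending and returns the
    comparison report; ``resolution`` picks ``"A"``, ``"B"`` or a third
    report by filename/evaluator.  Every storage writes a history entry.
    """
    if len(reports) == 1:
        return ValidationResult(
            sample_id=sample_id,
            status="pending",
            reason="missing second evaluation",
        )
    if len(reports) not in (2, 3):
        raise MitoprofileError(
            f"sample {sample_id!r}: expected 2 reports (or 3 after escalation), "
            f"got {len(reports)}"
        )
    if any(r.sample_id != sample_id for r in reports):
        raise ComparisonError(f"report sample IDs disagree with {sample_id!r}")
    if store.get_validated_profile(project, sample_id, tissue=tissue) is not None and not force:
        raise StoreError(
            f"sample {sample_id!r} is already validated; pass force=True to redo"
        )

    primary = sorted(reports[:2], key=lambda r: r.evaluator)
    comparison = compare_profiles(primary[0].profile, primary[1].profile)

    if comparison.concordant and resolution is None:
        chosen = primary[0]
        provenance = f"concordant with {primary[1].filename}"
    elif resolution is not None:
        chosen = _pick_resolution(list(primary) + list(reports[2:]), resolution)
        provenance = f"resolved by {employee} from {[r.filename for r in reports]}"
    else:
        return ValidationResult(
            sample_id=sample_id,
            status="pending",
            report=comparison,
        )

    store.store_validated_profile(
        project,
        sample_id,
        chosen.profile,
        employee=employee,
        tissue=tissue,
        source_file=chosen.filename,
        provenance=provenance,
        force=force,
    )
    return ValidationResult(
        sample_id=sample_id,
        status="validated",
        stored_profile=chosen.profile,
        report=comparison,
    )


def batch_validate(
    store: "Store",
    project: str,
    grouped_reports: Mapping[str, Sequence[MutationReportFile]],
    *,
    employee: str = "system",
    tissue: str | None = None,
) -> BatchSummary:
    """Apply :func:`validate_sample` to every sample of an import batch."""
    summary = BatchSummary()
    for sample_id in sorted(grouped_reports):
        result = validate_sample(
            store,
            project,
            sample_id,
            grouped_reports[sample_id],
            employee=employee,
            tissue=tissue,
        )
        summary.results[sample_id] = result
        if result.status == "validated":
            summary.n_validated += 1
        else:
            summary.n_pending += 1
    return summary
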