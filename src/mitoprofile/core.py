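"""Canonical domain types and the mtDNA profile algebra.

Haplotypes are expressed in forensic difference notation: a profile is a
list of variant tokens relative to a reference sequence (in real use the
revised Cambridge Reference Sequence, rCRS).  Three variant kinds exist:

* substitution  — ``<position><base>``, e.g. ``73G`` or ``16093Y`` (IUPAC
  ambiguity codes represent point heteroplasmy);
* insertion     — ``<position>.<k><base>``, e.g. ``309.1C`` for the first
  base inserted after position 309;
* deletion      — ``<position>del`` (canonical) or ``<position>-``.

Coordinates are 1-based and inclusive.  Ranges never wrap the circular
origin; callers cover the control region with two intervals, e.g.
``(16024, 16569)`` plus ``(1, 576)``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

from .errors import (
    DuplicateKeyError,
    MitoprofileError,
    PhantomVariantWarning,
    VariantParseError,
)

__all__ = [
    "IUPAC_CODES",
    "DELETION_MARKER",
    "VariantKind",
    "SourceProgram",
    "ProjectType",
    "Tissue",
    "Role",
    "ReferenceSequence",
    "VariantCall",
    "Profile",
    "SampleRecord",
    "Project",
    "substitution",
    "insertion",
    "deletion",
    "parse_variant_token",
    "format_variant",
    "canonical_order",
    "apply_profile",
    "diff_sequences",
    "parse_ranges",
    "format_ranges",
]

#: The 15 IUPAC single-nucleotide codes (4 bases + 10 ambiguity + N).
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")

#: Internal marker stored in ``observed`` for deletion calls.
DELETION_MARKER = "-"

_TOKEN_RE = re.compile(
    r"""^(?P<pos>\d+)
        (?:
            \.(?P<idx>\d+)(?P<insbase>[A-Za-z])   # insertion: pos.k + base
          | (?P<del>del|-)                        # deletion
          | (?P<base>[A-Za-z])                    # substitution
        )$""",
    re.VERBOSE | re.IGNORECASE,
)


class VariantKind(str, Enum):
    SUBSTITUTION = "substitution"
    INSERTION = "insertion"
    DELETION = "deletion"


class SourceProgram(str, Enum):
    SEQSCAPE = "seqscape"
    SEQUENCHER = "sequencher"


class ProjectType(str, Enum):
    POPULATION = "population"
    ASSOCIATION = "association"
    TUMOUR = "tumour"

    @property
    def requires_numeric_ids(self) -> bool:
        return self in (ProjectType.ASSOCIATION, ProjectType.TUMOUR)


class Tissue(str, Enum):
    BENIGN = "benign"
    TUMOUR = "tumour"


class Role(str, Enum):
    """User roles, ordered viewer < editor < validator < admin."""

    VIEWER = "viewer"
    EDITOR = "editor"
    VALIDATOR = "validator"
    ADMIN = "admin"

    @property
    def rank(self) -> int:
        return ("viewer", "editor", "validator", "admin").index(self.value)

    def at_least(self, other: "Role") -> bool:
        return self.rank >= other.rank


@dataclass(frozen=True)
class ReferenceSequence:
    """An rCRS-like reference: upper-case DNA over {A,C,G,T}."""

    name: str
    residues: str
    circular: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise MitoprofileError("reference sequence is empty")
        bad = set(self.residues) - set("ACGT")
        if bad:
            raise MitoprofileError(
                f"reference {self.name!r} contains non-ACGT residues: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def base_at(self, position: int) -> str:
        """1-based lookup."""
        if not 1 <= position <= self.length:
            raise MitoprofileError(
                f"position {position} outside reference [1, {self.length}]"
            )
        return self.residues[position - 1]


@dataclass(frozen=True, order=True)
class VariantCall:
    """One difference to the reference; the atomic unit of a profile.

    Sort order is the canonical profile order: (position, insertion_index).
    """

    position: int
    insertion_index: int
    observed: str = field(compare=False)
    kind: VariantKind = field(compare=False)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise VariantParseError(f"position must be >= 1, got {self.position}")
        if self.kind is VariantKind.INSERTION:
            if self.insertion_index < 1:
                raise VariantParseError("insertion_index must be >= 1 for insertions")
        elif self.insertion_index != 0:
            raise VariantParseError(
                f"{self.kind.value} must have insertion_index 0"
            )
        if self.kind is VariantKind.DELETION:
            if self.observed != DELETION_MARKER:
                raise VariantParseError("deletion must carry the deletion marker")
        else:
            if self.observed not in IUPAC_CODES:
                raise VariantParseError(
                    f"observed base {self.observed!r} is not an IUPAC code"
                )

    @property
    def key(self) -> tuple[int, int]:
        return (self.position, self.insertion_index)

    def __str__(self) -> str:
        return format_variant(self)


def substitution(position: int, observed: str) -> VariantCall:
    return VariantCall(position, 0, observed.upper(), VariantKind.SUBSTITUTION)


def insertion(position: int, index: int, observed: str) -> VariantCall:
    return VariantCall(position, index, observed.upper(), VariantKind.INSERTION)


def deletion(position: int) -> VariantCall:
    return VariantCall(position, 0, DELETION_MARKER, VariantKind.DELETION)


def parse_variant_token(token: str) -> VariantCall:
    """Parse one difference-notation token into a :class:`VariantCall`.

    Accepted grammar: ``73G`` / ``16093Y`` (substitution, any IUPAC code),
    ``309.1C`` (insertion, index >= 1), ``249del`` or ``249-`` (deletion).
    Input is case-insensitive; ``format_variant`` restores the canonical
    form, and ``parse_variant_token(format_variant(v)) == v``.
    """
    stripped = token.strip()
    if not stripped:
        raise VariantParseError("empty variant token")
    m = _TOKEN_RE.match(stripped)
    if m is None:
        raise VariantParseError(f"malformed variant token {token!r}")
    pos = int(m.group("pos"))
    if pos < 1:
        raise VariantParseError(f"position 0 is invalid in token {token!r}")
    if m.group("del") is not None:
        return deletion(pos)
    if m.group("idx") is not None:
        idx = int(m.group("idx"))
        if idx < 1:
            raise VariantParseError(
                f"insertion index must be >= 1 in token {token!r}"
            )
        base = m.group("insbase").upper()
        if base not in IUPAC_CODES:
            raise VariantParseError(f"unknown base {base!r} in token {token!r}")
        return insertion(pos, idx, base)
    base = m.group("base").upper()
    if base not in IUPAC_CODES:
        raise VariantParseError(f"unknown base {base!r} in token {token!r}")
    return substitution(pos, base)


def format_variant(v: VariantCall) -> str:
    """Canonical text form; inverse of :func:`parse_variant_token`."""
    if v.kind is VariantKind.DELETION:
        return f"{v.position}del"
    if v.kind is VariantKind.INSERTION:
        return f"{v.position}.{v.insertion_index}{v.observed}"
    return f"{v.position}{v.observed}"


def canonical_order(variants: Iterable[VariantCall]) -> tuple[VariantCall, ...]:
    """Sort ascending by (position, insertion_index); reject duplicate keys."""
    ordered = tuple(sorted(variants))
    seen: dict[tuple[int, int], VariantCall] = {}
    for v in ordered:
        if v.key in seen:
            raise DuplicateKeyError(
                f"duplicate variant key {v.key}: {seen[v.key]} vs {v}"
            )
        seen[v.key] = v
    return ordered


def parse_ranges(text: str) -> tuple[tuple[int, int], ...]:
    """Parse ``"16024-16569;1-576"`` (also accepts ``,``) into range pairs."""
    out = []
    for part in re.split(r"[;,]", text):
        part = part.strip()
        if not part:
            continue
        m = re.match(r"^(\d+)\s*-\s*(\d+)$", part)
        if m is None:
            if part.isdigit():  # single position
                out.append((int(part), int(part)))
                continue
            raise MitoprofileError(f"malformed range {part!r}")
        out.append((int(m.group(1)), int(m.group(2))))
    return tuple(out)


def format_ranges(ranges: Sequence[tuple[int, int]]) -> str:
    return ";".join(f"{a}-{b}" for a, b in ranges)


def _validate_ranges(ranges: Sequence[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    norm = tuple((int(a), int(b)) for a, b in ranges)
    for a, b in norm:
        if a > b:
            raise MitoprofileError(f"range ({a},{b}) has start > end")
        if a < 1:
            raise MitoprofileError(f"range ({a},{b}) starts before position 1")
    by_start = sorted(norm)
    for (a1, b1), (a2, b2) in zip(by_start, by_start[1:]):
        if a2 <= b1:
            raise MitoprofileError(
                f"sequenced ranges overlap: ({a1},{b1}) and ({a2},{b2})"
            )
    return norm


@dataclass(frozen=True)
class Profile:
    """An ordered set of variant calls for one sample from one evaluator."""

    sample_id: str
    evaluator: str = ""
    source_program: SourceProgram | None = None
    variants: tuple[VariantCall, ...] = ()
    sequenced_ranges: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "variants", canonical_order(self.variants))
        if self.sequenced_ranges is not None:
            object.__setattr__(
                self, "sequenced_ranges", _validate_ranges(self.sequenced_ranges)
            )

    @property
    def keys(self) -> tuple[tuple[int, int], ...]:
        return tuple(v.key for v in self.variants)

    def tokens(self) -> tuple[str, ...]:
        return tuple(format_variant(v) for v in self.variants)

    def variant_map(self) -> dict[tuple[int, int], VariantCall]:
        return {v.key: v for v in self.variants}

    def with_variants(self, variants: Iterable[VariantCall]) -> "Profile":
        return replace(self, variants=tuple(variants))

    def __len__(self) -> int:
        return len(self.variants)


@dataclass
class SampleRecord:
    """One sample inside a project."""

    sample_id: str
    haplogroup: str | None = None
    tissue: Tissue | None = None
    validated_profile: Profile | None = None


@dataclass
class Project:
    """A typed container of samples; the type is immutable after creation."""

    name: str
    project_type: ProjectType
    samples: dict[str, SampleRecord] = field(default_factory=dict)

    def check_sample_id(self, sample_id: str) -> None:
        if self.project_type.requires_numeric_ids and not sample_id.isdigit():
            raise MitoprofileError(
                f"sample ID {sample_id!r} must be numeric in a "
                f"{self.project_type.value} project"
            )


def apply_profile(
    ref: ReferenceSequence,
    profile: Profile | Iterable[VariantCall],
    ranges: Sequence[tuple[int, int]],
) -> str:
    """Reconstruct the sample sequence over the given 1-based inclusive ranges.

    Substitutions replace the reference base, insertions are appended after
    their anchor position in insertion-index order, deleted positions are
    omitted.  Ranges are emitted in the order given and concatenated;
    variants outside every range are ignored.  A substitution whose observed
    base equals the reference base raises :class:`PhantomVariantWarning` but
    is still applied.
    """
    variants = profile.variants if isinstance(profile, Profile) else canonical_order(profile)
    subs: dict[int, str] = {}
    dels: set[int] = set()
    ins: dict[int, list[VariantCall]] = {}
    for v in variants:
        if v.position > ref.length:
            raise MitoprofileError(
                f"variant {format_variant(v)} beyond reference length {ref.length}"
            )
        if v.kind is VariantKind.SUBSTITUTION:
            if v.observed == ref.base_at(v.position):
                warnings.warn(
                    f"variant {format_variant(v)} equals the reference base "
                    f"(suspected phantom mutation)",
                    PhantomVariantWarning,
                    stacklevel=2,
                )
            subs[v.position] = v.observed
        elif v.kind is VariantKind.DELETION:
            dels.add(v.position)
        else:
            ins.setdefault(v.position, []).append(v)

    pieces: list[str] = []
    for start, end in ranges:
        if start > end:
            raise MitoprofileError(f"range ({start},{end}) has start > end")
        if start < 1 or end > ref.length:
            raise MitoprofileError(
                f"range ({start},{end}) outside reference [1, {ref.length}]"
            )
        for pos in range(start, end + 1):
            if pos not in dels:
                pieces.append(subs.get(pos, ref.residues[pos - 1]))
            for v in sorted(ins.get(pos, []), key=lambda x: x.insertion_index):
                pieces.append(v.observed)
    return "".join(pieces)


def diff_sequences(ref: ReferenceSequence, obs: str) -> set[VariantCall]:
    """Position-wise substitution diff of an equal-length observed sequence.

    The inverse of :func:`apply_profile` for substitution-only profiles;
    indel alignment is out of scope (upstream evaluation software aligns).
    """
    obs = obs.upper()
    if len(obs) != ref.length:
        raise MitoprofileError(
            f"observed length {len(obs)} != reference length {ref.length}"
        )
    return {
        substitution(i + 1, o)
        for i, (r, o) in enumerate(zip(ref.residues, obs))
        if r != o
    }
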