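"""Deterministic synthetic data: references, report pairs, phenotypes.

Every generator is a pure function of its seed and spec, so identical
inputs produce byte-identical files.  The generators emulate the study
conditions this tool is built for: each sample is evaluated twice by
independent scientists, a fraction of pairs disagree by exactly one edit,
and tumour projects carry paired benign/tumour profiles with a known
number of planted somatic gains and losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    IUPAC_CODES,
    Profile,
    ProjectType,
    ReferenceSequence,
    SourceProgram,
    VariantCall,
    VariantKind,
    deletion,
    insertion,
    substitution,
)
from .errors import MitoprofileError
from .report_io import write_report

__all__ = [
    "FixtureSpec",
    "generate_reference",
    "generate_profile",
    "generate_report_pair",
    "generate_phenotypes",
    "generate_tumour_pair",
    "write_demo_project",
]

_BASES = np.array(list("ACGT"))
#: Point-heteroplasmy codes occasionally used as observed bases.
_AMBIGUITY = tuple(sorted(IUPAC_CODES - set("ACGT")))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic project.

    Defaults model a small double-evaluation batch: 20 samples, 3-8
    variants each on a 1 kb reference, 20% of evaluator pairs discordant
    by exactly one edit.
    """

    seed: int = 0
    ref_length: int = 1000
    n_samples: int = 20
    variants_per_sample: tuple[int, int] = (3, 8)
    discordance_rate: float = 0.2
    project_type: ProjectType = ProjectType.POPULATION

    def __post_init__(self) -> None:
        if not 0.0 <= self.discordance_rate <= 1.0:
            raise MitoprofileError("discordance_rate must lie in [0, 1]")
        lo, hi = self.variants_per_sample
        if lo < 0 or hi < lo:
            raise MitoprofileError("variants_per_sample must be a valid range")

    def sample_ids(self) -> list[str]:
        if self.project_type.requires_numeric_ids:
            return [str(1000 + i) for i in range(self.n_samples)]
        return [f"S{i:03d}" for i in range(self.n_samples)]


def generate_reference(seed: int, length: int, name: str = "synthetic-ref") -> ReferenceSequence:
    """Uniform random A/C/G/T reference; deterministic per seed."""
    if length < 10:
        raise MitoprofileError(f"reference length must be >= 10, got {length}")
    rng = np.random.default_rng(seed)
    residues = "".join(rng.choice(_BASES, size=length))
    return ReferenceSequence(name=name, residues=residues)


def _random_variant(rng: np.random.Generator, ref: ReferenceSequence, position: int) -> VariantCall:
    """One random variant anchored at *position* (sub 80%, ins 10%, del 10%)."""
    draw = rng.random()
    if draw < 0.8:
        ref_base = ref.base_at(position)
        if rng.random() < 0.05:
            obs = str(rng.choice(_AMBIGUITY))  # point heteroplasmy
        else:
            obs = str(rng.choice([b for b in "ACGT" if b != ref_base]))
        return substitution(position, obs)
    if draw < 0.9:
        return insertion(position, 1, str(rng.choice(_BASES)))
    return deletion(position)


def generate_profile(
    rng: np.random.Generator,
    ref: ReferenceSequence,
    sample_id: str,
    n_variants: int,
    evaluator: str = "",
) -> Profile:
    positions = sorted(
        int(p) + 1
        for p in rng.choice(ref.length, size=min(n_variants, ref.length), replace=False)
    )
    variants = tuple(_random_variant(rng, ref, p) for p in positions)
    ranges = ((1, ref.length),) if rng.random() < 0.5 else None
    return Profile(
        sample_id=sample_id,
        evaluator=evaluator,
        variants=variants,
        sequenced_ranges=ranges,
    )


def _inject_edit(rng: np.random.Generator, ref: ReferenceSequence, profile: Profile) -> Profile:
    """Return a copy differing from *profile* by exactly one edit.

    The edit adds, drops, or base-changes one variant, modelling a real
    evaluator disagreement (missed call, extra call, or different
    heteroplasmy interpretation).
    """
    variants = list(profile.variants)
    choices = ["add"]
    if variants:
        choices += ["drop", "change"]
    action = str(rng.choice(choices))
    if action == "drop":
        variants.pop(int(rng.integers(len(variants))))
    elif action == "change":
        i = int(rng.integers(len(variants)))
        v = variants[i]
        if v.kind is VariantKind.SUBSTITUTION:
            new_base = str(rng.choice([b for b in "ACGTY" if b != v.observed]))
            variants[i] = substitution(v.position, new_base)
        else:
            variants.pop(i)  # indel interpretation dropped by the second reader
    else:
        taken = {v.key for v in variants}
        while True:
            pos = int(rng.integers(ref.length)) + 1
            if (pos, 0) not in taken:
                break
        variants.append(_random_variant(rng, ref, pos))
    return profile.with_variants(tuple(variants))


def generate_report_pair(
    spec: FixtureSpec,
    ref: ReferenceSequence,
    out_dir: str | Path,
) -> tuple[list[tuple[Path, Path]], dict[str, bool]]:
    """Write one pair of evaluator report files per sample.

    Evaluator A ("AB") holds a random profile; evaluator B ("CD") is
    identical with probability ``1 - discordance_rate``, otherwise it
    differs by one injected edit.  Dialects (.txt / .sqs) are assigned
    randomly per file; a sequenced range only survives in the sequencher
    dialect, mirroring that only Sequencher exports it.

    Returns the per-sample (file_a, file_b) paths and a map
    sample_id -> was-made-discordant (the planted truth).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.variants_per_sample
    pairs: list[tuple[Path, Path]] = []
    truth: dict[str, bool] = {}
    for sample_id in spec.sample_ids():
        n_var = int(rng.integers(lo, hi + 1))
        prof_a = generate_profile(rng, ref, sample_id, n_var, evaluator="AB")
        discordant = bool(rng.random() < spec.discordance_rate)
        prof_b = _inject_edit(rng, ref, prof_a) if discordant else prof_a
        prof_b = Profile(
            sample_id=sample_id,
            evaluator="CD",
            variants=prof_b.variants,
            sequenced_ranges=prof_a.sequenced_ranges,
        )
        ext_a = ".txt" if rng.random() < 0.5 else ".sqs"
        ext_b = ".txt" if rng.random() < 0.5 else ".sqs"
        file_a = write_report(out_dir / f"{sample_id}_AB{ext_a}", prof_a)
        file_b = write_report(out_dir / f"{sample_id}_CD{ext_b}", prof_b)
        pairs.append((file_a, file_b))
        truth[sample_id] = discordant
    return pairs, truth


def generate_phenotypes(
    seed: int,
    sample_ids: Sequence[str],
    columns: Sequence[str],
    id_column: str = "ID",
) -> pd.DataFrame:
    """One row per sample; numeric columns drawn from a seeded normal."""
    if not sample_ids:
        raise MitoprofileError("sample_ids must be non-empty")
    rng = np.random.default_rng(seed)
    data: dict[str, object] = {id_column: list(sample_ids)}
    for col in columns:
        data[col] = np.round(rng.normal(loc=25.0, scale=4.0, size=len(sample_ids)), 1)
    return pd.DataFrame(data)


def generate_tumour_pair(
    rng: np.random.Generator,
    ref: ReferenceSequence,
    sample_id: str,
    n_variants: int = 5,
    n_gains: int = 2,
    n_losses: int = 1,
) -> tuple[Profile, Profile, set[VariantCall], set[VariantCall]]:
    """A benign/tumour profile pair with planted somatic alterations.

    The tumour profile equals the benign one plus *n_gains* new variants
    and minus *n_losses* existing ones.  Returns (benign, tumour, gained,
    lost) so detection has known truth.
    """
    benign = generate_profile(rng, ref, sample_id, n_variants)
    n_losses = min(n_losses, len(benign.variants))
    loss_idx = set(
        int(i) for i in rng.choice(len(benign.variants), size=n_losses, replace=False)
    ) if n_losses else set()
    lost = {v for i, v in enumerate(benign.variants) if i in loss_idx}
    kept = [v for i, v in enumerate(benign.variants) if i not in loss_idx]
    taken = {v.key for v in benign.variants}
    gained: set[VariantCall] = set()
    while len(gained) < n_gains:
        pos = int(rng.integers(ref.length)) + 1
        if (pos, 0) in taken:
            continue
        taken.add((pos, 0))
        gained.add(_random_variant(rng, ref, pos))
    tumour = Profile(
        sample_id=sample_id,
        evaluator=benign.evaluator,
        variants=tuple(kept) + tuple(gained),
        sequenced_ranges=benign.sequenced_ranges,
    )
    return benign, tumour, gained, lost


def write_demo_project(seed: int, out_dir: str | Path, spec: FixtureSpec | None = None) -> dict:
    """Write a complete demo project: reference FASTA, report pairs, phenotypes.

    Used by the CLI ``fixtures`` subcommand; returns a manifest of what was
    written.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    spec = spec or FixtureSpec(seed=seed)
    if spec.seed != seed:
        spec = FixtureSpec(
            seed=seed,
            ref_length=spec.ref_length,
            n_samples=spec.n_samples,
            variants_per_sample=spec.variants_per_sample,
            discordance_rate=spec.discordance_rate,
            project_type=spec.project_type,
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref = generate_reference(spec.seed, spec.ref_length)
    ref_path = out_dir / "reference.fasta"
    SeqIO.write(
        [SeqRecord(Seq(ref.residues), id=ref.name, description="")],
        str(ref_path),
        "fasta",
    )
    pairs, truth = generate_report_pair(spec, ref, out_dir / "reports")
    pheno = generate_phenotypes(spec.seed, spec.sample_ids(), ["BMI", "AGE"])
    pheno_path = out_dir / "phenotypes.tsv"
    pheno.to_csv(pheno_path, sep="\t", index=False)
    return {
        "reference": ref_path,
        "reports": [p for pair in pairs for p in pair],
        "phenotypes": pheno_path,
        "discordant_truth": truth,
        "spec": spec,
    }
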