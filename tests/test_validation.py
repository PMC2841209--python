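"""Double-evaluation comparison and the validation workflow."""

import numpy as np
import pytest

from mitoprofile.core import Profile, ProjectType, substitution
from mitoprofile.errors import ComparisonError, MitoprofileError, StoreError
from mitoprofile.fixtures import FixtureSpec, generate_reference, generate_report_pair
from mitoprofile.report_io import MutationReportFile, read_report_batch
from mitoprofile.core import SourceProgram
from mitoprofile.validation import (
    ComparisonStatus,
    batch_validate,
    compare_profiles,
    validate_sample,
)


def _profile(sample_id, tokens, ranges=None):
    from mitoprofile.core import parse_variant_token

    return Profile(
        sample_id,
        variants=tuple(parse_variant_token(t) for t in tokens),
        sequenced_ranges=ranges,
    )


def _report(profile, evaluator="AB", ext=".txt"):
    return MutationReportFile(
        filename=f"{profile.sample_id}_{evaluator}{ext}",
        dialect=SourceProgram.SEQUENCHER,
        sample_id=profile.sample_id,
        evaluator=evaluator,
        profile=Profile(
            profile.sample_id,
            evaluator=evaluator,
            variants=profile.variants,
            sequenced_ranges=profile.sequenced_ranges,
        ),
    )


class TestCompareProfiles:
    def test_identical_profiles_concordant(self):
        a = _profile("7", ["73G", "263G"])
        report = compare_profiles(a, a)
        assert report.status is ComparisonStatus.CONCORDANT
        assert report.discordances == ()

    def test_one_sided_difference(self):
        a = _profile("7", ["73G", "263G"])
        b = _profile("7", ["73G"])
        report = compare_profiles(a, b)
        assert not report.concordant
        (d,) = report.discordances
        assert d.key == (263, 0) and d.in_a_only is not None and not d.conflicting

    def test_same_key_different_base_is_conflict(self):
        report = compare_profiles(_profile("7", ["16189C"]), _profile("7", ["16189Y"]))
        (d,) = report.discordances
        assert d.conflicting and d.key == (16189, 0)

    def test_sample_id_mismatch_is_error(self):
        with pytest.raises(ComparisonError):
            compare_profiles(_profile("7", []), _profile("8", []))

    def test_range_disagreement_is_a_note_not_a_discordance(self):
        a = _profile("7", ["73G"], ranges=((1, 500),))
        b = _profile("7", ["73G"], ranges=((1, 400),))
        report = compare_profiles(a, b)
        assert report.concordant and report.notes

    def test_symmetry_of_sides(self, random_profiles):
        rng = np.random.default_rng(8)
        for a in random_profiles[:10]:
            b = random_profiles[int(rng.integers(len(random_profiles)))]
            b = Profile(a.sample_id, variants=b.variants)
            fwd = compare_profiles(a, b)
            rev = compare_profiles(b, a)
            assert [d.swapped() for d in fwd.discordances] == list(rev.discordances)

    def test_self_comparison_always_concordant(self, random_profiles):
        for p in random_profiles:
            assert compare_profiles(p, p).concordant

    def test_count_matches_brute_force_set_oracle(self, random_profiles):
        """Discordance count equals the key-wise symmetric-difference oracle."""
        rng = np.random.default_rng(9)
        for a in random_profiles:
            b = random_profiles[int(rng.integers(len(random_profiles)))]
            b = Profile(a.sample_id, variants=b.variants)
            calls_a = {(v.key, v.observed, v.kind) for v in a.variants}
            calls_b = {(v.key, v.observed, v.kind) for v in b.variants}
            expected = len({k for k, _, _ in calls_a ^ calls_b})
            assert len(compare_profiles(a, b).discordances) == expected


class TestValidateSample:
    def test_concordant_pair_stored_automatically(self, frozen_store):
        frozen_store.create_project("P", "population")
        a, b = _report(_profile("7", ["73G"]), "AB"), _report(_profile("7", ["73G"]), "CD")
        result = validate_sample(frozen_store, "P", "7", [a, b], employee="Anita")
        assert result.status == "validated"
        stored = frozen_store.get_validated_profile("P", "7")
        assert stored.tokens() == ("73G",)

    def test_first_evaluator_file_is_the_one_stored(self, frozen_store):
        frozen_store.create_project("P", "population")
        a = _report(_profile("7", ["73G"]), "CD")
        b = _report(_profile("7", ["73G"]), "AB")
        validate_sample(frozen_store, "P", "7", [a, b])
        assert frozen_store.get_validated_profile("P", "7").evaluator == "AB"

    def test_discordant_pair_without_resolution_stays_pending(self, frozen_store):
        frozen_store.create_project("P", "population")
        a, b = _report(_profile("7", ["73G"]), "AB"), _report(_profile("7", ["73A"]), "CD")
        result = validate_sample(frozen_store, "P", "7", [a, b])
        assert result.status == "pending"
        assert result.report is not None and not result.report.concordant
        assert frozen_store.get_validated_profile("P", "7") is None

    def test_resolution_picks_b(self, frozen_store):
        frozen_store.create_project("P", "population")
        a, b = _report(_profile("7", ["73G"]), "AB"), _report(_profile("7", ["73A"]), "CD")
        result = validate_sample(frozen_store, "P", "7", [a, b], resolution="B")
        assert result.status == "validated"
        assert frozen_store.get_validated_profile("P", "7").tokens() == ("73A",)

    def test_third_evaluation_chosen_by_filename(self, frozen_store):
        frozen_store.create_project("P", "population")
        reports = [
            _report(_profile("7", ["73G"]), "AB"),
            _report(_profile("7", ["73A"]), "CD"),
            _report(_profile("7", ["73G", "263G"]), "EF"),
        ]
        result = validate_sample(
            frozen_store, "P", "7", reports, resolution="7_EF.txt"
        )
        assert frozen_store.get_validated_profile("P", "7").tokens() == ("73G", "263G")
        assert result.status == "validated"

    def test_resolution_naming_unknown_report_is_error(self, frozen_store):
        frozen_store.create_project("P", "population")
        a, b = _report(_profile("7", ["73G"]), "AB"), _report(_profile("7", ["73A"]), "CD")
        with pytest.raises(MitoprofileError, match="resolution"):
            validate_sample(frozen_store, "P", "7", [a, b], resolution="nope.txt")

    def test_revalidation_without_force_is_error(self, frozen_store):
        frozen_store.create_project("P", "population")
        pair = [_report(_profile("7", ["73G"]), "AB"), _report(_profile("7", ["73G"]), "CD")]
        validate_sample(frozen_store, "P", "7", pair)
        with pytest.raises(StoreError):
            validate_sample(frozen_store, "P", "7", pair)
        validate_sample(frozen_store, "P", "7", pair, force=True)

    def test_single_report_pending_with_reason(self, frozen_store):
        frozen_store.create_project("P", "population")
        result = validate_sample(
            frozen_store, "P", "7", [_report(_profile("7", ["73G"]))]
        )
        assert result.status == "pending"
        assert result.reason == "missing second evaluation"

    def test_storage_writes_history(self, frozen_store):
        frozen_store.create_project("P", "population")
        before = frozen_store.history_length()
        pair = [_report(_profile("7", ["73G"]), "AB"), _report(_profile("7", ["73G"]), "CD")]
        validate_sample(frozen_store, "P", "7", pair, employee="Anita")
        entries = frozen_store.query_history(project="P", employee="Anita")
        assert frozen_store.history_length() > before
        assert any("Validated profile: 7" in e.location for e in entries)


class TestBatchValidate:
    def _run_batch(self, store, seed, rate, tmp_path, n=20):
        spec = FixtureSpec(seed=seed, n_samples=n, discordance_rate=rate)
        ref = generate_reference(seed, spec.ref_length)
        pairs, _ = generate_report_pair(spec, ref, tmp_path)
        grouped = read_report_batch([p for ab in pairs for p in ab], spec.project_type)
        return batch_validate(store, "P", grouped)

    def test_zero_rate_validates_everything(self, frozen_store, tmp_path):
        frozen_store.create_project("P", "population")
        summary = self._run_batch(frozen_store, 3, 0.0, tmp_path)
        assert (summary.n_validated, summary.n_pending) == (20, 0)

    def test_full_rate_leaves_everything_pending(self, frozen_store, tmp_path):
        frozen_store.create_project("P", "population")
        summary = self._run_batch(frozen_store, 3, 1.0, tmp_path)
        assert (summary.n_validated, summary.n_pending) == (0, 20)

    def test_mixed_rate_counts_are_reproducible(self, tmp_path):
        from mitoprofile.store import Store

        counts = []
        for run in range(2):
            store = Store(":memory:")
            store.create_project("P", "population")
            summary = self._run_batch(store, 7, 0.5, tmp_path / str(run))
            counts.append((summary.n_validated, summary.n_pending))
            store.close()
        assert counts[0] == counts[1]
        assert counts[0][0] + counts[0][1] == 20

    def test_counts_partition_the_samples(self, frozen_store, tmp_path):
        frozen_store.create_project("P", "population")
        summary = self._run_batch(frozen_store, 5, 0.3, tmp_path)
        assert summary.n_validated + summary.n_pending == len(summary.results) == 20
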