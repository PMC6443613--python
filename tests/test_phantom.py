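"""Synthetic cohort generator: construction guarantees and reproducibility."""

import numpy as np
import pytest

from myotriage import CohortSpec, StenosisGrade, generate_cohort, reference_label
from myotriage.phantom import (
    PhantomParams,
    assign_physiology,
    generate_phantom_volume,
    sample_phantom_params,
)


def _spec(**kw):
    base = dict(n_patients=4, seed=3)
    base.update(kw)
    return CohortSpec(**base)


class TestPhantomVolume:
    def test_zero_effect_makes_label_irrelevant(self):
        spec = _spec(effect_size=0.0)
        params = sample_phantom_params(5, spec)
        v_pos, m_pos = generate_phantom_volume(params, True, spec)
        v_neg, m_neg = generate_phantom_volume(params, False, spec)
        assert np.array_equal(v_pos, v_neg)
        assert np.array_equal(m_pos, m_neg)

    def test_noiseless_nonlesion_intensity_is_exact(self):
        spec = _spec(noise_sd=0.0)
        params = sample_phantom_params(5, spec)
        vol, mask = generate_phantom_volume(params, False, spec)
        assert vol[mask > 0].mean() == pytest.approx(params.myocardium_hu)
        # positive phantom: voxels outside the lesion sector keep the exact level
        vol_p, _ = generate_phantom_volume(params, True, spec)
        untouched = (vol_p == vol) & (mask > 0)
        assert untouched.sum() > 0
        assert vol_p[untouched].mean() == pytest.approx(params.myocardium_hu)

    def test_voxelized_shell_volume_matches_analytic(self):
        """Voxel count x voxel volume within 10% of the closed-form
        ellipsoidal-shell volume at 1 mm isotropic spacing."""
        spec = _spec()
        params = sample_phantom_params(5, spec)
        _, mask = generate_phantom_volume(params, False, spec)
        a = np.array(params.axes)
        inner = a - params.thickness
        analytic = 4.0 / 3.0 * np.pi * (np.prod(a) - np.prod(inner))
        voxel = float(mask.sum()) * np.prod(spec.voxel_spacing)
        assert abs(voxel - analytic) / analytic < 0.10

    def test_shell_must_fit_in_grid(self):
        spec = _spec(grid_shape=(8, 8, 8))
        params = PhantomParams(center=(4, 4, 4), axes=(6, 6, 6), thickness=2.0)
        with pytest.raises(ValueError, match="does not fit"):
            generate_phantom_volume(params, False, spec)

    def test_identical_seed_is_bit_identical(self):
        spec = _spec()
        params = sample_phantom_params(9, spec)
        v1, _ = generate_phantom_volume(params, True, spec)
        v2, _ = generate_phantom_volume(params, True, spec)
        assert np.array_equal(v1, v2)

    def test_mean_masked_hu_strictly_decreases_with_effect_size(self):
        params = sample_phantom_params(5, _spec())
        means = []
        for effect in (0.0, 20.0, 40.0, 60.0):
            vol, mask = generate_phantom_volume(
                params, True, _spec(effect_size=effect)
            )
            means.append(vol[mask > 0].mean())
        assert all(a > b for a, b in zip(means, means[1:]))


class TestPhysiology:
    def test_negative_label_never_meets_reference_rule(self):
        for seed in range(50):
            ffr, ica = assign_physiology(False, [StenosisGrade.G3], seed)
            assert all(v > 0.80 for v in ffr if v is not None)
            assert all(v < 90.0 for v in ica if v is not None)

    def test_positive_majority_path_has_low_ffr(self):
        ffr, ica = assign_physiology(
            True, [StenosisGrade.G2, StenosisGrade.G3], seed=4, ffr_path_prob=1.0
        )
        assert min(v for v in ffr if v is not None) <= 0.80

    def test_ffr_path_fraction_within_binomial_bounds(self):
        """Over 1000 seeded positives the FFR-path fraction stays inside the
        99% binomial interval around the configured 0.85."""
        n = 1000
        hits = 0
        for seed in range(n):
            ffr, _ = assign_physiology(True, [StenosisGrade.G3], seed)
            hits += any(v is not None and v <= 0.80 for v in ffr)
        half_width = 2.576 * np.sqrt(0.85 * 0.15 / n)
        assert abs(hits / n - 0.85) < half_width

    def test_requires_at_least_one_vessel(self):
        with pytest.raises(ValueError):
            assign_physiology(True, [], seed=0)


class TestCohort:
    def test_empty_cohort_writes_nothing(self, tmp_path):
        cohort = generate_cohort(_spec(n_patients=0), out_dir=tmp_path / "c")
        assert cohort.records == []
        assert not (tmp_path / "c").exists()

    def test_category_counts_and_prevalence_met_exactly(self):
        spec = CohortSpec(
            n_patients=126,
            prevalence=81 / 126,
            category_counts=(2, 8, 10, 91, 15),
            seed=2,
        )
        cohort = generate_cohort(spec, keep_volumes=False)
        cats = np.array([r.max_grade.ordinal for r in cohort.records])
        assert [int((cats == c).sum()) for c in range(5)] == [2, 8, 10, 91, 15]
        labels = [r.true_label for r in cohort.records]
        assert sum(labels) == 81
        # no positives below 25% DS
        for rec in cohort.records:
            if rec.max_grade.ordinal <= 1:
                assert not rec.true_label

    def test_same_seed_gives_byte_identical_table(self, tmp_path):
        spec = _spec(n_patients=5)
        generate_cohort(spec, out_dir=tmp_path / "a", keep_volumes=False)
        generate_cohort(spec, out_dir=tmp_path / "b", keep_volumes=False)
        assert (tmp_path / "a" / "cohort.csv").read_bytes() == (
            tmp_path / "b" / "cohort.csv"
        ).read_bytes()

    def test_reference_label_recovers_true_label(self):
        cohort = generate_cohort(_spec(n_patients=30, seed=8), keep_volumes=False)
        for rec in cohort.records:
            assert reference_label(rec) == rec.true_label

    def test_inconsistent_spec_rejected_before_files(self, tmp_path):
        with pytest.raises(ValueError, match="category_counts"):
            CohortSpec(n_patients=10, category_counts=(1, 1, 1, 1, 1))
        assert not any(tmp_path.iterdir())

    def test_lesion_separates_masked_means_at_high_effect(self):
        spec = CohortSpec(n_patients=20, prevalence=0.5, effect_size=60, seed=4)
        cohort = generate_cohort(spec)
        pos = [
            v[m > 0].mean()
            for v, m, r in zip(cohort.volumes, cohort.masks, cohort.records)
            if r.true_label
        ]
        neg = [
            v[m > 0].mean()
            for v, m, r in zip(cohort.volumes, cohort.masks, cohort.records)
            if not r.true_label
        ]
        assert np.mean(pos) < np.mean(neg) - 5.0
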