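import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import octadme as od


def _binarized_vpd(img):
    return od.vascular_perfusion_density(od.binarize(img, od.otsu_threshold(img)))


class TestGenerateAngiogram:
    def test_deterministic_for_fixed_seed(self):
        p = od.VesselSimParams(image_size=128, rng_seed=42, cyst_count=3)
        a = od.generate_angiogram(p)
        b = od.generate_angiogram(p)
        assert np.array_equal(a.intensities, b.intensities)

    def test_calibrated_vpd_near_target(self):
        p = od.VesselSimParams(cyst_count=0, target_vpd=0.36, rng_seed=1)
        img = od.generate_angiogram(p)
        assert 0.31 <= _binarized_vpd(img) <= 0.41

    def test_cysts_reduce_vpd_and_raise_lac(self):
        base = od.VesselSimParams(target_vpd=0.36, rng_seed=2, cyst_count=0)
        with_cysts = od.VesselSimParams(target_vpd=0.36, rng_seed=2, cyst_count=8)
        img0, img8 = od.generate_angiogram(base), od.generate_angiogram(with_cysts)
        m0 = od.binarize(img0, od.otsu_threshold(img0))
        m8 = od.binarize(img8, od.otsu_threshold(img8))
        assert od.vascular_perfusion_density(m8) < od.vascular_perfusion_density(m0)
        lac0 = od.lacunarity(od.skeletonize(m0)).lac
        lac8 = od.lacunarity(od.skeletonize(m8)).lac
        assert lac8 > lac0

    def test_vpd_monotone_in_cyst_count(self):
        vpds = []
        for k in (0, 4, 8, 12):
            p = od.VesselSimParams(image_size=128, target_vpd=0.33,
                                   rng_seed=9, cyst_count=k,
                                   cyst_radius_range=(6.0, 14.0))
            vpds.append(_binarized_vpd(od.generate_angiogram(p)))
        assert all(a >= b for a, b in zip(vpds, vpds[1:]))

    def test_unreachable_target_raises_calibration_error(self):
        # a single trunk already overshoots a near-zero density target
        p = od.VesselSimParams(image_size=64, target_vpd=0.02, rng_seed=0,
                               cyst_radius_range=(4.0, 8.0))
        with pytest.raises(od.CalibrationError, match="achieved"):
            od.generate_angiogram(p)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            od.VesselSimParams(image_size=32)
        with pytest.raises(ValueError):
            od.VesselSimParams(target_vpd=1.5)
        with pytest.raises(ValueError):
            od.VesselSimParams(image_size=64, cyst_radius_range=(4.0, 40.0))


class TestGenerateCohort:
    def test_deterministic_for_fixed_seed(self):
        p = od.CohortSimParams(n_eyes=50, rng_seed=5)
        a, b = od.generate_cohort(p), od.generate_cohort(p)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_noise_final_bcva_equals_leaf_values(self):
        p = od.CohortSimParams(n_eyes=2000, outcome_noise_sd=0.0, rng_seed=1)
        table = od.generate_cohort(p)
        expected = np.array([p.leaf_values[b] for b in table.true_branch])
        assert np.array_equal(table.bcva_final.to_numpy(), expected)

    def test_baseline_bcva_mean_matches_published(self):
        p = od.CohortSimParams(n_eyes=10000, rng_seed=7)
        table = od.generate_cohort(p)
        se = 12.73 / np.sqrt(10000)
        assert abs(table.bcva_baseline.mean() - 64.77) <= 2 * se

    def test_thick_cmt_fraction_matches_normal_cdf(self):
        p = od.CohortSimParams(n_eyes=10000, rng_seed=7)
        table = od.generate_cohort(p)
        p_norm = sps.norm.sf(373, loc=420.9, scale=103.7)
        se = np.sqrt(p_norm * (1 - p_norm) / 10000)
        assert abs((table.cmt_baseline >= 373).mean() - p_norm) <= 3 * se

    def test_covariates_respect_truncation_bounds(self):
        table = od.generate_cohort(od.CohortSimParams(n_eyes=3000, rng_seed=2))
        assert table.bcva_baseline.between(0, 100).all()
        assert table.cmt_baseline.between(150, 900).all()
        assert table.lac_dcp.between(0, 1.5).all()
        assert table.bcva_final.between(0, 100).all()

    def test_unset_leaf_value_raises_naming_branch(self):
        p = od.CohortSimParams(
            n_eyes=200, rng_seed=3,
            leaf_values={**od.simulate.DEFAULT_LEAF_VALUES, "vma_present": None},
            vma_prevalence=0.5,
        )
        with pytest.raises(ValueError, match="vma_present"):
            od.generate_cohort(p)

    def test_branch_probabilities_sum_to_one(self):
        probs = od.branch_probabilities(od.CohortSimParams())
        assert sum(probs.values()) == pytest.approx(1.0)

    def test_noise_sd_solves_signal_fraction(self):
        p = od.CohortSimParams()
        sd = od.noise_sd_for_signal_fraction(p, 0.81)
        probs = od.branch_probabilities(p)
        vals = np.array([p.leaf_values[k] for k in od.BRANCHES])
        pr = np.array([probs[k] for k in od.BRANCHES])
        var_s = pr @ (vals - pr @ vals) ** 2
        assert var_s / (var_s + sd**2) == pytest.approx(0.81)


class TestReferenceCohort:
    # the 14 published marginal counts the fixture must reproduce
    EXPECTED_COUNTS = {
        "microaneurysms": 48,
        "irma": 49,
        "neovascularization": 22,
        "macular_cysts": 63,
        "subretinal_fluid": 16,
        "hard_exudates": 22,
        "ez_alteration": 45,
        "macular_cysts_m12": 31,
        "subretinal_fluid_m12": 4,
        "hard_exudates_m12": 9,
        "ez_alteration_m12": 29,
    }

    def test_all_flag_margins_exact(self, reference_cohort):
        for col, expected in self.EXPECTED_COUNTS.items():
            assert reference_cohort[col].sum() == expected, col

    def test_outcome_strata_exact(self, reference_cohort):
        thick = reference_cohort.cmt_baseline >= 373
        assert thick.sum() == 36
        assert (thick & (reference_cohort.lac_dcp >= 0.41)).sum() == 10
        assert (thick & (reference_cohort.lac_dcp < 0.41)).sum() == 26

    def test_leaf_bcva_values(self, reference_cohort):
        thick = reference_cohort.cmt_baseline >= 373
        high = thick & (reference_cohort.lac_dcp >= 0.41)
        low = thick & (reference_cohort.lac_dcp < 0.41)
        assert (reference_cohort.loc[high, "bcva_final"] == 65).all()
        assert (reference_cohort.loc[low, "bcva_final"] == 73).all()

    def test_thick_cmt_mean_final_bcva(self, reference_cohort):
        thick = reference_cohort.cmt_baseline >= 373
        mean = reference_cohort.loc[thick, "bcva_final"].mean()
        assert mean == pytest.approx((10 * 65 + 26 * 73) / 36)
        assert round(mean) == 71

    def test_cohort_shape_and_validity(self, reference_cohort):
        assert len(reference_cohort) == 66
        assert reference_cohort.patient_id.nunique() == 62
        od.validate_cohort(reference_cohort)
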