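import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from illposed.synthetic_cohort import (
    DEFAULT_MASK_RATIOS,
    DEFAULT_THRESHOLDS,
    CohortConfig,
    ConfigurationError,
    VolumeGrid,
    _brain_region,
    default_effect_region,
    load_cohort,
    make_template,
    save_cohort,
    simulate_cohort,
    simulate_subject,
)
from illposed.template_masking import threshold_mask


class TestVolumeGrid:
    def test_small_dims_rejected(self):
        with pytest.raises(ConfigurationError):
            VolumeGrid(dims=(4, 16, 16))

    def test_nonpositive_voxel_size_rejected(self):
        with pytest.raises(ConfigurationError):
            VolumeGrid(dims=(16, 16, 16), voxel_size_mm=(0.0, 4.0, 4.0))


class TestMakeTemplate:
    def test_default_ratios_nested_increasing_counts(self):
        grid = VolumeGrid(dims=(32, 32, 32))
        tmpl = make_template(grid, seed=7)
        counts = [threshold_mask(tmpl, t).voxel_count for t in DEFAULT_THRESHOLDS]
        assert counts == sorted(counts)
        assert len(set(counts)) == 4

    def test_mask_sizes_within_ten_percent_of_targets(self):
        grid = VolumeGrid(dims=(32, 32, 32))
        tmpl = make_template(grid, seed=7)
        n_brain = int(_brain_region(grid).sum())
        for t, ratio in zip(DEFAULT_THRESHOLDS, DEFAULT_MASK_RATIOS):
            count = threshold_mask(tmpl, t).voxel_count
            target = ratio * n_brain
            assert abs(count - target) <= 0.10 * target

    def test_deterministic_for_fixed_seed(self, grid16):
        a = make_template(grid16, seed=5)
        b = make_template(grid16, seed=5)
        assert np.array_equal(a.values, b.values)

    def test_low_threshold_mask_contains_high_threshold_mask(self, template16):
        hi = threshold_mask(template16, 0.86)
        lo = threshold_mask(template16, 0.0021)
        assert lo.contains(hi)

    def test_nonincreasing_ratios_rejected(self, grid16):
        with pytest.raises(ConfigurationError):
            make_template(grid16, mask_size_ratios=(0.3, 0.2, 0.5, 0.9))

    def test_infeasible_largest_ratio_rejected(self, grid16):
        with pytest.raises(ConfigurationError):
            make_template(grid16, mask_size_ratios=(0.1, 0.2, 0.5, 1.5))

    @given(
        t_hi=st.floats(min_value=0.0, max_value=1.0),
        t_lo=st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_nesting_property(self, t_hi, t_lo):
        # masks are nested under any threshold ordering
        tmpl = TestMakeTemplate._tmpl
        if t_hi < t_lo:
            t_hi, t_lo = t_lo, t_hi
        hi = tmpl.values > t_hi
        lo = tmpl.values > t_lo
        assert np.all(lo[hi])

    _tmpl = make_template(VolumeGrid(dims=(16, 16, 16)), seed=3)


class TestSimulateSubject:
    def test_null_effect_classes_identical(self, template16, effect_region16):
        cfg = CohortConfig(
            n_cn=2, n_ad=2, effect_region=effect_region16, effect_size=0.0, seed=0
        )
        cn = simulate_subject(template16, cfg, "CN", seed=9)
        ad = simulate_subject(template16, cfg, "AD", seed=9)
        assert np.array_equal(cn.values, ad.values)

    def test_noiseless_effect_is_exact_indicator(self, template16, effect_region16):
        cfg = CohortConfig(
            n_cn=2, n_ad=2, effect_region=effect_region16,
            effect_size=1.0, noise_sd=0.0, seed=0,
        )
        cn = simulate_subject(template16, cfg, "CN", seed=4)
        ad = simulate_subject(template16, cfg, "AD", seed=4)
        diff = ad.values - cn.values
        region = np.array(sorted(effect_region16))
        on = tuple(region.T)
        off = np.ones(template16.grid.dims, bool)
        off[on] = False
        assert np.all(diff[off] == 0)
        # baseline here is < 1, so the unit effect is clipped at zero:
        # the realized difference equals minus the baseline
        np.testing.assert_allclose(diff[on], -cn.values[on])

    def test_noiseless_effect_unclipped_region(self):
        # a template whose core sits at 1.0 + no noise: difference exactly -1
        grid = VolumeGrid(dims=(8, 8, 8))
        values = np.ones(grid.dims)
        from illposed.synthetic_cohort import ProbabilityTemplate

        tmpl = ProbabilityTemplate(grid=grid, values=values)
        region = frozenset({(4, 4, 4), (4, 4, 5)})
        cfg = CohortConfig(n_cn=2, n_ad=2, effect_region=region, effect_size=1.0, noise_sd=0.0)
        cn = simulate_subject(tmpl, cfg, "CN", seed=0)
        ad = simulate_subject(tmpl, cfg, "AD", seed=0)
        diff = ad.values - cn.values
        assert diff[4, 4, 4] == -1.0 and diff[4, 4, 5] == -1.0
        assert np.count_nonzero(diff) == 2

    def test_effect_detectable_by_t_test(self, template16, effect_region16):
        cfg = CohortConfig(
            n_cn=100, n_ad=100, effect_region=effect_region16,
            effect_size=1.0, noise_sd=1.0, smoothing_fwhm_vox=1.0, seed=77,
        )
        cohort = simulate_cohort(template16, cfg)
        center = sorted(effect_region16)[len(effect_region16) // 2]
        cn = [v.values[center] for v in cohort if v.label == "CN"]
        ad = [v.values[center] for v in cohort if v.label == "AD"]
        _, p = stats.ttest_ind(cn, ad)
        assert p < 0.01


class TestSimulateCohort:
    def test_counts(self, cohort16, cohort_cfg16):
        assert len(cohort16) == cohort_cfg16.n_cn + cohort_cfg16.n_ad
        assert sum(v.label == "CN" for v in cohort16) == cohort_cfg16.n_cn

    def test_bit_identical_reruns(self, template16, cohort_cfg16, cohort16):
        again = simulate_cohort(template16, cohort_cfg16)
        for a, b in zip(cohort16, again):
            assert a.subject_id == b.subject_id
            assert a.values.tobytes() == b.values.tobytes()

    def test_smoothing_increases_lag1_autocorrelation(self, template16, effect_region16):
        def lag1(cfg):
            noise = []
            for v in simulate_cohort(template16, cfg)[:10]:
                resid = v.values - np.clip(template16.values, 0, None)
                noise.append(resid)
            r = np.concatenate([n.ravel() for n in noise])
            s = np.concatenate([n[1:].ravel() for n in noise])
            t = np.concatenate([n[:-1].ravel() for n in noise])
            return np.corrcoef(s, t)[0, 1]

        base = dict(n_cn=10, n_ad=10, effect_region=effect_region16,
                    effect_size=0.0, noise_sd=0.3, seed=5)
        rho_smooth = lag1(CohortConfig(smoothing_fwhm_vox=2.0, **base))
        rho_raw = lag1(CohortConfig(smoothing_fwhm_vox=0.0, **base))
        assert rho_smooth > rho_raw + 0.2

    def test_no_class_difference_off_region(self, template16, effect_region16):
        cfg = CohortConfig(
            n_cn=250, n_ad=250, effect_region=effect_region16,
            effect_size=1.0, noise_sd=0.5, smoothing_fwhm_vox=0.0, seed=21,
        )
        cohort = simulate_cohort(template16, cfg)
        # pick an off-region voxel well inside the brain
        mask = threshold_mask(template16, 0.65)
        region = set(effect_region16)
        off = next(tuple(c) for c in mask.voxel_index_map if tuple(c) not in region)
        cn = np.array([v.values[off] for v in cohort if v.label == "CN"])
        ad = np.array([v.values[off] for v in cohort if v.label == "AD"])
        se = np.sqrt(cn.var(ddof=1) / len(cn) + ad.var(ddof=1) / len(ad))
        assert abs(cn.mean() - ad.mean()) < 3 * se

    def test_effect_region_outside_core_rejected(self, template16):
        bad = frozenset({(0, 0, 0)})  # corner is outside the brain
        cfg = CohortConfig(n_cn=2, n_ad=2, effect_region=bad, seed=0)
        with pytest.raises(ConfigurationError):
            simulate_cohort(template16, cfg)


class TestDefaultEffectRegion:
    def test_region_survives_all_thresholds(self, template16, effect_region16):
        for t in DEFAULT_THRESHOLDS:
            mask = threshold_mask(template16, t)
            flags = mask.flags
            assert all(flags[v] for v in effect_region16)


class TestCohortIO:
    def test_nifti_roundtrip(self, tmp_path, template16, cohort_cfg16, cohort16):
        save_cohort(cohort16[:4], tmp_path)
        back = load_cohort(tmp_path)
        assert len(back) == 4
        for a, b in zip(cohort16[:4], back):
            assert a.subject_id == b.subject_id
            assert a.label == b.label
            np.testing.assert_allclose(a.values, b.values, rtol=1e-6)
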