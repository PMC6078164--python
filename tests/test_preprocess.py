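"""Expression threshold, detrending, TMT and metabolomics preprocessing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from circaomics.core import FeatureMatrix, TimeGrid
from circaomics.preprocess import (
    TMTSetLayout,
    apply_expression_filter,
    assemble_tmt_timecourse,
    delta_ct_quantify,
    fit_expression_threshold,
    linear_detrend,
    linear_detrend_profile,
    normalize_tmt_channels,
    qc_cv_filter,
    rt_window_filter,
    sample_normalize_logratio,
)


def _matrix(values, grid=None, **kw):
    values = np.atleast_2d(values)
    grid = grid or TimeGrid.regular(24, 24 + 3 * (values.shape[1] - 1), 3)
    data = pd.DataFrame(values, index=[f"f{i}" for i in range(values.shape[0])],
                        columns=grid.column_names())
    return FeatureMatrix(data, grid, **kw)


class TestExpressionThreshold:
    def test_recovers_low_component_quantile(self):
        # closed-form oracle: 0.95 quantile of the generating low
        # component, Normal(-1, 0.5) in log10, is 10**(-1 + 1.645*0.5)
        rng = np.random.default_rng(0)
        low = 10 ** rng.normal(-1.0, 0.5, 5000)
        high = 10 ** rng.normal(1.5, 0.7, 5000)
        expected = 10 ** stats.norm.ppf(0.95, -1.0, 0.5)
        thr = fit_expression_threshold(np.concatenate([low, high]), 0.95)
        assert thr.threshold_linear == pytest.approx(expected, rel=0.15)
        assert thr.means_log10[0] < thr.means_log10[1]

    def test_single_cluster_degenerates_to_sample_quantile(self):
        # on a single Gaussian cluster EM splits it into two overlapping
        # halves; the low component's 0.95 quantile still lands in the
        # cluster's upper tail, near the sample quantile on the log scale
        rng = np.random.default_rng(1)
        x = 10 ** rng.normal(0.5, 0.3, 4000)
        thr = fit_expression_threshold(x, 0.95)
        sample_q = np.quantile(x, 0.95)
        assert abs(np.log10(thr.threshold_linear) - np.log10(sample_q)) < 0.2

    def test_zeros_excluded_and_minimum_size(self):
        with pytest.raises(ValueError):
            fit_expression_threshold(np.zeros(100))
        with pytest.raises(ValueError):
            fit_expression_threshold(np.ones(10))

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        x = 10 ** np.concatenate([rng.normal(-1, 0.5, 500),
                                  rng.normal(1.5, 0.7, 500)])
        a = fit_expression_threshold(x, seed=0)
        b = fit_expression_threshold(x, seed=0)
        assert a.threshold_linear == b.threshold_linear


class TestExpressionFilter:
    def test_boundary_is_inclusive(self):
        m = _matrix(np.array([[1.0] * 20, [0.999] * 20]))
        kept = apply_expression_filter(m, 1.0)
        assert list(kept.feature_ids) == ["f0"]

    def test_all_below_gives_empty(self):
        m = _matrix(np.full((3, 20), 0.1))
        kept = apply_expression_filter(m, 5.0)
        assert kept.n_features == 0

    def test_retained_fraction_matches_component_weight(self):
        from circaomics.simulate import SimulationConfig, simulate_layer

        cfg = SimulationConfig(n_features=5000, fraction_rhythmic=0.0, seed=3)
        matrix, _ = simulate_layer(cfg)
        thr = fit_expression_threshold(np.nanmean(matrix.values(), axis=1))
        kept = apply_expression_filter(matrix, thr)
        frac = kept.n_features / matrix.n_features
        # expressed-component weight 0.6, minus the 5% of the low
        # component above its 0.95 quantile retained by construction
        assert frac == pytest.approx(0.6 + 0.4 * 0.05, abs=0.03)


class TestDetrend:
    def test_pure_line_maps_to_zero(self):
        t = np.arange(24, 84, 3.0)
        out = linear_detrend_profile(2 + 0.5 * t, t)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_idempotent(self):
        t = np.arange(24, 84, 3.0)
        y = np.cos(2 * np.pi * t / 24) + 0.1 * t
        once = linear_detrend_profile(y, t)
        twice = linear_detrend_profile(once, t)
        np.testing.assert_allclose(once, twice, atol=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.lists(st.floats(-100, 100), min_size=6, max_size=30))
    def test_residuals_orthogonal_to_design(self, values):
        y = np.asarray(values)
        t = 3.0 * np.arange(len(y)) + 24
        r = linear_detrend_profile(y, t)
        scale = max(1.0, np.abs(y).max()) * len(y)
        assert abs(r.sum()) / scale < 1e-8
        assert abs((r * t).sum()) / (scale * t.max()) < 1e-8

    def test_missing_values_preserved(self):
        t = np.arange(24, 54, 3.0)
        y = 1.0 + 0.2 * t
        y[3] = np.nan
        out = linear_detrend_profile(y, t)
        assert np.isnan(out[3])
        np.testing.assert_allclose(np.delete(out, 3), 0.0, atol=1e-10)

    def test_matrix_detrend_matches_per_profile(self):
        rng = np.random.default_rng(4)
        m = _matrix(rng.normal(size=(5, 20)))
        det = linear_detrend(m)
        t = m.grid.time_array()
        for i in range(5):
            np.testing.assert_allclose(
                det.values()[i], linear_detrend_profile(m.values()[i], t),
                atol=1e-10)

    def test_all_missing_errors(self):
        t = np.arange(24, 36, 3.0)
        with pytest.raises(ValueError):
            linear_detrend_profile(np.full(4, np.nan), t)


class TestTMT:
    def _layout(self, n=4, ref=True):
        channels = (("ref",) if ref else ()) + tuple(f"CT{24 + 3 * i}_r1"
                                                     for i in range(n))
        return TMTSetLayout("set1", channels, "ref" if ref else None)

    def test_affine_bias_removed(self):
        # noiseless construction: every channel reports the protein's
        # abundance exactly, then one channel gets a known log-affine bias
        rng = np.random.default_rng(5)
        protein_log = rng.normal(10, 1.5, size=(200, 1))
        true_log = np.repeat(protein_log, 5, axis=1)
        layout = self._layout(4)
        cols = list(layout.channels)
        clean = pd.DataFrame(np.exp(true_log), columns=cols)
        distorted = clean.copy()
        distorted[cols[2]] = np.exp(0.7 + 1.3 * np.log(clean[cols[2]]))
        fixed = normalize_tmt_channels(distorted, layout)
        np.testing.assert_allclose(fixed[cols[2]], clean[cols[2]], rtol=1e-8)

    def test_fixed_point_on_unbiased_matrix(self):
        rng = np.random.default_rng(6)
        base = rng.normal(8, 1, size=(100, 1))
        vals = np.exp(base + rng.normal(0, 1e-3, size=(100, 5)))
        layout = self._layout(4)
        m = pd.DataFrame(vals, columns=list(layout.channels))
        out = normalize_tmt_channels(m, layout)
        np.testing.assert_allclose(out.to_numpy(), m.to_numpy(), rtol=1e-2)

    def test_single_protein_errors(self):
        layout = self._layout(4)
        m = pd.DataFrame([[1.0] * 5], columns=list(layout.channels))
        with pytest.raises(ValueError):
            normalize_tmt_channels(m, layout)

    def test_layout_validation(self):
        with pytest.raises(ValueError):
            TMTSetLayout("s", ("a", "a"), None)
        with pytest.raises(ValueError):
            TMTSetLayout("s", ("a", "b"), "c")


class TestTMTAssembly:
    def _sets(self):
        # two 10-plex sets reproducing the 18-time-point design:
        # pooled reference + CT30..CT54 and pooled reference + CT57..CT81
        ch1 = ("ref",) + tuple(f"CT{h}_r1" for h in range(30, 55, 3))
        ch2 = ("ref",) + tuple(f"CT{h}_r1" for h in range(57, 82, 3))
        l1 = TMTSetLayout("set1", ch1, "ref")
        l2 = TMTSetLayout("set2", ch2, "ref")
        idx = [f"P{i}" for i in range(20)]
        rng = np.random.default_rng(7)
        s1 = pd.DataFrame(np.exp(rng.normal(8, 1, (20, 10))), index=idx,
                          columns=list(ch1))
        s2 = pd.DataFrame(np.exp(rng.normal(8, 1, (20, 10))), index=idx,
                          columns=list(ch2))
        return s1, s2, l1, l2

    def test_full_design_spans_18_timepoints(self):
        s1, s2, l1, l2 = self._sets()
        fm = assemble_tmt_timecourse(s1, s2, l1, l2, mode="reference")
        assert fm.grid.n_timepoints == 18
        assert fm.grid.unique_times[0] == 30.0
        assert fm.grid.unique_times[-1] == 81.0
        assert fm.scale == "log"

    def test_flat_protein_is_all_zero(self):
        s1, s2, l1, l2 = self._sets()
        s1.loc["P0"] = 123.0
        s2.loc["P0"] = 55.0  # flat within each set
        for mode in ("reference", "mean_centre"):
            fm = assemble_tmt_timecourse(s1, s2, l1, l2, mode=mode)
            np.testing.assert_allclose(fm.data.loc["P0"], 0.0, atol=1e-12)

    def test_reference_doubling_shifts_by_log2(self):
        s1, s2, l1, l2 = self._sets()
        base = assemble_tmt_timecourse(s1, s2, l1, l2, mode="reference")
        s1b = s1.copy()
        s1b["ref"] = 2 * s1b["ref"]
        shifted = assemble_tmt_timecourse(s1b, s2, l1, l2, mode="reference")
        set1_cols = [c for c in base.data.columns if c in l1.channels]
        diff = (shifted.data[set1_cols] - base.data[set1_cols]).to_numpy()
        np.testing.assert_allclose(diff, -np.log(2), atol=1e-12)
        # mean-centring is invariant to the reference channel
        mc1 = assemble_tmt_timecourse(s1, s2, l1, l2, mode="mean_centre")

    def test_only_shared_proteins_kept(self):
        s1, s2, l1, l2 = self._sets()
        fm = assemble_tmt_timecourse(s1.iloc[:15], s2.iloc[5:], l1, l2)
        assert fm.n_features == 10

    def test_missing_reference_errors(self):
        s1, s2, l1, l2 = self._sets()
        l1_noref = TMTSetLayout("set1", l1.channels, None)
        with pytest.raises(ValueError):
            assemble_tmt_timecourse(s1, s2, l1_noref, l2, mode="reference")


class TestMetabolomicsFilters:
    def test_cv_zero_kept(self):
        m = _matrix(np.ones((1, 20)))
        qc = pd.DataFrame({"QC_1": [10.0], "QC_2": [10.0], "QC_3": [10.0]},
                          index=m.feature_ids)
        kept, report = qc_cv_filter(m, qc, 0.30)
        assert kept.n_features == 1
        assert report["cv"].iloc[0] == 0.0

    def test_cv_above_threshold_dropped(self):
        m = _matrix(np.ones((1, 20)))
        # sd/mean = 0.35 exactly
        vals = np.array([1 - 0.35 / np.sqrt(2), 1 + 0.35 / np.sqrt(2)])
        qc = pd.DataFrame([vals], index=m.feature_ids,
                          columns=["QC_1", "QC_2"])
        kept, report = qc_cv_filter(m, qc, 0.30)
        assert kept.n_features == 0
        assert report["cv"].iloc[0] == pytest.approx(0.35)

    def test_cv_scale_invariant(self):
        m = _matrix(np.ones((1, 20)))
        rng = np.random.default_rng(8)
        qc_vals = rng.lognormal(2, 0.1, 5)
        qc1 = pd.DataFrame([qc_vals], index=m.feature_ids,
                           columns=[f"QC_{i}" for i in range(5)])
        qc2 = qc1 * 1000.0
        _, r1 = qc_cv_filter(m, qc1)
        _, r2 = qc_cv_filter(m, qc2)
        assert r1["cv"].iloc[0] == pytest.approx(r2["cv"].iloc[0], rel=1e-12)

    def test_rt_window_exclusion(self):
        m = _matrix(np.ones((3, 20)))
        rt = pd.Series([19.20, 19.14, 19.36], index=m.feature_ids)
        kept = rt_window_filter(m, rt, (19.15, 19.35))
        assert list(kept.feature_ids) == ["f1", "f2"]

    def test_rt_invalid_window(self):
        m = _matrix(np.ones((1, 20)))
        rt = pd.Series([19.0], index=m.feature_ids)
        with pytest.raises(ValueError):
            rt_window_filter(m, rt, (19.35, 19.15))

    def test_rt_missing_metadata(self):
        m = _matrix(np.ones((2, 20)))
        rt = pd.Series([19.0], index=["f0"])
        with pytest.raises(ValueError):
            rt_window_filter(m, rt)


class TestSampleNormalization:
    def test_inverts_global_scaling(self):
        rng = np.random.default_rng(9)
        base = rng.lognormal(3, 1, size=(50, 1)) * np.ones((50, 20))
        m = _matrix(base)
        scaled = m.data.copy()
        scaled.iloc[:, 4] *= 2.0
        mat = FeatureMatrix(scaled, m.grid)
        normed, factors = sample_normalize_logratio(mat)
        assert factors.iloc[4] == pytest.approx(np.log(2), abs=1e-10)
        np.testing.assert_allclose(normed.values(), base, rtol=1e-10)

    def test_identical_samples_zero_factors(self):
        m = _matrix(np.ones((10, 20)) * 7.0)
        _, factors = sample_normalize_logratio(m)
        np.testing.assert_allclose(factors, 0.0, atol=1e-12)

    def test_invariant_to_feature_order(self):
        rng = np.random.default_rng(10)
        m = _matrix(rng.lognormal(1, 1, size=(30, 20)))
        _, f1 = sample_normalize_logratio(m)
        perm = rng.permutation(30)
        m2 = FeatureMatrix(m.data.iloc[perm], m.grid)
        _, f2 = sample_normalize_logratio(m2)
        np.testing.assert_allclose(f1, f2, atol=1e-12)


class TestDeltaCt:
    @pytest.mark.parametrize("target,ref,expected",
                             [(20, 15, 0.03125), (15, 15, 1.0), (14, 15, 2.0)])
    def test_formula(self, target, ref, expected):
        assert delta_ct_quantify(target, ref) == pytest.approx(expected)

    def test_missing_ct(self):
        with pytest.raises(ValueError):
            delta_ct_quantify(np.nan, 15)
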