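"""Shape statistics: Procrustes disparity, t-tests, power/sample size."""

import numpy as np
import pytest
from scipy import stats as sps

from sfl.stats import (
    SFLCurve,
    channelwise_ttest,
    paired_channel_ttest,
    pairwise_disparity_matrix,
    procrustes_disparity,
    required_sample_size,
)


def curve(values, label="", group="", w=None):
    values = np.asarray(values, dtype=float)
    if w is None:
        w = np.linspace(560.0, 630.0, values.size)
    return SFLCurve(w, values, label=label, group=group)


def closed_form_disparity(a_pts, b_pts):
    """Independent Procrustes disparity via SVD of the cross-covariance.

    Standardize both point sets (zero centroid, unit Frobenius norm); the
    minimal residual after optimal rotation and scaling is 1 - (sum of
    singular values of A^T B)^2.
    """
    def standardize(x):
        x = x - x.mean(axis=0)
        return x / np.linalg.norm(x)

    a, b = standardize(a_pts), standardize(b_pts)
    s = np.linalg.svd(a.T @ b, compute_uv=False).sum()
    return 1.0 - s**2


class TestProcrustes:
    def test_identical_curves_zero(self):
        a = curve([1.0, 2.0, 1.5, 2.5, 1.8])
        assert procrustes_disparity(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_similarity_transform_invisible(self):
        """A uniform scale plus offset of the lifetimes is not a shape change."""
        vals = np.array([1.0, 2.2, 1.4, 2.9, 1.1, 2.0])
        a = curve(vals)
        b = curve(2.0 * vals + 0.7)
        assert procrustes_disparity(a, b) == pytest.approx(0.0, abs=1e-10)

    def test_matches_closed_form_oracle(self):
        a_vals = np.array([1.0, 2.0, 1.2, 2.8, 0.9])
        b_vals = np.array([1.5, 1.1, 2.6, 1.0, 2.2])
        a, b = curve(a_vals), curve(b_vals)
        x = np.arange(5) / 4.0

        def z(v):
            return (v - v.mean()) / v.std()

        expected = closed_form_disparity(
            np.column_stack([x, z(a_vals)]), np.column_stack([x, z(b_vals)])
        )
        assert procrustes_disparity(a, b) == pytest.approx(expected, abs=1e-12)

    def test_symmetric(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            a = curve(rng.uniform(0.5, 3.0, 20))
            b = curve(rng.uniform(0.5, 3.0, 20))
            assert procrustes_disparity(a, b) == pytest.approx(
                procrustes_disparity(b, a), abs=1e-12
            )

    def test_degenerate_constant_curve_error(self):
        a = curve([1.0, 2.0, 1.5, 2.5])
        flat = curve([2.0, 2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="degenerate"):
            procrustes_disparity(a, flat)

    def test_mismatched_length_error(self):
        a = curve([1.0, 2.0, 1.5, 2.5])
        with pytest.raises(ValueError, match="equal length"):
            procrustes_disparity(a, curve([1.0, 2.0, 1.5, 2.5, 3.0]))

    def test_mismatched_grid_error(self):
        a = curve([1.0, 2.0, 1.5, 2.5])
        b = curve([1.0, 2.0, 1.5, 2.5], w=np.linspace(500, 550, 4))
        with pytest.raises(ValueError, match="wavelength grid"):
            procrustes_disparity(a, b)


class TestDisparityMatrix:
    def test_identical_curves_zero_matrix(self):
        c = curve([1.0, 2.0, 1.1, 2.4, 1.9], group="normal")
        res = pairwise_disparity_matrix([c, c, c])
        np.testing.assert_allclose(res.matrix, 0.0, atol=1e-12)
        assert res.group_medians["normal"] == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(2)
        curves = [
            curve(rng.uniform(0.5, 3.0, 12), label=f"c{i}",
                  group="normal" if i % 2 else "abnormal")
            for i in range(6)
        ]
        res = pairwise_disparity_matrix(curves)
        np.testing.assert_array_equal(res.matrix, res.matrix.T)
        np.testing.assert_array_equal(np.diag(res.matrix), 0.0)

    def test_group_medians_over_within_group_pairs(self):
        flat = curve(np.linspace(2.0, 1.0, 10), group="normal")
        rng = np.random.default_rng(8)
        wiggly = [
            curve(np.linspace(2.0, 1.0, 10) + rng.normal(0, 0.4, 10),
                  group="abnormal")
            for _ in range(3)
        ]
        res = pairwise_disparity_matrix([flat, flat, flat] + wiggly)
        assert res.group_medians["abnormal"] > res.group_medians["normal"]


class TestChannelwiseTTest:
    def test_equal_groups_give_unit_pvalues(self):
        a = curve([1.0, 2.0, 1.5, 2.5])
        b = curve([1.2, 1.8, 1.6, 2.3])
        out = channelwise_ttest([a, b], [a, b])
        np.testing.assert_allclose(out["t_statistic"], 0.0)
        np.testing.assert_allclose(out["p_value"], 1.0)

    def test_zero_variance_channel_reported_undefined(self):
        a = curve([1.0, 2.0, 1.5, 2.5])
        out = channelwise_ttest([a, a], [a, a])
        assert out["p_value"].isna().all()

    def test_large_shift_significant_everywhere(self):
        rng = np.random.default_rng(5)
        base = np.linspace(2.0, 1.2, 16)
        ga = [curve(base + rng.normal(0, 0.02, 16)) for _ in range(6)]
        gb = [curve(base - 0.5 + rng.normal(0, 0.02, 16)) for _ in range(6)]
        out = channelwise_ttest(ga, gb)
        assert (out["p_value"] < 0.05).all()

    def test_type_one_error_calibrated_under_null(self):
        """Under a shared generating process the raw per-channel test rejects
        at about the nominal 5% rate."""
        rng = np.random.default_rng(42)
        n_rep, n_per, n_ch = 400, 5, 8
        rejections = 0
        for _ in range(n_rep):
            ga = [curve(rng.normal(2.0, 0.1, n_ch)) for _ in range(n_per)]
            gb = [curve(rng.normal(2.0, 0.1, n_ch)) for _ in range(n_per)]
            out = channelwise_ttest(ga, gb)
            rejections += (out["p_value"] < 0.05).sum()
        rate = rejections / (n_rep * n_ch)
        se = np.sqrt(0.05 * 0.95 / (n_rep * n_ch))
        assert abs(rate - 0.05) < 3 * se


class TestPairedTTest:
    def test_equal_means_p_one(self):
        a = curve([1.0, 2.0, 1.5, 2.5])
        out = paired_channel_ttest(a, a)
        assert out["p_value"] == 1.0
        assert out["degenerate"]

    def test_constant_shift_degenerate_extreme(self):
        a = curve([1.0, 2.0, 1.5, 2.5])
        b = curve([1.3, 2.3, 1.8, 2.8])
        out = paired_channel_ttest(a, b)
        assert out["degenerate"]
        assert out["p_value"] == 0.0
        assert out["mean_difference_ns"] == pytest.approx(-0.3)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(11)
        base = np.linspace(2.0, 1.0, 30)
        a = curve(base)
        b = curve(base + 0.05 + rng.normal(0, 0.1, 30))
        out = paired_channel_ttest(a, b)
        d = a.sfl_ns - b.sfl_ns
        t = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        p = 2 * sps.t.sf(abs(t), d.size - 1)
        assert out["t_statistic"] == pytest.approx(t, rel=1e-12)
        assert out["p_value"] == pytest.approx(p, rel=1e-12)


class TestRequiredSampleSize:
    def test_reference_scenario(self):
        """50 ps difference, 200 ps spread, alpha 0.05, power 0.8 -> 253."""
        assert required_sample_size(0.050, 0.200, 0.05, 0.8) == 253

    def test_normal_approximation_mode(self):
        assert required_sample_size(
            0.050, 0.200, 0.05, 0.8, method="normal_approx"
        ) == 252

    def test_huge_effect_needs_minimum_group(self):
        assert required_sample_size(100.0, 0.01, 0.05, 0.8) == 2

    def test_matches_independent_power_oracle(self):
        """Exhaustive check of n for a unit effect against the statsmodels
        power implementation."""
        from statsmodels.stats.power import TTestIndPower

        solver = TTestIndPower()
        target = required_sample_size(1.0, 1.0, 0.05, 0.8)
        powers = {
            n: solver.power(effect_size=1.0, nobs1=n, alpha=0.05, ratio=1.0)
            for n in range(2, 101)
        }
        brute = min(n for n, p in powers.items() if p >= 0.8)
        assert target == brute

    def test_monotone_in_effect_spread_power(self):
        grid_delta = [0.05, 0.1, 0.2]
        ns = [required_sample_size(d, 0.2) for d in grid_delta]
        assert ns == sorted(ns, reverse=True)
        grid_sd = [0.1, 0.2, 0.4]
        ns = [required_sample_size(0.05, s) for s in grid_sd]
        assert ns == sorted(ns)
        grid_pow = [0.5, 0.8, 0.95]
        ns = [required_sample_size(0.05, 0.2, power=p) for p in grid_pow]
        assert ns == sorted(ns)

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError, match="delta"):
            required_sample_size(0.0, 0.2)
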