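"""MR estimators against independent oracles and their symmetry properties."""

import numpy as np
import pytest

from mrmediate import (
    InputError,
    estimate_all,
    ivw,
    mr_egger,
    simple_mode,
    wald_ratios,
    weighted_median,
    weighted_mode,
)

# ---------------------------------------------------------------------------
# independent oracles (no shared code with the implementation)


def wls_through_origin(g, G, seG):
    """Weighted least squares of G on g without intercept, via normal equations."""
    w = np.diag(1.0 / np.asarray(seG) ** 2)
    X = np.asarray(g, dtype=float).reshape(-1, 1)
    y = np.asarray(G, dtype=float)
    return float(np.linalg.solve(X.T @ w @ X, X.T @ w @ y)[0])


def wls_with_intercept(g, G, seG):
    """Weighted normal equations with intercept; returns (intercept, slope)."""
    w = np.diag(1.0 / np.asarray(seG) ** 2)
    X = np.column_stack([np.ones(len(g)), g])
    sol = np.linalg.solve(X.T @ w @ X, X.T @ w @ np.asarray(G, dtype=float))
    return float(sol[0]), float(sol[1])


def weighted_cdf_median(ratios, weights):
    """Brute-force interpolation of the weighted empirical CDF at 0.5."""
    order = np.argsort(ratios)
    r = np.asarray(ratios, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    w = w / w.sum()
    p = []
    acc = 0.0
    for wi in w:
        p.append(acc + wi / 2.0)
        acc += wi
    p = np.asarray(p)
    if 0.5 <= p[0]:
        return float(r[0])
    if 0.5 >= p[-1]:
        return float(r[-1])
    j = int(np.searchsorted(p, 0.5))
    frac = (0.5 - p[j - 1]) / (p[j] - p[j - 1])
    return float(r[j - 1] + frac * (r[j] - r[j - 1]))


def grid_search_mode(ratios, weights, h):
    """Dense grid search of the weighted Gaussian-kernel density maximum."""
    r = np.asarray(ratios, dtype=float)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 20_001)
    dens = np.array([np.sum(w * np.exp(-0.5 * ((x - r) / h) ** 2)) for x in grid])
    return float(grid[np.argmax(dens)])


def random_instance(rng, j):
    g = rng.normal(0.2, 0.1, j)
    g[np.abs(g) < 1e-3] = 0.05
    G = rng.normal(0.05, 0.05, j)
    seG = rng.uniform(0.01, 0.1, j)
    seg = rng.uniform(0.005, 0.02, j)
    return g, seg, G, seG


class TestWaldRatios:
    def test_direct_arithmetic(self, make_h):
        wr = wald_ratios(make_h([0.1], [0.05], [0.01]))
        assert wr.loc[0, "ratio"] == pytest.approx(0.5)
        assert wr.loc[0, "se_ratio"] == pytest.approx(0.1)

    def test_null_outcome_effect(self, make_h):
        assert wald_ratios(make_h([0.1], [0.0], [0.01])).loc[0, "ratio"] == 0.0

    def test_sign_flip_of_gamma_negates_ratio_only(self, make_h):
        a = wald_ratios(make_h([0.1, 0.2], [0.05, 0.08], [0.01, 0.02]))
        b = wald_ratios(make_h([-0.1, -0.2], [0.05, 0.08], [0.01, 0.02]))
        assert np.allclose(a["ratio"], -b["ratio"])
        assert np.allclose(a["se_ratio"], b["se_ratio"])

    def test_zero_gamma_rows_dropped_and_empty_input_rejected(self, make_h):
        wr = wald_ratios(make_h([0.1, 0.0], [0.05, 0.05], [0.01, 0.01]))
        assert len(wr) == 1
        with pytest.raises(InputError):
            wald_ratios(make_h([], [], []))


class TestIVW:
    def test_single_snp_reduces_to_wald_ratio(self, make_h):
        est = ivw(make_h([0.1], [0.05], [0.01]))
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)
        assert est.n_snp == 1

    def test_homogeneous_ratios_fixed_equals_random(self, make_h):
        h = make_h([0.1, 0.2, 0.4], [0.03, 0.06, 0.12], [0.01, 0.01, 0.01])
        fixed = ivw(h, model="fixed")
        random = ivw(h, model="random_multiplicative")
        assert fixed.beta == pytest.approx(0.3)
        assert random.beta == pytest.approx(0.3)
        assert fixed.se == pytest.approx(random.se)  # Q = 0, no inflation

    def test_hand_worked_normal_equations_example(self, make_h):
        h = make_h([0.1, 0.2, 0.3], [0.03, 0.05, 0.12], [0.01, 0.01, 0.02])
        assert ivw(h).beta == pytest.approx(220.0 / 725.0, abs=1e-12)

    def test_or_and_ci_consistent_with_beta(self, make_h):
        est = ivw(make_h([0.1, 0.2], [0.05, 0.09], [0.01, 0.02]))
        assert est.or_ == pytest.approx(np.exp(est.beta))
        assert est.ci_low == pytest.approx(np.exp(est.beta - 1.96 * est.se))
        assert est.ci_high == pytest.approx(np.exp(est.beta + 1.96 * est.se))

    def test_matches_weighted_regression_oracle(self, make_h):
        rng = np.random.default_rng(11)
        for _ in range(100):
            g, seg, G, seG = random_instance(rng, int(rng.integers(2, 11)))
            est = ivw(make_h(g, G, seG, seg))
            assert est.beta == pytest.approx(wls_through_origin(g, G, seG), abs=1e-10)


class TestEgger:
    def test_exact_affine_points_recovered(self, make_h):
        g = np.array([0.1, 0.2, 0.3, 0.4])
        est = mr_egger(make_h(g, 0.03 + 0.2 * g, [0.01] * 4))
        assert est.intercept == pytest.approx(0.03, abs=1e-10)
        assert est.beta == pytest.approx(0.2, abs=1e-10)

    def test_proportional_points_give_zero_intercept_and_ivw_slope(self, make_h):
        g = np.array([0.1, 0.25, 0.3, 0.5])
        h = make_h(g, 0.4 * g, [0.01, 0.02, 0.01, 0.03])
        est = mr_egger(h)
        assert est.intercept == pytest.approx(0.0, abs=1e-10)
        assert est.beta == pytest.approx(ivw(h).beta, abs=1e-10)

    def test_matches_normal_equations_oracle(self, make_h):
        rng = np.random.default_rng(13)
        for _ in range(100):
            g, seg, G, seG = random_instance(rng, int(rng.integers(3, 11)))
            est = mr_egger(make_h(g, G, seG, seg))
            # oracle applies the same positive-gamma orientation
            sign = np.where(g < 0, -1.0, 1.0)
            b0, b1 = wls_with_intercept(g * sign, G * sign, seG)
            assert est.intercept == pytest.approx(b0, abs=1e-10)
            assert est.beta == pytest.approx(b1, abs=1e-10)

    def test_too_few_snps_reported_missing(self, make_h):
        assert mr_egger(make_h([0.1, 0.2], [0.05, 0.1], [0.01, 0.01])) is None


class TestWeightedMedian:
    def test_equal_weights_is_ordinary_median(self, make_h):
        h = make_h([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], [0.05, 0.05, 0.05])
        assert weighted_median(h, n_boot=50, seed=0).beta == pytest.approx(0.2)

    def test_hand_interpolated_weighted_cdf(self, make_h):
        # normalized weights (0.2, 0.3, 0.5): midpoints (0.1, 0.35, 0.75);
        # interpolation at 0.5 -> 0.2 + (0.15/0.4)*0.1 = 0.2375
        se_r = np.array([0.2, 0.3, 0.5]) ** -0.5
        h = make_h([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], se_r)
        assert weighted_median(h, n_boot=50, seed=0).beta == pytest.approx(0.2375, abs=1e-12)

    def test_matches_brute_force_cdf_oracle(self, make_h):
        rng = np.random.default_rng(17)
        for _ in range(100):
            g, seg, G, seG = random_instance(rng, int(rng.integers(3, 11)))
            est = weighted_median(make_h(g, G, seG, seg), n_boot=10, seed=0)
            wr = wald_ratios(make_h(g, G, seG, seg))
            expected = weighted_cdf_median(wr["ratio"], wr["se_ratio"] ** -2.0)
            assert est.beta == pytest.approx(expected, abs=1e-10)

    def test_bootstrap_se_reproducible_and_small_under_homogeneity(self, make_h):
        h = make_h([0.2, 0.3, 0.4, 0.5], [0.06, 0.09, 0.12, 0.15],
                   [1e-6] * 4, [1e-6] * 4)
        a = weighted_median(h, n_boot=200, seed=42)
        b = weighted_median(h, n_boot=200, seed=42)
        assert a.beta == b.beta and a.se == b.se  # bit-reproducible given the seed
        assert a.beta == pytest.approx(0.3)
        assert a.se < 1e-4  # near-noiseless resamples


class TestModes:
    def test_all_ratios_identical_is_exact(self, make_h):
        h = make_h([0.1, 0.2, 0.4], [0.03, 0.06, 0.12], [0.01, 0.02, 0.01])
        assert weighted_mode(h, n_boot=20, seed=0).beta == pytest.approx(0.3, abs=1e-12)
        assert simple_mode(h, n_boot=20, seed=0).beta == pytest.approx(0.3, abs=1e-12)

    def test_majority_cluster_wins_over_outlier(self, make_h):
        g = np.ones(7)
        G = np.array([0.29, 0.30, 0.31, 0.30, 0.295, 0.305, 2.0])
        est = simple_mode(make_h(g, G, [0.05] * 7), n_boot=20, seed=0)
        assert est.beta == pytest.approx(0.30, abs=0.02)

    def test_weighted_mode_follows_weight_not_count(self, make_h):
        # cluster at 0.1 has more SNPs, cluster at 0.5 carries far more weight
        g = np.ones(7)
        G = np.array([0.10, 0.11, 0.09, 0.105, 0.50, 0.51, 0.49])
        seG = np.array([0.2, 0.2, 0.2, 0.2, 0.01, 0.01, 0.01])
        wm = weighted_mode(make_h(g, G, seG), n_boot=20, seed=0)
        sm = simple_mode(make_h(g, G, seG), n_boot=20, seed=0)
        assert wm.beta == pytest.approx(0.50, abs=0.03)
        assert sm.beta == pytest.approx(0.10, abs=0.03)

    def test_matches_grid_search_oracle(self, make_h):
        rng = np.random.default_rng(19)
        for _ in range(20):
            g, seg, G, seG = random_instance(rng, 8)
            h = make_h(g, G, seG, seg)
            wr = wald_ratios(h)
            r = wr["ratio"].to_numpy()
            sd = np.std(r, ddof=1)
            from scipy.stats import median_abs_deviation
            bw = max(1e-8, 0.9 * min(sd, median_abs_deviation(r, scale="normal")) / len(r) ** 0.2)
            est = simple_mode(h, n_boot=5, seed=0)
            oracle = grid_search_mode(r, np.ones_like(r), bw)
            assert est.beta == pytest.approx(oracle, abs=2 * (r.max() - r.min() + 6 * bw) / 2048)


class TestEstimateAll:
    def test_homogeneous_table_all_methods_agree(self, make_h):
        rng = np.random.default_rng(23)
        g = rng.uniform(0.1, 0.5, 10)
        h = make_h(g, 0.25 * g, rng.uniform(0.01, 0.03, 10))
        results = estimate_all(h, seed=1, n_boot=50)
        for method, est in results.items():
            assert est is not None
            assert est.beta == pytest.approx(0.25, abs=1e-6), method

    def test_two_snp_table_only_ivw_applicable(self, make_h):
        results = estimate_all(make_h([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]), n_boot=20)
        assert results["ivw"] is not None
        for method in ("egger", "weighted_median", "weighted_mode", "simple_mode"):
            assert results[method] is None

    @pytest.mark.parametrize("c", [0.5, 3.0])
    def test_scale_equivariance(self, make_h, c):
        rng = np.random.default_rng(29)
        g, seg, G, seG = random_instance(rng, 8)
        base = estimate_all(make_h(g, G, seG, seg), seed=5, n_boot=50)
        scaled = estimate_all(make_h(g, c * G, c * seG, seg), seed=5, n_boot=50)
        for method in base:
            assert scaled[method].beta == pytest.approx(c * base[method].beta, rel=1e-9), method
            assert scaled[method].se == pytest.approx(c * base[method].se, rel=1e-9), method

    def test_sign_equivariance(self, make_h):
        rng = np.random.default_rng(31)
        g, seg, G, seG = random_instance(rng, 8)
        base = estimate_all(make_h(g, G, seG, seg), seed=5, n_boot=50)
        negated = estimate_all(make_h(g, -G, seG, seg), seed=5, n_boot=50)
        for method in base:
            assert negated[method].beta == pytest.approx(-base[method].beta, rel=1e-6, abs=1e-9), method
        # analytic SEs are exactly invariant; bootstrap SEs only in distribution
        for method in ("ivw", "egger"):
            assert negated[method].se == pytest.approx(base[method].se, rel=1e-9), method
        for method in ("weighted_median", "weighted_mode", "simple_mode"):
            assert negated[method].se == pytest.approx(base[method].se, rel=0.5), method
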