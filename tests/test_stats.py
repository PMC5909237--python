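"""Statistics and serial-transfer arithmetic, each checked against an
independent oracle (enumeration, closed form, or simulation)."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from hgtmosaic.simulate import logistic_curve
from hgtmosaic.stats import (
    LogisticGrowthModel,
    adapted_fraction,
    bottleneck_size,
    breakpoint_feature_enrichment,
    extinction_summary,
    generations_per_cycle,
    logistic_fit,
    mann_whitney_u,
    overlap_randomization,
    pearson_gof,
    percentage,
    total_generations,
)


class TestTransferArithmetic:
    def test_hundredfold_dilution_gives_six_point_six(self):
        assert round(generations_per_cycle(100), 1) == 6.6

    @pytest.mark.parametrize("d, expected", [(2, 1.0), (1024, 10.0)])
    def test_powers_of_two(self, d, expected):
        assert generations_per_cycle(d) == pytest.approx(expected)

    def test_invalid_dilution(self):
        with pytest.raises(ValueError):
            generations_per_cycle(1.0)

    def test_experiment_totals(self):
        assert total_generations(60, 100) == pytest.approx(396.0)
        assert total_generations(175, 100) == pytest.approx(1155.0)

    @pytest.mark.parametrize(
        "vol, dens, expected", [(20, 1e8, 2e6), (0, 5e7, 0.0), (1000, 1e6, 1e6)]
    )
    def test_bottleneck(self, vol, dens, expected):
        assert bottleneck_size(vol, dens) == pytest.approx(expected)


class TestAdaptedFraction:
    def test_worked_example(self):
        # 50 colonies at 1e4 dilution vs 100 at 1e6, same volume -> 0.005
        assert adapted_fraction(50, 1e4, 100, 1e6) == pytest.approx(0.005)

    def test_zero_adapted(self):
        assert adapted_fraction(0, 1e4, 100, 1e6) == 0.0

    def test_equal_counts_equal_dilutions(self):
        assert adapted_fraction(75, 1e4, 75, 1e4) == pytest.approx(1.0)

    def test_zero_total_undefined(self):
        assert math.isnan(adapted_fraction(10, 1e4, 0, 1e6))

    @settings(max_examples=50, deadline=None)
    @given(
        ca=st.integers(min_value=0, max_value=500),
        ct=st.integers(min_value=1, max_value=500),
        vol=st.floats(min_value=0.01, max_value=1.0),
    )
    def test_invariant_to_shared_plated_volume(self, ca, ct, vol):
        a = adapted_fraction(ca, 1e4, ct, 1e6, plated_volume_ml=vol)
        b = adapted_fraction(ca, 1e4, ct, 1e6, plated_volume_ml=0.1)
        assert a == pytest.approx(b)


class TestExtinctionSummary:
    def test_groups(self):
        status = pd.DataFrame(
            {
                "population": range(4),
                "group": ["x", "x", "y", "y"],
                "extinct": [True, False, False, False],
            }
        )
        out = extinction_summary(status).set_index("group")
        assert out.loc["x", "percent_extinct"] == 50
        assert out.loc["y", "percent_extinct"] == 0


class TestLogisticFit:
    def test_noise_free_recovery(self):
        t = np.arange(0, 48, 1 / 6)
        od = logistic_curve(t, 0.5, 1.2, 0.02)
        r, K, N0, flag = logistic_fit(t, od)
        assert flag == "ok"
        assert r == pytest.approx(0.5, abs=1e-6)
        assert K == pytest.approx(1.2, abs=1e-6)

    def test_flat_curve_flagged_no_growth(self):
        t = np.arange(0, 48, 1 / 6)
        rng = np.random.default_rng(0)
        od = 0.08 + rng.normal(0, 0.005, t.size)
        assert logistic_fit(t, od)[3] == "no_growth"

    def test_noisy_recovery_within_five_percent(self):
        t = np.arange(0, 48, 1 / 6)
        rng = np.random.default_rng(3)
        od = logistic_curve(t, 0.5, 1.2, 0.02) + rng.normal(0, 0.01, t.size)
        r, _, _, flag = logistic_fit(t, od)
        assert flag == "ok"
        assert abs(r - 0.5) / 0.5 < 0.05

    def test_non_monotone_time_rejected(self):
        with pytest.raises(ValueError):
            logistic_fit(np.array([0, 1, 1, 2] * 5), np.ones(20))

    def test_estimator_predict_roundtrip(self):
        t = np.arange(0, 48, 1 / 6)
        od = logistic_curve(t, 0.4, 1.0, 0.05)
        m = LogisticGrowthModel().fit(t, od)
        np.testing.assert_allclose(m.predict(t), od, atol=1e-6)


def _brute_force_mwu_p(x, y):
    """Exact two-sided p by enumerating all assignments of pooled ranks."""
    pooled = np.concatenate([x, y])
    n = len(x)
    u_obs = sum(1 for xi in x for yi in y if xi > yi) + 0.5 * sum(
        1 for xi in x for yi in y if xi == yi
    )
    us = []
    for idx in itertools.combinations(range(len(pooled)), n):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = sum(1 for xi in xs for yi in ys if xi > yi)
        us.append(u)
    us = np.array(us)
    p_low = (us <= u_obs).mean()
    p_high = (us >= u_obs).mean()
    return min(1.0, 2 * min(p_low, p_high))


class TestMannWhitney:
    def test_worked_example(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.method == "mann_whitney_exact"
        assert res.p_value == pytest.approx(0.1)
        assert min(res.statistic, 9 - res.statistic) == 0

    def test_identical_samples_p_one(self):
        res = mann_whitney_u([1.0, 2.5, 3.1], [1.0, 2.5, 3.1])
        assert res.p_value == pytest.approx(1.0)

    def test_exact_equals_enumeration_all_small_sizes(self):
        """Exact p matches brute-force enumeration for every n, m <= 7."""
        rng = np.random.default_rng(12)
        for n in range(1, 8):
            for m in range(1, 8):
                x = rng.permutation(np.arange(1, n + m + 1))[:n].astype(float)
                y = np.setdiff1d(np.arange(1, n + m + 1).astype(float), x)
                res = mann_whitney_u(x, y, mode="exact")
                assert res.p_value == pytest.approx(_brute_force_mwu_p(x, y)), (n, m)

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 7)
        y = rng.normal(0.5, 1, 7)
        exact = mann_whitney_u(x, y, mode="exact").p_value
        approx = mann_whitney_u(x, y, mode="normal").p_value
        assert abs(exact - approx) < 0.05

    def test_ties_fall_back_to_normal(self):
        res = mann_whitney_u([1, 1, 2], [1, 2, 3])
        assert res.method == "mann_whitney_normal"


class TestPearsonGof:
    def test_observed_percentages(self):
        _, pct_b = pearson_gof(2410, 2643, 0.9061)
        assert pct_b == 91.18
        _, pct_w = pearson_gof(258, 319, 0.8286)
        assert pct_w == 80.88

    def test_exact_match_gives_zero_statistic(self):
        res, _ = pearson_gof(500, 1000, 0.5)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_equals_squared_z_statistic(self):
        """Pearson chi2 on two cells equals the square of the one-sample
        proportion z statistic."""
        k, n, p = 430, 1000, 0.40
        res, _ = pearson_gof(k, n, p)
        z = (k / n - p) / math.sqrt(p * (1 - p) / n)
        assert res.statistic == pytest.approx(z**2)


class TestOverlapRandomization:
    def test_full_set_always_overlaps(self):
        res = overlap_randomization(20, 5, 20, 5, n_replicates=2000, seed=1)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_matches_hypergeometric_tail(self):
        """p within 3 Monte-Carlo standard errors of the closed-form
        hypergeometric tail P(X >= 5) at R = 1e5."""
        n_a = n_b = 5
        N, k, R = 20, 5, 100_000
        res = overlap_randomization(n_a, n_b, N, k, n_replicates=R, seed=7)
        p_true = float(sps.hypergeom.sf(k - 1, N, n_a, n_b))
        se = math.sqrt(p_true * (1 - p_true) / R)
        assert abs(res.p_value - p_true) < 3 * se + 2 / R

    def test_deterministic_for_fixed_seed(self):
        a = overlap_randomization(50, 40, 300, 12, n_replicates=5000, seed=3)
        b = overlap_randomization(50, 40, 300, 12, n_replicates=5000, seed=3)
        assert a.p_value == b.p_value

    def test_null_p_values_super_uniform(self):
        """Drawing the observed overlap from the null itself, P(p <= alpha)
        stays at or below alpha (within Monte-Carlo error) over 1000 trials."""
        rng = np.random.default_rng(11)
        N, n_a, n_b, R, trials = 40, 10, 12, 2000, 1000
        ks = rng.hypergeometric(n_a, N - n_a, n_b, size=trials)
        ps = np.array(
            [
                overlap_randomization(n_a, n_b, N, int(k), n_replicates=R, seed=int(s)).p_value
                for k, s in zip(ks, rng.integers(0, 2**31 - 1, trials))
            ]
        )
        for alpha in (0.01, 0.05, 0.1, 0.25):
            frac = (ps <= alpha).mean()
            mc_err = 3 * math.sqrt(alpha * (1 - alpha) / trials)
            assert frac <= alpha + mc_err, (alpha, frac)


class TestBreakpointEnrichment:
    def test_feature_free_genome_gives_p_one(self):
        bps = pd.DataFrame({"start": [1000, 5000], "end": [1200, 5100]})
        res = breakpoint_feature_enrichment(bps, 100_000, np.array([]), n_random=200, seed=2)
        assert res.p_value == 1.0

    def test_detects_planted_enrichment(self):
        """Breakpoints placed inside repeat clusters are detected as
        significantly feature-enriched."""
        rng = np.random.default_rng(9)
        L = 1_000_000
        cluster_centers = rng.integers(0, L, 50)
        features = np.concatenate(
            [c + rng.integers(-500, 500, 20) for c in cluster_centers]
        ) % L
        bps = pd.DataFrame(
            {"start": cluster_centers - 600, "end": cluster_centers + 600}
        ) % L
        res = breakpoint_feature_enrichment(bps, L, features, n_random=500, seed=4)
        assert res.p_value < 0.05

    def test_reproducible_for_fixed_seed(self):
        bps = pd.DataFrame({"start": [1000], "end": [3000]})
        feats = np.arange(0, 100_000, 997)
        a = breakpoint_feature_enrichment(bps, 100_000, feats, n_random=300, seed=5)
        b = breakpoint_feature_enrichment(bps, 100_000, feats, n_random=300, seed=5)
        assert a.p_value == b.p_value


def test_percentage_helper():
    assert percentage(174, 205) == 84.88
    with pytest.raises(ValueError):
        percentage(1, 0)
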