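"""Population statistics and serial-transfer arithmetic.

Covers the quantitative summaries applied to pipeline outputs: serial
transfer generations and bottleneck sizes, plating-assay adapted fractions,
extinction percentages, logistic growth-rate fitting with a no-growth rule,
the Mann-Whitney U test (exact two-sided for small untied samples),
the one-degree-of-freedom Pearson goodness-of-fit for orthologue fractions,
a gene-set overlap randomization test, and a breakpoint feature-enrichment
test. Raw p-values are reported throughout; no multiple-testing correction
is applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from sklearn.base import BaseEstimator, RegressorMixin

from .simulate import logistic_curve

__all__ = [
    "TestResult",
    "generations_per_cycle",
    "total_generations",
    "bottleneck_size",
    "adapted_fraction",
    "extinction_summary",
    "percentage",
    "LogisticGrowthModel",
    "logistic_fit",
    "mann_whitney_u",
    "pearson_gof",
    "overlap_randomization",
    "breakpoint_feature_enrichment",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple
    seed: int | None = None


def generations_per_cycle(dilution_factor: float) -> float:
    """Generations per serial-transfer cycle, log2 of the dilution factor
    (100-fold dilution -> ~6.6 generations)."""
    if dilution_factor <= 1:
        raise ValueError("dilution factor must exceed 1")
    return math.log2(dilution_factor)


def total_generations(n_cycles: int, dilution_factor: float, per_cycle_decimals: int = 1) -> float:
    """Total generations as cycles x per-cycle generations, the latter
    rounded to one decimal (so 60 cycles at 100-fold dilution give
    60 x 6.6 = 396)."""
    return n_cycles * round(generations_per_cycle(dilution_factor), per_cycle_decimals)


def bottleneck_size(transfer_volume_ul: float, density_per_ml: float) -> float:
    """Cells passing the transfer bottleneck: volume x density
    (20 ul x 1e8/ml = 2e6)."""
    if transfer_volume_ul < 0 or density_per_ml < 0:
        raise ValueError("volume and density must be non-negative")
    return transfer_volume_ul / 1000.0 * density_per_ml


def adapted_fraction(
    colonies_adapted: int,
    dilution_adapted: float,
    colonies_total: int,
    dilution_total: float,
    plated_volume_ml: float = 0.1,
    plated_volume_total_ml: float | None = None,
) -> float:
    """Fraction of cells adapted to the novel nutrient, from plating.

    Each density is colonies x dilution / plated volume (cfu/ml); the
    fraction is adapted density over total density. Returns NaN (undefined)
    when no colonies grew on the total-count plate.
    """
    if min(colonies_adapted, colonies_total) < 0 or min(dilution_adapted, dilution_total) < 1:
        raise ValueError("counts must be >= 0 and dilutions >= 1")
    if colonies_total == 0:
        return float("nan")
    v_t = plated_volume_total_ml if plated_volume_total_ml is not None else plated_volume_ml
    density_adapted = colonies_adapted * dilution_adapted / plated_volume_ml
    density_total = colonies_total * dilution_total / v_t
    return density_adapted / density_total


def extinction_summary(status: pd.DataFrame) -> pd.DataFrame:
    """Percent of extinct populations per treatment group.

    ``status`` columns: ``population``, ``group``, ``extinct`` (bool).
    Percentages are rounded to the nearest integer (2 of 12 -> 17%).
    """
    if status["extinct"].isna().any():
        raise ValueError("every population must be labeled extinct or not")
    grp = status.groupby("group")["extinct"].agg(["sum", "count"])
    grp["percent_extinct"] = (100.0 * grp["sum"] / grp["count"]).round().astype(int)
    return grp.rename(columns={"sum": "n_extinct", "count": "n_populations"}).reset_index()


def percentage(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """Share as a percentage rounded to ``ndigits`` (174/205 -> 84.88)."""
    if denominator == 0:
        raise ValueError("denominator must be nonzero")
    return round(100.0 * numerator / denominator, ndigits)


class LogisticGrowthModel(BaseEstimator, RegressorMixin):
    """Least-squares logistic growth fit N(t) = K / (1 + ((K-N0)/N0) e^(-rt)).

    Populations whose overall optical density change is below
    ``min_od_change`` (default 0.05), or whose fit fails, are flagged
    ``no_growth``. Fitted attributes: ``r_`` (per hour), ``K_``, ``N0_``,
    ``growth_flag_``.
    """

    def __init__(self, min_od_change: float = 0.05, min_points: int = 10):
        self.min_od_change = min_od_change
        self.min_points = min_points

    def fit(self, t, od):
        t = np.asarray(t, dtype=float)
        od = np.asarray(od, dtype=float)
        if t.size < self.min_points:
            raise ValueError(f"need at least {self.min_points} time points")
        if (np.diff(t) <= 0).any():
            raise ValueError("time vector must be strictly increasing")
        self.r_ = self.K_ = self.N0_ = None
        if od.max() - od.min() < self.min_od_change:
            self.growth_flag_ = "no_growth"
            return self
        k0 = float(od.max())
        n0 = float(max(od[0], 1e-4))
        p0 = (0.5, k0, n0)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(
                    logistic_curve,
                    t,
                    od,
                    p0=p0,
                    bounds=([1e-6, 1e-6, 1e-9], [100.0, 100.0, 100.0]),
                    maxfev=10000,
                )
        except (RuntimeError, ValueError):
            self.growth_flag_ = "no_growth"
            return self
        self.r_, self.K_, self.N0_ = (float(v) for v in popt)
        self.growth_flag_ = "ok"
        return self

    def predict(self, t):
        if self.growth_flag_ != "ok":
            raise ValueError("no successful fit available")
        return logistic_curve(np.asarray(t, dtype=float), self.r_, self.K_, self.N0_)


def logistic_fit(t, od, min_od_change: float = 0.05) -> tuple:
    """Thin wrapper over :class:`LogisticGrowthModel`; returns
    (r, K, N0, growth_flag)."""
    m = LogisticGrowthModel(min_od_change=min_od_change).fit(t, od)
    return m.r_, m.K_, m.N0_, m.growth_flag_


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact p by full enumeration of the U distribution when the samples are
    untied and n*m <= 10^4 (two-sided p defined as 2 x the smaller tail
    probability, capped at 1); tie-corrected normal approximation
    otherwise. ``mode`` may force ``exact`` or ``normal``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n, m = x.size, y.size
    exact_ok = not _has_ties(x, y) and n * m <= 10_000
    if mode == "exact" and not exact_ok:
        raise ValueError("exact mode requires untied samples with n*m <= 1e4")
    use_exact = exact_ok if mode == "auto" else (mode == "exact")
    u = float(sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic)
    if use_exact:
        p_less = sps.mannwhitneyu(x, y, alternative="less", method="exact").pvalue
        p_greater = sps.mannwhitneyu(x, y, alternative="greater", method="exact").pvalue
        p = min(1.0, 2.0 * min(p_less, p_greater))
        method = "mann_whitney_exact"
    else:
        p = float(
            sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        )
        method = "mann_whitney_normal"
    return TestResult(statistic=u, p_value=float(p), method=method, n=(n, m))


def pearson_gof(
    observed_with: int, observed_total: int, expected_proportion: float
) -> tuple[TestResult, float]:
    """Pearson chi-square goodness of fit (1 df) of (with, without) counts
    against an expected proportion; also returns the observed percentage.

    The expected-by-chance proportion is an input, not recomputed.
    """
    if observed_total <= 0:
        raise ValueError("observed_total must be positive")
    if not 0.0 < expected_proportion < 1.0:
        raise ValueError("expected_proportion must lie in (0, 1)")
    obs = np.array([observed_with, observed_total - observed_with], dtype=float)
    exp = np.array(
        [expected_proportion * observed_total, (1 - expected_proportion) * observed_total]
    )
    if (exp < 1).any():
        warnings.warn("expected cell count below 1; chi-square approximation is poor")
    stat = float(((obs - exp) ** 2 / exp).sum())
    p = float(sps.chi2.sf(stat, df=1))
    observed_percent = percentage(observed_with, observed_total)
    return (
        TestResult(statistic=stat, p_value=max(p, np.finfo(float).tiny), method="pearson_gof", n=(observed_total,)),
        observed_percent,
    )


def _random_overlaps(
    n_a: int, n_b: int, universe_n: int, r: int, rng: np.random.Generator, chunk: int | None = None
) -> np.ndarray:
    """Overlap sizes of ``r`` independent pairs of uniform random subsets.

    Both subsets are drawn explicitly per replicate (top-k of i.i.d. uniform
    scores), chunked to bound memory.
    """
    if chunk is None:
        chunk = max(1, int(4_000_000 // max(universe_n, 1)))
    out = np.empty(r, dtype=np.int64)
    done = 0
    rows = np.arange(chunk)
    while done < r:
        c = min(chunk, r - done)
        mask_a = np.zeros((c, universe_n), dtype=bool)
        mask_b = np.zeros((c, universe_n), dtype=bool)
        idx_a = np.argpartition(rng.random((c, universe_n)), n_a - 1, axis=1)[:, :n_a]
        idx_b = np.argpartition(rng.random((c, universe_n)), n_b - 1, axis=1)[:, :n_b]
        mask_a[rows[:c, None], idx_a] = True
        mask_b[rows[:c, None], idx_b] = True
        out[done : done + c] = (mask_a & mask_b).sum(axis=1)
        done += c
    return out


def overlap_randomization(
    n_a: int,
    n_b: int,
    universe_n: int,
    observed_overlap: int,
    n_replicates: int = 100_000,
    seed: int = 0,
) -> TestResult:
    """Randomization test for the overlap of two gene sets.

    Draws ``n_replicates`` pairs of uniform random subsets of sizes
    ``n_a`` and ``n_b`` from a universe of ``universe_n`` genes;
    p = (1 + #{overlap >= observed}) / (R + 1).
    """
    if not (0 <= n_a <= universe_n and 0 <= n_b <= universe_n):
        raise ValueError("set sizes cannot exceed the universe")
    if observed_overlap > min(n_a, n_b):
        raise ValueError("overlap cannot exceed the smaller set")
    if n_replicates < 1000:
        warnings.warn("fewer than 1000 replicates: poor p-value resolution")
    rng = np.random.default_rng(seed)
    overlaps = _random_overlaps(n_a, n_b, universe_n, n_replicates, rng)
    hits = int((overlaps >= observed_overlap).sum())
    p = (1 + hits) / (n_replicates + 1)
    return TestResult(
        statistic=float(observed_overlap),
        p_value=p,
        method="randomization",
        n=(n_a, n_b, universe_n),
        seed=seed,
    )


def _count_in_windows(
    windows: np.ndarray, feature_starts: np.ndarray, feature_ends: np.ndarray | None, L: int
) -> np.ndarray:
    """Features per circular window; point features when feature_ends is
    None, else interval overlap counts."""
    counts = np.zeros(len(windows), dtype=int)
    for i, (lo, hi) in enumerate(windows):
        lo_m, hi_m = lo % L, hi % L
        if feature_ends is None:
            if lo_m <= hi_m:
                counts[i] = int(((feature_starts >= lo_m) & (feature_starts < hi_m)).sum())
            else:
                counts[i] = int(((feature_starts >= lo_m) | (feature_starts < hi_m)).sum())
        else:
            if lo_m <= hi_m:
                counts[i] = int(((feature_starts < hi_m) & (feature_ends > lo_m)).sum())
            else:
                counts[i] = int(((feature_starts < hi_m) | (feature_ends > lo_m)).sum())
    return counts


def breakpoint_feature_enrichment(
    breakpoint_windows: pd.DataFrame,
    genome_length: int,
    feature_starts,
    feature_ends=None,
    n_random: int = 1000,
    seed: int = 0,
) -> TestResult:
    """Compare feature counts in breakpoint windows against length-matched
    random windows drawn uniformly on the circular genome.

    ``breakpoint_windows`` needs ``start``/``end`` columns. Random windows
    may not overlap any breakpoint window (redrawn if they do); overlaps
    among random windows are allowed. The two count samples are compared by
    :func:`mann_whitney_u`.
    """
    if not len(breakpoint_windows):
        raise ValueError("need at least one breakpoint window")
    rng = np.random.default_rng(seed)
    L = genome_length
    fs = np.asarray(feature_starts)
    fe = np.asarray(feature_ends) if feature_ends is not None else None
    bw = breakpoint_windows[["start", "end"]].to_numpy(dtype=np.int64)
    lengths = (bw[:, 1] - bw[:, 0]) % L
    obs_counts = _count_in_windows(bw, fs, fe, L)

    def overlaps_breakpoints(lo: int, hi: int) -> bool:
        for s, e in bw:
            s_, e_ = s % L, e % L
            for a, b in ((lo % L, hi % L),):
                # unroll circular intervals to linear pieces
                pieces_w = [(a, b)] if a <= b else [(a, L), (0, b)]
                pieces_b = [(s_, e_)] if s_ <= e_ else [(s_, L), (0, e_)]
                for wa, wb in pieces_w:
                    for ba, bb in pieces_b:
                        if wa < bb and ba < wb:
                            return True
        return False

    rand_windows = []
    tries = 0
    while len(rand_windows) < n_random:
        tries += 1
        if tries > 100 * n_random:
            raise RuntimeError("could not place non-overlapping random windows")
        length = int(lengths[rng.integers(0, len(lengths))])
        lo = int(rng.integers(0, L))
        hi = lo + length
        if overlaps_breakpoints(lo, hi):
            continue
        rand_windows.append((lo, hi))
    rand_counts = _count_in_windows(np.array(rand_windows), fs, fe, L)
    if obs_counts.max(initial=0) == 0 and rand_counts.max(initial=0) == 0:
        return TestResult(
            statistic=float("nan"), p_value=1.0, method="mann_whitney_normal",
            n=(len(obs_counts), len(rand_counts)), seed=seed,
        )
    res = mann_whitney_u(obs_counts, rand_counts, mode="auto")
    return TestResult(
        statistic=res.statistic, p_value=res.p_value, method=res.method,
        n=(len(obs_counts), len(rand_counts)), seed=seed,
    )
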