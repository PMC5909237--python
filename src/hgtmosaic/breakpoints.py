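"""Origin reconciliation, breakpoint localization, and OriT distances.

The two origin-assignment methods are consolidated per gene (shared call when
both agree, the single available call otherwise, discordant when they
disagree). Recombination breakpoints are then localized at origin switches:
around each pair of adjacent genes with different final origin, a window is
grown until it holds enough origin-labeled discriminating sites, and the
breakpoint region is the interval between the last site of one origin block
and the first site of the other -- provided the labels form a clean
two-block partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .types import DISCORDANT, DONOR, RECIPIENT, UNDETERMINED, AncestralPair

__all__ = [
    "consolidate",
    "find_origin_switches",
    "localize_breakpoint",
    "distance_to_nearest_oriT",
    "BreakpointMapper",
    "BreakpointRegion",
]

_ASSIGNED = (DONOR, RECIPIENT)


@dataclass
class BreakpointRegion:
    """Interval between two adjacent origin-discordant variant sites with
    clean single-origin flanks (recipient coordinates)."""

    clone_id: str
    left_site_pos: int
    right_site_pos: int
    left_origin: str
    right_origin: str
    n_sites_surveyed: int
    window_used: int


def consolidate(coverage_calls: pd.DataFrame, snp_calls: pd.DataFrame) -> pd.DataFrame:
    """Merge the two per-gene call tables into final origins.

    Final origin is the shared call when both methods assigned one, the
    single available call when only one did, ``discordant`` when both
    assigned and disagree, else ``undetermined``. Genes present in neither
    table are absent from the output.
    """
    cov = coverage_calls[["gene_id", "origin"]].rename(columns={"origin": "origin_coverage"})
    snp = snp_calls[["gene_id", "origin"]].rename(columns={"origin": "origin_snp"})
    df = cov.merge(snp, on="gene_id", how="outer")
    oc = df["origin_coverage"].fillna(UNDETERMINED).to_numpy(dtype=object)
    os_ = df["origin_snp"].fillna(UNDETERMINED).to_numpy(dtype=object)
    final = np.full(len(df), UNDETERMINED, dtype=object)
    methods = np.full(len(df), "", dtype=object)
    c_ok = np.isin(oc, _ASSIGNED)
    s_ok = np.isin(os_, _ASSIGNED)
    both = c_ok & s_ok
    final[both & (oc == os_)] = oc[both & (oc == os_)]
    final[both & (oc != os_)] = DISCORDANT
    only_c = c_ok & ~s_ok
    only_s = s_ok & ~c_ok
    final[only_c] = oc[only_c]
    final[only_s] = os_[only_s]
    methods[both] = "coverage+snp"
    methods[only_c] = "coverage"
    methods[only_s] = "snp"
    out = df.copy()
    out["origin_final"] = final
    out["methods_used"] = methods
    return out


def find_origin_switches(consolidated: pd.DataFrame, universe: pd.DataFrame) -> pd.DataFrame:
    """Ordered adjacent gene pairs whose final origins differ.

    Undetermined and discordant genes are skipped; adjacency is evaluated on
    the remaining genes ordered by genomic position, including the circular
    wrap pair. Output columns: left_gene, right_gene, left_origin,
    right_origin, left_end, right_start.
    """
    df = consolidated.merge(universe[["gene_id", "start", "end"]], on="gene_id")
    df = df[df["origin_final"].isin(_ASSIGNED)].sort_values("start").reset_index(drop=True)
    rows = []
    n = len(df)
    if n < 2:
        return pd.DataFrame(
            columns=["left_gene", "right_gene", "left_origin", "right_origin", "left_end", "right_start"]
        )
    for i in range(n):
        a = df.iloc[i]
        b = df.iloc[(i + 1) % n]
        if a["origin_final"] != b["origin_final"]:
            rows.append(
                (a["gene_id"], b["gene_id"], a["origin_final"], b["origin_final"], a["end"], b["start"])
            )
    return pd.DataFrame(
        rows, columns=["left_gene", "right_gene", "left_origin", "right_origin", "left_end", "right_start"]
    )


def _circular_window_sites(
    positions: np.ndarray, labels: np.ndarray, lo: int, hi: int, L: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sites within the circular interval [lo, hi), ordered from lo."""
    lo_m, hi_m = lo % L, hi % L
    if hi - lo >= L:
        order = np.argsort((positions - lo_m) % L)
        return positions[order], labels[order]
    if lo_m < hi_m:
        sel = (positions >= lo_m) & (positions < hi_m)
        pos, lab = positions[sel], labels[sel]
        order = np.argsort(pos)
    else:
        sel = (positions >= lo_m) | (positions < hi_m)
        pos, lab = positions[sel], labels[sel]
        order = np.argsort((pos - lo_m) % L)
    return pos[order], lab[order]


def localize_breakpoint(
    switch: pd.Series,
    site_positions: np.ndarray,
    site_labels: np.ndarray,
    genome_length: int,
    clone_id: str = "",
    min_sites: int = 30,
    half_window: int = 2000,
    step: int = 1000,
    cap: int = 50000,
    max_discordant: int = 0,
):
    """Localize one breakpoint, or explain why it cannot be.

    Starting from the gap between the two discordant genes padded by
    ``half_window`` on each side, the window grows symmetrically in ``step``
    increments until it holds at least ``min_sites`` origin-labeled sites or
    reaches ``cap`` (half-width). The region is returned only when the site
    labels form a clean two-block partition (at most ``max_discordant``
    off-origin sites, default none) matching the switch direction.

    Returns a :class:`BreakpointRegion` or ``(None, reason)``.
    """
    L = genome_length
    lo = int(switch["left_end"]) - half_window
    hi = int(switch["right_start"]) + half_window
    while True:
        pos, lab = _circular_window_sites(site_positions, site_labels, lo, hi, L)
        if pos.size >= min_sites or (hi - lo) >= 2 * cap:
            break
        lo -= step
        hi += step
    if pos.size < min_sites:
        return None, "insufficient_sites"
    left_origin, right_origin = switch["left_origin"], switch["right_origin"]
    if (lab == right_origin).sum() + (lab == left_origin).sum() != lab.size:
        return None, "mixed"
    want = np.where(lab == left_origin, 0, 1)
    if not want.any() or want.all():
        return None, "one_sided"
    # clean partition 0...0 1...1, tolerating at most max_discordant sites
    # on the wrong side of the best cut
    mismatches, cut = _best_two_block_cut(want)
    if mismatches > max_discordant:
        return None, "mixed"
    left_pos = int(pos[cut])
    right_pos = int(pos[cut + 1])
    return (
        BreakpointRegion(
            clone_id=clone_id,
            left_site_pos=left_pos,
            right_site_pos=right_pos,
            left_origin=left_origin,
            right_origin=right_origin,
            n_sites_surveyed=int(pos.size),
            window_used=int(hi - lo),
        ),
        None,
    )


def _best_two_block_cut(want: np.ndarray) -> tuple[int, int]:
    """Best split of a 0/1 label sequence into a leading 0-block and a
    trailing 1-block: (number of violating sites, index of last 0-block
    site)."""
    n = want.size
    ones_prefix = np.concatenate([[0], np.cumsum(want)])
    costs = np.array(
        [ones_prefix[c] + ((n - c) - (ones_prefix[n] - ones_prefix[c])) for c in range(n + 1)]
    )
    cut = int(np.argmin(costs))
    return int(costs[cut]), max(0, min(cut - 1, n - 2))


def distance_to_nearest_oriT(gene_start: int, orit_positions, genome_length: int) -> dict:
    """Distance downstream (increasing coordinate, modulo genome length) of
    the nearest upstream OriT."""
    if not len(orit_positions):
        raise ValueError("at least one OriT position is required")
    dists = [(int(gene_start) - int(o)) % genome_length for o in orit_positions]
    i = int(np.argmin(dists))
    return {
        "gene_start": int(gene_start),
        "nearest_oriT_pos": int(orit_positions[i]),
        "distance_downstream": int(dists[i]),
    }


class BreakpointMapper(BaseEstimator):
    """End-to-end breakpoint mapping for one clone.

    Consolidates coverage and SNP calls, finds origin switches along the
    genome, and localizes each breakpoint between discriminating sites.
    Parameters mirror :func:`localize_breakpoint`.
    """

    def __init__(
        self,
        min_sites: int = 30,
        half_window: int = 2000,
        step: int = 1000,
        cap: int = 50000,
        max_discordant: int = 0,
    ):
        self.min_sites = min_sites
        self.half_window = half_window
        self.step = step
        self.cap = cap
        self.max_discordant = max_discordant

    def fit(self, pair: AncestralPair, y=None):
        self.pair_ = pair
        self.universe_ = pair.universe()
        return self

    def map_breakpoints(
        self,
        coverage_calls: pd.DataFrame,
        snp_calls: pd.DataFrame,
        labeled_sites: pd.DataFrame,
        clone_id: str = "",
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Returns (breakpoints frame, unresolved-switches frame).

        ``labeled_sites`` is the output of
        :func:`hgtmosaic.snp.label_site_calls`; only usable sites matching
        one ancestor contribute origin labels.
        """
        cons = consolidate(coverage_calls, snp_calls)
        switches = find_origin_switches(cons, self.universe_)
        use = labeled_sites[labeled_sites["match"].isin(_ASSIGNED)]
        pos = use["recipient_pos"].to_numpy()
        lab = use["match"].to_numpy(dtype=object)
        regions, unresolved = [], []
        for _, sw in switches.iterrows():
            region, reason = localize_breakpoint(
                sw,
                pos,
                lab,
                self.pair_.length,
                clone_id=clone_id,
                min_sites=self.min_sites,
                half_window=self.half_window,
                step=self.step,
                cap=self.cap,
                max_discordant=self.max_discordant,
            )
            if region is None:
                unresolved.append((sw["left_gene"], sw["right_gene"], reason))
            else:
                regions.append(region.__dict__)
        bp = pd.DataFrame(
            regions,
            columns=[
                "clone_id",
                "left_site_pos",
                "right_site_pos",
                "left_origin",
                "right_origin",
                "n_sites_surveyed",
                "window_used",
            ],
        )
        unres = pd.DataFrame(unresolved, columns=["left_gene", "right_gene", "reason"])
        return bp, unres

    def orit_distances(self, gene_ids, origin_final: pd.DataFrame | None = None) -> pd.DataFrame:
        """OriT distance table for a set of (transferred) genes."""
        uni = self.universe_.set_index("gene_id")
        rows = []
        for gid in gene_ids:
            d = distance_to_nearest_oriT(
                uni.loc[gid, "start"], self.pair_.orit_positions, self.pair_.length
            )
            d["gene_id"] = gid
            rows.append(d)
        return pd.DataFrame(rows, columns=["gene_id", "gene_start", "nearest_oriT_pos", "distance_downstream"])
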