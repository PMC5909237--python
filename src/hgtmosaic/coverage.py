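"""Coverage-based strain-of-origin assignment.

Each surveyed gene is assigned an origin from the fraction of its reads that
mapped to the donor versus the recipient reference: donor when more than a
threshold tau (default 60%) of reads map to the donor copy, recipient when
less than 1 - tau do (the symmetric rule), undetermined in between.
Strain-unique genes, which exist on only one reference, are instead called
present/absent from their read count against a detection floor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .types import DONOR, RECIPIENT, UNDETERMINED, AncestralPair

__all__ = [
    "CoverageOriginClassifier",
    "donor_read_fraction",
    "assign_origin_by_coverage",
    "survey_universe",
    "threshold_sensitivity",
]


def donor_read_fraction(donor_reads: int, recipient_reads: int) -> float:
    """Fraction of a gene's reads attributable to the donor reference.

    Example: 200 donor-mapped and 50 recipient-mapped reads give 0.80, i.e.
    80% of reads are of donor origin.
    """
    total = donor_reads + recipient_reads
    if total <= 0:
        raise ValueError("donor_read_fraction undefined at zero coverage")
    return donor_reads / total


def assign_origin_by_coverage(f: float, tau: float = 0.6) -> str:
    """Origin label from a donor read fraction.

    Donor iff f > tau (strict, per the 'more than 60%' rule), recipient iff
    f < 1 - tau, undetermined in the closed band between.
    """
    if not 0.5 < tau < 1.0:
        raise ValueError(f"tau must lie in (0.5, 1), got {tau}")
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {f}")
    if f > tau:
        return DONOR
    if f < 1.0 - tau:
        return RECIPIENT
    return UNDETERMINED


def survey_universe(pair: AncestralPair) -> set:
    """Gene ids eligible for origin inference: one-to-one orthologues plus
    strain-unique genes, minus the exclusion mask."""
    uni = pair.universe()
    return set(uni.loc[~uni["masked"], "gene_id"])


class CoverageOriginClassifier(BaseEstimator):
    """Per-gene origin calls from dual-reference read counts.

    Parameters
    ----------
    tau : float, default 0.6
        Donor-fraction threshold; donor calls require f > tau, recipient
        calls f < 1 - tau.
    min_reads : int, default 10
        Minimum total reads for a fraction-based call; below this the gene
        is undetermined (a 60% rule on very few reads is binomially
        unstable).
    unique_floor_fraction : float, default 0.1
        A strain-unique gene is called present when its read count exceeds
        this fraction of the mean per-gene coverage.

    After :meth:`fit`, ``universe_`` holds the eligible survey universe and
    ``mean_coverage_`` the per-gene coverage used for the unique-gene floor.
    """

    def __init__(self, tau: float = 0.6, min_reads: int = 10, unique_floor_fraction: float = 0.1):
        self.tau = tau
        self.min_reads = min_reads
        self.unique_floor_fraction = unique_floor_fraction

    def fit(self, pair: AncestralPair, y=None):
        if not 0.5 < self.tau < 1.0:
            raise ValueError(f"tau must lie in (0.5, 1), got {self.tau}")
        self.pair_ = pair
        self.universe_ = pair.universe()
        if pair.config is not None:
            self.mean_coverage_ = float(pair.config.mean_coverage)
        else:
            self.mean_coverage_ = None
        return self

    def _floor(self, coverage: pd.DataFrame) -> float:
        mean_cov = self.mean_coverage_
        if mean_cov is None:
            totals = coverage["donor_reads"] + coverage["recipient_reads"]
            mean_cov = float(np.median(totals[totals > 0])) if (totals > 0).any() else 0.0
        return self.unique_floor_fraction * mean_cov

    def predict_frame(self, coverage: pd.DataFrame, tau: float | None = None) -> pd.DataFrame:
        """Full per-gene call table.

        ``coverage`` columns: gene_id, donor_reads, recipient_reads.
        Output columns: gene_id, kind, donor_fraction, n_reads, origin,
        eligible, reason, method.
        """
        tau = self.tau if tau is None else tau
        uni = self.universe_
        df = uni.merge(coverage, on="gene_id", how="left")
        missing = df["donor_reads"].isna()
        df.loc[missing, ["donor_reads", "recipient_reads"]] = 0
        d = df["donor_reads"].to_numpy(dtype=np.int64)
        r = df["recipient_reads"].to_numpy(dtype=np.int64)
        total = d + r
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, d / np.maximum(total, 1), np.nan)

        n = len(df)
        origin = np.full(n, UNDETERMINED, dtype=object)
        reason = np.full(n, "", dtype=object)
        eligible = ~df["masked"].to_numpy()
        reason[~eligible] = "masked"

        kind = df["kind"].to_numpy()
        # orthologues with no discriminating site carry no origin signal:
        # their reads split ~50/50 between the two references regardless of
        # the clone's true origin, so they cannot be surveyed
        n_disc = df["n_disc_sites"].to_numpy()
        unsurv = (kind == "orthologue") & eligible & (n_disc == 0)
        eligible = eligible & ~unsurv
        reason[unsurv] = "not_surveyable"

        orth = (kind == "orthologue") & eligible
        zero = orth & (total == 0)
        low = orth & (total > 0) & (total < self.min_reads)
        ok = orth & (total >= self.min_reads)
        reason[zero] = "zero_coverage"
        reason[low] = "low_coverage"
        origin[ok & (frac > tau)] = DONOR
        origin[ok & (frac < 1.0 - tau)] = RECIPIENT

        floor = self._floor(coverage)
        du = (kind == "donor_unique") & eligible
        ru = (kind == "recipient_unique") & eligible
        origin[du & (d > floor)] = DONOR
        origin[ru & (r > floor)] = RECIPIENT
        absent = (du & (d <= floor)) | (ru & (r <= floor))
        reason[absent] = "absent"

        out = pd.DataFrame(
            {
                "gene_id": df["gene_id"],
                "kind": kind,
                "donor_fraction": frac,
                "n_reads": total,
                "origin": origin,
                "eligible": eligible,
                "reason": reason,
                "method": "coverage",
            }
        )
        return out

    def predict(self, coverage: pd.DataFrame) -> np.ndarray:
        """Origin labels only, aligned with the survey universe."""
        return self.predict_frame(coverage)["origin"].to_numpy()


def threshold_sensitivity(
    classifier: CoverageOriginClassifier,
    coverage: pd.DataFrame,
    alternative_taus: list,
) -> dict:
    """Fraction of eligible genes whose origin label changes when the
    threshold is moved away from the classifier's tau."""
    base = classifier.predict_frame(coverage)
    base = base[base["eligible"]]
    out = {}
    for tau in alternative_taus:
        alt = classifier.predict_frame(coverage, tau=tau)
        alt = alt[alt["eligible"]]
        changed = (base["origin"].to_numpy() != alt["origin"].to_numpy()).sum()
        out[tau] = changed / len(base)
    return out
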