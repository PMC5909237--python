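"""Convenience orchestration of the per-clone analysis.

Runs both origin-assignment methods, consolidates them, maps breakpoints,
and calls de novo mutations for one clone's evidence against an ancestor
pair. Returned frames are exactly what the CLI writes to disk.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .breakpoints import BreakpointMapper, consolidate
from .coverage import CoverageOriginClassifier
from .denovo import DenovoCaller
from .snp import SnpOriginClassifier, label_site_calls
from .types import AncestralPair, CloneEvidence


@dataclass
class CloneAnalysis:
    clone_id: str
    coverage_calls: pd.DataFrame
    snp_calls: pd.DataFrame
    consolidated: pd.DataFrame
    breakpoints: pd.DataFrame
    unresolved_switches: pd.DataFrame
    mutations: pd.DataFrame
    exclusion_tally: dict


def analyse_clone(
    pair: AncestralPair,
    evidence: CloneEvidence,
    tau: float = 0.6,
    snp_window: int = 1000,
    snp_k: int = 3,
    min_breakpoint_sites: int = 30,
) -> CloneAnalysis:
    cov = CoverageOriginClassifier(tau=tau).fit(pair)
    snp = SnpOriginClassifier(window=snp_window, k=snp_k).fit(pair)
    cov_calls = cov.predict_frame(evidence.gene_coverage)
    snp_calls = snp.predict_frame(evidence.genotype_calls)
    cons = consolidate(cov_calls, snp_calls)
    mapper = BreakpointMapper(min_sites=min_breakpoint_sites).fit(pair)
    labeled = label_site_calls(pair, evidence.genotype_calls)
    bps, unresolved = mapper.map_breakpoints(
        cov_calls, snp_calls, labeled, clone_id=evidence.clone_id
    )
    caller = DenovoCaller().fit(pair)
    muts, tally = caller.call_clone(
        evidence.non_discriminating_calls, consolidated=cons, clone_id=evidence.clone_id
    )
    return CloneAnalysis(
        clone_id=evidence.clone_id,
        coverage_calls=cov_calls,
        snp_calls=snp_calls,
        consolidated=cons,
        breakpoints=bps,
        unresolved_switches=unresolved,
        mutations=muts,
        exclusion_tally=tally,
    )
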