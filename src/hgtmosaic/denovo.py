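"""De novo mutation calling against the origin-appropriate ancestor.

A clone allele is a de novo mutation when it differs from the alleles of
*both* ancestral genomes at that site; sites with a missing genotype in
either ancestor or the clone are excluded. Because a transferred gene's
local reference is the donor, each gene is analysed against the genome its
consolidated origin points to; genes with undetermined or discordant origin
are skipped. Coding effects are classified on the bacterial codon table
(NCBI table 11) with the alternative starts GTG/TTG treated as Met at
protein position 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqUtils import seq3
from sklearn.base import BaseEstimator

from .types import DISCORDANT, DONOR, MISSING, RECIPIENT, UNDETERMINED, AncestralPair, codes_to_str

__all__ = ["DenovoCaller", "select_reference", "call_denovo", "annotate_effect"]

_TABLE11 = unambiguous_dna_by_id[11]
_START_CODONS = set(_TABLE11.start_codons)


def select_reference(origin_final: str):
    """Origin context used as the gene's local reference, or None when the
    gene must be skipped (undetermined / discordant origin)."""
    if origin_final in (DONOR, RECIPIENT):
        return origin_final
    return None


def call_denovo(clone_call: str, donor_allele: str, recipient_allele: str):
    """Derived allele if the clone differs from both ancestors, else None.

    Raises ``ValueError`` on any missing genotype; callers count such sites
    in an exclusion tally rather than interpreting them.
    """
    if MISSING in (clone_call, donor_allele, recipient_allele):
        raise ValueError("missing genotype: site must be excluded")
    if clone_call != donor_allele and clone_call != recipient_allele:
        return clone_call
    return None


def _codon_aa(codon: str, codon_index: int) -> str:
    if codon_index == 0 and codon in _START_CODONS:
        return "M"
    if codon in _TABLE11.stop_codons:
        return "*"
    return str(Seq(codon).translate(table=11))


def annotate_effect(
    position: int,
    derived_allele: str,
    gene: pd.Series | None,
    genome_seq: np.ndarray,
    deletion_length: int = 0,
) -> tuple[str, str]:
    """Classify a mutation's coding effect; returns (effect, protein_change).

    ``gene`` carries start/end/strand (0-based half-open, collinear
    coordinates); ``genome_seq`` is the origin reference as a uint8 code
    array. Substitutions are compared codon against codon; length changes
    are frameshift unless divisible by 3 (then an in-frame deletion, label
    ``del``). Positions outside any gene are intergenic.
    """
    if gene is None:
        return "intergenic", ""
    if deletion_length:
        if deletion_length % 3 != 0:
            return "frameshift", "fs"
        return "deletion", "del"
    start, end, strand = int(gene["start"]), int(gene["end"]), gene["strand"]
    if strand == "+":
        offset = position - start
    else:
        offset = end - 1 - position
    codon_index = offset // 3
    within = offset % 3
    if strand == "+":
        cstart = start + codon_index * 3
        codon = codes_to_str(genome_seq[cstart : cstart + 3])
        alt_codon = codon[:within] + derived_allele + codon[within + 1 :]
    else:
        cstart = end - (codon_index + 1) * 3
        fwd = codes_to_str(genome_seq[cstart : cstart + 3])
        codon = str(Seq(fwd).reverse_complement())
        alt_codon = codon[:within] + str(Seq(derived_allele).reverse_complement()) + codon[within + 1 :]
    ref_aa = _codon_aa(codon, codon_index)
    alt_aa = _codon_aa(alt_codon, codon_index)
    aa_pos = codon_index + 1
    if alt_aa == "*" and ref_aa != "*":
        return "stop_gain", f"{seq3(ref_aa)}{aa_pos}*"
    if ref_aa == alt_aa:
        return "synonymous", f"{seq3(ref_aa)}{aa_pos}{seq3(alt_aa)}"
    return "missense", f"{seq3(ref_aa)}{aa_pos}{seq3(alt_aa)}"


class DenovoCaller(BaseEstimator):
    """Origin-aware de novo mutation caller for one clone.

    After :meth:`fit` on an :class:`AncestralPair`, :meth:`call_clone`
    screens the clone's surveyed site calls against both ancestral alleles
    and annotates coding effects against the origin-appropriate reference.
    """

    def __init__(self):
        pass

    def fit(self, pair: AncestralPair, y=None):
        self.pair_ = pair
        uni = pair.universe()
        self.universe_ = uni
        self._starts = uni["start"].to_numpy()
        self._ends = uni["end"].to_numpy()
        return self

    def _gene_at(self, position: int):
        idx = np.searchsorted(self._starts, position, side="right") - 1
        if idx >= 0 and position < self._ends[idx]:
            return self.universe_.iloc[idx]
        return None

    def call_clone(
        self,
        site_calls: pd.DataFrame,
        consolidated: pd.DataFrame | None = None,
        clone_id: str = "",
    ) -> tuple[pd.DataFrame, dict]:
        """Call de novo mutations from surveyed site calls.

        ``site_calls`` columns: position, call. ``consolidated`` (optional)
        supplies per-gene final origins; without it every gene is analysed
        in recipient context. Intergenic sites inherit the origin of the
        preceding assigned gene (segment membership proxy). Returns the
        mutation record frame and an exclusion tally.
        """
        pair = self.pair_
        origin_by_gene = {}
        if consolidated is not None:
            origin_by_gene = dict(
                zip(consolidated["gene_id"], consolidated["origin_final"])
            )
        tally = {"missing": 0, "skipped_gene": 0, "surveyed": 0}
        rows = []
        for _, row in site_calls.iterrows():
            pos = int(row["position"])
            call = row["call"]
            tally["surveyed"] += 1
            donor_allele = codes_to_str(pair.donor_seq[pos : pos + 1])
            recipient_allele = codes_to_str(pair.recipient_seq[pos : pos + 1])
            if call == MISSING:
                tally["missing"] += 1
                continue
            gene = self._gene_at(pos)
            if gene is not None:
                origin = origin_by_gene.get(gene["gene_id"], RECIPIENT)
                context = select_reference(origin)
                if context is None:
                    tally["skipped_gene"] += 1
                    continue
            else:
                context = self._intergenic_context(pos, origin_by_gene)
            derived = call_denovo(call, donor_allele, recipient_allele)
            if derived is None:
                continue
            genome = pair.donor_seq if context == DONOR else pair.recipient_seq
            effect, pchange = annotate_effect(pos, derived, gene, genome)
            rows.append(
                (
                    clone_id,
                    pos,
                    gene["gene_id"] if gene is not None else "",
                    context,
                    donor_allele,
                    recipient_allele,
                    derived,
                    effect,
                    pchange,
                )
            )
        records = pd.DataFrame(
            rows,
            columns=[
                "clone_id",
                "position",
                "gene_id",
                "origin_context",
                "donor_ancestral_allele",
                "recipient_ancestral_allele",
                "derived_allele",
                "effect",
                "protein_change",
            ],
        )
        return records, tally

    def _intergenic_context(self, position: int, origin_by_gene: dict) -> str:
        """Origin of the nearest preceding gene with an assigned origin."""
        uni = self.universe_
        idx = np.searchsorted(self._starts, position, side="right") - 1
        n = len(uni)
        for back in range(n):
            j = (idx - back) % n
            origin = origin_by_gene.get(uni.iloc[j]["gene_id"], UNDETERMINED)
            if origin in (DONOR, RECIPIENT):
                return origin
        return RECIPIENT

    def rollup(self, records: pd.DataFrame) -> pd.DataFrame:
        """Per-gene clone-count rollup of mutation records."""
        coding = records[records["gene_id"] != ""]
        if not len(coding):
            return pd.DataFrame(columns=["gene_id", "n_variant_sites", "n_clones"])
        grp = coding.groupby("gene_id").agg(
            n_variant_sites=("position", "nunique"),
            n_clones=("clone_id", "nunique"),
        )
        return grp.reset_index()
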