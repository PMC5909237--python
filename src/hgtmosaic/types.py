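"""Domain containers shared across the pipeline.

The pipeline operates on post-alignment evidence, not reads: an
:class:`AncestralPair` describes the donor/recipient reference universe
(genomes, genes, one-to-one orthologues, discriminating SNPs, OriT sites,
exclusion mask), a :class:`CloneTruth` holds the simulated ground truth for a
recombinant clone, and a :class:`CloneEvidence` holds what alignment and
genotype calling against *both* references would have produced for that clone.

Coordinates are 0-based half-open internally; genome arithmetic is modulo the
(circular) genome length. Tabular fields are plain :class:`pandas.DataFrame`
objects so they round-trip through the TSV interfaces in :mod:`hgtmosaic.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

DONOR = "donor"
RECIPIENT = "recipient"
UNDETERMINED = "undetermined"
CONFLICT = "conflict"
DISCORDANT = "discordant"
BOUNDARY = "boundary"

#: Missing genotype call sentinel in evidence tables.
MISSING = "N"

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_STR = "ACGT"

REPEAT_CLASSES = ("transposon", "prophage", "repeat_region", "tandem_repeat")


def codes_to_str(codes: np.ndarray) -> str:
    """Convert a uint8 base-code array (0..3 -> ACGT) to a string."""
    return BASES[codes].tobytes().decode("ascii")


def str_to_codes(seq: str) -> np.ndarray:
    """Convert an ACGT string to the internal uint8 code array."""
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(raw.shape, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        codes[raw == b] = i
    if (codes == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return codes


def code_to_base(code: int) -> str:
    return _BASE_STR[int(code)]


@dataclass
class SimConfig:
    """Knobs of the stated simulation world.

    Defaults mirror the experimental system being emulated: two E. coli-like
    ancestors at ~1% nucleotide divergence in orthologous regions with ~10%
    strain-unique genes per genome, three OriT sites on the donor chromosome,
    ~100x mean per-gene sequencing coverage, and small post-alignment error
    rates (per-read mismapping 1%, genotype miscall 0.2%, missing call 1%,
    dual-alignment inconsistency 0.5%).
    """

    genome_length: int = 1_000_000
    n_genes: int = 900
    divergence: float = 0.01
    unique_gene_fraction: float = 0.10
    n_orit: int = 3
    mean_coverage: float = 100.0
    identical_region_split: float = 0.5
    map_error: float = 0.01
    genotype_miscall_rate: float = 0.002
    genotype_missing_rate: float = 0.01
    inconsistency_rate: float = 0.005
    segment_length_mean: float = 200_000.0
    n_masked_genes: int = 20
    n_repeats: int = 60
    od_noise_sd: float = 0.01
    rng_seed: int = 0

    def validate(self) -> None:
        probs = {
            "divergence": self.divergence,
            "unique_gene_fraction": self.unique_gene_fraction,
            "identical_region_split": self.identical_region_split,
            "map_error": self.map_error,
            "genotype_miscall_rate": self.genotype_miscall_rate,
            "genotype_missing_rate": self.genotype_missing_rate,
            "inconsistency_rate": self.inconsistency_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if 2 * self.unique_gene_fraction >= 1.0:
            raise ValueError("unique_gene_fraction per genome must be < 0.5")
        if self.genome_length <= 0 or self.n_genes <= 0:
            raise ValueError("genome_length and n_genes must be positive")
        if self.n_orit < 1:
            raise ValueError("need at least one OriT")


@dataclass
class TransferSegment:
    """A contiguous donor segment transferred by conjugation.

    The segment starts at an OriT (``donor_start`` must equal the position of
    OriT ``start_oriT_index``) and covers the circular half-open interval
    ``[donor_start, donor_end)``; ``donor_end <= donor_start`` denotes a
    segment wrapping the origin.
    """

    start_oriT_index: int
    donor_start: int
    donor_end: int
    retained: bool = True

    def length(self, genome_length: int) -> int:
        n = (self.donor_end - self.donor_start) % genome_length
        return n if n > 0 else genome_length


@dataclass
class AncestralPair:
    """The donor/recipient reference universe.

    ``genes`` has one row per gene copy (columns ``gene_id``, ``genome``,
    ``start``, ``end``, ``strand``, ``product_class``); orthologous slots
    appear once per genome under paired ids, linked by ``orthologues``
    (columns ``donor_gene_id``, ``recipient_gene_id``, a bijection).
    ``snp_table`` lists inter-ancestor discriminating sites (columns
    ``donor_pos``, ``recipient_pos``, ``donor_allele``, ``recipient_allele``,
    ``gene_id`` -- empty string for intergenic sites).
    """

    donor_seq: np.ndarray
    recipient_seq: np.ndarray
    length: int
    genes: pd.DataFrame
    orthologues: pd.DataFrame
    donor_unique_genes: set
    recipient_unique_genes: set
    snp_table: pd.DataFrame
    orit_positions: list
    exclusion_mask: set
    repeat_track: pd.DataFrame
    config: SimConfig | None = None
    _universe: pd.DataFrame | None = field(default=None, repr=False)

    def universe(self) -> pd.DataFrame:
        """Survey universe, one row per comparable unit.

        Keyed by the recipient gene id for orthologue pairs and
        recipient-unique genes, and by the donor gene id for donor-unique
        genes. Columns: ``gene_id``, ``kind`` (orthologue / donor_unique /
        recipient_unique), ``start``, ``end``, ``strand``, ``masked``,
        ``n_disc_sites``.
        """
        if self._universe is not None:
            return self._universe
        orth = self.orthologues
        rec_genes = self.genes[self.genes["genome"] == RECIPIENT].set_index("gene_id")
        don_genes = self.genes[self.genes["genome"] == DONOR].set_index("gene_id")
        rows = []
        for rid in orth["recipient_gene_id"]:
            g = rec_genes.loc[rid]
            rows.append((rid, "orthologue", g["start"], g["end"], g["strand"]))
        for gid in sorted(self.donor_unique_genes):
            g = don_genes.loc[gid]
            rows.append((gid, "donor_unique", g["start"], g["end"], g["strand"]))
        for gid in sorted(self.recipient_unique_genes):
            g = rec_genes.loc[gid]
            rows.append((gid, "recipient_unique", g["start"], g["end"], g["strand"]))
        uni = pd.DataFrame(rows, columns=["gene_id", "kind", "start", "end", "strand"])
        uni = uni.sort_values("start", kind="stable").reset_index(drop=True)
        uni["masked"] = uni["gene_id"].isin(self.exclusion_mask)
        counts = self.snp_table["gene_id"].value_counts() if len(self.snp_table) else pd.Series(dtype=int)
        uni["n_disc_sites"] = uni["gene_id"].map(counts).fillna(0).astype(int)
        self._universe = uni
        return uni

    def check_invariants(self) -> None:
        orth = self.orthologues
        if orth["donor_gene_id"].duplicated().any() or orth["recipient_gene_id"].duplicated().any():
            raise AssertionError("orthologue map is not a bijection")
        dom = set(orth["donor_gene_id"]) | set(orth["recipient_gene_id"])
        if (self.donor_unique_genes | self.recipient_unique_genes) & dom:
            raise AssertionError("unique genes overlap the orthologue domain")
        if len(self.snp_table):
            same = self.snp_table["donor_allele"] == self.snp_table["recipient_allele"]
            if same.any():
                raise AssertionError("discriminating site with identical alleles")
        for p in self.orit_positions:
            if not 0 <= p < self.length:
                raise AssertionError("OriT outside genome")
        ids = set(self.genes["gene_id"])
        if not set(self.exclusion_mask) <= ids:
            raise AssertionError("exclusion mask references unknown genes")


@dataclass
class CloneTruth:
    """Ground truth for one simulated recombinant clone.

    ``origin_map`` is a per-base uint8 array (0 = recipient, 1 = donor);
    ``denovo_mutations`` has columns ``position``, ``donor_allele``,
    ``recipient_allele``, ``derived_allele``, ``origin_context``.
    """

    clone_id: str
    transfer_segments: list
    origin_map: np.ndarray
    denovo_mutations: pd.DataFrame

    def gene_origin(self, pair: AncestralPair) -> pd.DataFrame:
        """Per survey-universe gene: true origin and presence in the clone.

        ``true_origin`` is donor/recipient for genes fully inside one origin
        block and ``boundary`` for genes straddling a segment edge. Unique
        genes are ``present`` only when the clone carries the hosting
        genome's DNA at their locus.
        """
        uni = pair.universe()
        cum = np.concatenate([[0], np.cumsum(self.origin_map, dtype=np.int64)])
        starts = uni["start"].to_numpy()
        ends = uni["end"].to_numpy()
        donor_bases = cum[ends] - cum[starts]
        lengths = ends - starts
        frac = donor_bases / lengths
        origin = np.where(frac == 1.0, DONOR, np.where(frac == 0.0, RECIPIENT, BOUNDARY))
        out = uni[["gene_id", "kind"]].copy()
        out["true_origin"] = origin
        out["donor_base_fraction"] = frac
        present = np.ones(len(uni), dtype=bool)
        du = (uni["kind"] == "donor_unique").to_numpy()
        ru = (uni["kind"] == "recipient_unique").to_numpy()
        present[du] = frac[du] == 1.0
        present[ru] = frac[ru] == 0.0
        out["present"] = present
        return out


@dataclass
class CloneEvidence:
    """Post-alignment observables for one clone.

    ``gene_coverage``: gene_id, donor_reads, recipient_reads (one row per
    survey-universe gene). ``genotype_calls``: one row per discriminating
    site with the call from each alignment (missing = ``N``).
    ``non_discriminating_calls``: clone calls at additional surveyed sites
    (here, the planted-mutation sites), one ``call`` column.
    """

    clone_id: str
    gene_coverage: pd.DataFrame
    genotype_calls: pd.DataFrame
    non_discriminating_calls: pd.DataFrame
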