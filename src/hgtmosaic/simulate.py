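"""Synthetic ancestor pairs, recombinant clones, and their evidence tables.

The generator produces the *inputs* of the analysis pipeline at the level
where alignment and genotype calling have already happened: per-gene read
counts split by reference and per-site genotype calls from both alignments.
Every stochastic choice flows through one seeded :class:`numpy.random`
generator, so a fixed :class:`~hgtmosaic.types.SimConfig` reproduces the same
ancestor pair, clone truths, and evidence byte for byte.

Model in brief:

* A recipient chromosome of ``genome_length`` random bases carries
  ``n_genes`` non-overlapping genes (length a multiple of 3, >= 300 bp,
  never spanning the replication origin). A fixed fraction of gene slots is
  unique to each genome; the rest are one-to-one orthologues. Donor and
  recipient coordinates are kept collinear (no inter-ancestor indels).
* Discriminating SNPs arise per aligned base with probability ``divergence``
  (unique-gene loci are unalignable and carry none).
* Conjugative transfer plants contiguous donor segments anchored at OriT
  positions; the resulting per-base origin map is the ground truth that
  recovery tests compare against.
* Read counts per gene are Poisson(``mean_coverage``); reads from genes with
  at least one discriminating site map to the true-origin reference with
  probability ``1 - map_error``, reads from zero-SNP orthologues map to
  either reference with probability ``identical_region_split``, and
  strain-unique genes receive reads on their only reference in proportion to
  how much of their locus the clone actually carries.
* Genotype calls equal the true-origin allele (or a planted derived allele)
  subject to miscall, missing, and dual-alignment inconsistency rates.
"""

from __future__ import annotations

import zlib
from dataclasses import replace

import numpy as np
import pandas as pd

from .types import (
    BOUNDARY,
    DONOR,
    MISSING,
    RECIPIENT,
    REPEAT_CLASSES,
    AncestralPair,
    CloneEvidence,
    CloneTruth,
    SimConfig,
    TransferSegment,
    code_to_base,
)

_MIN_GAP = 20  # minimum intergenic spacer, bp

__all__ = [
    "generate_ancestral_pair",
    "plant_transfers",
    "plant_denovo",
    "emit_clone_evidence",
    "emit_growth_and_plating",
    "draw_transfer_segments",
    "simulate_clone",
    "logistic_curve",
]


def _clone_rng(config: SimConfig, clone_id: str, stream: int = 0) -> np.random.Generator:
    """Deterministic per-clone generator derived from the config seed."""
    key = zlib.crc32(clone_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(config.rng_seed, spawn_key=(key, stream)))


def generate_ancestral_pair(config: SimConfig) -> AncestralPair:
    """Generate a donor/recipient ancestor pair under ``config``.

    Raises a sizing error when the genome cannot host ``n_genes`` genes with
    minimal intergenic spacers.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    L, n = config.genome_length, config.n_genes

    # gene lengths: multiples of 3 in [300, 1500]
    lengths = rng.integers(100, 501, size=n) * 3
    total = int(lengths.sum())
    budget = L - total - (n + 1) * _MIN_GAP
    if budget < 0:
        raise ValueError(
            f"genome of {L} bp too short to host {n} genes totalling {total} bp"
        )
    gaps = rng.multinomial(budget, np.full(n + 1, 1.0 / (n + 1))) + _MIN_GAP
    starts = np.cumsum(gaps[:-1] + np.concatenate([[0], lengths[:-1]]))
    ends = starts + lengths

    # gene classes: fixed counts of unique genes per genome
    n_uni = int(round(config.unique_gene_fraction * n))
    perm = rng.permutation(n)
    donor_unique_slots = set(perm[:n_uni].tolist())
    recipient_unique_slots = set(perm[n_uni : 2 * n_uni].tolist())

    strands = np.where(rng.random(n) < 0.5, "+", "-")

    # sequences: shared backbone, unique-gene loci replaced on the donor side
    recipient_seq = rng.integers(0, 4, size=L, dtype=np.uint8)
    donor_seq = recipient_seq.copy()
    aligned = np.ones(L, dtype=bool)
    for i in sorted(donor_unique_slots | recipient_unique_slots):
        s, e = int(starts[i]), int(ends[i])
        donor_seq[s:e] = rng.integers(0, 4, size=e - s, dtype=np.uint8)
        aligned[s:e] = False

    # discriminating SNPs in the aligned fraction
    hit = (rng.random(L) < config.divergence) & aligned
    pos = np.nonzero(hit)[0]
    shift = rng.integers(1, 4, size=pos.size).astype(np.uint8)
    donor_seq[pos] = (donor_seq[pos] + shift) % 4

    gene_rows = []
    orth_rows = []
    donor_unique_ids: set = set()
    recipient_unique_ids: set = set()
    for i in range(n):
        s, e, st = int(starts[i]), int(ends[i]), strands[i]
        did, rid = f"d{i:04d}", f"r{i:04d}"
        if i in donor_unique_slots:
            gene_rows.append((did, DONOR, s, e, st, "unique"))
            donor_unique_ids.add(did)
        elif i in recipient_unique_slots:
            gene_rows.append((rid, RECIPIENT, s, e, st, "unique"))
            recipient_unique_ids.add(rid)
        else:
            gene_rows.append((did, DONOR, s, e, st, "orthologous"))
            gene_rows.append((rid, RECIPIENT, s, e, st, "orthologous"))
            orth_rows.append((did, rid))
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "genome", "start", "end", "strand", "product_class"]
    )
    orthologues = pd.DataFrame(orth_rows, columns=["donor_gene_id", "recipient_gene_id"])

    # map each SNP to its containing orthologous gene (or intergenic)
    orth_slots = np.array(sorted(set(range(n)) - donor_unique_slots - recipient_unique_slots))
    site_gene = np.full(pos.size, "", dtype=object)
    if pos.size and orth_slots.size:
        os_, oe_ = starts[orth_slots], ends[orth_slots]
        idx = np.searchsorted(os_, pos, side="right") - 1
        ok = (idx >= 0) & (pos < oe_[np.clip(idx, 0, None)])
        for j in np.nonzero(ok)[0]:
            site_gene[j] = f"r{orth_slots[idx[j]]:04d}"
    snp_table = pd.DataFrame(
        {
            "donor_pos": pos,
            "recipient_pos": pos,
            "donor_allele": [code_to_base(c) for c in donor_seq[pos]],
            "recipient_allele": [code_to_base(c) for c in recipient_seq[pos]],
            "gene_id": site_gene,
        }
    )

    orit_positions = sorted(int(p) for p in rng.choice(L, size=config.n_orit, replace=False))

    rep_starts = rng.integers(0, L, size=config.n_repeats)
    rep_lens = rng.integers(500, 3001, size=config.n_repeats)
    repeat_track = pd.DataFrame(
        {
            "start": rep_starts,
            "end": np.minimum(rep_starts + rep_lens, L),
            "element_class": rng.choice(REPEAT_CLASSES, size=config.n_repeats),
        }
    ).sort_values("start").reset_index(drop=True)

    mask_pool = orthologues["recipient_gene_id"].to_numpy()
    n_mask = min(config.n_masked_genes, mask_pool.size)
    masked_rec = rng.choice(mask_pool, size=n_mask, replace=False)
    exclusion_mask = set(masked_rec.tolist())
    # mark both copies of a masked orthologue
    rec_to_don = dict(zip(orthologues["recipient_gene_id"], orthologues["donor_gene_id"]))
    masked_all = exclusion_mask | {rec_to_don[g] for g in exclusion_mask}
    genes.loc[genes["gene_id"].isin(masked_all), "product_class"] = "masked"

    pair = AncestralPair(
        donor_seq=donor_seq,
        recipient_seq=recipient_seq,
        length=L,
        genes=genes,
        orthologues=orthologues,
        donor_unique_genes=donor_unique_ids,
        recipient_unique_genes=recipient_unique_ids,
        snp_table=snp_table,
        orit_positions=orit_positions,
        exclusion_mask=exclusion_mask,
        repeat_track=repeat_track,
        config=config,
    )
    pair.check_invariants()
    return pair


def _segment_mask(L: int, seg: TransferSegment) -> np.ndarray:
    m = np.zeros(L, dtype=bool)
    s, e = seg.donor_start % L, seg.donor_end % L
    if s < e:
        m[s:e] = True
    else:  # wraps the origin
        m[s:] = True
        m[:e] = True
    return m


def plant_transfers(pair: AncestralPair, clone_id: str, segments: list) -> CloneTruth:
    """Build the per-base origin map for a clone carrying ``segments``.

    Segments must be anchored at an OriT position and retained segments may
    not overlap one another (overlap would leave the origin undefined).
    """
    L = pair.length
    origin = np.zeros(L, dtype=np.uint8)
    covered = np.zeros(L, dtype=bool)
    for seg in segments:
        anchor = pair.orit_positions[seg.start_oriT_index]
        if seg.donor_start % L != anchor:
            raise ValueError(
                f"segment start {seg.donor_start} is not OriT #{seg.start_oriT_index} ({anchor})"
            )
        if seg.length(L) <= 0:
            raise ValueError("zero-length transfer segment")
        if not seg.retained:
            continue
        m = _segment_mask(L, seg)
        if (m & covered).any():
            raise ValueError("overlapping retained transfer segments: origin undefined")
        covered |= m
        origin[m] = 1
    return CloneTruth(
        clone_id=clone_id,
        transfer_segments=list(segments),
        origin_map=origin,
        denovo_mutations=pd.DataFrame(
            columns=["position", "donor_allele", "recipient_allele", "derived_allele", "origin_context"]
        ),
    )


def draw_transfer_segments(
    pair: AncestralPair,
    n_segments: int,
    rng: np.random.Generator,
    mean_length: float | None = None,
    max_fraction: float = 0.35,
    max_tries: int = 1000,
) -> list:
    """Draw ``n_segments`` non-overlapping retained segments.

    Each is anchored at a uniformly chosen OriT with exponential length
    (mean ``segment_length_mean`` by default), truncated at
    ``max_fraction`` of the genome so several segments can coexist on the
    circle, and resampled on overlap.
    """
    L = pair.length
    mean_length = mean_length if mean_length is not None else pair.config.segment_length_mean
    cap = max(1, int(max_fraction * L))
    for _ in range(max_tries):
        # draw the whole set fresh each attempt: keeping an unlucky first
        # segment that covers the remaining OriT anchors would deadlock
        segs: list = []
        covered = np.zeros(L, dtype=bool)
        ok = True
        for _ in range(n_segments):
            k = int(rng.integers(0, len(pair.orit_positions)))
            start = pair.orit_positions[k]
            length = int(min(max(1, round(rng.exponential(mean_length))), cap))
            seg = TransferSegment(k, start, (start + length) % L, retained=True)
            m = _segment_mask(L, seg)
            if (m & covered).any():
                ok = False
                break
            covered |= m
            segs.append(seg)
        if ok:
            return segs
    raise RuntimeError("could not place non-overlapping transfer segments")


def plant_denovo(
    truth: CloneTruth, pair: AncestralPair, n_mutations: int, seed: int
) -> CloneTruth:
    """Plant ``n_mutations`` substitutions whose derived allele differs from
    both ancestors, avoiding discriminating-site positions."""
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    if n_mutations == 0:
        return truth
    rng = np.random.default_rng(seed)
    forbidden = set(pair.snp_table["donor_pos"].tolist())
    rows = []
    chosen: set = set()
    while len(rows) < n_mutations:
        p = int(rng.integers(0, pair.length))
        if p in forbidden or p in chosen:
            continue
        chosen.add(p)
        da, ra = int(pair.donor_seq[p]), int(pair.recipient_seq[p])
        options = [b for b in range(4) if b not in (da, ra)]
        derived = int(options[rng.integers(0, len(options))])
        ctx = DONOR if truth.origin_map[p] else RECIPIENT
        rows.append((p, code_to_base(da), code_to_base(ra), code_to_base(derived), ctx))
    muts = pd.DataFrame(
        rows, columns=["position", "donor_allele", "recipient_allele", "derived_allele", "origin_context"]
    ).sort_values("position").reset_index(drop=True)
    return replace(truth, denovo_mutations=muts)


def _noisy_calls(
    true_codes: np.ndarray, rng: np.random.Generator, miscall: float, missing: float
) -> np.ndarray:
    """Apply miscall (uniform over the other three bases) and missingness.

    Returns an object array of base letters with ``N`` for missing.
    """
    n = true_codes.size
    call = true_codes.copy()
    bad = rng.random(n) < miscall
    call[bad] = (call[bad] + rng.integers(1, 4, size=int(bad.sum())).astype(np.uint8)) % 4
    out = np.array([code_to_base(c) for c in call], dtype=object)
    out[rng.random(n) < missing] = MISSING
    return out


def emit_clone_evidence(
    pair: AncestralPair, truth: CloneTruth, config: SimConfig | None = None
) -> CloneEvidence:
    """Emit the post-alignment evidence tables a clone would have produced."""
    config = config if config is not None else pair.config
    rng = _clone_rng(config, truth.clone_id)
    uni = pair.universe()
    gorigin = truth.gene_origin(pair)
    frac = gorigin["donor_base_fraction"].to_numpy()
    kind = uni["kind"].to_numpy()
    n_sites = uni["n_disc_sites"].to_numpy()

    totals = rng.poisson(config.mean_coverage, size=len(uni))

    p_donor = np.empty(len(uni))
    orth = kind == "orthologue"
    eps = config.map_error
    # discriminating genes: true-origin mapping with prob 1 - eps; boundary
    # genes mix the two sides in proportion to their donor base fraction
    p_donor[orth] = frac[orth] * (1 - eps) + (1 - frac[orth]) * eps
    p_donor[orth & (n_sites == 0)] = config.identical_region_split

    donor_reads = np.zeros(len(uni), dtype=np.int64)
    recipient_reads = np.zeros(len(uni), dtype=np.int64)
    donor_reads[orth] = rng.binomial(totals[orth], p_donor[orth])
    recipient_reads[orth] = totals[orth] - donor_reads[orth]

    du = kind == "donor_unique"
    ru = kind == "recipient_unique"
    # unique genes: reads appear on the hosting reference only, in proportion
    # to how much of the locus the clone carries from that genome
    donor_reads[du] = rng.binomial(totals[du], frac[du])
    recipient_reads[ru] = rng.binomial(totals[ru], 1.0 - frac[ru])

    gene_coverage = pd.DataFrame(
        {
            "gene_id": uni["gene_id"],
            "donor_reads": donor_reads,
            "recipient_reads": recipient_reads,
        }
    )

    snp = pair.snp_table
    S = len(snp)
    if S:
        spos = snp["donor_pos"].to_numpy()
        from_donor = truth.origin_map[spos] == 1
        true_allele = np.where(from_donor, snp["donor_allele"], snp["recipient_allele"])
        true_codes = np.array(
            ["ACGT".index(a) for a in true_allele], dtype=np.uint8
        )
        call = _noisy_calls(true_codes, rng, config.genotype_miscall_rate, config.genotype_missing_rate)
        other = call.copy()
        inc = (rng.random(S) < config.inconsistency_rate) & (call != MISSING)
        if inc.any():
            codes = np.array(["ACGT".index(c) for c in call[inc]], dtype=np.uint8)
            codes = (codes + rng.integers(1, 4, size=codes.size).astype(np.uint8)) % 4
            other[inc] = [code_to_base(c) for c in codes]
        genotype_calls = pd.DataFrame(
            {
                "donor_pos": snp["donor_pos"],
                "recipient_pos": snp["recipient_pos"],
                "call_donor_aln": call,
                "call_recipient_aln": other,
            }
        )
    else:
        genotype_calls = pd.DataFrame(
            columns=["donor_pos", "recipient_pos", "call_donor_aln", "call_recipient_aln"]
        )

    muts = truth.denovo_mutations
    if len(muts):
        codes = np.array(["ACGT".index(a) for a in muts["derived_allele"]], dtype=np.uint8)
        calls = _noisy_calls(codes, rng, config.genotype_miscall_rate, config.genotype_missing_rate)
        nd = pd.DataFrame({"position": muts["position"], "call": calls})
    else:
        nd = pd.DataFrame(columns=["position", "call"])

    return CloneEvidence(
        clone_id=truth.clone_id,
        gene_coverage=gene_coverage,
        genotype_calls=genotype_calls,
        non_discriminating_calls=nd,
    )


def simulate_clone(
    pair: AncestralPair,
    clone_id: str,
    n_segments: int = 2,
    n_denovo: int = 5,
    config: SimConfig | None = None,
) -> tuple[CloneTruth, CloneEvidence]:
    """Convenience wrapper: draw segments, plant mutations, emit evidence."""
    config = config if config is not None else pair.config
    rng = _clone_rng(config, clone_id, stream=1)
    segs = draw_transfer_segments(pair, n_segments, rng)
    truth = plant_transfers(pair, clone_id, segs)
    truth = plant_denovo(truth, pair, n_denovo, seed=int(rng.integers(0, 2**31 - 1)))
    evidence = emit_clone_evidence(pair, truth, config)
    return truth, evidence


def logistic_curve(t: np.ndarray, r: float, K: float, N0: float) -> np.ndarray:
    """Logistic growth N(t) = K / (1 + ((K - N0)/N0) exp(-r t))."""
    t = np.asarray(t, dtype=float)
    if r == 0:
        return np.full_like(t, N0)
    return K / (1.0 + ((K - N0) / N0) * np.exp(-r * t))


def emit_growth_and_plating(
    fitness_params: list,
    config: SimConfig,
    hours: float = 48.0,
    step_minutes: float = 10.0,
    plated_volume_ml: float = 0.1,
    adapted_dilution: float = 1e4,
    total_dilution: float = 1e6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate growth curves (OD600 every 10 min over 48 h, Gaussian noise)
    and plating counts (Poisson around density x volume / dilution).

    ``fitness_params`` is a list of dicts with keys ``population``, ``r``,
    ``K``, ``N0`` and optionally ``adapted_density`` / ``total_density``
    (cfu/ml) for the plating assay.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed, spawn_key=(101,)))
    t = np.arange(0.0, hours + 1e-9, step_minutes / 60.0)
    growth_rows = []
    plating_rows = []
    for p in fitness_params:
        od = logistic_curve(t, p["r"], p["K"], p["N0"])
        od = od + rng.normal(0.0, config.od_noise_sd, size=t.size)
        for ti, oi in zip(t, od):
            growth_rows.append((p["population"], ti, oi))
        if "adapted_density" in p and "total_density" in p:
            lam_a = p["adapted_density"] * plated_volume_ml / adapted_dilution
            lam_t = p["total_density"] * plated_volume_ml / total_dilution
            plating_rows.append(
                (
                    p["population"],
                    int(rng.poisson(lam_a)),
                    adapted_dilution,
                    int(rng.poisson(lam_t)),
                    total_dilution,
                    plated_volume_ml,
                )
            )
    growth = pd.DataFrame(growth_rows, columns=["population", "time_h", "od600"])
    plating = pd.DataFrame(
        plating_rows,
        columns=[
            "population",
            "colonies_adapted",
            "dilution_adapted",
            "colonies_total",
            "dilution_total",
            "plated_volume_ml",
        ],
    )
    return growth, plating
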