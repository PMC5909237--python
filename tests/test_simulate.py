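"""Generator behaviour: determinism, divergence calibration, truth
consistency, and the evidence model's noise-free limit."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import hgtmosaic as hm
from hgtmosaic.simulate import draw_transfer_segments, emit_growth_and_plating, logistic_curve
from hgtmosaic.types import BOUNDARY, DONOR, RECIPIENT


class TestGenerateAncestralPair:
    def test_zero_divergence_gives_no_discriminating_sites(self):
        cfg = hm.SimConfig(genome_length=100_000, n_genes=90, divergence=0.0, rng_seed=2)
        pair = hm.generate_ancestral_pair(cfg)
        assert len(pair.snp_table) == 0

    def test_realized_snp_count_within_binomial_interval(self):
        # central 99.9% binomial interval at p = divergence over aligned bases
        cfg = hm.SimConfig(genome_length=100_000, n_genes=90, divergence=0.01, rng_seed=7)
        pair = hm.generate_ancestral_pair(cfg)
        uni = pair.universe()
        unique_bp = int(
            (uni.loc[uni["kind"] != "orthologue", "end"] - uni.loc[uni["kind"] != "orthologue", "start"]).sum()
        )
        aligned = cfg.genome_length - unique_bp
        lo = sps.binom.ppf(0.0005, aligned, cfg.divergence)
        hi = sps.binom.ppf(0.9995, aligned, cfg.divergence)
        assert lo <= len(pair.snp_table) <= hi

    def test_no_unique_genes_means_full_orthologue_map(self):
        cfg = hm.SimConfig(genome_length=100_000, n_genes=90, unique_gene_fraction=0.0, rng_seed=3)
        pair = hm.generate_ancestral_pair(cfg)
        assert len(pair.orthologues) == 90
        assert not pair.donor_unique_genes and not pair.recipient_unique_genes

    def test_unique_gene_fraction_within_two_percent(self, small_pair, small_config):
        n = small_config.n_genes
        for s in (small_pair.donor_unique_genes, small_pair.recipient_unique_genes):
            assert abs(len(s) / n - small_config.unique_gene_fraction) <= 0.02

    def test_deterministic_for_fixed_seed(self, small_config, small_pair):
        again = hm.generate_ancestral_pair(small_config)
        assert np.array_equal(again.donor_seq, small_pair.donor_seq)
        pd.testing.assert_frame_equal(again.snp_table, small_pair.snp_table)
        assert again.orit_positions == small_pair.orit_positions

    def test_genome_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            hm.generate_ancestral_pair(hm.SimConfig(genome_length=10_000, n_genes=100, rng_seed=1))

    def test_divergence_converges_at_one_megabase(self):
        # realized divergence within 3 standard errors of the target
        cfg = hm.SimConfig(rng_seed=11)
        pair = hm.generate_ancestral_pair(cfg)
        uni = pair.universe()
        unique_bp = int(
            (uni.loc[uni["kind"] != "orthologue", "end"] - uni.loc[uni["kind"] != "orthologue", "start"]).sum()
        )
        aligned = cfg.genome_length - unique_bp
        p = cfg.divergence
        se = np.sqrt(p * (1 - p) / aligned)
        assert abs(len(pair.snp_table) / aligned - p) < 3 * se

    def test_three_orits_by_default(self, small_pair):
        assert len(small_pair.orit_positions) == 3


class TestPlantTransfers:
    def test_no_segments_all_recipient(self, small_pair):
        truth = hm.plant_transfers(small_pair, "c", [])
        assert not truth.origin_map.any()

    def test_gene_inside_segment_is_donor(self, small_pair):
        uni = small_pair.universe()
        orit = small_pair.orit_positions[0]
        # a segment long enough to fully cover at least one gene
        seg = hm.TransferSegment(0, orit, (orit + 30_000) % small_pair.length)
        truth = hm.plant_transfers(small_pair, "c", [seg])
        go = truth.gene_origin(small_pair)
        inside = uni[(uni["start"] >= orit) & (uni["end"] <= orit + 30_000)]
        assert len(inside) > 0
        got = go.set_index("gene_id").loc[inside["gene_id"], "true_origin"]
        assert (got == DONOR).all()

    def test_boundary_spanning_gene_flagged(self, small_pair):
        uni = small_pair.universe()
        orit = small_pair.orit_positions[0]
        # end the segment strictly inside some gene
        host = uni[(uni["start"] > orit + 1000) & (uni["end"] < orit + 40_000)].iloc[0]
        mid = (host["start"] + host["end"]) // 2
        seg = hm.TransferSegment(0, orit, int(mid))
        truth = hm.plant_transfers(small_pair, "c", [seg])
        go = truth.gene_origin(small_pair).set_index("gene_id")
        assert go.loc[host["gene_id"], "true_origin"] == BOUNDARY

    def test_overlapping_segments_rejected(self, small_pair):
        orit = small_pair.orit_positions[0]
        a = hm.TransferSegment(0, orit, (orit + 10_000) % small_pair.length)
        b = hm.TransferSegment(0, orit, (orit + 5_000) % small_pair.length)
        with pytest.raises(ValueError, match="overlap"):
            hm.plant_transfers(small_pair, "c", [a, b])

    def test_segment_must_anchor_at_orit(self, small_pair):
        with pytest.raises(ValueError, match="OriT"):
            hm.plant_transfers(small_pair, "c", [hm.TransferSegment(0, 12345, 50_000)])


class TestPlantDenovo:
    def test_zero_mutations_is_identity(self, small_pair):
        truth = hm.plant_transfers(small_pair, "c", [])
        assert hm.plant_denovo(truth, small_pair, 0, seed=1) is truth

    def test_derived_allele_differs_from_both_ancestors(self, small_pair):
        truth = hm.plant_transfers(small_pair, "c", [])
        truth = hm.plant_denovo(truth, small_pair, 50, seed=5)
        for _, m in truth.denovo_mutations.iterrows():
            assert m["derived_allele"] != m["donor_allele"]
            assert m["derived_allele"] != m["recipient_allele"]
        # planted positions avoid discriminating sites
        assert not set(truth.denovo_mutations["position"]) & set(small_pair.snp_table["donor_pos"])

    def test_deterministic_for_fixed_seed(self, small_pair):
        truth = hm.plant_transfers(small_pair, "c", [])
        a = hm.plant_denovo(truth, small_pair, 5, seed=9)
        b = hm.plant_denovo(truth, small_pair, 5, seed=9)
        pd.testing.assert_frame_equal(a.denovo_mutations, b.denovo_mutations)


class TestEmitCloneEvidence:
    def test_noise_free_donor_gene_fully_donor_mapped(self, noisefree_pair):
        orit = noisefree_pair.orit_positions[0]
        seg = hm.TransferSegment(0, orit, (orit + 50_000) % noisefree_pair.length)
        truth = hm.plant_transfers(noisefree_pair, "c", [seg])
        ev = hm.emit_clone_evidence(noisefree_pair, truth)
        uni = noisefree_pair.universe()
        go = truth.gene_origin(noisefree_pair).set_index("gene_id")
        cov = ev.gene_coverage.set_index("gene_id")
        donor_orth = uni[
            (uni["kind"] == "orthologue")
            & (uni["n_disc_sites"] > 0)
            & (go.loc[uni["gene_id"], "true_origin"] == DONOR).to_numpy()
        ]
        assert len(donor_orth) > 0
        sub = cov.loc[donor_orth["gene_id"]]
        assert (sub["recipient_reads"] == 0).all()
        assert (sub["donor_reads"] > 0).all()
        # all discriminating-site calls equal the true-origin allele
        labeled = ev.genotype_calls.merge(noisefree_pair.snp_table, on=["donor_pos", "recipient_pos"])
        from_donor = truth.origin_map[labeled["donor_pos"].to_numpy()] == 1
        expected = np.where(from_donor, labeled["donor_allele"], labeled["recipient_allele"])
        assert (labeled["call_donor_aln"].to_numpy() == expected).all()
        assert (labeled["call_recipient_aln"].to_numpy() == expected).all()

    def test_zero_snp_gene_split_is_binomial_half(self):
        # donor-mapped fraction of an identical gene within the central
        # 99.9% binomial interval around 0.5 at 200 reads
        cfg = hm.SimConfig(
            genome_length=100_000, n_genes=90, divergence=0.0, mean_coverage=200.0, rng_seed=13
        )
        pair = hm.generate_ancestral_pair(cfg)
        truth = hm.plant_transfers(pair, "c", [])
        ev = hm.emit_clone_evidence(pair, truth)
        uni = pair.universe()
        cov = ev.gene_coverage.set_index("gene_id")
        orth = uni[uni["kind"] == "orthologue"]["gene_id"]
        d = cov.loc[orth, "donor_reads"].to_numpy()
        t = d + cov.loc[orth, "recipient_reads"].to_numpy()
        lo = sps.binom.ppf(0.0005, t, 0.5)
        hi = sps.binom.ppf(0.9995, t, 0.5)
        ok = (d >= lo) & (d <= hi)
        # individual genes may graze the 99.9% interval; all but a couple must sit inside
        assert ok.mean() > 0.99

    def test_read_count_conservation(self, small_pair, small_clone):
        truth, ev = small_clone
        # orthologous genes: donor + recipient reads reproduce one Poisson total
        uni = small_pair.universe()
        cov = ev.gene_coverage.set_index("gene_id")
        totals = cov["donor_reads"] + cov["recipient_reads"]
        assert (totals >= 0).all()
        assert len(cov) == len(uni)
        assert not cov.index.duplicated().any()

    def test_byte_identical_for_fixed_seed(self, small_pair, small_clone, tmp_path):
        import hgtmosaic.io as hio

        truth, ev = small_clone
        ev2 = hm.emit_clone_evidence(small_pair, truth)
        hio.write_evidence(ev, tmp_path / "a", small_pair.config)
        hio.write_evidence(ev2, tmp_path / "b", small_pair.config)
        for name in ("gene_coverage", "genotype_calls", "site_calls"):
            fa = (tmp_path / "a" / f"cloneA.{name}.tsv").read_bytes()
            fb = (tmp_path / "b" / f"cloneA.{name}.tsv").read_bytes()
            assert fa == fb


class TestGrowthAndPlating:
    def test_flat_curve_when_rate_zero(self):
        cfg = hm.SimConfig(rng_seed=5, od_noise_sd=0.001)
        growth, _ = emit_growth_and_plating(
            [{"population": "p1", "r": 0.0, "K": 1.0, "N0": 0.05}], cfg
        )
        od = growth["od600"].to_numpy()
        assert od.max() - od.min() < 0.05

    def test_noise_free_matches_closed_form(self):
        cfg = hm.SimConfig(rng_seed=5, od_noise_sd=0.0)
        growth, _ = emit_growth_and_plating(
            [{"population": "p1", "r": 0.5, "K": 1.2, "N0": 0.03}], cfg
        )
        t = growth["time_h"].to_numpy()
        expected = logistic_curve(t, 0.5, 1.2, 0.03)
        np.testing.assert_allclose(growth["od600"].to_numpy(), expected, rtol=1e-12)
        assert len(t) == 48 * 6 + 1  # every 10 min over 48 h

    def test_identical_outputs_for_fixed_seed(self):
        cfg = hm.SimConfig(rng_seed=8)
        params = [{"population": "p", "r": 0.4, "K": 1.0, "N0": 0.02,
                   "adapted_density": 5e6, "total_density": 1e9}]
        g1, p1 = emit_growth_and_plating(params, cfg)
        g2, p2 = emit_growth_and_plating(params, cfg)
        pd.testing.assert_frame_equal(g1, g2)
        pd.testing.assert_frame_equal(p1, p2)


def test_segment_drawing_respects_orit_anchoring(small_pair):
    rng = np.random.default_rng(4)
    segs = draw_transfer_segments(small_pair, 2, rng)
    for s in segs:
        assert s.donor_start == small_pair.orit_positions[s.start_oriT_index]
        assert s.length(small_pair.length) > 0
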