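"""Readers and writers for the pipeline's on-disk interfaces.

Ancestor pairs are written as FASTA (genomes), GFF3 (genes and repeat
track), BED (OriT positions, exclusion mask), and TSV (orthologues,
discriminating-SNP table); evidence tables and call tables are TSV with a
``#`` header line naming the generating config seed; truth is JSON;
mutations additionally go out as a minimal VCF. External coordinates are
1-based inclusive (GFF3/VCF), internal ones 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    DONOR,
    RECIPIENT,
    AncestralPair,
    CloneEvidence,
    CloneTruth,
    SimConfig,
    TransferSegment,
    codes_to_str,
    str_to_codes,
)


def _header(config: SimConfig | None) -> str:
    if config is None:
        return "# hgtmosaic\n"
    return f"# hgtmosaic seed={config.rng_seed} genome_length={config.genome_length}\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: SimConfig | None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_pair(pair: AncestralPair, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    SeqIO.write(
        [SeqRecord(Seq(codes_to_str(pair.donor_seq)), id="donor", description="ancestral donor")],
        out / "donor.fasta",
        "fasta",
    )
    SeqIO.write(
        [SeqRecord(Seq(codes_to_str(pair.recipient_seq)), id="recipient", description="ancestral recipient")],
        out / "recipient.fasta",
        "fasta",
    )
    with open(out / "genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in pair.genes.iterrows():
            attrs = f"ID={g['gene_id']};product_class={g['product_class']}"
            fh.write(
                f"{g['genome']}\thgtmosaic\tgene\t{g['start'] + 1}\t{g['end']}\t.\t{g['strand']}\t.\t{attrs}\n"
            )
        for _, r in pair.repeat_track.iterrows():
            fh.write(
                f"recipient\thgtmosaic\trepeat_region\t{r['start'] + 1}\t{r['end']}\t.\t+\t.\t"
                f"element_class={r['element_class']}\n"
            )
    with open(out / "orit.bed", "w") as fh:
        for p in pair.orit_positions:
            fh.write(f"donor\t{p}\t{p + 1}\toriT\n")
    with open(out / "mask.bed", "w") as fh:
        genes = pair.genes.set_index("gene_id")
        for gid in sorted(pair.exclusion_mask):
            g = genes.loc[gid]
            g = g.iloc[0] if isinstance(g, pd.DataFrame) else g
            fh.write(f"recipient\t{g['start']}\t{g['end']}\t{gid}\n")
    _write_tsv(pair.orthologues, out / "orthologues.tsv", pair.config)
    _write_tsv(pair.snp_table, out / "snp_table.tsv", pair.config)
    if pair.config is not None:
        with open(out / "config.json", "w") as fh:
            json.dump(pair.config.__dict__, fh, indent=1)


def load_pair(indir) -> AncestralPair:
    ind = Path(indir)
    donor = next(SeqIO.parse(ind / "donor.fasta", "fasta"))
    recipient = next(SeqIO.parse(ind / "recipient.fasta", "fasta"))
    donor_seq = str_to_codes(str(donor.seq))
    recipient_seq = str_to_codes(str(recipient.seq))
    gene_rows, repeat_rows = [], []
    with open(ind / "genes.gff3") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            seqid, _, ftype, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            kv = dict(a.split("=", 1) for a in attrs.split(";") if "=" in a)
            if ftype == "gene":
                gene_rows.append(
                    (kv["ID"], seqid, int(start) - 1, int(end), strand, kv.get("product_class", ""))
                )
            else:
                repeat_rows.append((int(start) - 1, int(end), kv.get("element_class", "repeat_region")))
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "genome", "start", "end", "strand", "product_class"]
    )
    repeat_track = pd.DataFrame(repeat_rows, columns=["start", "end", "element_class"])
    orthologues = read_tsv(ind / "orthologues.tsv")
    snp_table = read_tsv(ind / "snp_table.tsv")
    if len(snp_table):
        snp_table["gene_id"] = snp_table["gene_id"].fillna("")
    orit = []
    with open(ind / "orit.bed") as fh:
        for line in fh:
            orit.append(int(line.split("\t")[1]))
    mask = set()
    mask_path = ind / "mask.bed"
    if mask_path.exists():
        with open(mask_path) as fh:
            for line in fh:
                mask.add(line.rstrip("\n").split("\t")[3])
    config = None
    cfg_path = ind / "config.json"
    if cfg_path.exists():
        with open(cfg_path) as fh:
            config = SimConfig(**json.load(fh))
    orth_dom = set(orthologues["donor_gene_id"]) | set(orthologues["recipient_gene_id"])
    donor_unique = set(genes.loc[(genes["genome"] == DONOR), "gene_id"]) - orth_dom
    recipient_unique = set(genes.loc[(genes["genome"] == RECIPIENT), "gene_id"]) - orth_dom
    pair = AncestralPair(
        donor_seq=donor_seq,
        recipient_seq=recipient_seq,
        length=len(donor_seq),
        genes=genes,
        orthologues=orthologues,
        donor_unique_genes=donor_unique,
        recipient_unique_genes=recipient_unique,
        snp_table=snp_table,
        orit_positions=sorted(orit),
        exclusion_mask=mask,
        repeat_track=repeat_track,
        config=config,
    )
    pair.check_invariants()
    return pair


def write_evidence(evidence: CloneEvidence, outdir, config: SimConfig | None = None) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(evidence.gene_coverage, out / f"{evidence.clone_id}.gene_coverage.tsv", config)
    _write_tsv(evidence.genotype_calls, out / f"{evidence.clone_id}.genotype_calls.tsv", config)
    _write_tsv(
        evidence.non_discriminating_calls, out / f"{evidence.clone_id}.site_calls.tsv", config
    )


def load_evidence(indir, clone_id: str) -> CloneEvidence:
    ind = Path(indir)
    return CloneEvidence(
        clone_id=clone_id,
        gene_coverage=read_tsv(ind / f"{clone_id}.gene_coverage.tsv"),
        genotype_calls=read_tsv(ind / f"{clone_id}.genotype_calls.tsv"),
        non_discriminating_calls=read_tsv(ind / f"{clone_id}.site_calls.tsv"),
    )


def write_truth(truth: CloneTruth, path) -> None:
    """Truth as JSON: segments, planted mutations, and the origin map as
    run-length encoded (start, origin) blocks."""
    origin = truth.origin_map
    change = np.nonzero(np.diff(origin))[0] + 1
    starts = np.concatenate([[0], change])
    blocks = [[int(s), int(origin[s])] for s in starts]
    doc = {
        "clone_id": truth.clone_id,
        "transfer_segments": [
            {
                "start_oriT_index": s.start_oriT_index,
                "donor_start": s.donor_start,
                "donor_end": s.donor_end,
                "retained": s.retained,
            }
            for s in truth.transfer_segments
        ],
        "denovo_mutations": truth.denovo_mutations.to_dict(orient="records"),
        "origin_blocks": blocks,
        "genome_length": int(origin.size),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_truth(path) -> CloneTruth:
    with open(path) as fh:
        doc = json.load(fh)
    L = doc["genome_length"]
    origin = np.zeros(L, dtype=np.uint8)
    blocks = doc["origin_blocks"]
    for i, (start, val) in enumerate(blocks):
        end = blocks[i + 1][0] if i + 1 < len(blocks) else L
        origin[start:end] = val
    return CloneTruth(
        clone_id=doc["clone_id"],
        transfer_segments=[TransferSegment(**s) for s in doc["transfer_segments"]],
        origin_map=origin,
        denovo_mutations=pd.DataFrame(
            doc["denovo_mutations"],
            columns=["position", "donor_allele", "recipient_allele", "derived_allele", "origin_context"],
        ),
    )


def write_breakpoints_bed(breakpoints: pd.DataFrame, path) -> None:
    """Breakpoint regions as BED on recipient coordinates, score = number
    of surveyed sites."""
    with open(path, "w") as fh:
        for _, b in breakpoints.iterrows():
            fh.write(
                f"recipient\t{b['left_site_pos']}\t{b['right_site_pos']}\t"
                f"{b['clone_id']}:{b['left_origin']}-{b['right_origin']}\t{b['n_sites_surveyed']}\n"
            )


def write_mutations_vcf(records: pd.DataFrame, path) -> None:
    """De novo mutations as a minimal VCF (CHROM = origin reference, REF =
    origin-ancestral allele)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id or intergenic">\n')
        fh.write('##INFO=<ID=EFFECT,Number=1,Type=String,Description="Coding effect">\n')
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Protein change">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, r in records.iterrows():
            ref = (
                r["donor_ancestral_allele"]
                if r["origin_context"] == DONOR
                else r["recipient_ancestral_allele"]
            )
            gene = r["gene_id"] if r["gene_id"] else "intergenic"
            info = f"GENE={gene};EFFECT={r['effect']}"
            if r["protein_change"]:
                info += f";AA={r['protein_change']}"
            fh.write(
                f"{r['origin_context']}\t{r['position'] + 1}\t.\t{ref}\t{r['derived_allele']}\t.\tPASS\t{info}\n"
            )
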