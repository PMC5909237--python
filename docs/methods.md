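# Methods

## Scope and evidence model

`hgtmosaic` detects donor-derived DNA in evolved clones of a bacterial
donor/recipient pair, starting from *post-alignment* evidence rather than
reads: for each clone, (i) per-gene read counts split by which reference
(donor or recipient) the reads aligned to, and (ii) per-site genotype calls
made from each of the two alignments. Upstream read alignment, duplicate
marking and genotype calling are outside the package; their output shape is
the contract. This keeps the package desk-scale and makes every inference
step checkable against simulated ground truth.

Coordinates are 0-based half-open internally (1-based in GFF3/VCF output)
and all genome arithmetic is modulo the circular genome length.

## Synthetic-data generator

The generator emulates a pair of *E. coli*-like ancestors and the evidence
their recombinant descendants would produce.

**Ancestor pair.** A recipient chromosome of `genome_length` (default 1 Mb)
i.i.d. random bases hosts `n_genes` (default 900, ~1 gene/kbp as in
*E. coli*) non-overlapping genes with lengths uniform over multiples of 3 in
[300, 1500] bp; genes never span the replication origin. A fixed count
`round(unique_gene_fraction × n_genes)` of gene slots per genome (default
10% each, within the 7–19% strain-unique range typical of *E. coli* strain
pairs) is unique to that genome: the other genome carries unrelated random
sequence at the locus. The remaining slots are one-to-one orthologues.
Donor and recipient coordinates are collinear (no inter-ancestor indels);
discriminating SNPs arise per aligned base (everything outside unique-gene
loci) with probability `divergence` (default 0.01, matching the ~0.8–1.4%
nucleotide divergence of the emulated strain pairs). The donor carries
three OriT positions (uniform), a repeat track (60 elements of 0.5–3 kb per
Mb across four element classes), and an exclusion mask of `n_masked_genes`
orthologues (default 20, ~2% of genes — mirroring the proportion of
pre-experiment HGT candidates excluded in the emulated analysis).

**Clones.** Transfer segments are contiguous, anchored at an OriT, with
exponential length (mean 200 kb) truncated at 35% of the genome so several
segments can coexist; retained segments may not overlap (whole-set
redraw on conflict). The per-base origin map they induce is the ground
truth. De novo substitutions are planted at non-SNP positions with a
derived allele differing from both ancestors.

**Evidence.** Per gene, total reads ~ Poisson(`mean_coverage`, default
100). Reads of orthologues with ≥ 1 discriminating SNP map to the
true-origin reference with probability `1 − map_error` (default 0.01; the
real per-read mismapping rate between strain references is unknown, so this
is a free parameter, not an estimate); zero-SNP orthologues split 50/50;
boundary-spanning genes mix the two sides in proportion to their donor base
fraction. Strain-unique genes receive reads on their only reference in
proportion to how much of the locus the clone carries. Genotype calls equal
the true-origin allele subject to a miscall rate (`0.002`, uniform over the
other three bases), a missing rate (`0.01`), and a dual-alignment
inconsistency rate (`0.005`). All randomness flows from one seeded
generator; per-clone streams are derived deterministically from the config
seed and the clone id (CRC32), so outputs are byte-reproducible.

What the generator does **not** emulate: indels and structural variants
between ancestors or in clones, read-level artifacts (quality, GC bias,
chimeras), alignment-score pathologies near repeats, donor-population
dynamics during co-culture, and selection (segment retention is specified,
not evolved). A green recovery test therefore establishes correctness of
the inference logic on this evidence model, not robustness to real-data
artifacts upstream of it.

## Coverage-based origin assignment

`f = donor_reads / (donor_reads + recipient_reads)`; donor iff `f > τ`
(strict, default 0.6), recipient iff `f < 1 − τ`, undetermined between.
Only the donor rule is classical; the recipient rule is made symmetric to
avoid asymmetric bias. Additional rules, all configurable:

* genes with < 10 total reads are undetermined (`low_coverage`): a 60%
  rule on a handful of reads is binomially unstable;
* zero-read genes are undetermined (`zero_coverage`);
* orthologues with **no** discriminating SNP are ineligible
  (`not_surveyable`): their reads split ~50/50 regardless of true origin,
  so any fraction-based call would be a coin flip (at 100× coverage a
  50/50 split exceeds 60% with probability ≈ 1.8% per gene);
* strain-unique genes are present (origin = hosting genome) when their
  read count exceeds 10% of mean per-gene coverage, absent otherwise;
* masked genes are excluded (`masked`).

`threshold_sensitivity` recomputes labels at alternative τ and reports the
changed fraction of the eligible universe.

## SNP-based origin assignment

Candidate genes have discriminating-SNP density strictly above 3 per kbp of
gene length. A site is usable only when both alignments call the same
non-missing genotype. A gene is donor-origin when ≥ k (default 3) usable
donor-matching sites fall within a sliding window of ≤ 1000 bp (any span
between first and last qualifying site — the most permissive reading;
fixed tiles would miss straddling clusters); recipient by the symmetric
rule; `conflict` when both fire (a window is not required to be free of
opposite-matching sites — conflicts are reported instead). Inconsistent
sites are tallied but never support an origin.

## Consolidation, breakpoints, OriT distances

Final origin = shared call when both methods agree, the single available
call when only one applies, `discordant` (excluded from breakpoint search)
when they disagree. Origin switches are adjacent gene pairs with different
final origins, evaluated on assigned genes ordered along the genome,
including the circular wrap pair.

For each switch, a window from the flanking genes' facing ends ± 2 kb is
grown symmetrically in 1 kb steps until it holds ≥ 30 origin-labeled usable
sites, up to a 50 kb half-width cap (the cap bounds runtime; real window
growth depends on local sequence similarity). If the labels form a clean
two-block partition matching the switch direction (at most `max_discordant`
violations, default 0 — strict by design, relaxable for noisy data), the
breakpoint region is the interval between the last site of the first block
and the first site of the second. Otherwise the switch is reported
unresolved with a reason (`insufficient_sites`, `mixed`, `one_sided`).

OriT distance for a transferred gene is `(gene_start − oriT) mod L`
minimized over OriTs — downstream in the increasing-coordinate direction,
a convention chosen because real Hfr transfer direction depends on the
insert orientation, which is not modeled.

## De novo mutations

A site yields a mutation record iff the clone's call differs from **both**
ancestral alleles; any missing genotype excludes the site (tallied). Genes
are analysed against the genome their consolidated origin points to;
undetermined/discordant genes are skipped (tallied) because no reference
can be chosen. Intergenic sites inherit the origin of the nearest preceding
assigned gene as a segment-membership proxy. Effects are classified by
codon comparison on NCBI translation table 11, strand-aware, with ATG/GTG/
TTG starts read as Met at protein position 1; length changes not divisible
by 3 are frameshifts (`fs`), in-frame deletions are `del`, stop gains are
labelled `*` (e.g. `Tyr123*`), substitutions `Ala123Val`. Under the
evidence model the per-site false-positive rate at discriminating-type
sites is `miscall_rate × 2/3` (a miscall must hit a non-ancestral allele).

## Statistics

* `generations_per_cycle(D) = log2(D)`; `total_generations` multiplies the
  cycle count by the per-cycle value rounded to one decimal, reproducing
  the conventional arithmetic (60 × 6.6 = 396).
* `bottleneck_size` = transfer volume × pre-transfer density.
* `adapted_fraction` = (colonies × dilution / volume) for the selective
  assay over the same for the total-count assay; undefined (NaN) at zero
  total colonies.
* `logistic_fit`: least squares on `N(t) = K / (1 + ((K−N0)/N0) e^(−rt))`
  (scipy `curve_fit`, bounded, initialized from the curve); populations
  with overall ΔOD < 0.05 or failed fits are flagged `no_growth`.
* `mann_whitney_u`: exact two-sided p — defined as 2 × min(tail
  probabilities), capped at 1 — when samples are untied and n·m ≤ 10⁴,
  tie-corrected normal approximation otherwise.
* `pearson_gof`: 1-df χ² of (with, without) counts against an expected
  proportion, which is an *input* (the emulated analysis' expected-by-
  chance percentages are not derivable from its printed counts).
* `overlap_randomization`: p = (1 + #{overlap ≥ k}) / (R + 1) over R
  (default 10⁵) explicitly drawn pairs of uniform random subsets
  (chunk-vectorized); the hypergeometric tail is used only as an oracle in
  tests, never as the implementation.
* `breakpoint_feature_enrichment`: feature counts in breakpoint windows vs
  length-matched random windows (uniform on the circle, redrawn if they
  overlap a breakpoint window; overlaps among random windows allowed),
  compared by Mann-Whitney.

No multiple-testing correction is applied; raw p-values are reported.

## Numerical and design choices

* Strict inequalities wherever a rule is phrased as "more than" (τ, the
  3-per-kbp candidate density).
* Exact Mann-Whitney uses scipy's exact one-sided tails under the
  2 × min(tail) definition; enumeration verifies it for all n, m ≤ 7.
* Windows, thresholds, k, caps, detection floors are all constructor
  parameters with the defaults above.
* Degenerate inputs: zero-coverage genes and zero-total-colony assays are
  flagged rather than raised at pipeline level; invalid configuration
  (τ ∉ (0.5, 1), D ≤ 1, no OriT) raises immediately.

## Known limitations

* Collinear ancestor coordinates: the I/O schema carries separate donor and
  recipient positions per site, but the generator never exercises
  non-collinear maps, so coordinate-lift bugs would not be caught here.
* Only substitutions and simple deletions are annotated; complex events
  (insertions, multi-nucleotide variants) are out of scope.
* Breakpoint localization assumes switches are farther apart than the grown
  window; two true breakpoints within a few kb can render both unresolved
  (`mixed`).
* Recombination-induced point mutations cannot be distinguished from
  independent ones; records near breakpoints carry no special flag.
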