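# Methods

This note documents the models, conventions, and design choices behind
ribotide, in the spirit of a methods appendix: what is computed, under what
assumptions, and where the genuinely open choices were made.

## Coordinate and orientation conventions

All in-memory coordinates are 1-based inclusive (GFF convention); bedGraph
output converts to 0-based half-open intervals at the single write boundary
(`io.write_bedgraph`). Minus-strand CDSs store genomic coordinates; their
reading frame runs from the high coordinate downward, and codon *i*
(1-based) occupies genomic positions `end−3i+1 … end−3(i−1)`.

The A-site offset convention: counting the 3'-terminal aligned base of a
footprint as position 1, the A-site nucleotide is position 12. On the plus
strand this is `end − 11`; on the minus strand `start + 11`. Whether a
3'-offset of 12 lands on the first, middle, or third base of the decoded
codon is not fixed by convention in the field; here the simulator anchors
footprints so the offset-12 base is the **middle** base of the sampled
codon, and the mapper shares that convention, making A-site recovery exact
on synthetic data. All downstream statistics assign an A-site to the codon
*containing* its nucleotide, so they are insensitive to the within-codon
choice.

## The synthetic-data generator

The generator emulates the design of a two-condition bacterial ribosome
profiling study: one chromosome of operon-organized CDSs, and 12 libraries
(WT/MUT × RPF/RNA × 3 replicates). Defaults (all in `SimulationConfig`):

| parameter | default | meaning |
|---|---|---|
| n_operons × genes_per_operon | 12 × 5 | 60 CDSs, alternating operon strands |
| gene_length_range | 150–1200 nt | uniform over whole codons |
| intergenic_length | 50 nt | spacer between operons (12 nt within) |
| replicates_per_group | 3 | paired by index (harvest batch) |
| rpf_depth, rna_depth | 200,000 reads/sample | sequencing depth |
| nb_dispersion | 0.1 | NB overdispersion of gene counts |
| base_expression_sigma | 1.0 | log-normal SD of baseline abundance |
| read lengths | 20–40 nt, discretized Gaussian peaked at 28, SD 2 | footprint sizes |

The read-length mode of real trimmed libraries is not fixed a priori; 28 nt
is the conventional bacterial footprint mode and is exposed in the config.

**Count model.** Per-gene counts are gamma–Poisson: count ~
Poisson(μ·G) with G ~ Gamma(1/φ, φ) (mean 1, variance φ), giving the
marginal negative binomial with mean μ = depth·w/Σw and variance
μ + φμ². Crucially, G is drawn once per (gene, replicate index) and
**shared across assay and condition**: the RPF and RNA libraries of one
replicate come from the same lysate, and the WT/MUT replicate pairs share a
harvest batch. This is the biological structure that (a) makes replicate
pairs covary, which is exactly what the covariance term of the SD-of-ratio
formula corrects for, and (b) lets within-replicate ratios (TE, fold
changes) cancel shared biological noise, as they do in a well-paired real
design. Totals per sample are therefore NB-distributed around the
configured depth rather than exactly equal to it — matching the count model
the differential test assumes.

**Planted effects.** Condition effects use the signed-fold convention
(|fold| ≥ 1; −k means ÷k). The mutant's expected mRNA mean is scaled by
`mrna_fold`, its RPF mean by `mrna_fold × te_fold`. Within a gene, RPF
A-site codons are drawn with weights ∝ codon dwell factors (`codon_pause`,
mutant only), with the first five codons additionally divided by
`start_depletion` in the mutant. RNA read 5' starts are uniform over the
CDS, clipped so the read lies inside the CDS (this keeps the midpoint
counting rule exact and avoids cross-gene bleed at operon junctions).

The default panel mirrors the affected-gene archetypes of the study system:
a cadB-like gene (mRNA −4, TE −7, start depletion 5), an adiY-like gene
(TE −4, start depletion 3), a gadA-like gene (mRNA +14), and a
well-expressed pause exemplar. The 2× AGA dwell factor is planted on
**every** gene in the mutant: longer rare-codon occupancy is a property of
the mutant ribosome, not of one transcript, and the pooled per-codon pause
ratio is only a meaningful genome-wide statistic under that reading. Panel
genes carry fixed baseline expression weights (2–3× the log-normal median)
so the positional detectors see adequate counts — the analogues of these
genes in real data are robustly expressed transcripts.

**What the generator does not emulate:** sequencing errors, rRNA
contamination, ligation/PCR biases, nucleotide-resolution dwell-time
structure beyond codon identity, UMI handling, or partial-CDS coverage
(every simulated read maps exactly). Passing tests therefore demonstrate
the correctness and calibration of the statistics under the assumed count
model — not robustness to alignment noise or library-preparation artifacts.

## Mapping

Reads of 20–40 nt (inclusive bounds) are aligned by exact string match
against both strands; a 20-mer prefix index locates candidates and a full
comparison confirms them. Reads matching zero loci or containing N are
unaligned; reads matching ≥ 2 loci across both strands are discarded as
multi-mapped (and counted) rather than fractionally assigned — the
conservative choice at this scale. RNA-seq alignments are never A-site
offset; they are counted by their integer midpoint `floor((start+end)/2)`.

## Quantification and normalization

RPF A-sites increment the same-strand CDS containing them; positions inside
overlapping same-strand CDSs are tallied ambiguous and assigned to none.
Library size is the per-sample total of **gene-assigned** signal and CPM is
computed on it, so intergenic noise cannot distort scaling. The method
behind "normalized counts" in comparable studies is typically unstated; CPM
is the simplest choice consistent with TE being a within-gene ratio (gene
length cancels, so no TPM/RPKM). Genes below 1 CPM in all four
condition × assay mean cells are excluded from testing — a documented
stand-in for the unstated analyzed-gene filter of such studies.

## Differential statistics

Fold changes are ratios of group means (not means of per-replicate ratios),
mapped to signed folds. Per-replicate TE uses a 0.5 pseudocount on both CPM
values before the ratio; tests are two-sided Welch t on log2(CPM + 0.5)
(the underlying test of the upstream web tools is unstated; Welch on log2
is a defensible default and is isolated behind one function). BH adjustment
runs within each metric. The SD-of-ratio is reported on the printed fold
scale: for reductions (r < 1) the fold magnitude is 1/r and its
delta-method SD is SD(r)/r². A slightly negative radicand (strong
covariance plus sampling noise) is clipped to zero and flagged.

Note the deliberate contrast: the phenotype module uses the classical
equal-variance Student t (matching how such assays are conventionally
analyzed), while the sequencing side uses Welch.

## Positional analysis

The start region is the first 5 codons (configurable); the body is codons
6…L−5; genes shorter than 2·window+1 codons are skipped. The depletion
score (MUT/WT start:body ratio) is invariant to library size and to the
gene's own expression fold. Pause scores exclude 5 edge codons to avoid
initiation/termination artifacts. Codon-level pooling weights each
occurrence equally; the per-gene mean of normalized scores is 1 by
construction. The pooled pause-ratio statistic is a deliberate,
documented stand-in: rare-codon occupancy shifts are usually reported
qualitatively, without a canonical statistic.

## Logo statistics

Gaps and non-standard residues (X/B/Z) reduce the effective count n rather
than forming a 21st symbol (Weblogo default). Information content is
R = log2 20 − H with the optional Basharin small-sample correction
e = 19/(2·ln2·n), clamped at zero; letter heights are f·R and sum to R.
A column is "conserved" when its dominant residue reaches frequency 0.5
(boundary inclusive). The packaged loop alignment is synthetic — the
multi-species loop alignments are not deposited — with designed
conserved/variable columns and charge composition; per-column values carry
no biological meaning beyond those contrasts.

## Phenotype formulas

Two-point doubling time (t2−t1)·ln2/ln(N2/N1) with the 140–150 → 240 min
Klett window as the documented default; percent survival
100·CFU_after/CFU_before; OD620-vs-CFU by ordinary least squares (constant
response returns slope 0, R² 0); two-group comparisons by two-tailed
unpaired Student t at α = 0.05, with degenerate zero-variance groups
returning p = 1 (identical) or p = 0 with a flag (separated).

## Determinism and numerical choices

All randomness derives from one root seed through `numpy.random
.SeedSequence` spawn keys (genome, expression, biology factors, one stream
per sample), so identical configurations give byte-identical FASTQ files
and reports. Reports are JSON with sorted keys and no timestamps or
absolute paths. Ties in the BH step-up are handled by the standard
monotone cumulative minimum; `signed_fold` rejects non-positive ratios, and
zero group means propagate as NaN flags rather than infinities.

## Problem sizes

The default simulation (60 genes, 200k reads × 12 samples, ~2.2 M reads)
was chosen as the smallest design in which all planted effects are
detectable with comfortable margins; a full pipeline run takes a few
seconds on one CPU, and the test suite (two full runs plus the Monte-Carlo
and grid oracles) completes in well under a minute.

## Known limitations

Exact-match alignment cannot model mismatches or indels; multi-mapped
reads are dropped, which would bias real repeat-containing genomes;
the Welch-on-log2-CPM test is not a dispersion-sharing count model (no
shrinkage à la DESeq2/edgeR) and is underpowered at 3 replicates for small
effects; the pooled pause score ignores codon-context effects; and the
signed-fold convention cannot represent |fold| < 1 values that sometimes
appear in published tables (they are treated as convention inconsistencies,
not reproduced).
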