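# Methods

This note documents the statistical models, conventions and design choices
behind `fmm`, in the spirit of a model reference: what each stage assumes,
which tunables matter, and what validation on synthetic data does and does
not establish.

## Coordinates and formats

All genomic coordinates are 0-based half-open, uniformly: BED peak files and
5-column fragment files are consumed as-is, and the gene-model TSV is
declared to use the same convention. The TSS is `start` on the + strand and
`end − 1` on the − strand. Count matrices travel as MatrixMarket triplets
with one-ID-per-line sidecars; motifs as JASPAR text PFMs; gene sets as GMT.
Unknown configuration keys are an error — a misspelled tunable should fail
loudly, not silently run with defaults.

## Per-cell QC

Nucleosome signal is the count-weighted ratio of mono-nucleosomal
(147–294 bp) to sub-nucleosomal (< 147 bp) fragments, +∞ when a cell has no
short fragments. TSS enrichment treats both fragment ends as insertions and
compares mean per-base insertion coverage within ±100 bp of the nearest TSS
(201 positions) to two 100-bp flanks centred at ±950 bp (202 positions in
unsigned-distance space, both sides counted) plus a 10⁻⁹ pseudocount; flat
coverage therefore gives exactly 1. The window geometry is a field
convention, not something the upstream toolchain documents precisely; the
flat-signal limit is the anchor we test.

The filter cascade keeps a cell iff **all** of: nucleosome signal < 1.5,
TSS enrichment > 1, 1,000 < RNA counts < 15,000, 100 < ATAC fragments
< 75,000, mitochondrial counts < 5 %, ribosomal counts < 10 % — all strict
inequalities, evaluated as an order-independent conjunction. "Percent
ribosomal" is implemented as percent of counts from Rps/Rpl-prefixed genes
(the counts-vs-detected-genes reading is ambiguous in common usage; counts
is our documented choice). The lineage purge removes any cell with count
> 0 for any of *Cd3d, Cd3e, Cd3g, Cd4, Cd19, Cd8a, Itgam*. Fate-map labels
are RAG_EXP iff the reporter transcript (tdRFP) has count ≥ 1; the
threshold is exposed in the configuration.

## Normalization, reduction, clustering

RNA: `log1p(1e4 · x / cell_total)` by default; analytic Poisson Pearson
residuals (clipped at √n) are available. A regularized negative-binomial
regression normalization is deliberately **not** re-implemented — the
downstream statistics need a variance-stabilized matrix, not a particular
implementation of one. ATAC: TF-IDF with TF = count/cell total,
IDF = n_cells / n_cells detecting the peak, mapped through
`log1p(1e4 · TF · IDF)`. Both are exactly depth-invariant per cell.

LSI is a truncated SVD of the TF-IDF matrix with a deterministic sign
convention (the largest-|loading| feature of each component is made
positive); component 1 is dropped and dimensions 2–25 retained, because the
first component tracks sequencing depth — on simulated data it correlates
at ~0.97 with the per-cell detected-peak count, the depth measure a
near-binary assay actually encodes (correlation with raw total counts is
slightly lower, ~0.9). PCA on the centred, unit-scaled normalized RNA
matrix retains dimensions 1–25 with the same sign convention.

Gene activity counts fragments (weighted by their duplicate count)
overlapping the gene body extended 2,000 bp upstream of the TSS,
strand-aware; a fragment overlapping several gene windows counts for each.

The joint graph is built from per-modality shared-nearest-neighbor Jaccard
similarities over Euclidean k-NN sets (k = 20, each cell's set includes
itself) and combined with fixed equal weights, 0.5·S_RNA + 0.5·S_ATAC —
"equal weighting" is taken literally rather than as learned per-cell
weights. Clustering is Leiden on the RB-configuration modularity at
resolution 0.1 with a fixed seed; cluster ids are relabelled by descending
size for stability. A constant (degenerate) embedding contributes a
complete graph, keeping the joint graph defined.

## Marker tests

GEX and GA markers use a one-vs-rest two-sided Wilcoxon rank-sum on
normalized values, gated on max(pct_in, pct_out) ≥ 0.20 and |log fold
change| ≥ 0.25, where log_fc = ln((mean(expm1 x_in)+1)/(mean(expm1
x_out)+1)). For ≤ 30 cells the p-value is exact, computed by dynamic
programming over the null distribution of the rank sum on doubled midranks
(ties handled exactly); larger samples use the tie-corrected normal
approximation with continuity correction. Correction is Bonferroni over the
tested features (BH is available).

DA peaks use a likelihood-ratio test between logistic regressions of
cluster membership on {TF-IDF peak value, latent} vs {latent}, with the
total ATAC fragment count per cell as the latent covariate and a detection
gate of 0.02. The logistic fits use damped Newton iterations with a tiny
ridge (10⁻⁸) so perfect separation yields a finite, well-defined statistic;
the reported log-likelihood is unpenalized and matches an unregularized GLM
oracle to < 10⁻⁶ on separated fixtures. The latent enters linearly; the
calibration property (type-I ≤ 0.07 under a depth-confounded null) holds
when the latent is supplied on the scale on which the confound is linear.

Nearest-gene assignment gives distance 0 on gene-body overlap, otherwise
the base-pair gap between closest interval boundaries; ties go to the gene
with the smaller start, then lexicographic name; peaks farther than 10⁵ bp
from any gene are dropped. The multiomic signature takes the top 100
features per assay (DA deduplicated to genes in best-p order before
truncation — a documented interpretation), and reports the union and all
seven Venn regions.

## Gene-peak links

Candidate pairs are (gene, peak) with the **peak centre** within 10⁶ bp of
the TSS, both detected (raw count > 0) in ≥ 2 cells of the analysed
population. The score is the Pearson correlation of the normalized
(log-CP10K / TF-IDF) vectors across cells. The null for each candidate peak
is the score of 200 background peaks matched on GC content, log total
accessibility and log width — nearest neighbours in standardized 3-feature
space, sampled with the run seed from the 2× nearest pool —
giving z = (r − μ_bg)/σ_bg and a two-sided normal p. Links are retained at
p < 0.05 and |r| ≥ 0.05. Under permuted expression the retained fraction of
candidates sits at the nominal level (~5 %); this calibration is re-measured
by `scripts/acceptance.py` at every run.

Per-condition runs subset cells but reuse the full-cohort normalization and
the same background sample (seeded once), keeping scores and nulls
comparable across conditions; a 30-cell floor per condition guards against
degenerate correlations. Regulome counts are per-gene link tallies per
fate-map state, with delta = naive − experienced, sorted descending (ties
by name). For set analysis each condition's links are deduplicated to
unique peaks, and every peak in the union is assigned to exactly one of the
15 exclusive combinations (UpSet semantics); induced peaks are
(naive_SS ∩ naive_AD ∩ exp_AD) \ exp_SS, mapped back to genes through any
condition's links and ranked by distinct induced peaks. The Th2-locus
report runs the same machinery restricted to *Il4, Il13, Rad50, Il5*,
retaining cross-gene links within the locus.

## Motifs

PFMs become log₂-odds matrices with a total pseudocount of 0.8 against a
uniform background. A peak is a hit when the best window score over both
strands reaches 0.8 × the motif's maximum attainable score; N bases score
0. Deviations follow the chromVAR contract: expected motif counts per cell
are cell_total × the all-cell count fraction in motif peaks; raw deviation
is (obs − exp)/exp; z-scores come from 50 background resamplings in which
each peak is replaced by one from the same GC × mean-accessibility decile
bin (10 × 10 binned matching rather than full multivariate sampling — a
documented simplification with the same matched-null contract). Enrichment
of a foreground peak set is a hypergeometric upper tail against a GC-binned
background sample of the remaining peaks, BH-corrected. The expression
cross-reference joins motif statistics to the TF gene's detection fraction
and mean normalized expression; "concordant" = enriched (BH < 0.05) and
detected in ≥ 10 % of cells.

## Preranked GSEA

The ranked list comes from the marker machinery between fate-map states
with permissive gates (min.pct 0.1, |logFC| 0.1), metric = log fold change
(positive = higher in RAG-experienced), ties broken by smaller p then gene
name. The enrichment score is the maximum deviation of the weighted KS
running sum (hit increments ∝ |metric|¹, miss decrements uniform).
Significance uses seeded gene-label permutations with the sign-conditional
convention p = (1 + #{same-sign permutations with |ES| ≥ observed}) /
(1 + #same-sign permutations), which keeps null p-values uniform — a
normalization by all permutations regardless of sign would halve the null
mean and mis-calibrate the test. NES divides ES by the mean |ES| of
same-sign permutations; BH across reported sets; sets are size-gated to
[50, 500] after intersection with the ranked list.

## The synthetic generator

Counts are gamma–Poisson: per-cell lognormal size factors (σ = 0.25 RNA,
σ = 0.65 ATAC — ATAC depth varies more in real nuclei), feature weights
that depend on cell type, fate map and disease, normalized to the
configured mean depths (2,500 RNA counts, 1,000 fragments). Each planted
link group — the links of one gene sharing an activity pattern — draws one
gamma latent a (shape 2, mean 1) per cell; in active states the gene and
all its peaks share the draw, in inactive states each side gets an
independent draw, and every multiplier exp(β(a−1)) is divided by its
analytic mean. Marginal feature means are therefore *identical across
states*; only the correlation is state-dependent, so differential
expression can never masquerade as differential linkage. Fragments are
emitted inside counted peaks (one record per peak-cell pair, duplicates in
the count field), at TSSs in proportion to the cell's expression program
(70 % tight ±40 bp, 30 % spread ±1.2 kb so enrichment ratios stay finite),
and as uniform genomic background; lengths come from a sub- vs
mono-nucleosomal mixture (70/30). Peak sequences are random at a per-peak
GC drawn from Beta(8, 8), with consensus motifs embedded at peak centres
where the scenario plants them.

The default scenario holds 2,000 cells — 1,000 ILC2s and 250 each of
T, B, NK and DC cells, split by fate map and disease — over 300 genes and
~400 peaks on a tiled genome (one gene per 2-Mb tile, distal peaks on a
gene-free chromosome, the Th2 block clustered within 200 kb). It plants 90
naive-only ILC2-program links (β = 1.2), 20 induced links (β = 1.5, active
except in experienced steady state), 15 constitutive links, and a 14-peak
Th2 block with cross-gene and induced links; lineage-panel genes have
structurally zero rates in ILC2/NK cells, the reporter is zero in naive
cells and detected with probability 0.9 in experienced cells. Effect sizes
were chosen once so the planted structure is detectable at the scenario's
per-condition sample sizes (≈250 cells) and then frozen; the induced-link
cohort is larger than the minimum because the induced-set statistic is
vulnerable to chance false-positive calls in the experienced-steady-state
run at the fixed α, and a small cohort would make its recovery rate
unstable. Problem sizes throughout (cells, genes, peaks, permutation
counts) are chosen so a full pipeline run takes seconds and the whole
validation suite minutes on one CPU.

What passing on this generator shows: the statistics recover exactly the
structure they claim to measure, at calibrated error rates, under a
best-case model — Poisson sampling, no batch effects, no doublets, no
ambient contamination, one sample, known peak set. What it does not show:
robustness to overdispersion beyond the planted latents, to
anchor-integration artefacts, to peak-calling errors, or to cell-type
misassignment; ambient-RNA and doublet removal are explicitly out of
scope, and the purge's effectiveness on real data depends on capture
efficiency of the panel transcripts. The pipeline clusters all QC-passing
cells and applies the lineage purge afterwards to define the lymphoid
subset for fate-map analyses; on real lymph-node data (where purged types
are a minority) the two orders agree, while on the synthetic mixture
clustering first preserves all five planted types for validation.

## Determinism

Every stochastic step (simulation, background sampling, binned resampling,
permutations, Leiden) derives from explicit integer seeds; SVD signs are
fixed by convention; sorts use stable keys with documented tie-breaks. Two
runs of the full pipeline with the same seed are bit-identical, which the
test suite and the acceptance script both verify.
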