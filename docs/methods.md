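# Methods

This note documents the models and procedures implemented in `epimn`, the
assumptions behind them, the parameters that matter, and what the synthetic
data can and cannot show about real data.

## Coordinates and transcript models

All genomic coordinates are 0-based, half-open; any 1-based table must be
converted at its reader. A `TranscriptModel` is a list of exons ordered
5'→3' (descending genomic coordinate on the minus strand) plus a
5'UTR/CDS/3'UTR partition in transcript coordinates; the transcript↔genomic
mapping is a strand-aware bijection over the exon union, and the loader
derives the partition from a genomic CDS span. The metagene coordinate
rescales each segment to unit length — 5'UTR→[0,1), CDS→[1,2),
3'UTR→[2,3) — so the stop codon sits at exactly 2.0 regardless of segment
lengths. This normalizes transcripts of different architecture onto one
axis but distorts absolute distances: a bin of width 0.1 spans different
nucleotide counts on different transcripts.

Region annotation assigns one category per point (intervals are annotated
at their midpoint) with the promoter-first precedence TSS > TTS >
5'UTR-exon > 3'UTR-exon > CDS-exon > intronic > intergenic. The TSS/TTS
windows default to ±1,000 bp, a conventional promoter-proximal window, and
are flags because external annotators vary here; no attempt is made to
match any specific annotator's category counts. With several transcripts in
reach, the candidates at minimal feature distance are compared by category
precedence, then transcript_id — a single deterministic rule covering both
the "nearest transcript" and the "promoter beats intron" intuitions.

## Consensus m6A calling

Inputs are per-tool, per-sample site tables: an EpiNano-style dialect
(probability column kept at > 0.5) and an m6Anet-style dialect (kept at
> 0.9, carrying a per-site `mod_ratio` stoichiometry). Thresholds are
strict inequalities. Candidates may be required to sit in a DRACH 5-mer
(D∈{A,G,T}, R∈{A,G}, central A, C, H∈{A,C,T}; 18 of the 1,024 5-mers).

Two consensus policies exist because replication-based and cross-tool-based
criteria answer different robustness questions, and both are defensible:

- `replicated_either_tool` (default): a (transcript, position) is consensus
  iff one tool calls it in ≥ 2 distinct samples — robust to per-sample
  noise within a tool;
- `shared_across_tools_per_sample`: consensus iff both tools call it in the
  same sample at least once — robust to tool-specific artifacts.

Site identity across tools is exact coordinate equality; a ±k nt merge
window exists as a flag (default 0) since both predictors emit
single-nucleotide calls on the same reference. Stoichiometry summaries
(mean/min/max of supporting `mod_ratio` values) are reported only when at
least one supporting call carries one. The dataset summary counts regions
via each site's genomic projection, histograms metagene coordinates
(n_bins divisible by 3 so each segment gets equal bins), and tallies a 4×5
position-frequency matrix of the site 5-mers.

## Enrichment statistics

`hypergeom_upper_tail(k, K, n, N)` returns P(X ≥ k) for
X ~ Hypergeometric(N, K, n): log-PMF terms from log-gamma functions,
accumulated with log-sum-exp. Exhaustive comparison against integer-exact
summation shows ≤ 1.2e-13 relative error over every valid instance with
N ≤ 60; the log-space route stays finite at genome scale (N ≈ 22,000).
Fractions k/n and K/N are kept at full precision internally and rounded
only for presentation (two decimals on percentages). The BH and Bonferroni
adjusters delegate to statsmodels after validating the inputs; BH is
step-up with running-minimum enforcement, Bonferroni is min(p·m, 1).

A note on the headline worked example: 34/81 = 41.975% and
7921/22280 = 35.552%, so the latter prints as 35.55 at two decimals under
ordinary rounding. The standard one-tailed hypergeometric on these counts
gives p ≈ 0.137; the package reports the standard test.

## Multiome differential analysis

RNA counts are log-normalized as ln(1 + 10⁴·x/cell_total); ATAC counts get
log-TF-IDF, ln(1 + 10⁴·tf·idf) with tf = x/cell_total and
idf = n_cells/n_cells_detecting — the log variant keeps values finite for
very rare peaks; a flag switches to plain tf·idf. All-zero features are
dropped with a warning, zero-total cells are an error naming the cell. LSI
is a seeded truncated SVD; downstream consumers receive components 2–10
(1-based), the chromatin convention that discards the depth-dominated first
component.

The DE test is a two-part likelihood-ratio test. Per group g the model is:
a cell detects the gene with probability π_g, and detected (nonzero
log-normalized) values are Normal(μ_g, σ) with σ pooled across groups
within each model. The null shares π and μ. Both models have closed-form
MLEs, so the statistic 2(ℓ_full − ℓ_null) is computed directly and referred
to χ² with 2 df. Two numerical choices matter: (i) when the pooled nonzero
variance is zero, a floor of 1e-8 replaces σ̂ in **both** models, so the
degenerate Gaussian terms cancel and the detection part carries the
statistic; (ii) genes detected in fewer than 3 cells in either condition
are not tested (an LRT on all-zero input is undefined; the filter is
logged). Although the Gaussian component is misspecified for log-normalized
counts, both sub-statistics are asymptotically χ²₁ by the CLT — the
mean-difference part is a pooled-variance t² and the detection part a
binomial LRT — so null p-values are close to uniform at realistic group
sizes, which the calibration test verifies (KS p > 0.01 on 2,000 null
genes at 200 cells/group). Multiple testing is Bonferroni over the tested
genes (strict < 0.05), with BH available by flag; log2FC is
log2((mean(expm1 n₁)+1)/(mean(expm1 n₂)+1)), whose pseudocount keeps it
stable under sparsity.

Differential accessibility uses the rank-sum z with midranks, the
tie-corrected variance n₁n₂/12·[(n+1) − Σ(t³−t)/(n(n−1))], and a 0.5
continuity correction; all-tied input returns (0, 1) rather than failing.
After BH adjustment a peak is **open** in the first condition iff
p_adj < 0.01 and log2FC > 0.1 and more than 5 percent of first-condition
cells are nonzero; the symmetric test with conditions swapped defines
**closed**; everything else is **neutral**. Because the two directions
share p-values, swapping the condition labels exactly exchanges open and
closed.

## Peak-to-gene linkage

Sparse chromatin signal is stabilized by aggregation: n_aggregates seed
cells are sampled without replacement (seeded RNG) and each is pooled with
its k−1 nearest neighbors in the selected LSI components, ties broken by
cell index. Defaults k = 50 and n_aggregates = 500 (capped at the cell
count) balance noise averaging against aggregate redundancy at desk scale.
Aggregates overlapping a previously kept one by more than 80% of k are
dropped in creation order. Aggregate count vectors are summed then
log-normalized like cells. Candidate pairs are peaks whose **midpoint**
falls within a closed ±250 kb window of a gene start (an any-overlap flag
exists); distance is signed, strand-oriented. Pearson r across aggregates
is converted to p via t = r·√((m−2)/(1−r²)) with m−2 df, two-sided,
BH-adjusted over all candidate pairs of the run; a pair passes iff
r ≥ 0.45 and p_adj ≤ 1e-4 (both inclusive). Zero-variance features yield
r = 0, p = 1, flagged degenerate rather than NaN. Because aggregates share
cells, their rows are not independent; the t-based p is therefore
anti-conservative in absolute terms and the r threshold carries most of
the selectivity — the planted-truth recovery test measures the procedure
end-to-end rather than the p's calibration.

## Neurite morphometry

The pipeline replaces interactive tooling (classifier-based segmentation,
manual leveling) with deterministic primitives: a percentile contrast
stretch (defaults 0.5/99.5) onto the fixed range [0, 1] — fixing the target
range is what makes the output invariant to global intensity scaling —
followed by Otsu thresholding (foreground strictly above the threshold; a
fixed threshold uses ≥ so that fixed(0) keeps everything). Cell bodies are
removed via the Euclidean distance transform: pixels deeper than the soma
radius (default 8 px) seed the soma regions, which are re-dilated by that
radius and subtracted — tubes thinner than the radius are untouched.

Particles are 8-connected components filtered by area and circularity
4πA/P², with the perimeter from boundary-contour tracing and circularity
capped at 1.0 (rasterized small disks overshoot). All bounds are
inclusive. The degeneration index divides the area of particles in
[20, 10,000] px with circularity [0.2, 1.0] by the total foreground area;
long tubes fail the circularity floor (a 1-px line of length L has
circularity ≈ 4πL/(2L)² → 0) so intact fields score 0, and a field of
compact blebs scores 1. Border-touching particles are included by default
(flag provided). Skeleton length counts unique neighbor steps on the
1-px skeleton (orthogonal 1, diagonal √2; a straight 100-px line measures
99); branch points are skeleton pixels with ≥ 3 skeleton neighbors, with
adjacent branch pixels merged into one junction. Thickness is twice the
mean distance-transform value over skeleton pixels — on an axis-aligned
band of even width w this measures ≈ w+1, an inherent half-pixel bias of
pixel-center distances. Puncta density counts particles of area (0, 100] px
and circularity ≥ 0.2 per unit skeleton length. Nuclear signal density is
the summed marker intensity inside each nucleus mask divided by the mask
area.

Published DI magnitudes from classifier-segmented micrographs are not
expected to be matched on real images; the implementation preserves the
statistic's definition and its endpoint/monotonicity properties.

## Synthetic data

All generators draw from per-stage substreams: the run seed is combined
with a CRC32 hash of the stage name, so outputs are bit-reproducible and
adding a stage never perturbs another stage's draws.

**m6A predictions.** A toy transcriptome of 2,000 single-exon,
single-transcript genes (5'UTR 80–300 nt, CDS 300–1,800 nt, 3'UTR 200–800
nt) spaced 100 kb apart. A gene is modified with probability
base_rate = 0.35 (matching the ~35% modified fraction of a motor-neuron
transcriptome), risk genes at base_rate × enrichment_factor (capped at 1);
modified genes carry 1 + Poisson(2) sites whose positions mix
0.5·Uniform(CDS) with 0.5·Normal(stop boundary, σ = 5% of CDS length) —
the stop-codon pile-up real metagene profiles show. True sites get DRACH
5-mers and Beta(4,2) stoichiometries. Each tool detects a true site per
sample with its sensitivity (defaults 0.8/0.85); a detected site's score is
threshold + (1 − threshold)·Beta(a, b) with (8,2)/(12,1.5) per tool, i.e.
the Beta shapes model the above-threshold score distribution while
sensitivity alone governs detection — drawing raw Beta scores would let
"detected" sites fall below the strict thresholds and silently change the
effective sensitivity, breaking the noiseless-recovery identity the
generator guarantees (sensitivity 1, FPR 0 ⇒ consensus = planted truth
exactly, under either policy). False sites arise at fp_rate per kb per
tool/sample with low above-threshold scores. The generator does not model
read-level signal, coverage-dependent sensitivity, or positional error.

**Multiome.** Defaults: one cell type ("skeletal MN") × {Ctrl, KO} at 200
cells per group; gene means log-normal with negative-binomial counts
(dispersion 0.3); ATAC counts Bernoulli(rate)·(1 + Poisson(0.5)). Planted
DE genes get a ±log2 effect in KO; planted DA peaks a ±detection-rate
shift. Cells carry an 8-dimensional Gaussian latent state standing in for
graded within-type cell-state variation; 200 structural background peaks
load on it so LSI can recover it and kNN aggregation pools cells of
similar state. Each linked pair couples one state dimension to its gene's
log-mean (loading 1.2) and a ρ-mixture of that dimension and an
independent one to its peak's logit-rate (loading 1.8); with count noise
averaged over aggregates the observable aggregate-level Pearson r then
sits near the requested latent correlation (empirically within ±0.15 of
0.7 at 500 aggregates, per the generator's sampling check). Linked peaks
sit within ±200 kb of their gene's start; "decoy" peaks (same count by
default) sit in linked-gene windows with no state loading, giving the
unlinked pass rate a real denominator; all other peaks are ≥ 300 kb from
every gene start. The toy genome has no chromatin domains, no shared
enhancers, and conditions differ only through the planted effects.

**Neurite images.** Default 1024×1024. Each neurite is a smooth random
path (heading random-walk with momentum) rendered as a tube of half-width
2–4 px, optionally branching once, confined to its own horizontal band so
structures from different neurites never merge — a deliberate geometric
simplification that keeps the DI endpoint identities exact; real fields
have crossing neurites. The fragmentation parameter f converts a fraction
f of each path's segments into elliptical blebs (semi-major 3.5–6 px,
axis ratio ≥ 0.65, ≥ 3 px gaps); the fragmented segment set is a prefix of
a seeded permutation drawn with a fixed draw count, so it is nested across
f for the same seed and DI is nondecreasing in f. Blebs landing within
3 px of an intact tube, or merging into a blob that fails the fragment
filters (possible where a branch crosses its parent), are dropped whole —
the generator's contract is that the fragment mask contains only
qualifying particles, which is what makes f = 0 ⇒ DI = 0 and
f = 1 ⇒ DI = 1 exact identities rather than approximations. Somata are
disks of radius 12–18 px; puncta are small disks scattered along the tubes
at a rate per 100 px of path length; channels get additive Gaussian noise.
No point-spread function, uneven illumination, or out-of-focus light is
modeled, so passing tests demonstrate the statistics' correctness on clean
geometry, not segmentation robustness on real micrographs.

## Problem sizes in the shipped tests

The test suite exercises the pipelines at sizes chosen to make each
property measurable with comfortable margin: 2,000 genes for null
calibration and the metagene profile; 200 cells/group for DE recovery and
400/group for linkage (more cells reduce aggregate overlap and with it
spurious aggregate correlations); 5,000 peaks × 20 seeds for the DA null;
1024×1024 images for the DI properties; the hypergeometric oracle sweep is
exhaustive for N ≤ 60. The Wilcoxon-vs-exact bound (|Δp| ≤ 0.02) is
asserted over every rank split at n = 5, 6 and sampled at n = 7, 8;
exhaustive enumeration shows the normal approximation itself exceeds that
bound for some splits at n ≤ 4, so no implementation of the
Gaussian-approximation test can meet it there.

## Known limitations

- The DE test is a quasi-likelihood: its Gaussian component ignores the
  discreteness of low counts; calibration degrades below ~30 cells/group.
- Linkage p-values inherit dependence from overlapping aggregates (see
  above); treat the pass set, not the p's, as the result.
- The region annotator uses simplified transcript models, not a full
  GTF/GFF3 parse, and one category per feature.
- Consensus calling trusts the predictors' coordinates; systematic
  misalignment between tools would need the ±k nt merge flag.
- Image metrics assume 2-D fields; z-stacks must be projected upstream.
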