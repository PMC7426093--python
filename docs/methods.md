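# Methods

This note documents the statistical models, the simulation the package
verifies itself against, and the numerical choices made where the design
was genuinely open.

## UMI error collapse

Sequencing errors inside the UMI create spurious molecules that are (a)
rare — usually a single read — and (b) one substitution away from a real
UMI. Within each (cell barcode, gene) group, every UMI supported by
exactly one read that has a hamming-distance-1 neighbor supported by two
or more reads is merged into that neighbor; recipients are chosen by
highest read count, then lexicographically smallest UMI. Merging is a
single pass evaluated against the *initial* table state, which makes the
result independent of iteration order; reads are conserved and the
distinct-UMI count never increases. Candidates are found by enumerating
the 3L single-substitution variants of each singleton against a hash of
the multi-read UMIs (O(n·L) per group); an exhaustive O(n²) pairwise
implementation is retained as a test oracle.

**Limitation.** The rule cannot repair a 2-read molecule with one errored
read: both UMIs are then singletons and the recipient requirement (≥2
reads) never holds. At a Q30-grade per-base error rate (0.001, the
simulator default) this affects well under 1% of groups; at 5×10⁻³ it
rises to several percent. The inverse-of-simulation benchmark (≥99% of
groups restored exactly) is therefore run at the Q30 default with ~4
reads per molecule.

## Ambient ("soup") model

Every droplet, cell-containing or not, is assumed to receive the same
number of ambient molecules drawn from a sample-wide soup profile. The
profile is estimated as the pooled gene fractions of the empty droplets
(barcodes inside a per-sample inclusive total-UMI window). The budget m
is the modal empty-droplet total; a valid cell with n UMIs gets
ρ = min(1, m/n). The raw sample mode of a Poisson-dispersed count
distribution wanders by several counts, so the mode is taken as the
argmax of a histogram smoothed with a moving average whose window is
√mean rounded to odd (the Poisson-scale bandwidth); window 1 recovers the
raw mode, and ties resolve toward the smaller value (conservative
removal).

**Count adjustment.** The removal target per cell is T = round(ρ·n) with
per-gene soup expectation e_g = ρ·n·soup_g. The default allocator removes
⌊min(observed_g, e_g)⌋ per gene outright and draws the remainder
multinomially over the fractional parts (seeded, hence reproducible).
Sampling the sub-integer part decorrelates removals across cells, so
pooled removals track the expected soup; a deterministic rounding rule
instead hits the same mid-expression genes in every cell and measurably
*increases* the distance between corrected profiles and the true
endogenous profiles. A fully deterministic greedy variant
(`method="greedy"`: clamped rounding plus largest soup-excess ratio
e/(remaining+1)) is kept for comparison and covered by a hand-executed
oracle test.

**Resolvable regime.** A per-cell, cluster-blind corrector can only
attribute counts at genes whose expected ambient count is of order one or
more: when e_g ≪ 1, any unbiased allocator removes a fraction ≈e_g of a
count that is either entirely soup or entirely endogenous, and expected
per-gene removal cannot exceed E[min(observed, e)]. The soup-recovery
benchmark therefore uses a compact panel (80 genes, ambient budget 150
UMIs/droplet across 4 samples) in which foreign-marker soup expectations
are ~1–5 UMIs; under those conditions the corrector removes ≳75% of
soup-only foreign-marker signal and shrinks the total-variation distance
of every cell type's pooled profile to its true endogenous profile by
~4×. On transcriptome-wide panels with weak ambient contamination,
per-gene attribution is intrinsically diluted even though the aggregate
correction remains unbiased.

## Pooled size factors and band filter

Size factors θ are estimated per broad population by pool-and-deconvolve:
cells are ringed in library-size order; for pool sizes {21, 41, 61, 81,
101} (capped at the group size) and every ring start, the pooled profile
over the top-20%-mean genes is divided by the population's mean profile
and the median ratio gives one equation Σ_{c∈pool} θ_c = b. Low-weight
(0.1) per-cell anchor equations θ_c ≈ libsize ratio make the sparse
system full rank; LSQR solves it, non-positive solutions are clamped to
10⁻³ × the smallest positive value with a warning, and groups under 20
cells fall back to library-size factors. Groups are made comparable by
rescaling each group's mean θ to its mean library size over the global
mean. On planted scalings with multinomial resampling noise the recovery
correlation exceeds 0.99.

Cells are kept when 0.1·mean(θ) < θ < 10·mean(θ), strict at the
boundaries, with the mean taken over all input cells and the filter
applied once. Counts are then converted to per-cell gene fractions
x_gc = (c_gc/θ_c)/Σ_g(c_gc/θ_c); note the per-cell normalizer cancels θ
algebraically — θ still matters for the band filter and as the DE offset.

## Clustering

Variable genes are the top quintile (configurable) by CV = sd/mean on the
supplied matrix. Because the CV of a barely detected gene is dominated by
1/√mean sampling noise, the pipeline first drops genes whose mean raw
count across valid cells is below 1 (configurable); without this floor
the top-CV set is mostly noise and label recovery collapses. PCA keeps
the minimal number of leading components whose cumulative explained
variance exceeds the configured threshold; t-SNE (perplexity 30, no
duplicate check, fixed seed) embeds them in 2-D; clustering runs on the
embedding. Local density uses a Gaussian kernel ρ_i = Σ_j exp(−(d_ij/d_c)²)
with d_c at the 2nd percentile of pairwise distances (the density-peak
authors' rule of thumb); δ_i is the distance to the nearest denser cell
(density ties broken by index; the global maximum takes the largest
pairwise distance); the k largest γ = ρ×δ are centers and every other
cell joins its nearest denser neighbor's cluster in decreasing-density
order. k is user-supplied, as in the original procedure, where a first
broad round is manually merged into six populations before a finer
second round; the pipeline externalizes that merge as an explicit label
map. Cluster expression is aggregated as UPM: gene sums over the
cluster's cells divided by the cluster's total UMIs ×10⁶, so every column
sums to one million.

## Marker statistics

Per gene and cluster, a negative binomial log-linear model
count ~ intercept + is_cluster + batch with offset log(θ·n̄) (n̄ = mean
library size) is fit twice (with and without the cluster term); the LRT
statistic is referred to χ²₁ and BH-corrected per cluster. Dispersions
come from an offset-adjusted method of moments,
α̂_g = Σ[(y−sμ)² − sμ]/Σ(s²μ²), floored at 10⁻⁸ and shrunk 50/50 on the
log scale toward a binned-median trend over log mean abundance. On NB
null simulations (2000 genes) the empirical type-I error at α = 0.05 sits
inside the binomial 95% band, and planted 8-fold markers are recovered at
FDR < 0.01 with power 1.0 and log2FC ≈ 3. All-zero genes report p = 1 and
log2FC = 0 by convention; clusters under 3 cells are skipped with a
warning.

Fold-enrichment selection keeps genes whose maximal cluster UPM is at
least fourfold (configurable) the mean of the other clusters with a 1-UPM
pseudocount in the denominator; the bulk region filter keeps genes with
log2(max region / (median across regions + 0.1 ppm)) ≥ 2 and max ≥ 20 ppm.

The ZINB model P(x) = π·1[x=0] + (1−π)·NB(x; μ, size) is fit by EM: the
E-step computes the posterior structural-zero weight of the observed
zeros; the M-step updates π in closed form, the NB mean as the weighted
mean (its exact MLE), and profiles the size parameter by Brent search.
The observed-data log-likelihood is tracked and non-decreasing;
convergence is a likelihood change below 10⁻⁸ or 500 iterations. The
expressing fraction is 1−π̂ and mean_positive is the mean over cells with
x > 0 (which belong to the NB component with posterior one). Recovery on
π = 0.4, μ = 5, size = 2, n = 2000 is within ±0.05 over 50 replicates.

## Ligand-receptor networks

Ligands and receptors are kept when ≥20% (inclusive) of at least one
population's cells have a nonzero count; pairs need both ends. Surviving
genes are k-means-clustered (k = 13 ligands / 14 receptors by default, 50
restarts, fixed seed) on row-normalized per-population UPM profiles; each
cluster is labeled by its centroid's argmax population (ties by column
order) and same-labeled clusters merge. Connections are counted per
(ligand group, receptor group) and each cell of the matrix is scored by
an upper-tail hypergeometric test on the margins: population N = total
pairs, successes K = row total, draws n = column total. Raw p < 0.01
flags significance (no multiple-testing correction, matching the reported
convention; BH is available behind a flag). The parameterization over
connection-matrix margins is the note-worthy interpretive choice: it
reads "expected by chance given the number of ligands and receptors
expressed in each cell type" as the product of group margins over the
pair total. The compositional test applies the same tail probability to
cells: population = all cells, successes = cells of a type, draws = cells
of a sample.

## Synthetic data: what it emulates, and what it does not

The generator draws per-type expression profiles from a shared Gamma(2,1)
baseline with disjoint marker blocks multiplied by `marker_fold`
(optionally exclusive — zero outside their own type); cell libraries are
log-normal; each cell's counts are one multinomial draw, so totals are
exact. Soup is the pooled endogenous profile of the sample; mixing
replaces a Binomial(n, s) share of each cell's molecules with soup draws,
where s is either a fixed fraction or budget/n when a fixed ambient
budget per droplet is configured. Empty droplets draw Poisson totals from
the soup. Read-level data assigns each molecule a uniform UMI and
1+Poisson reads, then flips each base independently with the configured
error rate — so hamming-1 singleton artifacts arise exactly the way the
collapse rule assumes. Ligand-receptor programs are planted additively
(independent Poisson(3) counts on the program genes in the sender and
receiver types), leaving all other genes byte-identical.

Passing benchmarks on these data establish internal correctness —
each stage inverts the generative process it assumes — not performance on
real tissue: the simulator has no doublets, no batch effects beyond
per-sample soup pools, no gene-gene correlation within a type, no
transcriptome-scale expression distribution, and discrete, well-separated
cell types. Benchmark problem sizes (hundreds to a few thousand cells, 80
to 1000 genes) were chosen so the full verification runs in well under a
minute while keeping every statistical margin comfortably away from its
threshold.

## Numerical choices and degenerate inputs

- Bounds are inclusive everywhere a range is quoted (cell calling,
  empty-droplet windows, the 20% expression filter); the size-factor band
  is strict, per its "differs by less than an order of magnitude" reading.
- Mode ties resolve to the smaller value; density ties and γ ties resolve
  by cell index; k-means argmax ties by population order.
- Zero-total cells are rejected by gene-fraction conversion (they cannot
  survive cell calling); all-zero genes get p = 1/log2FC = 0; all-zero
  ZINB inputs report π = 1 with a flag.
- All randomness flows through seeded numpy Generators; t-SNE and k-means
  take explicit seeds; rerunning the pipeline with the same config and
  seed reproduces identical output checksums.
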