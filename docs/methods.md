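# Methods

## Setting and model

`dualchip` analyzes histone-modification ChIP-seq from a host organism
co-cultivated with a symbiont, where sequencing libraries mix reads from two
genomes in condition-dependent proportions. The central statistical object is
a genes × libraries count matrix with library labels
(condition ∈ {mono, cocult}, antibody target, replicate). Counts are modeled
as negative binomial, `var = μ + φμ²`, with a dispersion φ shared across
genes (optionally moderated per-gene). The differential chromatin state (DCS)
test asks, per gene and antibody target, whether normalized counts differ
between mono- and co-culture.

Assumptions: replicates within a condition share a gene mean up to library
scaling; between-library differences that affect most genes are technical and
removable by TMM; bacterial reads carry no information about host chromatin
and are excluded from all normalization denominators.

## Coordinates and read handling

All internal coordinates are 0-based half-open; GFF3 (1-based closed) and SAM
(1-based) convert at the I/O boundary. The TSS is the annotated gene 5′ end
(the annotation used here does not distinguish transcription from translation
starts, and promoter windows are defined purely by distance: 1000 bp up- /
500 bp downstream of the TSS, clipped at contig bounds with the clipping
recorded, never truncated at neighboring genes). Reads can be extended from
their 5′ end to a fixed fragment length (config `fragment_length`, default
200 bp; 0 disables) before counting; the simulator already emits
fragment-sized intervals, so the pipeline default for simulated input is 0.

Two counting conventions are used deliberately:

* **bins** — single assignment by fragment midpoint, so per-library bin sums
  equal the number of assigned reads (conservation matters for display and
  normalization sanity checks);
* **gene/promoter/peak features** — any-overlap (≥ 1 bp) multi-assignment, so
  a read in a bidirectional promoter counts for both flanking genes. Reads
  overlapping no feature still count in effective sizes.

Gene-body counts are the default DCS input; promoter-window counting is a
switch (`count_mode`) because promoter-level questions (e.g. the figures
centered on TSS regions) are better served by it.

## Normalization

Effective library size = number of host-assigned reads. TMM factors are
computed on host feature counts: for library *j* vs reference *r*, gene-wise
`M = log2((y_gj/N_j)/(y_gr/N_r))` and `A = ½ log2` of the product of relative
abundances over genes nonzero in both; the extreme 30% of M and 5% of A are
trimmed from each tail (rank-based); the factor is 2 to the precision-weighted
mean of the remaining M (delta-method weights `(N−y)/(Ny)` summed over the two
libraries); factors are centered to geometric mean 1. The reference defaults
to the library whose 75th percentile of relative counts is closest to the mean
of those percentiles.

Two deliberate choices here:

* **Common scaling size.** Before testing, counts are mean-scaled to the
  *reference library's* normalized size rather than the geometric mean of all
  normalized sizes. The geometric mean drifts by `c^(1/J)` when any one
  library is rescaled by `c`, which would perturb every adjusted count; the
  reference size is invariant, so a TMM-absorbed rescaling leaves the adjusted
  counts — and hence the p-values — unchanged.
* **Weighting.** Precision weighting follows the standard TMM construction
  and is the default. Because the weights are not scale-invariant, the factor
  absorbs a constant scaling of one library only approximately (relative error
  ~10⁻³ in practice); `tmm_factors(weighted=False)` gives the plain trimmed
  mean, for which the absorption — and the resulting p-value invariance — is
  exact. The property tests assert both behaviors.

A deliberately *wrong* alternative, total-read library-size scaling with TMM
disabled (`normalization="library-size"` on a matrix built with
`total_library_sizes`), is shipped so the failure mode can be demonstrated:
with symbiont fractions 0.05 vs 0.40 it miscalls a large fraction of a null
genome, while the host-only scheme stays at the nominal false-positive level.
Note that TMM *on host gene counts* would largely absorb even a total-read
size error — the host-only rule and TMM are redundant defenses against
contamination, which is why the naive comparator must disable both.

## Dispersion and exact test

The common dispersion maximizes the conditional NB log-likelihood pooled over
genes and conditions: given *n* replicates with a shared mean, the counts
conditional on their total follow a Dirichlet-multinomial with concentration
`r = 1/φ` per replicate, so the mean parameter cancels. Optimization is
bounded scalar search on log₁₀φ ∈ [−6, log₁₀5] (tolerance 10⁻⁶); estimates
below 10⁻⁵, or likelihoods not exceeding the Poisson limit, return φ = 0.
Optional per-gene values maximize the gene's own conditional likelihood plus
`prior_weight` (default 10) times the gene-averaged likelihood, on a 60-point
log grid — empirical-Bayes shrinkage toward the common value. A design with
one replicate everywhere is not identifiable: φ = 0 with a Poisson-fallback
flag and a warning.

The exact test conditions on the rounded two-group total of mean-scaled
counts. With `n₁`, `n₂` replicates per group, the first group's sum given the
total is `P(a|t) ∝ C(a+n₁r−1, a)·C(t−a+n₂r−1, t−a)`; two-sided p-values sum
all splits with probability ≤ the observed one (log-space comparison with a
10⁻¹⁰ tie tolerance; probabilities are normalized by log-sum-exp). φ = 0 uses
the conditional binomial `Bin(t, n₁/(n₁+n₂))`. An all-zero gene gets p = 1,
LFC = 0; genes with zero counts in every library are dropped before
normalization (their M/A values are undefined) and reported as unchanged.
LFC uses a display pseudo-count of 0.125 that never enters the test.
Background/input libraries are carried for display but excluded from testing.
BH adjustment delegates to statsmodels.

## Peak calling and concordance

The caller is a deliberately simple, deterministic sliding-window scheme
standing in for a model-based caller: windows of 200 bp every 50 bp on host
contigs; `λ_local = window · max(genome rate, 5 kb rate, 10 kb rate)` around
the window center (the max guards against calling inside enriched domains);
windows with upper Poisson tail ≤ 10⁻⁵ are kept and merged when gaps are
≤ 100 bp; the summit is the fragment-coverage argmax inside the peak; peak
p-value is the best member-window p. All thresholds are config keys. Peaks
are quantified per library (counts and reads-per-million of host-only sizes)
and the resulting matrix feeds the same DCS machinery; significant peaks map
to every gene whose body or promoter window they overlap.

Concordance between the DCS gene set A and peak-derived gene set B is
`100 · mean(|A∩B|/|A|, |A∩B|/|B|)` — the mean of the two directional overlap
fractions — with both fractions and the Jaccard index reported alongside,
since "similarity" between two gene sets admits several definitions. An
empty input set yields 0 with a flag.

## Meta-profiles

Coverage is averaged in anchor-centered coordinates (TSS or TTS; flank
1500 bp, bin 25 bp by default — enough to resolve promoter-proximal structure
a few hundred bp downstream of the TSS), minus-strand genes flipped so
downstream is positive. Genes are weighted equally (not per-read), so highly
covered genes cannot dominate; positions beyond a contig end contribute
nothing and the per-position gene count is tracked (ragged averaging).
Expression-stratified profiles split genes into quantile strata (default 4),
reducing the stratum count with a warning when there are fewer distinct
expression values.

## Synthetic data

The generator emulates the study design at desk scale: 8 host contigs of
500 kb plus one 500 kb symbiont contig, 2000 non-overlapping genes
(lognormal lengths, median ≈ 1.5 kb), two conditions × 3 replicates, mean
per-gene depth 100. Per-gene relative abundances are lognormal (σ = 0.5 —
histone-mark coverage spans a far narrower dynamic range than transcript
abundance), and dispersion defaults to φ = 0.04, i.e. a biological
coefficient of variation of 0.2, the canonical value for genetically
identical model organisms grown under controlled conditions. A planted subset
of genes (default 100 at |LFC| = 2, two-thirds increases) defines the truth
table.

Two layers share this model. The *count layer* draws NB gene counts directly.
The *read layer* draws per-gene, per-replicate Poisson counts with gamma
multipliers (shape 1/φ), so gene totals are marginally NB and the two layers
are statistically consistent; fragment midpoints mix a uniform within-gene
component with Gaussian bumps at +75 and +225 bp downstream of the TSS
(sd 40 bp, 80% bump weight) — the +1/+2 nucleosome positions where
promoter-proximal acetylation concentrates — plus a genome-wide uniform host
background (30% of host reads) and uniform symbiont reads at the condition's
contamination fraction (defaults 0.05 mono / 0.40 co-culture). Fragments are
200 bp, strands fair coin flips, everything deterministic given the seed.

With 200 bp fragments the coverage of the two equal bumps (150 bp apart,
< 4 sd separation after boxcar smoothing) peaks at their midpoint: the
planted geometry's true coverage argmax is **+150 bp**, and profile-recovery
checks assert the measured argmax within ±25 bp (one bin) of that value, for
both strand subsets.

What the generator does **not** emulate: sequence-dependent mappability and
GC bias, duplicate reads, sequencing error, paired-end fragment-length
variation, nucleosome phasing beyond +1/+2, chromatin domains, and any
correlation structure between neighboring genes. Passing tests therefore
demonstrate the statistical machinery and its contamination robustness under
the stated model, not robustness to alignment artifacts in real data.

## Validation benchmarks and problem sizes

`dualchip.validation` (used by the test suite and `scripts/acceptance.py`)
runs each benchmark at these sizes, chosen to give stable estimates in
seconds per benchmark:

* exact test vs enumeration oracle: every split of every total ≤ 60,
  φ ∈ {0, 0.05, 0.2}, designs 3v3 and 2v3 (oracle: scipy pmf products,
  normalized by full enumeration);
* null FDR: 20 simulations of 5000 genes, 3v3, φ = 0.1;
* recovery: 500 of 5000 genes planted at |LFC| = 1.5, depth 100, 3v3;
* contamination: 1000 genes, read layer, symbiont fractions 0.05/0.40, no
  planted effects, host-only+TMM vs total-read/no-TMM;
* TMM: 5-gene toy matrices vs a pure-Python step-by-step evaluation;
* profiles: 300 genes at depth 120, default geometry;
* concordance: 600 genes, 60 planted at LFC 2, depth 100;
* counting: the hand-computed bin and gene fixtures plus bin-count
  conservation on a simulated read set;
* correlation pattern: 2000 genes, 200 differential, expression = chromatin
  LFC + N(0, 0.5) noise for differential genes and independent noise
  otherwise.

## Known limitations

* The exact test rounds mean-scaled group sums to integers; for very shallow
  libraries this discretization is a non-trivial fraction of the signal.
* The tagwise dispersion grid (60 points) trades resolution for speed; the
  common dispersion is the default and the tested path.
* The peak caller has no fragment-model, paired-end or broad-peak support and
  is not intended to compete with dedicated callers — its role is the
  independent second route to differential genes.
* Promoter windows may overlap neighboring genes by construction; counts are
  intentionally multi-assigned rather than partitioned.
* The concordance statistic depends on both routes' thresholds; it is
  reported with its directional components rather than as a single canonical
  number.
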