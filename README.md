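# dualchip

Differential chromatin state analysis for **dual-organism ChIP-seq** — histone-mark
profiling of a fungal host co-cultivated with a bacterial symbiont.

When a host organism is sequenced together with a partner microbe, every ChIP-seq
library is a mixture of reads from both genomes, and the mixing fraction changes
with the culture condition. Naive library-size normalization then converts
bacterial contamination into fake genome-wide chromatin changes. `dualchip`
implements the full analysis path that avoids this:

1. **Fused reference** — host and symbiont contigs concatenated into one
   coordinate system, so a single mapping run classifies every read by organism.
2. **Host-restricted normalization** — per-library effective sizes are the
   counts of *host-assigned* reads only; symbiont and junction-ambiguous reads
   never enter a denominator.
3. **Quantification** — genome-wide bins (midpoint assignment, conserved
   totals), gene-body or promoter-window counts (any-overlap; the promoter
   window is 1000 bp upstream to 500 bp downstream of the TSS, strand-aware),
   and reads-per-million coverage tracks.
4. **Differential chromatin state (DCS) testing** — TMM scaling factors on host
   gene counts, a negative-binomial model (variance `μ + φμ²`) with
   conditional-likelihood dispersion estimation, an exact test conditional on
   per-gene group totals, Benjamini–Hochberg FDR, and classification into
   *higher* / *lower* / *unchanged* acetylation at an FDR cut-off (default
   0.01, no extra fold-change filter).
5. **Peak-based cross-validation** — a sliding-window caller with a local
   Poisson background (`λ_local = window · max(genome, 5 kb, 10 kb rates)`),
   peak-level differential testing, peak→gene assignment, and a concordance
   statistic between the two differential gene sets.
6. **Meta-profiles** — equal-weight average coverage around TSS/TTS,
   strand-flipped so downstream is positive, optionally stratified by
   expression level.
7. **Integration** — chromatin-vs-expression LFC correlation, transcription-
   factor candidate screening of the differential set, secondary-metabolism
   cluster summaries, and TPM normalization for RNA-seq counts.
8. **Synthetic data** — a generator with planted ground truth (NB counts,
   +1/+2-nucleosome promoter enrichment geometry, condition-dependent symbiont
   read fractions) so every stage is testable without external data.

## The statistics in brief

For gene *g* in library *j* with host-assigned size `N_j` and TMM factor `f_j`,
counts are modeled as `y_gj ~ NB(mean = μ_gj, var = μ_gj + φ μ_gj²)`. TMM
factors are trimmed (30% on M, 5% on A), precision-weighted means of gene-wise
log-ratios of relative abundances against a reference library, centered to
geometric mean 1. Counts are mean-scaled to the reference's normalized size;
conditional on a gene's two-group total `t`, the first group's sum `a` follows
a beta-binomial-type law

```
P(a | t) ∝ C(a + n₁r − 1, a) · C(t − a + n₂r − 1, t − a),   r = 1/φ,
```

and the two-sided p-value sums all splits no more likely than the observed one
(`φ = 0` reduces to the conditional binomial). LFC is
`log2((mean_cocult + 0.125) / (mean_mono + 0.125))` on normalized counts (the
pseudo-count is display-only).

## Worked example

```python
from dualchip import SimulationConfig, dcs_analysis, simulate_count_matrix

config = SimulationConfig(seed=2, n_genes=2000, host_contig_length=800_000,
                          n_differential=100, differential_lfc=2.0, depth=100)
matrix, truth = simulate_count_matrix(config)
result = dcs_analysis(matrix, target="H3K9ac", fdr_cutoff=0.01)
```

Running `python examples/02_differential_chromatin_state.py` (this exact
script) prints:

```
common NB dispersion estimate: 0.0399 (simulated with 0.04)
classified at FDR < 0.01: 63 higher, 36 lower, 1901 unchanged
planted differential genes recovered: 99/100 (0 false positives)
```

The dispersion estimate recovers the simulated value; *higher* means more
acetylation in co-culture; 99 of the 100 planted genes are recovered with no
false calls at FDR < 0.01. The other `examples/*.py` scripts demonstrate
counting and host-only sizes, peak/DCS concordance (≈ 84% on planted signal),
TSS meta-profiles (argmax ≈ +150 bp for the planted +75/+225 bump geometry
under 200 bp fragments), and expression integration (Pearson *r* much higher
on the differential subset than over all genes).

## Command line

```
dualchip run --config pipeline.yaml        # all stages, fixed layout + manifest
dualchip simulate --seed 1 --out sim/      # reference, annotation, reads, truth
dualchip count / dcs / peaks / profile / integrate   # per-stage subcommands
```

Exit codes: 0 success, 2 config error, 3 stage failure.

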