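"""Planted-truth validation experiments.

Each function runs one self-contained benchmark of the pipeline against
independent oracles or simulated ground truth: exact-test enumeration
equivalence, FDR control under the null, planted-signal recovery,
contamination robustness of host-only normalization, TMM agreement with a
step-by-step evaluation, meta-profile geometry recovery, DCS-vs-peak
concordance, counting fixtures, and the chromatin-expression correlation
pattern.  The oracles here are deliberately coded independently of the
implementation paths they check (scipy pmf enumeration, pure-Python
spreadsheet-style TMM, brute-force overlap loops).

Used by the test suite and by ``scripts/acceptance.py``; every function is
deterministic given its seed.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .dcs import _exact_nb_pvalue, dcs_analysis, tmm_factors
from .genome import library_key
from .peaks import assign_peaks_to_genes, call_peaks, concordance, quantify_peaks
from .profiles import meta_profile
from .quantify import (
    BinGrid,
    CountMatrix,
    bin_counts,
    feature_counts,
    total_library_sizes,
)
from .simulate import (
    SimulationConfig,
    simulate_count_matrix,
    simulate_expression_lfc,
    simulate_reads,
    simulate_reference,
)


# ---------------------------------------------------------------------------
# 1. exact test vs enumeration oracle
# ---------------------------------------------------------------------------

def _enumeration_oracle(a: int, b: int, n1: int, n2: int, phi: float) -> float:
    """Conditional two-sided p-value by explicit enumeration of all splits."""
    t = a + b
    if t == 0:
        return 1.0
    k = np.arange(t + 1)
    if phi == 0:
        pk = stats.binom.pmf(k, t, n1 / (n1 + n2))
    else:
        pk = stats.nbinom.pmf(k, n1 / phi, 0.5) * stats.nbinom.pmf(t - k, n2 / phi, 0.5)
        pk = pk / pk.sum()
    return float(min(1.0, pk[pk <= pk[a] * (1 + 1e-10)].sum()))


def exact_test_oracle_deviation(max_total: int = 60,
                                phis: tuple[float, ...] = (0.0, 0.05, 0.2),
                                designs: tuple[tuple[int, int], ...] = ((3, 3), (2, 3)),
                                ) -> dict:
    """Max |p_implementation - p_oracle| over all group totals <= max_total."""
    worst = 0.0
    n = 0
    for phi in phis:
        for n1, n2 in designs:
            for t in range(max_total + 1):
                for a in range(t + 1):
                    dev = abs(_exact_nb_pvalue(a, t - a, n1, n2, phi)
                              - _enumeration_oracle(a, t - a, n1, n2, phi))
                    worst = max(worst, dev)
                    n += 1
    return {"max_abs_dp": worst, "n": n}


# ---------------------------------------------------------------------------
# 2/3. null FDR control and planted recovery (count layer)
# ---------------------------------------------------------------------------

def _count_config(seed: int, n_genes: int, **kw) -> SimulationConfig:
    # contig length scaled so gene placement always fits
    return SimulationConfig(seed=seed, n_genes=n_genes,
                            host_contig_length=max(320 * n_genes, 200_000), **kw)


def null_fdr_fraction(seed: int, n_seeds: int = 20, n_genes: int = 5000,
                      phi: float = 0.1, depth: float = 100.0) -> dict:
    """Mean fraction of FDR < 0.01 calls over null simulations (no effects)."""
    fracs = []
    for k in range(n_seeds):
        cfg = _count_config(seed + k, n_genes, dispersion=phi, depth=depth,
                            n_differential=0)
        matrix, _ = simulate_count_matrix(cfg)
        res = dcs_analysis(matrix, target="H3K9ac")
        fracs.append(len(res.differential) / n_genes)
    return {"mean_fraction": float(np.mean(fracs)), "n": n_seeds * n_genes}


def recovery_metrics(seed: int, n_genes: int = 5000, n_differential: int = 500,
                     lfc: float = 1.5, depth: float = 100.0) -> dict:
    """Sensitivity, empirical FDR, and LFC RMSE on a planted differential set."""
    cfg = _count_config(seed, n_genes, n_differential=n_differential,
                        differential_lfc=lfc, depth=depth)
    matrix, truth = simulate_count_matrix(cfg)
    res = dcs_analysis(matrix, target="H3K9ac")
    planted = set(truth.differential)
    called = set(res.differential)
    sens = len(planted & called) / len(planted)
    efdr = len(called - planted) / max(len(called), 1)
    idx = list(planted)
    err = res.table.loc[idx, "lfc"].to_numpy() - truth.table.loc[idx, "lfc"].to_numpy()
    return {"sensitivity": sens, "empirical_fdr": efdr,
            "lfc_rmse": float(np.sqrt(np.mean(err ** 2))), "n": n_genes}


# ---------------------------------------------------------------------------
# 4. contamination robustness (read layer)
# ---------------------------------------------------------------------------

def contamination_robustness(seed: int, n_genes: int = 1000,
                             depth: float = 100.0) -> dict:
    """False-positive counts under host-only vs total-read normalization.

    Symbiont read fractions 0.05 (mono) vs 0.40 (co-culture) with zero
    planted host effects: any differential call is a false positive.
    """
    cfg = SimulationConfig(seed=seed, n_genes=n_genes, n_host_contigs=4,
                           host_contig_length=max(650 * n_genes, 200_000),
                           depth=depth, n_differential=0,
                           symbiont_fraction={"mono": 0.05, "cocult": 0.40})
    genome, genes, truth = simulate_reference(cfg)
    reads = simulate_reads(cfg, genome, truth)
    matrix = feature_counts(reads, genes, genome)
    host_fp = len(dcs_analysis(matrix, target="H3K9ac").differential)
    naive = CountMatrix(matrix.counts, total_library_sizes(reads),
                        matrix.feature_lengths, matrix.libraries)
    total_fp = len(dcs_analysis(naive, target="H3K9ac",
                                normalization="library-size").differential)
    return {"host_norm_fp": host_fp, "total_norm_fp": total_fp, "n": n_genes}


# ---------------------------------------------------------------------------
# 5. TMM vs step-by-step oracle
# ---------------------------------------------------------------------------

def _tmm_oracle_pair(y, yr, n, nr, trim_m=0.3, trim_a=0.05):
    rows = [(yi, yri) for yi, yri in zip(y, yr) if yi > 0 and yri > 0]
    M, A, W = [], [], []
    for yi, yri in rows:
        p, pr = yi / n, yri / nr
        M.append(math.log2(p / pr))
        A.append(0.5 * math.log2(p * pr))
        W.append((n - yi) / (n * yi) + (nr - yri) / (nr * yri))
    m = len(M)
    rank_m = {i: k + 1 for k, i in enumerate(sorted(range(m), key=lambda i: M[i]))}
    rank_a = {i: k + 1 for k, i in enumerate(sorted(range(m), key=lambda i: A[i]))}
    lo_m, hi_m = math.floor(m * trim_m) + 1, m - math.floor(m * trim_m)
    lo_a, hi_a = math.floor(m * trim_a) + 1, m - math.floor(m * trim_a)
    keep = [i for i in range(m)
            if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a]
    num = sum(M[i] / W[i] for i in keep)
    den = sum(1.0 / W[i] for i in keep)
    return 2.0 ** (num / den)


def tmm_oracle_error() -> dict:
    """Max |factor - oracle factor| over 5-gene toy matrices (plus the
    identical-libraries identity)."""
    toys = [
        ([10, 20, 30, 40, 50], [12, 44, 28, 80, 55]),
        ([100, 5, 60, 33, 90], [90, 12, 70, 60, 80]),
        ([7, 7, 7, 7, 7], [3, 9, 21, 6, 14]),
    ]
    worst = 0.0
    for y_a, y_b in toys:
        counts = pd.DataFrame({"mono:H3:1": y_a, "cocult:H3:1": y_b},
                              index=[f"g{i}" for i in range(5)])
        matrix = CountMatrix(counts, counts.sum(axis=0).astype(float))
        f = tmm_factors(matrix, reference="mono:H3:1")
        raw_b = _tmm_oracle_pair(y_b, y_a, float(sum(y_b)), float(sum(y_a)))
        center = math.sqrt(raw_b)
        worst = max(worst,
                    abs(f.factors["mono:H3:1"] - 1.0 / center),
                    abs(f.factors["cocult:H3:1"] - raw_b / center))
    # identical libraries must give exactly 1
    counts = pd.DataFrame({"mono:H3:1": [10, 20, 30, 40, 50],
                           "cocult:H3:1": [10, 20, 30, 40, 50]},
                          index=[f"g{i}" for i in range(5)])
    matrix = CountMatrix(counts, counts.sum(axis=0).astype(float))
    ident_dev = float(np.abs(tmm_factors(matrix).factors - 1.0).max())
    return {"max_abs_error": float(max(worst, ident_dev)),
            "identical_libraries_max_dev": ident_dev, "n": len(toys) + 1}


# ---------------------------------------------------------------------------
# 6. meta-profile geometry recovery
# ---------------------------------------------------------------------------

def profile_recovery(seed: int, n_genes: int = 300, depth: float = 120.0) -> dict:
    """TSS profile argmax for + and - strand genes under planted +75/+225
    bumps.

    With the default 200 bp fragments the coverage of two equal bumps 150 bp
    apart peaks at their midpoint, so the planted geometry's true coverage
    argmax is +150 bp.
    """
    cfg = SimulationConfig(seed=seed, n_genes=n_genes, n_host_contigs=2,
                           host_contig_length=max(1300 * n_genes, 200_000),
                           depth=depth, n_differential=0)
    genome, genes, truth = simulate_reference(cfg)
    reads = simulate_reads(cfg, genome, truth)
    lib = library_key("mono", cfg.targets[0], 1)
    out = {"expected_bp": 150.0, "n": n_genes}
    for name, subset in (("plus", [g for g in genes if g.strand == "+"]),
                         ("minus", [g for g in genes if g.strand == "-"])):
        prof = meta_profile(reads, lib, subset, genome)
        out[f"argmax_{name}_bp"] = prof.argmax_position
    return out


# ---------------------------------------------------------------------------
# 7. DCS vs peak concordance
# ---------------------------------------------------------------------------

def peak_dcs_concordance(seed: int, n_genes: int = 600, depth: float = 100.0,
                         lfc: float = 2.0, n_differential: int = 60) -> dict:
    """Concordance between DCS gene calls and peak-derived gene calls on a
    strong planted signal, plus the identical-sets identity."""
    cfg = SimulationConfig(seed=seed, n_genes=n_genes, n_host_contigs=2,
                           host_contig_length=max(1300 * n_genes, 200_000),
                           depth=depth, n_differential=n_differential,
                           differential_lfc=lfc)
    genome, genes, truth = simulate_reference(cfg)
    reads = simulate_reads(cfg, genome, truth)
    target = cfg.targets[0]
    matrix = feature_counts(reads, genes, genome)
    dcs_set = set(dcs_analysis(matrix, target=target).differential)

    pooled_key = library_key("pooled", target, 0)
    pooled = reads.assign(library=pooled_key)
    peaks = call_peaks(pooled, pooled_key, genome)
    pk_matrix = quantify_peaks(peaks, reads, genome)
    pk_res = dcs_analysis(pk_matrix, target=target)
    sig = [p for p in peaks if p.id in set(pk_res.differential)]
    gene_map, _ = assign_peaks_to_genes(sig, genes, genome)
    rep = concordance(dcs_set, set(gene_map))
    identical = concordance(dcs_set, dcs_set)
    return {"similarity_pct": rep.similarity,
            "identical_sets_pct": identical.similarity,
            "n_dcs": rep.n_dcs, "n_peak": rep.n_peak, "n": n_genes}


# ---------------------------------------------------------------------------
# 8. counting fixtures
# ---------------------------------------------------------------------------

def counting_fixture_error(seed: int = 0) -> dict:
    """Deviation of the two hand-computed counting fixtures and the worst
    per-library bin-conservation defect on a simulated read set."""
    from .genome import Contig, Gene, build_fused_genome

    worst = 0
    # 3 reads, 2 bins: midpoints 10, 60, 99 on a 50 bp grid -> (1, 2)
    g = build_fused_genome([Contig("c", 100, "host")], [])
    reads = pd.DataFrame({"contig": ["c"] * 3, "start": [5, 55, 98],
                          "end": [15, 65, 100], "strand": ["+"] * 3,
                          "library": ["mono:H3:1"] * 3})
    m = bin_counts(reads, BinGrid(50, g), g)
    worst = max(worst, int(np.abs(m.counts.iloc[:, 0].to_numpy()
                                  - np.array([1, 2])).max()))

    # 10 reads, 3 genes with brute-force-verified expected counts (2, 2, 2)
    genome2 = build_fused_genome([Contig("chrI", 10_000, "host"),
                                  Contig("chrII", 8_000, "host")], [])
    genes = [Gene("g1", "chrI", 1_000, 3_000, "+"),
             Gene("g2", "chrI", 4_000, 5_500, "-"),
             Gene("g3", "chrII", 2_000, 4_000, "+")]
    rows = [("chrI", 500, 700), ("chrI", 900, 1_100), ("chrI", 2_900, 3_100),
            ("chrI", 3_500, 3_700), ("chrI", 4_100, 4_300), ("chrI", 5_400, 5_600),
            ("chrII", 1_900, 2_100), ("chrII", 3_000, 3_200),
            ("chrII", 4_000, 4_200), ("chrII", 7_000, 7_200)]
    reads2 = pd.DataFrame(rows, columns=["contig", "start", "end"])
    reads2["strand"] = "+"
    reads2["library"] = "mono:H3:1"
    fm = feature_counts(reads2, genes, genome2)
    expected = {}
    for gene in genes:  # brute-force overlap oracle
        expected[gene.id] = sum(
            1 for r in rows
            if r[0] == gene.contig and r[1] < gene.end and r[2] > gene.start)
    got = fm.counts.iloc[:, 0].to_dict()
    worst = max(worst, max(abs(got[k] - expected[k]) for k in expected))

    # bin-count conservation on every simulated library
    cfg = SimulationConfig(seed=seed, n_genes=150, n_host_contigs=2,
                           host_contig_length=300_000, depth=30)
    genome3, _, truth = simulate_reference(cfg)
    sim_reads = simulate_reads(cfg, genome3, truth)
    bm = bin_counts(sim_reads, BinGrid(50_000, genome3), genome3)
    assigned = sim_reads.groupby("library").size()
    conserve = int((bm.counts.sum(axis=0) - assigned[bm.counts.columns]).abs().max())
    worst = max(worst, conserve)
    return {"max_abs_error": worst, "bin_conservation_max_dev": conserve,
            "n": len(rows) + 3 + len(sim_reads)}


# ---------------------------------------------------------------------------
# 9. chromatin-expression correlation pattern
# ---------------------------------------------------------------------------

def correlation_pattern(seed: int, n_genes: int = 2000,
                        n_differential: int = 200) -> dict:
    """Pearson r over all genes vs over the differential subset when
    expression tracks chromatin only for truly changed genes."""
    from .integrate import correlate_lfc, join_lfc

    cfg = _count_config(seed, n_genes, n_differential=n_differential,
                        differential_lfc=1.5)
    matrix, truth = simulate_count_matrix(cfg)
    res = dcs_analysis(matrix, target="H3K9ac")
    expr = simulate_expression_lfc(truth)
    join = join_lfc(res, expr)
    r_all, n_all = correlate_lfc(join, "all")
    r_diff, n_diff = correlate_lfc(join, "differential")
    return {"r_all": r_all, "r_differential": r_diff,
            "n_all": n_all, "n_differential": n_diff, "n": n_genes}
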