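"""TMM factors, NB dispersion, exact test, BH-FDR, and DCS classification.

Oracles are kept independent of the implementation: the TMM oracle is a
step-by-step pure-Python evaluation of the trimmed-M formula, and the
exact-test oracle builds the conditional distribution from scipy's nbinom /
binom pmfs and normalizes by full enumeration.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dualchip import (
    CountMatrix,
    SimulationConfig,
    bh_adjust,
    dcs_analysis,
    estimate_dispersion,
    ma_table,
    nb_exact_test,
    simulate_count_matrix,
    tmm_factors,
)
from dualchip.dcs import _exact_nb_pvalue, unit_factors


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def tmm_oracle_pair(y, yr, n, nr, trim_m=0.3, trim_a=0.05, weighted=True):
    """Spreadsheet-style evaluation of the trimmed-M factor for one library."""
    rows = [(yi, yri) for yi, yri in zip(y, yr) if yi > 0 and yri > 0]
    M, A, W = [], [], []
    for yi, yri in rows:
        p, pr = yi / n, yri / nr
        M.append(math.log2(p / pr))
        A.append(0.5 * math.log2(p * pr))
        W.append((n - yi) / (n * yi) + (nr - yri) / (nr * yri))
    m = len(M)
    order_m = sorted(range(m), key=lambda i: M[i])
    order_a = sorted(range(m), key=lambda i: A[i])
    rank_m = {i: k + 1 for k, i in enumerate(order_m)}
    rank_a = {i: k + 1 for k, i in enumerate(order_a)}
    lo_m, hi_m = math.floor(m * trim_m) + 1, m - math.floor(m * trim_m)
    lo_a, hi_a = math.floor(m * trim_a) + 1, m - math.floor(m * trim_a)
    keep = [i for i in range(m)
            if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a]
    if weighted:
        num = sum(M[i] / W[i] for i in keep)
        den = sum(1.0 / W[i] for i in keep)
    else:
        num, den = sum(M[i] for i in keep), len(keep)
    return 2.0 ** (num / den)


def exact_oracle(a, b, n1, n2, phi):
    """Conditional two-sided p by brute-force enumeration of all splits."""
    t = a + b
    if t == 0:
        return 1.0
    k = np.arange(t + 1)
    if phi == 0:
        pk = stats.binom.pmf(k, t, n1 / (n1 + n2))
    else:
        r1, r2 = n1 / phi, n2 / phi
        pk = stats.nbinom.pmf(k, r1, 0.5) * stats.nbinom.pmf(t - k, r2, 0.5)
        pk = pk / pk.sum()
    return float(min(1.0, pk[pk <= pk[a] * (1 + 1e-10)].sum()))


def two_group_matrix(counts_by_lib, sizes=None, target="H3K9ac"):
    counts = pd.DataFrame(counts_by_lib)
    counts.index = [f"g{i}" for i in range(len(counts))]
    if sizes is None:
        sizes = counts.sum(axis=0).astype(float)
    else:
        sizes = pd.Series(sizes, dtype=float)
    return CountMatrix(counts, sizes)


def condition_groups(matrix):
    libs = matrix.libraries
    return {c: list(libs.index[libs["condition"] == c])
            for c in libs["condition"].unique()}


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

class TestTmm:
    def test_identical_libraries_give_unit_factors(self):
        m = two_group_matrix({
            "mono:H3K9ac:1": [10, 20, 30, 40, 50],
            "cocult:H3K9ac:1": [10, 20, 30, 40, 50],
        })
        f = tmm_factors(m)
        assert np.allclose(f.factors.to_numpy(), 1.0)

    def test_five_gene_toy_matches_step_by_step_oracle(self):
        y_a = [10, 20, 30, 40, 50]
        y_b = [12, 44, 28, 80, 55]
        m = two_group_matrix({"mono:H3K9ac:1": y_a, "cocult:H3K9ac:1": y_b})
        n_a, n_b = float(sum(y_a)), float(sum(y_b))
        f = tmm_factors(m, reference="mono:H3K9ac:1")
        raw_b = tmm_oracle_pair(y_b, y_a, n_b, n_a)
        center = math.sqrt(raw_b)  # geometric mean of (1, raw_b)
        assert f.factors["mono:H3K9ac:1"] == pytest.approx(1.0 / center, abs=1e-9)
        assert f.factors["cocult:H3K9ac:1"] == pytest.approx(raw_b / center, abs=1e-9)

    def test_doubled_library_is_compensated(self):
        """Library B = 2x library A with equal effective sizes: the factor
        ratio absorbs the doubling so normalized abundances agree."""
        rng = np.random.default_rng(12)
        y = rng.poisson(100, 200)
        m = two_group_matrix({"mono:H3K9ac:1": y, "cocult:H3K9ac:1": 2 * y},
                             sizes={"mono:H3K9ac:1": 2e4, "cocult:H3K9ac:1": 2e4})
        f = tmm_factors(m, reference="mono:H3K9ac:1")
        norm = m.counts / f.normalized_sizes
        assert np.allclose(norm.iloc[:, 0], norm.iloc[:, 1], rtol=1e-9)

    def test_unweighted_factors_exactly_absorb_count_scaling(self):
        cfg = SimulationConfig(seed=9, n_genes=500, host_contig_length=400_000,
                               n_differential=0)
        m, _ = simulate_count_matrix(cfg)
        ref = m.counts.columns[0]
        lib = m.counts.columns[-1]
        scaled = CountMatrix(m.counts.assign(**{lib: m.counts[lib] * 3}),
                             m.effective_sizes, m.feature_lengths)
        f1 = tmm_factors(m, reference=ref, weighted=False)
        f2 = tmm_factors(scaled, reference=ref, weighted=False)
        p1 = nb_exact_test(m, f1, 0.04)["pvalue"]
        p2 = nb_exact_test(scaled, f2, 0.04)["pvalue"]
        assert np.max(np.abs(p1.to_numpy() - p2.to_numpy())) < 1e-9

    def test_weighted_factors_absorb_count_scaling_approximately(self):
        cfg = SimulationConfig(seed=9, n_genes=500, host_contig_length=400_000,
                               n_differential=0)
        m, _ = simulate_count_matrix(cfg)
        ref = m.counts.columns[0]
        lib = m.counts.columns[-1]
        scaled = CountMatrix(m.counts.assign(**{lib: m.counts[lib] * 3}),
                             m.effective_sizes, m.feature_lengths)
        f1 = tmm_factors(m, reference=ref)
        f2 = tmm_factors(scaled, reference=ref)
        ratio = (f2.factors[lib] / f1.factors[lib]) * (f1.factors[ref] / f2.factors[ref])
        assert ratio == pytest.approx(3.0, rel=0.01)

    def test_single_library_rejected(self):
        m = two_group_matrix({"mono:H3K9ac:1": [5, 5, 5]})
        with pytest.raises(ValueError):
            tmm_factors(m)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

class TestDispersion:
    def test_poisson_counts_give_near_zero_dispersion(self):
        cfg = SimulationConfig(seed=6, n_genes=2000, host_contig_length=800_000,
                               dispersion=0.0, n_differential=0, depth=100)
        m, _ = simulate_count_matrix(cfg)
        d = estimate_dispersion(m, tmm_factors(m), condition_groups(m))
        assert d.common <= 0.01

    def test_nb_dispersion_recovered(self):
        cfg = SimulationConfig(seed=5, n_genes=2000, host_contig_length=800_000,
                               dispersion=0.2, n_differential=0, depth=100)
        m, _ = simulate_count_matrix(cfg)
        d = estimate_dispersion(m, tmm_factors(m), condition_groups(m))
        assert 0.15 <= d.common <= 0.25

    def test_identical_replicates_give_zero(self):
        m = two_group_matrix({
            "mono:H3K9ac:1": [50, 80, 20], "mono:H3K9ac:2": [50, 80, 20],
            "cocult:H3K9ac:1": [50, 80, 20], "cocult:H3K9ac:2": [50, 80, 20],
        }, sizes={k: 150.0 for k in ["mono:H3K9ac:1", "mono:H3K9ac:2",
                                     "cocult:H3K9ac:1", "cocult:H3K9ac:2"]})
        d = estimate_dispersion(m, unit_factors(m), condition_groups(m))
        assert d.common == 0.0

    def test_single_replicate_poisson_fallback(self):
        m = two_group_matrix({"mono:H3K9ac:1": [10, 20], "cocult:H3K9ac:1": [30, 5]})
        with pytest.warns(UserWarning, match="Poisson"):
            d = estimate_dispersion(m, unit_factors(m), condition_groups(m))
        assert d.common == 0.0 and d.poisson_fallback


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

class TestExactTest:
    def test_equal_counts_give_p_one(self):
        for phi in (0.0, 0.05, 0.2):
            assert _exact_nb_pvalue(7, 7, 3, 3, phi) == pytest.approx(1.0)

    def test_poisson_three_vs_nine_matches_binomial_enumeration(self):
        # 1v1 libraries, equal sizes: conditional binomial(12, 1/2);
        # splits {0..3, 9..12} are no more likely than the observed (3, 9)
        expected = sum(math.comb(12, k) for k in [0, 1, 2, 3, 9, 10, 11, 12]) / 2 ** 12
        assert expected == pytest.approx(598 / 4096)
        assert _exact_nb_pvalue(3, 9, 1, 1, 0.0) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("phi", [0.0, 0.05, 0.2])
    @pytest.mark.parametrize("n1,n2", [(3, 3), (2, 3)])
    def test_matches_enumeration_oracle_small_totals(self, phi, n1, n2):
        for t in range(0, 26):
            for a in range(t + 1):
                got = _exact_nb_pvalue(a, t - a, n1, n2, phi)
                want = exact_oracle(a, t - a, n1, n2, phi)
                assert got == pytest.approx(want, abs=1e-9), (a, t - a, phi)

    def test_zero_total_feature(self):
        m = two_group_matrix({"mono:H3K9ac:1": [0, 10], "cocult:H3K9ac:1": [0, 10]},
                             sizes={"mono:H3K9ac:1": 10.0, "cocult:H3K9ac:1": 10.0})
        res = nb_exact_test(m, unit_factors(m), 0.1)
        assert res.loc["g0", "pvalue"] == 1.0
        assert res.loc["g0", "lfc"] == 0.0


# ---------------------------------------------------------------------------
# BH
# ---------------------------------------------------------------------------

class TestBhAdjust:
    def test_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_all_ones(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_manual_step_up_on_random_inputs(self):
        rng = np.random.default_rng(2)
        p = rng.random(57)
        order = np.argsort(p)
        m = len(p)
        q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        manual = np.empty(m)
        manual[order] = np.minimum(q_sorted, 1.0)
        assert np.allclose(bh_adjust(p), manual)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# DCS composition and MA diagnostics
# ---------------------------------------------------------------------------

class TestDcsAnalysis:
    def test_sign_flip_of_contrast_swaps_classes(self):
        cfg = SimulationConfig(seed=13, n_genes=800, host_contig_length=600_000,
                               n_differential=80)
        m, _ = simulate_count_matrix(cfg)
        fwd = dcs_analysis(m, target="H3K9ac", contrast=("mono", "cocult"))
        rev = dcs_analysis(m, target="H3K9ac", contrast=("cocult", "mono"))
        assert set(fwd.higher) == set(rev.lower)
        assert set(fwd.lower) == set(rev.higher)
        assert np.allclose(fwd.table["lfc"], -rev.table["lfc"], atol=1e-9)

    def test_null_simulation_yields_almost_no_calls(self):
        cfg = SimulationConfig(seed=14, n_genes=2000, host_contig_length=800_000,
                               dispersion=0.1, n_differential=0)
        m, _ = simulate_count_matrix(cfg)
        res = dcs_analysis(m, target="H3K9ac")
        assert len(res.differential) <= 0.01 * 2000

    def test_planted_high_lfc_mostly_recovered(self):
        cfg = SimulationConfig(seed=15, n_genes=2000, host_contig_length=800_000,
                               n_differential=100, differential_lfc=2.0, frac_up=1.0)
        m, truth = simulate_count_matrix(cfg)
        res = dcs_analysis(m, target="H3K9ac")
        recovered = set(truth.differential) & set(res.higher)
        assert len(recovered) >= 0.8 * 100

    def test_class_consistent_with_fdr_and_lfc(self):
        cfg = SimulationConfig(seed=16, n_genes=500, host_contig_length=400_000,
                               n_differential=50)
        m, _ = simulate_count_matrix(cfg)
        res = dcs_analysis(m, target="H3K9ac")
        t = res.table
        called = t["dcs_class"] != "unchanged"
        assert (t.loc[called, "fdr"] < 0.01).all()
        assert (t.loc[t["dcs_class"] == "higher", "lfc"] > 0).all()
        assert (t.loc[t["dcs_class"] == "lower", "lfc"] < 0).all()


class TestMaTable:
    def test_identical_groups_have_zero_m(self):
        y = [30, 60, 90, 120]
        m = two_group_matrix({"mono:H3K9ac:1": y, "cocult:H3K9ac:1": y})
        ma = ma_table(m, tmm_factors(m))
        assert np.allclose(ma["M"], 0.0, atol=1e-12)

    def test_null_m_distribution_centered_even_after_library_scaling(self):
        cfg = SimulationConfig(seed=17, n_genes=1000, host_contig_length=600_000,
                               n_differential=0)
        m, _ = simulate_count_matrix(cfg)
        ma0 = ma_table(m, tmm_factors(m))
        assert abs(ma0["M"].median()) < 0.05
        lib = m.counts.columns[0]
        scaled = CountMatrix(m.counts.assign(**{lib: m.counts[lib] * 2}),
                             m.effective_sizes, m.feature_lengths)
        ma1 = ma_table(scaled, tmm_factors(scaled))
        assert abs(ma1["M"].median()) < 0.05
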