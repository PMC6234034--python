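"""Bin/feature counting, effective sizes, RPKM, coverage tracks."""

import numpy as np
import pandas as pd
import pytest

from dualchip import (
    BinGrid,
    Contig,
    CountMatrix,
    Gene,
    SimulationConfig,
    bin_counts,
    build_fused_genome,
    coverage_track,
    effective_library_sizes,
    feature_counts,
    rpkm,
    simulate_reads,
    simulate_reference,
)
from dualchip.genome import promoter_windows
from dualchip.quantify import total_library_sizes

from conftest import make_reads


class TestEffectiveSizes:
    def test_counts_only_host_reads(self, toy_genome):
        rows = [("chrI", i * 10, i * 10 + 5) for i in range(900)]
        rows += [("plasmid", i, i + 5) for i in range(100)]
        sizes = effective_library_sizes(make_reads(rows), toy_genome)
        assert sizes["mono:H3K9ac:1"] == 900.0
        assert total_library_sizes(make_reads(rows))["mono:H3K9ac:1"] == 1000.0

    def test_contamination_does_not_change_size(self, toy_genome):
        """Two libraries with equal host reads but symbiont fractions 0.05 vs
        0.40 get identical effective sizes — the property motivating the
        host-only rule."""
        host = [("chrI", i, i + 5, "+", lib)
                for i in range(600) for lib in ("mono:H3:1", "cocult:H3:1")]
        sym = [("plasmid", i % 4000, i % 4000 + 5, "+", "mono:H3:1") for i in range(32)]
        sym += [("plasmid", i % 4000, i % 4000 + 5, "+", "cocult:H3:1") for i in range(400)]
        sizes = effective_library_sizes(make_reads(host + sym), toy_genome)
        assert sizes["mono:H3:1"] == sizes["cocult:H3:1"] == 600.0

    def test_zero_host_reads_rejected(self, toy_genome):
        reads = make_reads([("plasmid", 0, 50, "+", "mono:H3:1")])
        with pytest.raises(ValueError, match="mono:H3:1"):
            effective_library_sizes(reads, toy_genome)


class TestBinCounts:
    def test_midpoint_assignment_fixture(self):
        """Reads with midpoints 10, 60, 99 on a 50 bp grid over a 100 bp
        contig land in bins (1, 2)."""
        g = build_fused_genome([Contig("c", 100, "host")], [])
        reads = make_reads([("c", 5, 15), ("c", 55, 65), ("c", 98, 100)])
        m = bin_counts(reads, BinGrid(50, g), g)
        assert m.counts.iloc[:, 0].tolist() == [1, 2]

    def test_conservation_on_simulated_library(self):
        cfg = SimulationConfig(seed=4, n_genes=100, n_host_contigs=2,
                               host_contig_length=200_000, depth=20)
        genome, genes, truth = simulate_reference(cfg)
        reads = simulate_reads(cfg, genome, truth)
        m = bin_counts(reads, BinGrid(50_000, genome), genome)
        per_lib_assigned = reads.groupby("library").size()
        for lib in m.counts.columns:
            assert m.counts[lib].sum() == per_lib_assigned[lib]

    def test_empty_reads_give_empty_matrix(self, toy_genome):
        m = bin_counts(make_reads([]), BinGrid(1_000, toy_genome), toy_genome)
        assert m.counts.shape[1] == 0
        assert (m.counts.to_numpy() == 0).all()


def brute_force_counts(reads, intervals):
    """Independent O(R*F) overlap oracle."""
    out = {}
    for fid, iv in intervals.items():
        n = 0
        for r in reads.itertuples(index=False):
            if r.contig == iv.contig and r.start < iv.end and r.end > iv.start:
                n += 1
        out[fid] = n
    return out


class TestFeatureCounts:
    def test_one_bp_overlap_counts(self, toy_genome):
        gene = Gene("g", "chrI", 200, 900, "+")
        m = feature_counts(make_reads([("chrI", 100, 300)]), [gene], toy_genome)
        assert m.counts.loc["g"].iloc[0] == 1
        m2 = feature_counts(make_reads([("chrI", 100, 200)]), [gene], toy_genome)
        assert m2.counts.loc["g"].iloc[0] == 0  # half-open: no shared base

    def test_bidirectional_promoter_read_counted_twice(self, toy_genome):
        # two divergent genes sharing an intergenic promoter region
        left = Gene("gl", "chrI", 2_000, 3_000, "-")    # TSS at 3000
        right = Gene("gr", "chrI", 3_400, 4_400, "+")   # TSS at 3400
        reads = make_reads([("chrI", 3_150, 3_250)])
        m = feature_counts(reads, [left, right], toy_genome, mode="promoter")
        assert m.counts.loc["gl"].iloc[0] == 1
        assert m.counts.loc["gr"].iloc[0] == 1

    def test_ten_read_three_gene_fixture_matches_oracle(self, toy_genome, toy_genes):
        reads = make_reads([
            ("chrI", 500, 700), ("chrI", 900, 1_100), ("chrI", 2_900, 3_100),
            ("chrI", 3_500, 3_700), ("chrI", 4_100, 4_300), ("chrI", 5_400, 5_600),
            ("chrII", 1_900, 2_100), ("chrII", 3_000, 3_200), ("chrII", 4_000, 4_200),
            ("chrII", 7_000, 7_200),
        ])
        ivals = {g.id: g.interval() for g in toy_genes}
        expected = brute_force_counts(reads, ivals)
        # hand check: g1 gets reads 2,3; g2 gets 5,6; g3 gets 7,8
        assert expected == {"g1": 2, "g2": 2, "g3": 2}
        m = feature_counts(reads, toy_genes, toy_genome)
        got = m.counts.iloc[:, 0].to_dict()
        assert got == expected

    def test_random_reads_match_oracle_and_order_invariance(self, toy_genome, toy_genes):
        rng = np.random.default_rng(7)
        rows = []
        for _ in range(300):
            contig = rng.choice(["chrI", "chrII"])
            s = int(rng.integers(0, toy_genome.length(contig) - 200))
            rows.append((contig, s, s + int(rng.integers(30, 200))))
        reads = make_reads(rows)
        ivals = {g.id: g.interval() for g in toy_genes}
        expected = brute_force_counts(reads, ivals)
        m = feature_counts(reads, toy_genes, toy_genome)
        assert m.counts.iloc[:, 0].to_dict() == expected
        shuffled = reads.sample(frac=1.0, random_state=1).reset_index(drop=True)
        m2 = feature_counts(shuffled, toy_genes, toy_genome)
        pd.testing.assert_frame_equal(m.counts, m2.counts)

    def test_empty_feature_list_rejected(self, toy_genome):
        with pytest.raises(ValueError, match="empty"):
            feature_counts(make_reads([("chrI", 0, 50)]), [], toy_genome)

    def test_symbiont_features_rejected(self, toy_genome):
        g = Gene("s", "plasmid", 0, 100, "+")
        with pytest.raises(ValueError, match="host"):
            feature_counts(make_reads([("chrI", 0, 50)]), [g], toy_genome)


class TestRpkm:
    def _matrix(self, count, size):
        counts = pd.DataFrame({"mono:H3:1": [count], "cocult:H3:1": [count]},
                              index=["f"])
        sizes = pd.Series({"mono:H3:1": size, "cocult:H3:1": size})
        return CountMatrix(counts, sizes, feature_lengths=pd.Series({"f": 1_000.0}))

    def test_formula(self):
        out = rpkm(self._matrix(10, 1e6))
        assert out.loc["f", "mono:H3:1"] == pytest.approx(10.0)
        assert rpkm(self._matrix(0, 1e6)).loc["f"].eq(0).all()

    def test_doubling_effective_size_halves(self):
        a = rpkm(self._matrix(10, 1e6))
        b = rpkm(self._matrix(10, 2e6))
        assert np.allclose(a.to_numpy(), 2 * b.to_numpy())

    def test_duplicating_reads_leaves_rpkm_fixed(self):
        """Doubling all counts doubles effective sizes too, so RPKM is
        unchanged."""
        a = rpkm(self._matrix(10, 1e6))
        b = rpkm(self._matrix(20, 2e6))
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_zero_length_rejected(self):
        m = self._matrix(10, 1e6)
        with pytest.raises(ValueError):
            rpkm(m, pd.Series({"f": 0.0}))


class TestCoverageTrack:
    def test_planted_enrichment_is_track_maximum(self, toy_genome):
        rng = np.random.default_rng(3)
        rows = [("chrI", int(s), int(s) + 50)
                for s in rng.integers(0, 9_950, 400)]
        rows += [("chrI", int(s), int(s) + 50)
                 for s in rng.integers(4_000, 4_950, 400)]  # 10x enriched 1 kb
        track = coverage_track(make_reads(rows), "mono:H3K9ac:1", 500, toy_genome)
        assert 4_000 <= int(np.argmax(track["chrI"])) * 500 < 5_000

    def test_unknown_library_rejected(self, toy_genome):
        with pytest.raises(ValueError):
            coverage_track(make_reads([("chrI", 0, 50)]), "nope:x:1", 500, toy_genome)
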