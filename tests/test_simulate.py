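"""Synthetic-data generator: determinism, planted structure, statistical
moments, format round-trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dualchip import (
    SimulationConfig,
    dcs_analysis,
    feature_counts,
    simulate_count_matrix,
    simulate_reads,
    simulate_reference,
)
from dualchip.genome import classify_reads, promoter_windows


SMALL = dict(n_genes=150, n_host_contigs=2, host_contig_length=300_000)


class TestReference:
    def test_same_seed_reproduces_everything(self):
        cfg = SimulationConfig(seed=42, **SMALL)
        g1, genes1, t1 = simulate_reference(cfg)
        g2, genes2, t2 = simulate_reference(cfg)
        assert [c.name for c in g1.contigs] == [c.name for c in g2.contigs]
        assert genes1 == genes2
        pd.testing.assert_frame_equal(t1.table, t2.table)
        r1 = simulate_reads(cfg, g1, t1)
        r2 = simulate_reads(cfg, g2, t2)
        pd.testing.assert_frame_equal(r1, r2)

    def test_sequences_deterministic(self):
        cfg = SimulationConfig(seed=7, n_genes=10, n_host_contigs=1,
                               host_contig_length=20_000,
                               symbiont_contig_length=5_000)
        *_, s1 = simulate_reference(cfg, with_sequences=True)
        *_, s2 = simulate_reference(cfg, with_sequences=True)
        assert s1 == s2
        assert len(s1["chr1"]) == 20_000

    def test_zero_genes_is_valid(self):
        cfg = SimulationConfig(seed=1, n_genes=0, n_host_contigs=1,
                               host_contig_length=50_000)
        genome, genes, truth = simulate_reference(cfg)
        assert genes == [] and len(truth.table) == 0
        assert genome.total_length == 50_000 + cfg.symbiont_contig_length

    def test_genes_that_do_not_fit_rejected(self):
        cfg = SimulationConfig(seed=1, n_genes=500, n_host_contigs=1,
                               host_contig_length=100_000)
        with pytest.raises(ValueError, match="fit"):
            simulate_reference(cfg)

    def test_genes_non_overlapping_and_strand_balanced(self):
        cfg = SimulationConfig(seed=3, n_genes=1000, n_host_contigs=4,
                               host_contig_length=600_000)
        _, genes, _ = simulate_reference(cfg)
        by_contig = {}
        for g in genes:
            by_contig.setdefault(g.contig, []).append(g)
        for gs in by_contig.values():
            gs = sorted(gs, key=lambda g: g.start)
            for a, b in zip(gs, gs[1:]):
                assert a.end <= b.start
        n_plus = sum(g.strand == "+" for g in genes)
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.5)
        assert lo <= n_plus <= hi

    def test_planted_structure_matches_config(self):
        cfg = SimulationConfig(seed=4, n_genes=400, n_host_contigs=2,
                               host_contig_length=500_000, n_differential=40,
                               n_tf_flags=30, n_clusters=3, genes_per_cluster=5)
        _, genes, truth = simulate_reference(cfg)
        t = truth.table
        assert t["differential"].sum() == 40
        assert t["tf_flag"].sum() == 30
        assert set(np.abs(t.loc[t["differential"], "lfc"])) == {cfg.differential_lfc}
        assert (t.loc[~t["differential"], "lfc"] == 0).all()
        sizes = t.loc[t["cluster_id"] != ""].groupby("cluster_id").size()
        assert len(sizes) == 3 and (sizes == 5).all()


class TestReads:
    def test_contamination_fraction_recovered(self):
        cfg = SimulationConfig(seed=8, n_genes=200, n_host_contigs=2,
                               host_contig_length=400_000, depth=250,
                               replicates=1,
                               symbiont_fraction={"mono": 0.05, "cocult": 0.40})
        genome, genes, truth = simulate_reference(cfg)
        reads = simulate_reads(cfg, genome, truth)
        org = classify_reads(reads, genome)
        for lib, want in [("mono:H3K9ac:1", 0.05), ("cocult:H3K9ac:1", 0.40)]:
            sel = reads["library"] == lib
            frac = (org[sel] == "symbiont").mean()
            assert sel.sum() > 50_000
            assert abs(frac - want) < 0.02

    def test_planted_lfc_shows_in_promoter_count_ratio(self):
        """A gene planted at LFC = 2 has ~4x the promoter reads in
        co-culture at high depth."""
        cfg = SimulationConfig(seed=9, n_genes=100, n_host_contigs=1,
                               host_contig_length=400_000, depth=200,
                               n_differential=15, differential_lfc=2.0,
                               frac_up=1.0, background_fraction=0.0)
        genome, genes, truth = simulate_reference(cfg)
        reads = simulate_reads(cfg, genome, truth)
        m = feature_counts(reads, genes, genome, mode="promoter")
        libs = m.libraries
        mono = m.counts[libs.index[libs["condition"] == "mono"]].sum(axis=1)
        co = m.counts[libs.index[libs["condition"] == "cocult"]].sum(axis=1)
        planted = truth.differential
        ratio = co[planted].sum() / mono[planted].sum()
        assert 3.3 <= ratio <= 4.8

    def test_zero_depth_rejected(self):
        cfg = SimulationConfig(seed=1, depth=0.0, **SMALL)
        genome, genes, truth = simulate_reference(cfg)
        with pytest.raises(ValueError):
            simulate_reads(cfg, genome, truth)

    def test_reads_lie_within_contigs(self):
        cfg = SimulationConfig(seed=10, **SMALL, depth=30)
        genome, genes, truth = simulate_reference(cfg)
        reads = simulate_reads(cfg, genome, truth)
        for contig, sub in reads.groupby("contig"):
            assert sub["start"].min() >= 0
            assert sub["end"].max() <= genome.length(contig)
            assert (sub["end"] - sub["start"] == cfg.fragment_length).all()


class TestCountLayer:
    def test_poisson_limit_variance_mean_ratio(self):
        cfg = SimulationConfig(seed=11, n_genes=500, host_contig_length=400_000,
                               dispersion=0.0, n_differential=0, replicates=10)
        m, _ = simulate_count_matrix(cfg)
        ratios = m.counts.var(axis=1) / m.counts.mean(axis=1)
        assert abs(ratios.mean() - 1.0) < 0.1

    def test_null_group_means_equal(self):
        cfg = SimulationConfig(seed=12, n_genes=1000, host_contig_length=600_000,
                               n_differential=0)
        m, _ = simulate_count_matrix(cfg)
        libs = m.libraries
        mono = m.counts[libs.index[libs["condition"] == "mono"]].to_numpy().mean()
        co = m.counts[libs.index[libs["condition"] == "cocult"]].to_numpy().mean()
        assert abs(np.log2(co / mono)) < 0.05

    def test_marginal_mean_matches_model(self):
        """Across many replicate libraries the empirical mean of each gene
        approaches depth * baseline."""
        cfg = SimulationConfig(seed=13, n_genes=50, n_host_contigs=1,
                               host_contig_length=200_000, replicates=400,
                               conditions=("mono",), n_differential=0, depth=80)
        m, truth = simulate_count_matrix(cfg)
        want = 80 * truth.table["baseline"]
        got = m.counts.mean(axis=1)
        rel = np.abs(got / want - 1.0)
        assert np.median(rel) < 0.05

    def test_read_and_count_layers_give_consistent_recovery(self):
        """The read-layer pipeline and the count-layer shortcut recover a
        matched planted signal at similar rates."""
        shared = dict(seed=14, n_genes=600, n_host_contigs=2,
                      host_contig_length=600_000, depth=60, n_differential=60,
                      differential_lfc=2.0, background_fraction=0.0)
        cfg = SimulationConfig(**shared)
        m, truth = simulate_count_matrix(cfg)
        sens_count = len(set(truth.differential)
                         & set(dcs_analysis(m, target="H3K9ac").differential)) / 60
        genome, genes, truth2 = simulate_reference(cfg)
        reads = simulate_reads(cfg, genome, truth2)
        m2 = feature_counts(reads, genes, genome)
        sens_read = len(set(truth2.differential)
                        & set(dcs_analysis(m2, target="H3K9ac").differential)) / 60
        assert sens_count >= 0.8 and sens_read >= 0.8
        assert abs(sens_count - sens_read) <= 0.15
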