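"""Synthetic dual-organism ChIP-seq data with planted ground truth.

Generates fused references (host + symbiont contigs), non-overlapping gene
annotations, and two layers of synthetic observations that share one
statistical model:

* a *read layer* — per-library aligned fragments whose host midpoints follow
  a mixture of uniform background and Gaussian enrichment bumps on the +1/+2
  nucleosome positions downstream of each TSS, with per-gene/replicate gamma
  factors so that gene-level counts are marginally negative-binomial, plus a
  condition-dependent fraction of reads placed uniformly on the symbiont
  contig (the co-culture contamination the fused reference exists to
  absorb);
* a *count layer* — per-gene NB counts drawn directly (variance
  mu + phi * mu^2), bypassing read placement for fast statistical tests.

Planted per-gene log2 fold-changes between mono- and co-culture define the
ground truth against which recovery, FDR control, and concordance are
measured.  Every layer is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genome import Contig, FusedGenome, Gene, HOST, SYMBIONT, READ_COLUMNS, library_key
from .quantify import CountMatrix, library_table

_NT = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study-condition parameters for the generator.

    Defaults mirror the experimental design being emulated at desk scale:
    eight host chromosomes plus one bacterial contig, three replicates per
    condition, NB dispersion 0.04 (a biological coefficient of variation of
    0.2, typical for genetically identical cultures), mean per-gene depth
    100, a narrow per-gene dynamic range (histone-mark coverage varies far
    less across genes than transcript abundance), enrichment
    concentrated on the +1/+2 nucleosomes (+75 / +225 bp downstream of the
    TSS, sd 40 bp), and symbiont read fractions of 5% in monoculture vs 40%
    in co-culture.
    """

    seed: int = 0
    # reference geometry
    n_host_contigs: int = 8
    host_contig_length: int = 500_000
    symbiont_contig_length: int = 500_000
    n_genes: int = 2000
    gene_length_log_mean: float = float(np.log(1500.0))
    gene_length_log_sd: float = 0.35
    min_gene_length: int = 300
    # annotation extras
    n_tf_flags: int = 100
    n_clusters: int = 6
    genes_per_cluster: int = 6
    # design
    conditions: tuple[str, ...] = ("mono", "cocult")
    targets: tuple[str, ...] = ("H3K9ac",)
    replicates: int = 3
    # count model
    baseline_log_sd: float = 0.5
    dispersion: float = 0.04
    depth: float = 100.0            # mean reads per gene per library
    n_differential: int = 100
    differential_lfc: float = 2.0
    frac_up: float = 0.67           # fraction of planted changes that are increases
    differential_targets: tuple[str, ...] = ("H3K9ac", "H3K14ac")
    # read-layer geometry
    bump_offsets: tuple[int, ...] = (75, 225)
    bump_sd: float = 40.0
    enrichment_weight: float = 0.8  # fraction of a gene's reads on the bumps
    background_fraction: float = 0.3  # fraction of host reads uniform genome-wide
    symbiont_fraction: dict = field(default_factory=lambda: {"mono": 0.05, "cocult": 0.40})
    fragment_length: int = 200

    def libraries(self) -> list[str]:
        return [library_key(c, t, r)
                for c in self.conditions for t in self.targets
                for r in range(1, self.replicates + 1)]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for k in ("conditions", "targets", "differential_targets", "bump_offsets"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class TruthTable:
    """Planted per-gene ground truth: baseline abundance, LFC, flags, geometry."""

    table: pd.DataFrame
    config: SimulationConfig

    def lfc_for(self, target: str) -> pd.Series:
        if target in self.config.differential_targets:
            return self.table["lfc"]
        return pd.Series(0.0, index=self.table.index)

    @property
    def differential(self) -> pd.Index:
        return self.table.index[self.table["differential"]]

    def to_tsv(self, path) -> None:
        self.table.rename_axis("gene").to_csv(path, sep="\t")


def _rng(config: SimulationConfig, layer: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), layer])


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------

def simulate_reference(config: SimulationConfig, with_sequences: bool = False):
    """Fused genome, gene models, truth table (and optionally sequences).

    Genes are placed without overlap by partitioning each contig's free
    space into random gaps; strands are independent fair coin flips.
    Returns ``(genome, genes, truth)`` or ``(genome, genes, truth, seqs)``.
    """
    rng = _rng(config, 0)
    host = [Contig(f"chr{i + 1}", config.host_contig_length, HOST)
            for i in range(config.n_host_contigs)]
    sym = [Contig("symbiont", config.symbiont_contig_length, SYMBIONT)]
    genome = FusedGenome(host + sym)

    # distribute genes over host contigs as evenly as possible
    quota = np.full(config.n_host_contigs, config.n_genes // config.n_host_contigs)
    quota[: config.n_genes % config.n_host_contigs] += 1

    genes: list[Gene] = []
    gidx = 0
    for contig, n in zip(host, quota):
        if n == 0:
            continue
        lengths = np.maximum(
            rng.lognormal(config.gene_length_log_mean, config.gene_length_log_sd, n),
            config.min_gene_length,
        ).astype(np.int64)
        free = contig.length - int(lengths.sum())
        if free < 0:
            raise ValueError(
                f"genes do not fit contig {contig.name}: need {lengths.sum()} bp "
                f"of {contig.length}")
        gaps = rng.multinomial(free, np.full(n + 1, 1.0 / (n + 1)))
        pos = 0
        for k in range(n):
            pos += int(gaps[k])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(f"gene_{gidx:05d}", contig.name, pos,
                              pos + int(lengths[k]), strand))
            pos += int(lengths[k])
            gidx += 1

    n_genes = len(genes)
    ids = [g.id for g in genes]

    tf = np.zeros(n_genes, dtype=bool)
    if config.n_tf_flags:
        tf[rng.choice(n_genes, size=min(config.n_tf_flags, n_genes), replace=False)] = True

    cluster = np.array([""] * n_genes, dtype=object)
    if config.n_clusters and config.genes_per_cluster and n_genes:
        span = config.genes_per_cluster
        starts = rng.choice(max(n_genes - span, 1), size=config.n_clusters, replace=False) \
            if max(n_genes - span, 1) >= config.n_clusters else []
        for ci, s in enumerate(sorted(starts)):
            cluster[s: s + span] = f"cluster_{ci + 1}"

    baseline = rng.lognormal(0.0, config.baseline_log_sd, n_genes)
    if n_genes:
        baseline /= baseline.mean()

    diff = np.zeros(n_genes, dtype=bool)
    lfc = np.zeros(n_genes)
    if config.n_differential:
        chosen = rng.choice(n_genes, size=min(config.n_differential, n_genes), replace=False)
        diff[chosen] = True
        up = rng.random(chosen.size) < config.frac_up
        lfc[chosen] = np.where(up, config.differential_lfc, -config.differential_lfc)

    table = pd.DataFrame({
        "contig": [g.contig for g in genes],
        "start": [g.start for g in genes],
        "end": [g.end for g in genes],
        "strand": [g.strand for g in genes],
        "length": [g.length for g in genes],
        "baseline": baseline,
        "tf_flag": tf,
        "cluster_id": cluster,
        "differential": diff,
        "lfc": lfc,
        "bump_offsets": [",".join(map(str, config.bump_offsets))] * n_genes,
        "bump_sd": config.bump_sd,
    }, index=pd.Index(ids, name="gene"))

    genes = [Gene(g.id, g.contig, g.start, g.end, g.strand,
                  is_tf=bool(tf[i]), cluster_id=(cluster[i] or None))
             for i, g in enumerate(genes)]
    truth = TruthTable(table, config)
    if not with_sequences:
        return genome, genes, truth
    seqs = {c.name: "".join(rng.choice(_NT, size=c.length)) for c in genome.contigs}
    return genome, genes, truth, seqs


# ---------------------------------------------------------------------------
# Read layer
# ---------------------------------------------------------------------------

def simulate_reads(config: SimulationConfig, genome: FusedGenome,
                   truth: TruthTable) -> pd.DataFrame:
    """Aligned fragments per library as a read frame (BED-ready).

    Host fragment midpoints mix uniform within-gene background with Gaussian
    bumps at the configured +1/+2 nucleosome offsets downstream of each TSS;
    bump intensity scales with the gene's condition-dependent mean and a
    per-gene/replicate gamma factor (so gene counts are marginally NB).  A
    genome-wide uniform host background and condition-dependent uniform
    symbiont reads complete each library.
    """
    if config.depth <= 0:
        raise ValueError("depth must be positive")
    rng = _rng(config, 1)
    t = truth.table
    tss = np.where(t["strand"] == "+", t["start"], t["end"]).astype(np.int64)
    direction = np.where(t["strand"] == "+", 1, -1)
    gene_start = t["start"].to_numpy()
    gene_len = t["length"].to_numpy()
    contigs = t["contig"].to_numpy()
    baseline = t["baseline"].to_numpy()
    clen = {c.name: c.length for c in genome.contigs}
    sym_contigs = genome.symbiont_contigs()
    d = config.fragment_length
    offsets = np.asarray(config.bump_offsets, dtype=float)

    cocult_cond = config.conditions[1] if len(config.conditions) > 1 else None
    frames = []
    for cond in config.conditions:
        contam = float(config.symbiont_fraction.get(cond, 0.0))
        for target in config.targets:
            lfc = truth.lfc_for(target).to_numpy()
            mu = config.depth * baseline
            if cond == cocult_cond:
                mu = mu * 2.0 ** lfc
            for rep in range(1, config.replicates + 1):
                lib = library_key(cond, target, rep)
                if config.dispersion > 0:
                    gamma = rng.gamma(1.0 / config.dispersion, config.dispersion, len(t))
                else:
                    gamma = np.ones(len(t))
                lam = mu * gamma
                n_g = rng.poisson(lam)
                total_gene = int(n_g.sum())

                # gene-attached midpoints
                gidx = np.repeat(np.arange(len(t)), n_g)
                on_bump = rng.random(total_gene) < config.enrichment_weight
                mids = np.empty(total_gene, dtype=np.int64)
                off = offsets[rng.integers(0, offsets.size, total_gene)]
                bump_pos = (tss[gidx] + direction[gidx]
                            * (off + rng.normal(0.0, config.bump_sd, total_gene)))
                unif_pos = gene_start[gidx] + rng.random(total_gene) * gene_len[gidx]
                mids[on_bump] = np.rint(bump_pos[on_bump]).astype(np.int64)
                mids[~on_bump] = unif_pos[~on_bump].astype(np.int64)
                read_contigs = contigs[gidx]

                # genome-wide uniform host background
                expect_host = total_gene / max(1.0 - config.background_fraction, 1e-9)
                n_bg = rng.poisson(expect_host * config.background_fraction)
                bg_fused = rng.integers(0, genome.host_length, n_bg)
                bg_contig = np.empty(n_bg, dtype=object)
                bg_mid = np.empty(n_bg, dtype=np.int64)
                off0 = 0
                for c in genome.host_contigs():
                    sel = (bg_fused >= off0) & (bg_fused < off0 + c.length)
                    bg_contig[sel] = c.name
                    bg_mid[sel] = bg_fused[sel] - off0
                    off0 += c.length

                # symbiont contamination at the condition's fraction
                n_host = total_gene + n_bg
                n_sym = rng.poisson(n_host * contam / max(1.0 - contam, 1e-9)) \
                    if contam > 0 else 0
                sym_c = sym_contigs[0].name if sym_contigs else None
                sym_mid = (rng.integers(0, clen[sym_c], n_sym)
                           if n_sym and sym_c else np.empty(0, dtype=np.int64))

                all_contig = np.concatenate([read_contigs, bg_contig,
                                             np.full(len(sym_mid), sym_c, dtype=object)])
                all_mid = np.concatenate([mids, bg_mid, sym_mid])
                lens = np.array([clen[c] for c in all_contig])
                start = np.clip(all_mid - d // 2, 0, None)
                end = np.minimum(start + d, lens)
                start = np.maximum(end - d, 0)
                strand = np.where(rng.random(len(all_mid)) < 0.5, "+", "-")
                frames.append(pd.DataFrame({
                    "contig": all_contig, "start": start.astype(np.int64),
                    "end": end.astype(np.int64), "strand": strand, "library": lib,
                }))
    out = pd.concat(frames, ignore_index=True)
    return out[READ_COLUMNS]


# ---------------------------------------------------------------------------
# Count layer
# ---------------------------------------------------------------------------

def simulate_count_matrix(config: SimulationConfig,
                          truth: TruthTable | None = None) -> tuple[CountMatrix, TruthTable]:
    """Per-gene NB counts drawn directly from the shared model.

    counts_gj ~ NB(mean = depth * q_g * 2^(lfc_g * [co-culture]), dispersion
    phi); effective sizes are the per-library host totals (column sums).
    """
    if truth is None:
        _, _, truth = simulate_reference(config)
    rng = _rng(config, 2)
    t = truth.table
    libs = config.libraries()
    meta = library_table(libs)
    counts = np.zeros((len(t), len(libs)), dtype=np.int64)
    cocult_cond = config.conditions[1] if len(config.conditions) > 1 else None
    for j, lib in enumerate(libs):
        cond, target, _ = meta.loc[lib]
        lfc = truth.lfc_for(target).to_numpy()
        mu = config.depth * t["baseline"].to_numpy()
        if cond == cocult_cond:
            mu = mu * 2.0 ** lfc
        if config.dispersion > 0:
            p = 1.0 / (1.0 + config.dispersion * mu)
            counts[:, j] = rng.negative_binomial(1.0 / config.dispersion, p)
        else:
            counts[:, j] = rng.poisson(mu)
    df = pd.DataFrame(counts, index=t.index, columns=libs)
    sizes = df.sum(axis=0).astype(float)
    matrix = CountMatrix(df, sizes, feature_lengths=t["length"].astype(float))
    return matrix, truth


def simulate_expression_lfc(truth: TruthTable, noise_sd: float = 0.5,
                            seed: int | None = None) -> pd.Series:
    """Expression LFCs that track chromatin LFCs only for truly changed genes.

    Differential genes get their planted chromatin LFC plus Gaussian noise;
    unchanged genes get independent noise.  Correlating this against
    chromatin LFCs therefore yields a stronger r on the differential subset
    than over all genes.
    """
    cfg = truth.config
    rng = np.random.default_rng([cfg.seed if seed is None else int(seed), 3])
    t = truth.table
    noise = rng.normal(0.0, noise_sd, len(t))
    expr = np.where(t["differential"], t["lfc"] + noise, noise)
    return pd.Series(expr, index=t.index, name="expression_lfc")
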