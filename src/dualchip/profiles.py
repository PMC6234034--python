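"""Meta-profiles: average fragment coverage around TSS / TTS anchors.

Each gene contributes its coverage in anchor-centered coordinates, with
minus-strand genes flipped so downstream of the anchor is always positive.
Genes are averaged with equal weight (per-gene, not per-read) so a handful
of highly covered genes cannot dominate the profile; positions a gene cannot
define (beyond its contig's ends) are excluded from that gene's average
(ragged averaging with a per-position n).  Values are reads-per-million of
the host-only effective library size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import HOST, FusedGenome, Gene, as_read_frame
from .quantify import effective_library_sizes


@dataclass
class MetaProfile:
    anchor: str            # "TSS" or "TTS"
    flank: int             # bp on each side of the anchor
    bin_size: int
    values: np.ndarray     # mean RPM per position bin, downstream positive
    n_genes: int
    n_per_bin: np.ndarray  # genes contributing to each bin

    @property
    def positions(self) -> np.ndarray:
        """Bin-center offsets from the anchor (bp, downstream positive)."""
        edges = np.arange(-self.flank, self.flank + 1, self.bin_size)
        return (edges[:-1] + edges[1:]) / 2

    @property
    def argmax_position(self) -> float:
        return float(self.positions[int(np.argmax(self.values))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, "mean_rpm": self.values,
                             "n_genes": self.n_per_bin})

    def plot(self, ax=None, **kwargs):
        """Line plot of the profile (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.positions, self.values, **kwargs)
        ax.axvline(0, color="grey", lw=0.8, ls="--")
        ax.set_xlabel(f"distance from {self.anchor} (bp)")
        ax.set_ylabel("mean coverage (RPM)")
        return ax


def _contig_depth(sub: pd.DataFrame, length: int) -> np.ndarray:
    d = np.zeros(length + 1)
    s = np.clip(sub["start"].to_numpy(), 0, length)
    e = np.clip(sub["end"].to_numpy(), 0, length)
    np.add.at(d, s, 1.0)
    np.add.at(d, e, -1.0)
    return np.cumsum(d)[:-1]


def meta_profile(reads, library: str, genes: list[Gene], genome: FusedGenome,
                 anchor: str = "TSS", flank: int = 1500, bin_size: int = 25) -> MetaProfile:
    """Equal-weight average coverage profile around TSS or TTS for one library."""
    if anchor not in ("TSS", "TTS"):
        raise ValueError("anchor must be 'TSS' or 'TTS'")
    if not genes:
        raise ValueError("empty gene list")
    if flank % bin_size:
        raise ValueError("flank must be a multiple of bin_size")
    df = as_read_frame(reads)
    sizes = effective_library_sizes(df, genome)
    sub = df.loc[(df["library"] == library).to_numpy()]
    host_names = {c.name for c in genome.host_contigs()}
    sub = sub.loc[sub["contig"].isin(host_names)]

    n_bins = 2 * flank // bin_size
    acc = np.zeros(n_bins)
    n_per_bin = np.zeros(n_bins)

    depth: dict[str, np.ndarray] = {}
    for contig in sorted({g.contig for g in genes}):
        csub = sub.loc[(sub["contig"] == contig).to_numpy()]
        depth[contig] = _contig_depth(csub, genome.length(contig))

    for g in genes:
        a = g.tss if anchor == "TSS" else g.tts
        d = depth[g.contig]
        lo, hi = a - flank, a + flank
        window = np.zeros(2 * flank)
        defined = np.zeros(2 * flank, dtype=bool)
        s = max(lo, 0)
        e = min(hi, len(d))
        if e > s:
            window[s - lo: e - lo] = d[s:e]
            defined[s - lo: e - lo] = True
        if g.strand == "-":
            window = window[::-1]
            defined = defined[::-1]
        wb = window.reshape(n_bins, bin_size)
        db = defined.reshape(n_bins, bin_size)
        nb = db.sum(axis=1)
        ok = nb > 0
        acc[ok] += wb.sum(axis=1)[ok] / nb[ok]
        n_per_bin += ok

    per_million = sizes[library] / 1e6
    values = np.divide(acc, n_per_bin, out=np.zeros_like(acc), where=n_per_bin > 0)
    return MetaProfile(anchor, flank, bin_size, values / per_million,
                       len(genes), n_per_bin)


def stratified_profiles(reads, library: str, genes: list[Gene], genome: FusedGenome,
                        expression: dict[str, float], quantiles: int = 4,
                        anchor: str = "TSS", flank: int = 1500,
                        bin_size: int = 25) -> list[tuple[pd.Interval, MetaProfile]]:
    """One meta-profile per expression-quantile stratum (lowest first)."""
    expr = pd.Series({g.id: expression[g.id] for g in genes if g.id in expression})
    if expr.empty:
        raise ValueError("no gene has an expression value")
    n_distinct = expr.nunique()
    q = quantiles
    if n_distinct < quantiles:
        q = max(n_distinct, 1)
        warnings.warn(f"only {n_distinct} distinct expression values; using {q} strata")
    strata = pd.qcut(expr, q, duplicates="drop")
    by_id = {g.id: g for g in genes}
    out = []
    for interval in strata.cat.categories:
        ids = strata.index[strata == interval]
        stratum_genes = [by_id[i] for i in ids]
        out.append((interval, meta_profile(reads, library, stratum_genes, genome,
                                           anchor, flank, bin_size)))
    return out
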