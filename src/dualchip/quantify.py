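"""Read quantification: bins, features, coverage tracks, effective library sizes.

The effective library size of a library is the number of *host*-assigned
reads: symbiont-derived reads vary with the co-culture condition and would
otherwise distort between-library scaling, so they never enter normalization
(they are still counted in symbiont bins for display).

Bins use single assignment by fragment midpoint so per-library bin counts
are conserved; gene/promoter features use any-overlap (>= 1 bp)
multi-assignment, the convention for counting reads that overlap genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import (
    HOST,
    SYMBIONT,
    FusedGenome,
    Gene,
    GenomicInterval,
    as_read_frame,
    classify_reads,
    parse_library_key,
    promoter_windows,
)


@dataclass
class CountMatrix:
    """Features x libraries integer counts with library metadata.

    ``counts``: DataFrame indexed by feature id, one column per library key.
    ``libraries``: DataFrame indexed by library key with columns
    condition / target / replicate.  ``effective_sizes``: per-library
    normalization denominators (host-assigned read counts).
    ``feature_lengths``: optional per-feature lengths in bp (for RPKM).
    """

    counts: pd.DataFrame
    effective_sizes: pd.Series
    feature_lengths: pd.Series | None = None
    libraries: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.libraries is None:
            self.libraries = library_table(self.counts.columns)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        sizes = self.effective_sizes.reindex(self.counts.columns)
        if sizes.isna().any() or (sizes <= 0).any():
            bad = sizes.index[sizes.isna() | (sizes <= 0)].tolist()
            raise ValueError(f"effective sizes must be positive for all libraries: {bad}")
        self.effective_sizes = sizes.astype(float)
        if not self.counts.index.is_unique:
            raise ValueError("feature ids must be unique")

    def select_target(self, target: str, conditions: Sequence[str] | None = None) -> "CountMatrix":
        """Sub-matrix for one antibody target (optionally restricted to conditions)."""
        keep = self.libraries.index[self.libraries["target"] == target]
        if conditions is not None:
            keep = [k for k in keep if self.libraries.loc[k, "condition"] in conditions]
        keep = list(keep)
        if not keep:
            raise ValueError(f"no libraries for target {target!r}")
        return CountMatrix(
            self.counts[keep], self.effective_sizes[keep], self.feature_lengths,
            self.libraries.loc[keep],
        )

    def to_tsv(self, path) -> None:
        self.counts.rename_axis("feature").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, effective_sizes: Mapping[str, float],
                 feature_lengths: pd.Series | None = None) -> "CountMatrix":
        counts = pd.read_csv(path, sep="\t", index_col="feature")
        return cls(counts, pd.Series(effective_sizes), feature_lengths)


def library_table(keys: Iterable[str]) -> pd.DataFrame:
    rows = {k: parse_library_key(k) for k in keys}
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=["condition", "target", "replicate"])


@dataclass
class BinGrid:
    """Non-overlapping fixed-size bins tiling every contig from 0 (last bin truncated)."""

    bin_size: int
    genome: FusedGenome

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")

    def n_bins(self, contig: str) -> int:
        return -(-self.genome.length(contig) // self.bin_size)

    def bin_ids(self, contig: str) -> list[str]:
        L = self.genome.length(contig)
        return [
            f"{contig}:{i * self.bin_size}-{min((i + 1) * self.bin_size, L)}"
            for i in range(self.n_bins(contig))
        ]

    def intervals(self) -> list[GenomicInterval]:
        out = []
        for c in self.genome.contigs:
            for i in range(self.n_bins(c.name)):
                out.append(GenomicInterval(
                    c.name, i * self.bin_size, min((i + 1) * self.bin_size, c.length)))
        return out


def _midpoints(df: pd.DataFrame) -> np.ndarray:
    return (df["start"].to_numpy() + df["end"].to_numpy()) // 2


def effective_library_sizes(reads, genome: FusedGenome) -> pd.Series:
    """Host-assigned read count per library; the normalization denominator.

    Symbiont and ambiguous reads are excluded so that condition-dependent
    bacterial read fractions cannot masquerade as global chromatin changes.
    """
    df = as_read_frame(reads)
    org = classify_reads(df, genome)
    host = df.loc[org.to_numpy() == HOST]
    sizes = host.groupby("library").size().astype(float)
    empty = set(df["library"].unique()) - set(sizes.index)
    if empty:
        raise ValueError(f"libraries with zero host reads: {sorted(empty)}")
    return sizes


def total_library_sizes(reads) -> pd.Series:
    """Total read count per library, ignoring organism.

    Deliberately *wrong* for dual-organism data: contamination shifts it with
    condition.  Provided so the failure mode can be demonstrated and tested.
    """
    df = as_read_frame(reads)
    return df.groupby("library").size().astype(float)


def bin_counts(reads, grid: BinGrid, genome: FusedGenome) -> CountMatrix:
    """Genome-wide per-bin counts; each read goes to the bin holding its midpoint.

    Symbiont-contig bins are included (display) but effective sizes come from
    host reads only.
    """
    df = as_read_frame(reads)
    sizes = effective_library_sizes(df, genome)
    libs = sorted(df["library"].unique())
    features: list[str] = []
    for c in genome.contigs:
        features.extend(grid.bin_ids(c.name))
    mat = np.zeros((len(features), len(libs)), dtype=np.int64)
    row0 = {}
    r = 0
    for c in genome.contigs:
        row0[c.name] = r
        r += grid.n_bins(c.name)
    mids = _midpoints(df)
    for j, lib in enumerate(libs):
        sel = (df["library"] == lib).to_numpy()
        sub = df.loc[sel]
        m = mids[sel]
        for contig, idx in sub.groupby("contig").indices.items():
            if contig == "fused":
                continue
            b = m[idx] // grid.bin_size
            counts = np.bincount(b, minlength=grid.n_bins(contig))
            mat[row0[contig]: row0[contig] + grid.n_bins(contig), j] += counts
    lengths = pd.Series(
        {f: int(f.rsplit(":", 1)[1].split("-")[1]) - int(f.rsplit(":", 1)[1].split("-")[0])
         for f in features}
    )
    return CountMatrix(pd.DataFrame(mat, index=features, columns=libs),
                       sizes, feature_lengths=lengths)


def _overlap_counts_contig(starts: np.ndarray, ends: np.ndarray,
                           f_starts: np.ndarray, f_ends: np.ndarray) -> np.ndarray:
    """Count reads overlapping each feature by >= 1 bp (half-open intervals).

    A read [s, e) overlaps feature [fs, fe) iff s < fe and e > fs.  With
    sorted read starts and ends: (# starts < fe) - (# ends <= fs).
    """
    s_sorted = np.sort(starts)
    e_sorted = np.sort(ends)
    a = np.searchsorted(s_sorted, f_ends, side="left")
    b = np.searchsorted(e_sorted, f_starts, side="right")
    return a - b


def feature_counts(
    reads,
    features: Sequence[Gene] | Mapping[str, GenomicInterval],
    genome: FusedGenome,
    mode: str = "gene_body",
    promoter_upstream: int = 1000,
    promoter_downstream: int = 500,
) -> CountMatrix:
    """Per-feature, per-library read counts over gene bodies or promoter windows.

    A read contributes to every feature it overlaps by >= 1 bp, so a read in
    a bidirectional promoter counts for both flanking genes.  Reads
    overlapping no feature still count in the effective library sizes.
    """
    if mode not in ("gene_body", "promoter", "interval"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(features, Mapping):
        ivals = dict(features)
    else:
        genes = list(features)
        if mode == "promoter":
            ivals = promoter_windows(genes, genome, promoter_upstream, promoter_downstream)
        else:
            ivals = {g.id: g.interval() for g in genes}
    if not ivals:
        raise ValueError("empty feature list")
    for fid, iv in ivals.items():
        if genome.organism_of(iv.contig) != HOST:
            raise ValueError(f"feature {fid} not on a host contig")

    df = as_read_frame(reads)
    sizes = effective_library_sizes(df, genome)
    libs = sorted(df["library"].unique())
    fids = list(ivals)
    mat = np.zeros((len(fids), len(libs)), dtype=np.int64)

    by_contig: dict[str, tuple[list[int], np.ndarray, np.ndarray]] = {}
    for row, fid in enumerate(fids):
        iv = ivals[fid]
        by_contig.setdefault(iv.contig, ([], [], []))
        by_contig[iv.contig][0].append(row)
        by_contig[iv.contig][1].append(iv.start)
        by_contig[iv.contig][2].append(iv.end)

    for j, lib in enumerate(libs):
        sub = df.loc[(df["library"] == lib).to_numpy()]
        for contig, (rows, fs, fe) in by_contig.items():
            sel = sub.loc[(sub["contig"] == contig).to_numpy()]
            if not len(sel):
                continue
            counts = _overlap_counts_contig(
                sel["start"].to_numpy(), sel["end"].to_numpy(),
                np.asarray(fs), np.asarray(fe),
            )
            mat[np.asarray(rows), j] = counts
    lengths = pd.Series({fid: len(ivals[fid]) for fid in fids}, dtype=float)
    return CountMatrix(pd.DataFrame(mat, index=fids, columns=libs), sizes,
                       feature_lengths=lengths)


def rpkm(matrix: CountMatrix, lengths: pd.Series | None = None) -> pd.DataFrame:
    """Reads per kilobase per million host-assigned reads."""
    if lengths is None:
        lengths = matrix.feature_lengths
    if lengths is None:
        raise ValueError("feature lengths required for RPKM")
    lengths = lengths.reindex(matrix.counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("all feature lengths must be positive")
    per_kb = matrix.counts.div(lengths / 1e3, axis=0)
    return per_kb.div(matrix.effective_sizes / 1e6, axis=1)


def coverage_track(reads, library: str, bin_size: int, genome: FusedGenome) -> dict[str, np.ndarray]:
    """Per-contig, per-bin reads-per-million track for one library.

    Values use the library's host-only effective size, so symbiont
    contamination does not rescale host coverage.
    """
    df = as_read_frame(reads)
    if library not in set(df["library"]):
        raise ValueError(f"library {library!r} not present")
    sizes = effective_library_sizes(df, genome)
    sub = df.loc[(df["library"] == library).to_numpy()]
    mids = _midpoints(sub)
    per_million = sizes[library] / 1e6
    track: dict[str, np.ndarray] = {}
    for c in genome.contigs:
        n = -(-c.length // bin_size)
        sel = (sub["contig"] == c.name).to_numpy()
        counts = np.bincount(mids[sel] // bin_size, minlength=n) if sel.any() else np.zeros(n)
        track[c.name] = counts / per_million
    return track
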