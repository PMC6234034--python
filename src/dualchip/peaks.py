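"""Enrichment peak calling with a local Poisson background, peak quantification,
peak-to-gene assignment, and the DCS-vs-peak concordance statistic.

The caller slides a fixed window along each host contig, models the local
background as Poisson with rate lambda_local = window * max(genome rate,
5 kb rate, 10 kb rate) around the window (the max guards against calling
peaks inside locally enriched domains), keeps windows whose upper Poisson
tail falls below a cut-off, and merges nearby significant windows.  It is a
deliberately simple, fully deterministic stand-in for a model-based caller:
its role here is the *second route* to differential genes, cross-validating
the count-based DCS calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .genome import HOST, FusedGenome, Gene, GenomicInterval, as_read_frame, promoter_window
from .quantify import CountMatrix, effective_library_sizes, feature_counts


@dataclass
class Peak:
    interval: GenomicInterval
    summit: int
    enrichment: float
    pvalue: float
    signal_rpm: dict[str, float] = field(default_factory=dict)

    @property
    def id(self) -> str:
        iv = self.interval
        return f"{iv.contig}:{iv.start}-{iv.end}"


def _window_counts(mids: np.ndarray, starts: np.ndarray, width: int) -> np.ndarray:
    return (np.searchsorted(mids, starts + width, side="left")
            - np.searchsorted(mids, starts, side="left"))


def call_peaks(reads, library: str, genome: FusedGenome,
               window: int = 200, step: int = 50, p_cut: float = 1e-5,
               merge_gap: int = 100, local_spans: tuple[int, int] = (5000, 10000)) -> list[Peak]:
    """Sliding-window Poisson peak calls on host contigs for one library."""
    df = as_read_frame(reads)
    sub = df.loc[(df["library"] == library).to_numpy()]
    if not len(sub):
        raise ValueError(f"library {library!r} has no reads")
    host_names = {c.name for c in genome.host_contigs()}
    sub = sub.loc[sub["contig"].isin(host_names)]
    total = len(sub)
    genome_rate = total / genome.host_length

    peaks: list[Peak] = []
    for contig in genome.host_contigs():
        csub = sub.loc[(sub["contig"] == contig.name).to_numpy()]
        if not len(csub):
            continue
        mids = np.sort((csub["start"].to_numpy() + csub["end"].to_numpy()) // 2)
        starts = np.arange(0, max(contig.length - window, 0) + 1, step)
        obs = _window_counts(mids, starts, window)
        centers = starts + window // 2
        rates = [np.full(starts.size, genome_rate)]
        for span in local_spans:
            half = span // 2
            lo = np.clip(centers - half, 0, contig.length)
            hi = np.clip(centers + half, 0, contig.length)
            c = (np.searchsorted(mids, hi, side="left")
                 - np.searchsorted(mids, lo, side="left"))
            rates.append(c / np.maximum(hi - lo, 1))
        lam = window * np.max(rates, axis=0)
        pvals = poisson.sf(obs - 1, lam)
        sig = np.flatnonzero(pvals <= p_cut)
        if not sig.size:
            continue

        # merge significant windows whose gaps are <= merge_gap
        runs: list[list[int]] = [[sig[0]]]
        for i in sig[1:]:
            prev = runs[-1][-1]
            if starts[i] - (starts[prev] + window) <= merge_gap:
                runs[-1].append(i)
            else:
                runs.append([i])
        for run in runs:
            s = int(starts[run[0]])
            e = int(min(starts[run[-1]] + window, contig.length))
            in_peak = mids[(mids >= s) & (mids < e)]
            # summit: fragment-coverage argmax within the peak
            cov = np.zeros(e - s + 1)
            ps = np.clip(csub["start"].to_numpy(), s, e) - s
            pe = np.clip(csub["end"].to_numpy(), s, e) - s
            keep = pe > ps
            np.add.at(cov, ps[keep], 1)
            np.add.at(cov, pe[keep], -1)
            cov = np.cumsum(cov)[:-1]
            summit = s + int(np.argmax(cov))
            lam_peak = float(np.max(lam[run]) / window) * (e - s)
            enrich = len(in_peak) / max(lam_peak, 1e-12)
            pk = Peak(GenomicInterval(contig.name, s, e), summit, enrich,
                      float(np.min(pvals[run])))
            peaks.append(pk)
    return peaks


def quantify_peaks(peaks: list[Peak], reads, genome: FusedGenome) -> CountMatrix:
    """Per-peak, per-library counts with reads-per-million signal attached.

    The resulting matrix uses host-only effective sizes and is a valid input
    to :func:`dualchip.dcs.dcs_analysis`.
    """
    ivals = {pk.id: pk.interval for pk in peaks}
    matrix = feature_counts(reads, ivals, genome, mode="interval")
    rpm = matrix.counts.div(matrix.effective_sizes / 1e6, axis=1)
    for pk in peaks:
        pk.signal_rpm = rpm.loc[pk.id].to_dict()
    return matrix


def assign_peaks_to_genes(peaks: list[Peak], genes: list[Gene],
                          genome: FusedGenome | None = None,
                          promoter_upstream: int = 1000,
                          promoter_downstream: int = 500) -> tuple[dict[str, list[Peak]], list[Peak]]:
    """Map each peak to every gene whose body or promoter window it overlaps.

    A peak in a bidirectional promoter is assigned to both flanking genes.
    Returns (gene id -> peaks, unassigned peaks).
    """
    assigned: dict[str, list[Peak]] = {}
    orphan: list[Peak] = []
    windows = {}
    for g in genes:
        clen = genome.length(g.contig) if genome is not None else None
        windows[g.id] = promoter_window(g, promoter_upstream, promoter_downstream,
                                        contig_length=clen)
    for pk in peaks:
        hit = False
        for g in genes:
            if pk.interval.overlaps(g.interval()) or pk.interval.overlaps(windows[g.id]):
                assigned.setdefault(g.id, []).append(pk)
                hit = True
        if not hit:
            orphan.append(pk)
    return assigned, orphan


@dataclass
class ConcordanceReport:
    """Agreement between DCS-derived and peak-derived differential gene sets."""

    n_dcs: int
    n_peak: int
    n_intersection: int
    frac_dcs_in_peak: float
    frac_peak_in_dcs: float
    similarity: float  # percentage, mean of the two directional fractions
    jaccard: float
    empty_input: bool = False

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def concordance(dcs_genes: set, peak_genes: set) -> ConcordanceReport:
    """Similarity percentage between the two differential gene sets.

    Defined as 100 * mean(|A∩B|/|A|, |A∩B|/|B|); both directional fractions
    and the Jaccard index are reported alongside.  An empty input set gives
    similarity 0 with a flag.
    """
    dcs_genes, peak_genes = set(dcs_genes), set(peak_genes)
    if not dcs_genes or not peak_genes:
        return ConcordanceReport(len(dcs_genes), len(peak_genes), 0, 0.0, 0.0, 0.0, 0.0,
                                 empty_input=True)
    inter = dcs_genes & peak_genes
    f1 = len(inter) / len(dcs_genes)
    f2 = len(inter) / len(peak_genes)
    union = dcs_genes | peak_genes
    return ConcordanceReport(
        len(dcs_genes), len(peak_genes), len(inter), f1, f2,
        100.0 * 0.5 * (f1 + f2), len(inter) / len(union),
    )


def write_peaks_bed(path, peaks: list[Peak]) -> None:
    """BED6+ peak export: score is -10*log10(p), extra columns enrichment and RPM."""
    with open(path, "w") as fh:
        for i, pk in enumerate(peaks):
            score = int(min(1000, round(-10 * np.log10(max(pk.pvalue, 1e-300)))))
            rpm = ",".join(f"{k}={v:.4f}" for k, v in sorted(pk.signal_rpm.items()))
            fh.write(f"{pk.interval.contig}\t{pk.interval.start}\t{pk.interval.end}\t"
                     f"peak_{i}\t{score}\t.\t{pk.enrichment:.4f}\t{rpm}\n")
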