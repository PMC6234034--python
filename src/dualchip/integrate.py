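"""Chromatin–expression integration.

Joins per-gene chromatin LFCs (from DCS analysis) with expression LFCs from
any platform, computes Pearson correlations over all genes and over the
differentially acetylated subset, extracts transcription-factor candidates
from the differential set, summarizes secondary-metabolism gene clusters,
and provides TPM normalization for RNA-seq count tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .dcs import DCSResult


@dataclass
class LfcJoin:
    """Per-gene chromatin and expression LFCs; only genes in both tables."""

    table: pd.DataFrame          # columns: chromatin_lfc, expression_lfc, dcs_class
    n_chromatin_only: int
    n_expression_only: int


def join_lfc(dcs: DCSResult, expression_lfc: pd.Series) -> LfcJoin:
    """Inner-join chromatin LFCs with an expression LFC table (gene -> LFC)."""
    expr = pd.Series(expression_lfc, dtype=float).dropna()
    common = dcs.table.index.intersection(expr.index)
    table = pd.DataFrame({
        "chromatin_lfc": dcs.table.loc[common, "lfc"],
        "expression_lfc": expr.loc[common],
        "dcs_class": dcs.table.loc[common, "dcs_class"],
    })
    return LfcJoin(table, len(dcs.table.index.difference(expr.index)),
                   len(expr.index.difference(dcs.table.index)))


def correlate_lfc(join: LfcJoin, subset: str = "all") -> tuple[float, int]:
    """Pearson r between chromatin and expression LFCs; returns (r, n).

    ``subset="differential"`` restricts to genes classified higher/lower by
    DCS, the comparison behind the stronger correlation seen when only
    differentially acetylated genes are considered.
    """
    t = join.table
    if subset == "differential":
        t = t.loc[t["dcs_class"] != "unchanged"]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    t = t.loc[np.isfinite(t["chromatin_lfc"]) & np.isfinite(t["expression_lfc"])]
    if len(t) < 3:
        raise ValueError(f"subset {subset!r}: need >= 3 paired genes, have {len(t)}")
    x = t["chromatin_lfc"].to_numpy()
    y = t["expression_lfc"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance in one LFC vector; correlation undefined")
        return float("nan"), len(t)
    r, _ = pearsonr(x, y)
    return float(r), len(t)


@dataclass
class CandidateReport:
    """Transcription-factor candidates among differentially acetylated genes."""

    n_differential: int
    candidates: pd.DataFrame     # index: gene, columns lfc, fdr, dcs_class
    n_higher: int
    n_lower: int


def tf_candidates(dcs: DCSResult, tf_flags: dict[str, bool] | pd.Series) -> CandidateReport:
    """Intersect the differential gene set with transcription-factor annotations.

    Mirrors the screen for regulators that transduce the bacterial signal:
    among all genes with a significant chromatin change, keep those annotated
    as putative transcription factors and report the higher/lower split.
    """
    flags = pd.Series(tf_flags, dtype=bool)
    diff = dcs.differential
    tf_genes = diff.intersection(flags.index[flags])
    cand = dcs.table.loc[tf_genes, ["lfc", "fdr", "dcs_class"]].sort_values("fdr")
    return CandidateReport(
        n_differential=len(diff),
        candidates=cand,
        n_higher=int((cand["dcs_class"] == "higher").sum()),
        n_lower=int((cand["dcs_class"] == "lower").sum()),
    )


def cluster_summary(dcs: DCSResult, clusters: dict[str, str] | pd.Series) -> pd.DataFrame:
    """Per-cluster chromatin response summary.

    For each secondary-metabolism cluster: member count, median LFC, counts
    of higher/lower/unchanged members, and a direction call — the sign of
    the median LFC when at least half the members are classified, else
    ``mixed``.
    """
    cl = pd.Series(clusters).dropna()
    cl = cl[cl.astype(str).str.len() > 0]
    dropped = len(pd.Series(clusters)) - len(cl)
    if dropped:
        warnings.warn(f"{dropped} genes with empty cluster id excluded")
    cl = cl[cl.index.isin(dcs.table.index)]
    rows = []
    for cid, members in cl.groupby(cl):
        sub = dcs.table.loc[members.index]
        n = len(sub)
        n_higher = int((sub["dcs_class"] == "higher").sum())
        n_lower = int((sub["dcs_class"] == "lower").sum())
        med = float(sub["lfc"].median())
        if (n_higher + n_lower) * 2 >= n and med != 0:
            direction = "higher" if med > 0 else "lower"
        else:
            direction = "mixed"
        rows.append((cid, n, med, n_higher, n_lower, n - n_higher - n_lower, direction))
    return pd.DataFrame(rows, columns=["cluster_id", "n_genes", "median_lfc",
                                       "n_higher", "n_lower", "n_unchanged",
                                       "direction"]).set_index("cluster_id")


def tpm(counts: pd.Series | pd.DataFrame, lengths: pd.Series) -> pd.Series | pd.DataFrame:
    """Transcripts per million: length-normalized rates scaled to sum to 1e6."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("all gene lengths must be positive")
    rates = counts.div(lengths, axis=0)
    total = rates.sum(axis=0)
    if np.any(np.asarray(total) == 0):
        raise ValueError("all-zero counts: TPM undefined")
    return rates.div(total, axis=1) * 1e6 if isinstance(counts, pd.DataFrame) \
        else rates / total * 1e6
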