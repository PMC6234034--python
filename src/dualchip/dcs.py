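"""Differential chromatin state (DCS) testing.

Gene-level (or promoter/peak-level) ChIP-seq counts are compared between
mono- and co-culture with the standard count-based machinery for sequencing
data: TMM scaling factors computed on host gene counts, a negative-binomial
model (variance = mu + phi * mu^2), an exact test conditional on per-feature
group totals, and Benjamini-Hochberg FDR.  Features are classified as
``higher`` / ``lower`` / ``unchanged`` acetylation at an FDR cut-off
(default 0.01) with no additional fold-change filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .quantify import CountMatrix

LFC_PSEUDOCOUNT = 0.125  # display-only; never enters the exact test


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationFactors:
    """Per-library TMM factors (geometric mean 1) and effective sizes."""

    factors: pd.Series
    effective_sizes: pd.Series
    reference: str

    @property
    def normalized_sizes(self) -> pd.Series:
        return self.factors * self.effective_sizes


def _tmm_pair(y: np.ndarray, yr: np.ndarray, n: float, nr: float,
              trim_m: float, trim_a: float, weighted: bool = True) -> float:
    """Trimmed, precision-weighted mean of M-values of one library vs the reference."""
    ok = (y > 0) & (yr > 0)
    y, yr = y[ok].astype(float), yr[ok].astype(float)
    if y.size == 0:
        raise ValueError("no features with nonzero counts in both libraries")
    p, pr = y / n, yr / nr
    M = np.log2(p / pr)
    A = 0.5 * np.log2(p * pr)
    # delta-method variance of M (binomial sampling in each library)
    w = (n - y) / (n * y) + (nr - yr) / (nr * yr)

    m = M.size
    rank_m = np.argsort(np.argsort(M, kind="stable"), kind="stable") + 1
    rank_a = np.argsort(np.argsort(A, kind="stable"), kind="stable") + 1
    lo_m, hi_m = np.floor(m * trim_m) + 1, m - np.floor(m * trim_m)
    lo_a, hi_a = np.floor(m * trim_a) + 1, m - np.floor(m * trim_a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        raise ValueError("no features survive TMM trimming")
    if weighted:
        with np.errstate(divide="ignore"):
            inv_w = 1.0 / w[keep]
    else:
        # plain trimmed mean: exactly absorbs a constant scaling of one library
        inv_w = np.ones(int(keep.sum()))
    f = np.sum(M[keep] * inv_w) / np.sum(inv_w)
    return float(2.0 ** f)


def tmm_factors(matrix: CountMatrix, reference: str | None = None,
                trim_m: float = 0.3, trim_a: float = 0.05,
                weighted: bool = True) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scaling factors on host feature counts.

    For each library vs the reference, gene-wise M (log2 ratio of relative
    abundances) and A (mean log2 abundance) are computed over features with
    nonzero counts in both; the most extreme ``trim_m`` of M and ``trim_a``
    of A are discarded from each tail, and the factor is 2 to the
    precision-weighted mean of the remaining M.  Factors are centered to
    geometric mean 1.  The reference defaults to the library whose 75th
    percentile of relative counts is closest to the mean of those
    percentiles.  ``weighted=False`` drops the precision weights (plain
    trimmed mean), which makes the factor absorb a constant scaling of one
    library exactly rather than approximately.
    """
    counts = matrix.counts
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two libraries")
    nonzero = counts.loc[counts.sum(axis=1) > 0]
    N = matrix.effective_sizes

    if reference is None:
        q75 = (nonzero / N).quantile(0.75)
        reference = (q75 - q75.mean()).abs().idxmin()
    elif reference not in counts.columns:
        raise ValueError(f"reference library {reference!r} not in matrix")

    yr = nonzero[reference].to_numpy()
    factors = {}
    for lib in counts.columns:
        if lib == reference:
            factors[lib] = 1.0
        else:
            factors[lib] = _tmm_pair(nonzero[lib].to_numpy(), yr,
                                     N[lib], N[reference], trim_m, trim_a, weighted)
    f = pd.Series(factors, dtype=float).reindex(counts.columns)
    f /= np.exp(np.log(f).mean())  # center to geometric mean 1
    return NormalizationFactors(f, N, reference)


def unit_factors(matrix: CountMatrix) -> NormalizationFactors:
    """All-ones factors: plain library-size scaling without TMM."""
    f = pd.Series(1.0, index=matrix.counts.columns)
    return NormalizationFactors(f, matrix.effective_sizes, matrix.counts.columns[0])


# ---------------------------------------------------------------------------
# NB dispersion (conditional likelihood, counts scaled to a common size)
# ---------------------------------------------------------------------------

@dataclass
class DispersionEstimate:
    common: float
    tagwise: pd.Series | None = None
    prior_weight: float = 10.0
    poisson_fallback: bool = False

    def per_feature(self, features: pd.Index) -> np.ndarray:
        if self.tagwise is None:
            return np.full(len(features), self.common)
        return self.tagwise.reindex(features).fillna(self.common).to_numpy()


def _scaled_group_counts(matrix: CountMatrix, factors: NormalizationFactors,
                         groups: dict[str, list[str]]) -> dict[str, np.ndarray]:
    """Counts rescaled (mean adjustment) to a common normalized size.

    The common size is the reference library's normalized size: unlike the
    geometric mean, it does not drift when another library is rescaled, so a
    TMM-absorbed scaling leaves the adjusted counts bit-identical.
    """
    nsize = factors.normalized_sizes
    common = float(nsize.get(factors.reference, np.exp(np.log(nsize).mean())))
    out = {}
    for gname, libs in groups.items():
        sub = matrix.counts[libs].to_numpy(dtype=float)
        out[gname] = sub * (common / nsize[libs].to_numpy())[None, :]
    return out


def _cond_nb_loglik(y: np.ndarray, phi: float) -> np.ndarray:
    """Per-feature NB log-likelihood conditional on the replicate-sum.

    Given n replicates with a shared mean, the vector of counts conditional
    on its total follows a Dirichlet-multinomial with concentration
    r = 1/phi per replicate; the mean parameter cancels.  ``y`` is
    (features x replicates); returns one value per feature.
    """
    n = y.shape[1]
    z = y.sum(axis=1)
    if phi <= 0:
        # Poisson limit: conditional is multinomial(1/n, ..., 1/n)
        return (gammaln(z + 1) - gammaln(y + 1).sum(axis=1) - z * np.log(n))
    r = 1.0 / phi
    return (
        gammaln(y + r).sum(axis=1) - n * gammaln(r) - gammaln(y + 1).sum(axis=1)
        - (gammaln(z + n * r) - gammaln(n * r) - gammaln(z + 1))
    )


def estimate_dispersion(matrix: CountMatrix, factors: NormalizationFactors,
                        groups: dict[str, list[str]],
                        tagwise: bool = False, prior_weight: float = 10.0,
                        max_phi: float = 5.0) -> DispersionEstimate:
    """Common (and optionally moderated tagwise) NB dispersion.

    Maximizes the conditional log-likelihood pooled across features and
    groups, on counts mean-scaled to a common normalized library size.
    Tagwise values maximize the feature's own conditional likelihood plus
    ``prior_weight`` times the feature-averaged likelihood (empirical-Bayes
    shrinkage toward the common value).  With a single replicate everywhere
    the dispersion is not identifiable and 0 is returned with a flag
    (Poisson fallback).
    """
    scaled = _scaled_group_counts(matrix, factors, groups)
    usable = [y for y in scaled.values() if y.shape[1] >= 2]
    if not usable:
        warnings.warn("no group with >= 2 replicates; falling back to Poisson (phi = 0)")
        return DispersionEstimate(0.0, poisson_fallback=True)

    def neg_pooled(log10_phi: float) -> float:
        phi = 10.0 ** log10_phi
        return -sum(_cond_nb_loglik(y, phi).sum() for y in usable)

    res = minimize_scalar(neg_pooled, bounds=(-6.0, np.log10(max_phi)), method="bounded",
                          options={"xatol": 1e-6})
    common = float(10.0 ** res.x)
    ll_at_zero = sum(_cond_nb_loglik(y, 0.0).sum() for y in usable)
    if ll_at_zero >= -res.fun - 1e-8:
        common = 0.0
    if common < 1e-5:
        common = 0.0

    tw = None
    if tagwise:
        grid = np.concatenate([[1e-6], np.logspace(-4, np.log10(max_phi), 60)])
        per_feat = np.zeros((len(matrix.counts), grid.size))
        for y in usable:
            for k, phi in enumerate(grid):
                per_feat[:, k] += _cond_nb_loglik(y, phi)
        pooled = per_feat.mean(axis=0)
        weighted = per_feat + prior_weight * pooled[None, :]
        tw = pd.Series(grid[np.argmax(weighted, axis=1)], index=matrix.counts.index)
        tw[tw <= 1e-5] = 0.0
    return DispersionEstimate(common, tw, prior_weight)


# ---------------------------------------------------------------------------
# NB exact test
# ---------------------------------------------------------------------------

def _exact_nb_pvalue(a: int, b: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided exact p-value for group sums ``a`` vs ``b``.

    Conditional on t = a + b, with per-replicate NB(r = 1/phi) counts at a
    shared mean, the first group's sum follows a beta-binomial-type law
    P(k | t) proportional to C(k + n1*r - 1, k) * C(t - k + n2*r - 1, t - k);
    the two-sided p-value sums the probabilities of all splits no more
    likely than the observed one.  phi = 0 reduces to the conditional
    binomial with success probability n1 / (n1 + n2).
    """
    t = a + b
    if t == 0:
        return 1.0
    k = np.arange(t + 1)
    if phi <= 0:
        logp = (gammaln(t + 1) - gammaln(k + 1) - gammaln(t - k + 1)
                + k * np.log(n1 / (n1 + n2)) + (t - k) * np.log(n2 / (n1 + n2)))
    else:
        r = 1.0 / phi
        logp = (gammaln(k + n1 * r) - gammaln(k + 1)
                + gammaln(t - k + n2 * r) - gammaln(t - k + 1))
        logp -= logsumexp(logp)
    p_obs = logp[a]
    mask = logp <= p_obs + 1e-10  # tolerate fp ties
    return float(min(1.0, np.exp(logsumexp(logp[mask]))))


def nb_exact_test(matrix: CountMatrix, factors: NormalizationFactors,
                  dispersion: DispersionEstimate | float,
                  contrast: tuple[str, str] = ("mono", "cocult")) -> pd.DataFrame:
    """Per-feature exact NB test between the two contrast conditions.

    Counts are mean-scaled to a common normalized library size; the test
    conditions on the rounded group-sum total.  Returns a DataFrame with
    per-group normalized means, ``lfc`` (log2 second/first condition, with a
    small display pseudo-count) and ``pvalue``.
    """
    ref_cond, alt_cond = contrast
    libs = matrix.libraries
    g1 = list(libs.index[libs["condition"] == ref_cond])
    g2 = list(libs.index[libs["condition"] == alt_cond])
    if not g1 or not g2:
        raise ValueError(f"contrast {contrast}: both conditions need >= 1 library")
    scaled = _scaled_group_counts(matrix, factors, {"g1": g1, "g2": g2})
    y1, y2 = scaled["g1"], scaled["g2"]
    a = np.rint(y1.sum(axis=1)).astype(np.int64)
    b = np.rint(y2.sum(axis=1)).astype(np.int64)

    if isinstance(dispersion, DispersionEstimate):
        phis = dispersion.per_feature(matrix.counts.index)
    else:
        phis = np.full(len(matrix.counts), float(dispersion))

    pvals = np.ones(len(a))
    cache: dict[tuple[int, int, float], float] = {}
    for i in range(len(a)):
        key = (int(a[i]), int(b[i]), float(phis[i]))
        if key not in cache:
            cache[key] = _exact_nb_pvalue(int(a[i]), int(b[i]), len(g1), len(g2), phis[i])
        pvals[i] = cache[key]

    m1 = y1.mean(axis=1)
    m2 = y2.mean(axis=1)
    lfc = np.log2((m2 + LFC_PSEUDOCOUNT) / (m1 + LFC_PSEUDOCOUNT))
    zero = (a + b) == 0
    lfc[zero] = 0.0
    return pd.DataFrame(
        {f"mean_{ref_cond}": m1, f"mean_{alt_cond}": m2, "lfc": lfc, "pvalue": pvals},
        index=matrix.counts.index,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR), original order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Full DCS analysis
# ---------------------------------------------------------------------------

@dataclass
class DCSResult:
    """Per-feature differential chromatin state calls for one antibody target."""

    table: pd.DataFrame
    target: str
    fdr_cutoff: float
    factors: NormalizationFactors = field(repr=False, default=None)  # type: ignore
    dispersion: DispersionEstimate = field(repr=False, default=None)  # type: ignore

    @property
    def higher(self) -> pd.Index:
        return self.table.index[self.table["dcs_class"] == "higher"]

    @property
    def lower(self) -> pd.Index:
        return self.table.index[self.table["dcs_class"] == "lower"]

    @property
    def differential(self) -> pd.Index:
        return self.table.index[self.table["dcs_class"] != "unchanged"]

    def to_tsv(self, path) -> None:
        self.table.rename_axis("feature").to_csv(path, sep="\t")


def dcs_analysis(matrix: CountMatrix, target: str | None = None,
                 contrast: tuple[str, str] = ("mono", "cocult"),
                 fdr_cutoff: float = 0.01, normalization: str = "tmm",
                 tagwise: bool = False,
                 exclude_targets: tuple[str, ...] = ("background",)) -> DCSResult:
    """TMM -> dispersion -> exact test -> BH, then classify at the FDR cut-off.

    ``normalization="library-size"`` disables TMM (factors all 1); combined
    with total-read effective sizes this reproduces the naive scheme that the
    host-only rule exists to avoid.  Background (input) libraries are
    excluded from testing.  Classification: ``higher`` if FDR < cut-off and
    LFC > 0, ``lower`` if FDR < cut-off and LFC < 0, else ``unchanged`` —
    no further fold-change filter.
    """
    sub = matrix
    if target is not None:
        sub = sub.select_target(target, conditions=contrast)
    else:
        keep = [k for k in sub.counts.columns
                if sub.libraries.loc[k, "target"] not in exclude_targets
                and sub.libraries.loc[k, "condition"] in contrast]
        targets = sub.libraries.loc[keep, "target"].unique()
        if len(targets) != 1:
            raise ValueError(f"matrix holds several targets {list(targets)}; pass target=")
        target = targets[0]
        sub = CountMatrix(sub.counts[keep], sub.effective_sizes[keep],
                          sub.feature_lengths, sub.libraries.loc[keep])

    # features with zero counts everywhere have undefined M/A values
    expressed = sub.counts.sum(axis=1) > 0
    core = CountMatrix(sub.counts.loc[expressed], sub.effective_sizes,
                       sub.feature_lengths, sub.libraries)

    if normalization == "tmm":
        factors = tmm_factors(core)
    elif normalization == "library-size":
        factors = unit_factors(core)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")

    libs = core.libraries
    groups = {c: list(libs.index[libs["condition"] == c]) for c in contrast}
    disp = estimate_dispersion(core, factors, groups, tagwise=tagwise)
    res = nb_exact_test(core, factors, disp, contrast)
    res["fdr"] = bh_adjust(res["pvalue"].to_numpy())
    cls = np.where(
        (res["fdr"] < fdr_cutoff) & (res["lfc"] > 0), "higher",
        np.where((res["fdr"] < fdr_cutoff) & (res["lfc"] < 0), "lower", "unchanged"),
    )
    res["dcs_class"] = cls

    full = res.reindex(matrix.counts.index if target is None else sub.counts.index)
    full.loc[~expressed, ["lfc"]] = 0.0
    full.loc[~expressed, ["pvalue", "fdr"]] = 1.0
    full.loc[~expressed, "dcs_class"] = "unchanged"
    full[[c for c in full.columns if c.startswith("mean_")]] = \
        full[[c for c in full.columns if c.startswith("mean_")]].fillna(0.0)
    return DCSResult(full, target, fdr_cutoff, factors, disp)


def ma_table(matrix: CountMatrix, factors: NormalizationFactors,
             contrast: tuple[str, str] = ("mono", "cocult")) -> pd.DataFrame:
    """Per-feature (A, M) for the MA diagnostic plot.

    A = mean log2 normalized abundance, M = LFC.  After TMM on null data the
    M distribution should be symmetric and centered at 0.
    """
    res = nb_exact_test(matrix, factors, 0.0, contrast)
    ref, alt = contrast
    m1 = res[f"mean_{ref}"] + LFC_PSEUDOCOUNT
    m2 = res[f"mean_{alt}"] + LFC_PSEUDOCOUNT
    return pd.DataFrame({"A": 0.5 * (np.log2(m1) + np.log2(m2)), "M": res["lfc"]},
                        index=res.index)
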