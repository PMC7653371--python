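"""Comparative statistics: PCA, Pearson correlation reports and binning.

Two PCAs are used when comparing complexity metrics: a *shape* PCA on
flattened superimposed semi-landmarks (centered, never standardized —
coordinates share units) and a *score* PCA on the five complexity metrics
(standardized by default, since SI ~ 1-5 and SCI ~ 0-90 live on
incommensurable scales).  Correlations are plain Pearson r with two-sided
t-test p-values and Fisher-z confidence intervals; no multiple-testing
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PcaResult",
    "CorrelationReport",
    "pca",
    "num_pcs_for",
    "correlation_report",
    "bin_scores",
    "metric_shape_alignment",
]


@dataclass(frozen=True)
class PcaResult:
    """Principal component analysis result.

    Attributes
    ----------
    scores
        (n_samples, n_components) DataFrame of PC scores, indexed like the
        input rows; columns ``PC1..PCk``.
    loadings
        (n_variables, n_components) DataFrame of unit-norm eigenvector
        loadings; the largest-magnitude entry of each column is positive.
    variance_fraction
        Per-PC fraction of total variance (sums to 1).
    contributions
        Per-variable percentage contribution to each PC (squared loading
        x 100; sums to 100 per PC).
    standardized
        Whether variables were scaled to unit variance before the
        decomposition.
    """

    scores: pd.DataFrame = field(repr=False)
    loadings: pd.DataFrame = field(repr=False)
    variance_fraction: np.ndarray
    contributions: pd.DataFrame = field(repr=False)
    standardized: bool

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass(frozen=True)
class CorrelationReport:
    """Pairwise Pearson correlations with significance and 95% CIs.

    ``r``, ``p``, ``ci_low`` and ``ci_high`` are DataFrames sharing the
    same row/column labels (square and symmetric for a self-correlation
    of one table; rectangular for cross-correlations).  ``n`` is the
    common sample size.  Pairs involving a zero-variance column carry NaN.
    """

    r: pd.DataFrame = field(repr=False)
    p: pd.DataFrame = field(repr=False)
    ci_low: pd.DataFrame = field(repr=False)
    ci_high: pd.DataFrame = field(repr=False)
    n: int

    def to_long(self) -> pd.DataFrame:
        """Long-format table: var1, var2, r, p, ci_low, ci_high, n."""
        rows = []
        for a in self.r.index:
            for b in self.r.columns:
                rows.append(
                    {
                        "var1": a,
                        "var2": b,
                        "r": self.r.loc[a, b],
                        "p": self.p.loc[a, b],
                        "ci_low": self.ci_low.loc[a, b],
                        "ci_high": self.ci_high.loc[a, b],
                        "n": self.n,
                    }
                )
        return pd.DataFrame(rows)


def pca(data: pd.DataFrame | np.ndarray, standardize: bool = False) -> PcaResult:
    """PCA via eigendecomposition of the covariance (or correlation) matrix.

    Components are ordered by decreasing variance.  Sign convention: the
    largest-magnitude entry of each loading vector is made positive, so
    results are reproducible across linear-algebra backends.

    Raises
    ------
    ValueError
        Fewer than 2 rows/columns, missing values, or a constant column
        with ``standardize=True``.
    """
    df = pd.DataFrame(data).copy()
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError(f"PCA needs >= 2 rows and >= 2 columns, got {df.shape}")
    if df.isna().any().any():
        raise ValueError("PCA input contains missing values")
    x = df.to_numpy(float)
    x = x - x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = list(df.columns[sd == 0])
            raise ValueError(f"cannot standardize constant column(s) {bad}")
        x = x / sd

    # SVD of the centered matrix == eigendecomposition of its covariance
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eigvals = s**2 / (x.shape[0] - 1)
    order = np.argsort(eigvals)[::-1]
    eigvals, vt, u, s = eigvals[order], vt[order], u[:, order], s[order]

    loadings = vt.T
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = x @ loadings

    total = eigvals.sum()
    var_frac = eigvals / total if total > 0 else np.zeros_like(eigvals)
    pcs = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    contrib = 100.0 * loadings**2 / (loadings**2).sum(axis=0)
    return PcaResult(
        scores=pd.DataFrame(scores, index=df.index, columns=pcs),
        loadings=pd.DataFrame(loadings, index=df.columns, columns=pcs),
        variance_fraction=var_frac,
        contributions=pd.DataFrame(contrib, index=df.columns, columns=pcs),
        standardized=standardize,
    )


def num_pcs_for(fraction: float, result: PcaResult) -> int:
    """Smallest number of leading PCs whose cumulative variance fraction
    reaches ``fraction``."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    cum = np.cumsum(result.variance_fraction)
    return int(np.searchsorted(cum, fraction - 1e-12) + 1)


def _pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, float]:
    if a.std() == 0 or b.std() == 0:
        return (np.nan, np.nan, np.nan, np.nan)
    res = sps.pearsonr(a, b)
    ci = res.confidence_interval(0.95)
    return (float(res.statistic), float(res.pvalue), float(ci.low), float(ci.high))


def correlation_report(table: pd.DataFrame) -> CorrelationReport:
    """Pearson r, two-sided p and 95% CI for every column pair of a table.

    p-values come from the t-test with n-2 degrees of freedom,
    t = r sqrt((n-2)/(1-r^2)); confidence intervals from the Fisher
    z-transform.  Zero-variance columns yield NaN for their pairs rather
    than failing the whole report.
    """
    df = pd.DataFrame(table)
    n = df.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 rows, got {n}")
    cols = list(df.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    lo = np.ones((k, k))
    hi = np.ones((k, k))
    x = df.to_numpy(float)
    for i in range(k):
        if x[:, i].std() == 0:
            r[i, i] = lo[i, i] = hi[i, i] = np.nan
            p[i, i] = np.nan
        for j in range(i + 1, k):
            rij, pij, l, h = _pearson(x[:, i], x[:, j])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
            lo[i, j] = lo[j, i] = l
            hi[i, j] = hi[j, i] = h
    mk = lambda m: pd.DataFrame(m, index=cols, columns=cols)
    return CorrelationReport(r=mk(r), p=mk(p), ci_low=mk(lo), ci_high=mk(hi), n=n)


def bin_scores(values, k: int = 10) -> np.ndarray:
    """Assign values to ``k`` equal-width bins spanning [min, max].

    Labels run 1..k; the maximum lands in bin k; a constant vector goes
    entirely to bin 1.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot bin an empty vector")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return np.ones(v.size, dtype=int)
    bins = np.floor((v - lo) / (hi - lo) * k).astype(int) + 1
    return np.minimum(bins, k)


def metric_shape_alignment(
    scores: pd.DataFrame,
    shape_pca: PcaResult,
    top_fraction: float = 0.05,
) -> CorrelationReport:
    """Correlate complexity metrics against the dominant shape PCs.

    Only PCs whose variance fraction exceeds ``top_fraction`` (default 5%)
    are retained.  Specimen ordering must match between the score table and
    the shape PCA scores.

    Raises
    ------
    ValueError
        If the specimen indices differ (content or order).
    """
    if list(scores.index) != list(shape_pca.scores.index):
        raise ValueError("specimen ordering mismatch between scores and shape PCA")
    keep = [
        pc
        for pc, f in zip(shape_pca.scores.columns, shape_pca.variance_fraction)
        if f > top_fraction
    ]
    if not keep:
        raise ValueError(f"no PC exceeds variance fraction {top_fraction}")
    pcs = shape_pca.scores[keep]
    n = scores.shape[0]
    metric_cols = list(scores.columns)
    r = pd.DataFrame(index=metric_cols, columns=keep, dtype=float)
    p, lo, hi = r.copy(), r.copy(), r.copy()
    for m in metric_cols:
        for pc in keep:
            rv, pv, l, h = _pearson(
                scores[m].to_numpy(float), pcs[pc].to_numpy(float)
            )
            r.loc[m, pc], p.loc[m, pc] = rv, pv
            lo.loc[m, pc], hi.loc[m, pc] = l, h
    return CorrelationReport(r=r, p=p, ci_low=lo, ci_high=hi, n=n)
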