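"""Two-pass Mahalanobis-distance outlier test over a feature x sample matrix.

This is the core differential statistic of the pipeline. Given a matrix X
whose rows are genomic features (100-kb compartment bins, or TADs) and
whose columns are samples (e.g. one pooled young and one pooled old
sample), the squared Mahalanobis distance of each row from the centroid,

    MD = diag((X - Xc) @ Cinv @ (X - Xc)^T),

is referred to a one-sided upper-tail chi-squared test with df equal to
the number of columns. The calculation is run twice: pass 1 estimates the
centroid Xc and covariance C from all rows and flags outliers at
p < alpha; pass 2 re-estimates Xc and C without those outliers and scores
every row against the cleaned estimates. Features whose behaviour across
conditions is atypical (e.g. a compartment PC1 sign flip) land in the
chi-squared tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "FeatureMatrix",
    "MDResult",
    "mahalanobis_md",
    "chi2_upper_p",
    "two_pass_md",
    "classify_compartment_switch",
    "SWITCH_CATEGORIES",
]


@dataclass
class FeatureMatrix:
    """Features x samples value matrix with condition labels per column."""

    feature_ids: np.ndarray
    sample_ids: list
    conditions: list  # condition label per column (e.g. 1 or 2)
    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.feature_ids = np.asarray(self.feature_ids)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (features x samples)")
        n, p = self.X.shape
        if p < 2:
            raise ValueError("need at least 2 sample columns")
        if n < p + 2:
            raise ValueError("need at least columns + 2 feature rows")
        if len(self.sample_ids) != p or len(self.conditions) != p:
            raise ValueError("sample_ids/conditions must match the number of columns")
        if not np.isfinite(self.X).all():
            raise ValueError("X must not contain missing values")

    def condition_means(self) -> dict:
        """Per-feature mean value over the columns of each condition."""
        conds = np.asarray(self.conditions)
        return {c: self.X[:, conds == c].mean(axis=1) for c in dict.fromkeys(self.conditions)}


@dataclass
class MDResult:
    md_pass1: np.ndarray
    md_pass2: np.ndarray
    pvalues: np.ndarray  # one-sided chi-squared, pass 2
    significant: np.ndarray
    center: np.ndarray  # pass-2 centroid
    inv_cov: np.ndarray  # pass-2 inverse covariance
    alpha: float
    df: int
    pass1_outliers: np.ndarray
    singular_covariance: bool = False


def mahalanobis_md(x: np.ndarray, center: np.ndarray, inv_cov: np.ndarray) -> np.ndarray:
    """Squared Mahalanobis distance of each row of ``x`` from ``center``."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    center = np.asarray(center, dtype=float)
    inv_cov = np.asarray(inv_cov, dtype=float)
    p = x.shape[1]
    if center.shape != (p,) or inv_cov.shape != (p, p):
        raise ValueError("center/inv_cov dimensions must match the number of columns")
    diff = x - center
    md = np.einsum("ij,jk,ik->i", diff, inv_cov, diff)
    return np.maximum(md, 0.0)  # clip roundoff negatives of a PSD form


def chi2_upper_p(md, df: int):
    """Upper-tail (one-sided) chi-squared p-value for a squared MD."""
    md = np.asarray(md, dtype=float)
    if np.any(md < 0):
        raise ValueError("MD must be non-negative")
    if df < 1:
        raise ValueError("df must be >= 1")
    return stats.chi2.sf(md, df)


def _inv_or_pinv(cov: np.ndarray) -> tuple[np.ndarray, bool]:
    p = cov.shape[0]
    if np.linalg.matrix_rank(cov, tol=1e-10 * max(1.0, float(np.abs(cov).max()))) < p:
        return np.linalg.pinv(cov, rcond=1e-10), True
    return np.linalg.inv(cov), False


def two_pass_md(fm: FeatureMatrix, alpha: float = 0.01) -> MDResult:
    """Two-pass MD outlier detection with a one-sided chi-squared test.

    df equals the number of sample columns (the squared MD of a
    p-dimensional Gaussian vector is chi-squared with p degrees of
    freedom). A singular covariance falls back to the Moore-Penrose
    pseudo-inverse and is flagged.
    """
    X = fm.X
    n, p = X.shape
    df = p

    xc1 = X.mean(axis=0)
    cov1 = np.cov(X, rowvar=False, ddof=1)
    inv1, sing1 = _inv_or_pinv(np.atleast_2d(cov1))
    md1 = mahalanobis_md(X, xc1, inv1)
    outliers = chi2_upper_p(md1, df) < alpha

    keep = ~outliers
    if keep.sum() < p + 2:
        raise ValueError(
            f"only {int(keep.sum())} features remain after pass 1; need >= {p + 2}"
        )
    xc2 = X[keep].mean(axis=0)
    cov2 = np.cov(X[keep], rowvar=False, ddof=1)
    inv2, sing2 = _inv_or_pinv(np.atleast_2d(cov2))
    md2 = mahalanobis_md(X, xc2, inv2)
    pvals = chi2_upper_p(md2, df)
    return MDResult(
        md_pass1=md1,
        md_pass2=md2,
        pvalues=pvals,
        significant=pvals < alpha,
        center=xc2,
        inv_cov=inv2,
        alpha=alpha,
        df=df,
        pass1_outliers=outliers,
        singular_covariance=sing1 or sing2,
    )


SWITCH_CATEGORIES = ("A->B", "B->A", "A-stable-shifted", "B-stable-shifted")


def classify_compartment_switch(
    result: MDResult, mean_cond1: np.ndarray, mean_cond2: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Label each significant bin by its PC1 sign pair across conditions.

    (+,-) -> "A->B", (-,+) -> "B->A"; same-sign significant bins are
    "stable-shifted" within their compartment. Non-significant bins are
    "unchanged"; a PC1 of exactly 0 in either condition makes the bin
    indeterminate and it is excluded from the per-category counts.
    """
    mean_cond1 = np.asarray(mean_cond1, dtype=float)
    mean_cond2 = np.asarray(mean_cond2, dtype=float)
    n = len(result.pvalues)
    if mean_cond1.shape != (n,) or mean_cond2.shape != (n,):
        raise ValueError("condition means must be defined on all tested bins")
    categories = np.full(n, "unchanged", dtype=object)
    sig = result.significant
    zero = (mean_cond1 == 0) | (mean_cond2 == 0)
    categories[sig & zero] = "indeterminate"
    s1 = mean_cond1 > 0
    s2 = mean_cond2 > 0
    ok = sig & ~zero
    categories[ok & s1 & ~s2] = "A->B"
    categories[ok & ~s1 & s2] = "B->A"
    categories[ok & s1 & s2] = "A-stable-shifted"
    categories[ok & ~s1 & ~s2] = "B-stable-shifted"
    counts = {c: int((categories == c).sum()) for c in SWITCH_CATEGORIES}
    return categories, counts
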