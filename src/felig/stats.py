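"""Descriptive statistics matching the study's reporting conventions.

Pairwise-complete Pearson correlation tables with exact-t p-values,
unrotated PCA on z-scored variables (eigendecomposition of the correlation
matrix, loadings scaled by sqrt(eigenvalue)), and box summaries reporting
mean, SD and the 5th/95th percentiles with linear interpolation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import DomainError

__all__ = [
    "CorrelationEntry",
    "PcaSummary",
    "BoxSummary",
    "pearson_table",
    "pca_loadings",
    "box_summary",
]

ALPHA = 0.05  # significance level used for flagging


@dataclass(frozen=True)
class CorrelationEntry:
    var_x: str
    var_y: str
    r: float
    n: int
    p: float
    significant: bool


@dataclass(frozen=True)
class PcaSummary:
    """Loadings (variables × components), explained variance per component
    (%), and per-variable communality over the first two components (%)."""

    loadings: pd.DataFrame
    explained_pct: np.ndarray
    communality_pct: pd.Series


@dataclass(frozen=True)
class BoxSummary:
    mean: float
    sd: float
    p5: float
    p95: float
    n: int


def pearson_table(
    records: pd.DataFrame, variables: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pairwise-deletion Pearson correlations among ``variables``.

    Each pair uses its own complete observations (n therefore varies per
    pair).  p is two-sided from the t-transform with n−2 degrees of
    freedom; entries with fewer than 3 complete pairs or a constant
    variable get r = NaN and a flag.
    """
    if variables is None:
        variables = [c for c in records.columns
                     if pd.api.types.is_numeric_dtype(records[c])]
    rows = []
    for i, vx in enumerate(variables):
        for vy in variables[i + 1:]:
            pair = records[[vx, vy]].dropna()
            n = len(pair)
            if n < 3 or pair[vx].nunique() < 2 or pair[vy].nunique() < 2:
                rows.append({"var_x": vx, "var_y": vy, "r": math.nan,
                             "n": n, "p": math.nan, "significant": False,
                             "flag": "undefined"})
                continue
            r, p = sstats.pearsonr(pair[vx], pair[vy])
            rows.append({"var_x": vx, "var_y": vy, "r": float(r), "n": n,
                         "p": float(p), "significant": bool(p < ALPHA),
                         "flag": ""})
    return pd.DataFrame(
        rows, columns=["var_x", "var_y", "r", "n", "p", "significant", "flag"])


def pca_loadings(
    records: pd.DataFrame,
    variables: Sequence[str],
    standardize: bool = True,
) -> PcaSummary:
    """Unrotated PCA of complete-case rows.

    With ``standardize`` (default) variables are z-scored, i.e. the
    eigendecomposition is of the correlation matrix.  Loadings are
    eigenvectors scaled by sqrt(eigenvalue); the sign convention makes the
    largest-magnitude loading of each component positive.  Near-zero
    eigenvalues (rank deficiency) reduce the component count with a
    warning.  Communality is reported over PC1–PC2.
    """
    data = records[list(variables)].dropna()
    k = len(variables)
    if len(data) < k:
        raise DomainError(
            f"PCA needs at least {k} complete-case rows, got {len(data)}")
    X = data.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [v for v, s in zip(variables, sd) if s == 0]
            raise DomainError(f"constant variable(s) in PCA input: {bad}")
        X = (X - X.mean(axis=0)) / sd
        mat = np.corrcoef(X, rowvar=False)
    else:
        mat = np.cov(X, rowvar=False)

    eigval, eigvec = np.linalg.eigh(mat)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    total = eigval.sum()

    tol = max(eigval.max(), 1.0) * 1e-10
    keep = eigval > tol
    if not keep.all():
        warnings.warn(
            f"rank-deficient input: keeping {int(keep.sum())} of {k} components",
            stacklevel=2)
    eigval, eigvec = eigval[keep], eigvec[:, keep]

    load = eigvec * np.sqrt(eigval)
    for j in range(load.shape[1]):
        if load[np.argmax(np.abs(load[:, j])), j] < 0:
            load[:, j] = -load[:, j]

    comps = [f"PC{j + 1}" for j in range(load.shape[1])]
    loadings = pd.DataFrame(load, index=list(variables), columns=comps)
    explained = 100.0 * eigval / total
    n12 = min(2, load.shape[1])
    communality = 100.0 * (load[:, :n12] ** 2).sum(axis=1) / np.diag(mat)
    return PcaSummary(
        loadings=loadings,
        explained_pct=explained,
        communality_pct=pd.Series(communality, index=list(variables)),
    )


def box_summary(values: Sequence[float] | np.ndarray) -> BoxSummary:
    """Mean, sample SD, and linear-interpolation 5th/95th percentiles."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    n = arr.size
    if n == 0:
        return BoxSummary(math.nan, math.nan, math.nan, math.nan, 0)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if n >= 2 else math.nan
    p5, p95 = np.percentile(arr, [5, 95], method="linear")
    return BoxSummary(mean, sd, float(p5), float(p95), n)
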