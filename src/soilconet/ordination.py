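"""Redundancy analysis (RDA) and Monte Carlo permutation testing.

RDA projects a column-centered community matrix Y (samples × taxa) onto the
column space of a standardized covariate matrix X (samples × chemistry
variables); the eigendecomposition of the fitted values yields constrained
axes whose eigenvalues are reported both as a share of the total community
variance and of the constrained (explained) variance.  Significance of the
community–chemistry relationship comes from permuting whole samples (rows
of X) and recomputing the constrained trace, with the add-one p-value
(1 + #{perm >= obs}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg


@dataclass
class RdaResult:
    eigenvalues: np.ndarray            # constrained axes, non-increasing
    pct_total: np.ndarray              # % of total variance per axis
    pct_constrained: np.ndarray        # % of constrained variance per axis
    trace: float                       # total constrained variance
    total_variance: float
    sample_scores: pd.DataFrame
    taxon_scores: pd.DataFrame
    biplot_scores: pd.DataFrame        # covariate-axis correlations


def hellinger(rel: np.ndarray | pd.DataFrame):
    """Hellinger transform: square root of per-sample proportions."""
    return np.sqrt(rel)


def _names(obj, n, prefix):
    if isinstance(obj, pd.DataFrame):
        return list(obj.columns)
    return [f"{prefix}{i}" for i in range(n)]


def _sample_names(obj, n):
    if isinstance(obj, pd.DataFrame):
        return list(obj.index)
    return [f"s{i}" for i in range(n)]


def rda_fit(Y, X) -> RdaResult:
    """Fit an RDA of community matrix Y on covariates X.

    Y is column-centered and X standardized internally, so percent explained
    is invariant to rescaling any covariate.  Rank-deficient X raises an
    error naming the collinear columns.
    """
    y = np.asarray(Y, dtype=float)
    x = np.asarray(X, dtype=float)
    if y.ndim != 2 or x.ndim != 2 or y.shape[0] != x.shape[0]:
        raise ValueError("Y and X must be 2-D with matching sample rows")
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than covariates ({p})")
    x_names = _names(X, p, "x")
    taxon_names = _names(Y, y.shape[1], "taxon")
    sample_names = _sample_names(Y, n)

    yc = y - y.mean(axis=0)
    total_variance = float((yc**2).sum() / (n - 1))
    if total_variance == 0:
        raise ValueError("community matrix has no variance")

    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [x_names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant covariate column(s): {bad}")
    xs = (x - x.mean(axis=0)) / sd

    _, r, piv = linalg.qr(xs, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag[0] * max(n, p) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < p:
        bad = [x_names[i] for i in sorted(piv[rank:])]
        raise ValueError(f"collinear covariate column(s): {bad}")

    beta, *_ = np.linalg.lstsq(xs, yc, rcond=None)
    fitted = xs @ beta
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    eig = s**2 / (n - 1)
    n_axes = min(rank, y.shape[1], n - 1)
    keep = np.flatnonzero(eig > max(eig[0], 1.0) * 1e-12)[:n_axes]
    eig = eig[keep]
    trace = float((fitted**2).sum() / (n - 1))

    axes = [f"RDA{i + 1}" for i in range(len(keep))]
    scores = u[:, keep] * s[keep]
    sample_scores = pd.DataFrame(scores, index=sample_names, columns=axes)
    taxon_scores = pd.DataFrame(vt[keep].T, index=taxon_names, columns=axes)
    # biplot arrows: correlation of each standardized covariate with the axes
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.array(
            [
                [
                    np.corrcoef(xs[:, j], scores[:, a])[0, 1]
                    if scores[:, a].std() > 0
                    else 0.0
                    for a in range(len(keep))
                ]
                for j in range(p)
            ]
        )
    biplot = pd.DataFrame(np.nan_to_num(corr), index=x_names, columns=axes)

    return RdaResult(
        eigenvalues=eig,
        pct_total=100.0 * eig / total_variance,
        pct_constrained=100.0 * eig / eig.sum() if eig.sum() > 0 else eig * 0.0,
        trace=trace,
        total_variance=total_variance,
        sample_scores=sample_scores,
        taxon_scores=taxon_scores,
        biplot_scores=biplot,
    )


@dataclass
class PermutationTest:
    observed: float
    n_permutations: int
    p_value: float
    seed: int
    statistic: str


def _trace_stat(yc: np.ndarray, xs: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(xs, yc, rcond=None)
    return float(((xs @ beta) ** 2).sum())


def monte_carlo_test(
    Y, X, statistic: str = "trace", n_perm: int = 999, seed: int = 0
) -> PermutationTest:
    """Permutation test of the community–covariate association.

    Rows of X are permuted uniformly; the constrained trace (or the first
    constrained eigenvalue with ``statistic='axis1'``) is recomputed per
    permutation.  p = (1 + #{perm >= obs}) / (1 + n_perm), so p > 0 always.
    """
    if n_perm < 99:
        raise ValueError(f"need at least 99 permutations, got {n_perm}")
    if statistic not in ("trace", "axis1"):
        raise ValueError(f"unknown statistic {statistic!r}")
    y = np.asarray(Y, dtype=float)
    x = np.asarray(X, dtype=float)
    yc = y - y.mean(axis=0)
    if (yc**2).sum() == 0:
        raise ValueError("community matrix is constant")
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant covariate column")
    xs = (x - x.mean(axis=0)) / sd

    def stat(xmat: np.ndarray) -> float:
        if statistic == "trace":
            return _trace_stat(yc, xmat)
        beta, *_ = np.linalg.lstsq(xmat, yc, rcond=None)
        s = np.linalg.svd(xmat @ beta, compute_uv=False)
        return float(s[0] ** 2)

    observed = stat(xs)
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if stat(xs[perm]) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermutationTest(
        observed=observed, n_permutations=n_perm, p_value=p, seed=seed,
        statistic=statistic,
    )
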