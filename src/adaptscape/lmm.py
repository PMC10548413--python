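"""Kinship estimation and an exact spectral linear mixed model.

Model per marker: y = mu + x*beta + g + e with Var(g) = K*sigma_g^2 and
Var(e) = I*sigma_e^2.  K is eigendecomposed once; the variance ratio
delta = sigma_e^2 / sigma_g^2 is profiled by restricted maximum
likelihood on the intercept-only null model (log grid + golden-section
refinement) and
reused for every marker (the EMMAX/P3D approximation), which turns each
marker test into a two-parameter generalized least squares fit in the
rotated space with a Wald t test on n - 2 degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .io_formats import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class LmmScanResult:
    table: pd.DataFrame  # per marker: beta, se, p
    sigma_g2: float
    sigma_e2: float
    delta: float
    loglik: float


def kinship(M: np.ndarray, kind: str = "genotype") -> np.ndarray:
    """Standardized-crossproduct kinship from a samples x features matrix.

    Missing entries are mean-imputed per feature; zero-variance features
    are excluded; columns are standardized and K = Z Z^T / n_features,
    with negative eigenvalues clipped at zero to enforce PSD.  ``kind``
    only labels the provenance (genotype dosages or methylation levels).
    """
    M = np.asarray(M, dtype=float)
    col_mean = np.nanmean(M, axis=0)
    idx = np.where(np.isnan(M))
    if idx[0].size:
        M = M.copy()
        M[idx] = np.take(col_mean, idx[1])
    sd = M.std(axis=0, ddof=0)
    # tolerance guards against ~1e-17 round-off "variance" in columns
    # that are constant up to floating point
    usable = sd > 1e-12 * np.maximum(1.0, np.abs(col_mean))
    if usable.sum() < 2:
        raise ValidationError(
            f"kinship needs >= 2 variable features, got {int(usable.sum())}"
        )
    Z = (M[:, usable] - M[:, usable].mean(axis=0)) / sd[usable]
    K = Z @ Z.T / Z.shape[1]
    K = (K + K.T) / 2
    vals, vecs = np.linalg.eigh(K)
    if vals.min() < -1e-10:
        logger.info("clipping %d negative kinship eigenvalues",
                    int((vals < 0).sum()))
    vals = np.clip(vals, 0.0, None)
    return (vecs * vals) @ vecs.T


def _null_loglik(delta: float, uy: np.ndarray, uone: np.ndarray,
                 s: np.ndarray) -> float:
    """REML log-likelihood of the intercept-only model at ratio delta.

    REML (rather than raw ML) is required here: a kinship built from
    centered marker columns has the all-ones vector in its null space,
    and the ML profile diverges as delta -> 0 because the intercept
    absorbs that zero-variance direction exactly.  The restricted
    criterion cancels the offending terms and stays well behaved.
    """
    n = uy.size
    w = 1.0 / (s + delta)
    xwx = (w * uone * uone).sum()
    mu = (w * uone * uy).sum() / xwx
    rss = (w * (uy - mu * uone) ** 2).sum()
    if rss <= 0:
        return -np.inf
    df = n - 1
    sigma_g2 = rss / df
    return float(
        -0.5 * (
            df * np.log(2 * np.pi * sigma_g2)
            + np.log(s + delta).sum()
            + np.log(xwx)
            - np.log((uone * uone).sum())
            + df
        )
    )


def _profile_delta(uy: np.ndarray, uone: np.ndarray, s: np.ndarray,
                   n_grid: int = 100):
    """Grid + golden-section ML profile of delta on [1e-5, 1e5]."""

    def f(delta: float) -> float:
        return _null_loglik(delta, uy, uone, s)

    grid = np.logspace(-5, 5, n_grid)
    lls = np.asarray([f(d) for d in grid])
    i = int(np.argmax(lls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    # golden-section on log(delta)
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = np.log(lo), np.log(hi)
    c, d = b - gr * (b - a), a + gr * (b - a)
    fc, fd = f(np.exp(c)), f(np.exp(d))
    for _ in range(60):
        if b - a < 1e-8:
            break
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = f(np.exp(c))
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = f(np.exp(d))
    delta = float(np.exp((a + b) / 2))
    ll = f(delta)
    if lls[i] > ll:  # guard: keep the best grid point if refinement slipped
        delta, ll = float(grid[i]), float(lls[i])
    return delta, ll


def fit_lmm(
    y: np.ndarray,
    X_markers: np.ndarray,
    K: np.ndarray,
    marker_ids: list | None = None,
) -> LmmScanResult:
    """Kinship-corrected per-marker association scan.

    ``y`` is the response across samples (here a climate variable mapped
    to each sample's site), ``X_markers`` the samples x markers
    explanatory matrix (methylation levels or genotype dosages; missing
    values mean-imputed per marker).  Zero-variance markers get missing
    results.  Wald two-sided p on n - 2 df at the null-model delta.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X_markers, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = y.size
    if n < 4:
        raise ValidationError("fit_lmm needs at least 4 samples")
    if X.shape[0] != n or K.shape != (n, n):
        raise ValidationError("dimension mismatch between y, X_markers and K")

    col_mean = np.nanmean(X, axis=0)
    nan_ix = np.where(np.isnan(X))
    if nan_ix[0].size:
        X = X.copy()
        X[nan_ix] = np.take(col_mean, nan_ix[1])

    s, U = np.linalg.eigh((K + K.T) / 2)
    s = np.clip(s, 0.0, None)
    if (s < -1e-8).any():
        raise ValidationError("kinship matrix not PSD")
    uy = U.T @ y
    one = U.T @ np.ones(n)
    delta, ll = _profile_delta(uy, one, s)
    w = 1.0 / (s + delta)

    ux = U.T @ X
    # per-marker weighted 2-parameter regression, vectorized over markers
    S1y = (w * one * uy).sum()
    S11 = (w * one * one).sum()
    Sx1 = ux.T @ (w * one)
    Sxy = ux.T @ (w * uy)
    Sxx = (ux * ux[:, :] * w[:, None]).sum(axis=0)
    Syy = (w * uy * uy).sum()
    det = S11 * Sxx - Sx1**2
    var_marker = X.std(axis=0, ddof=0)
    degenerate = (var_marker == 0) | (det <= 1e-30)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = (S11 * Sxy - Sx1 * S1y) / det
        mu = (S1y - Sx1 * beta) / S11
        rss = Syy - mu * S1y - beta * Sxy
        sigma2 = np.clip(rss, 0, None) / (n - 2)
        se = np.sqrt(sigma2 * S11 / det)
        tval = beta / se
        p = 2.0 * t_dist.sf(np.abs(tval), df=n - 2)
    beta[degenerate] = np.nan
    se[degenerate] = np.nan
    p[degenerate] = np.nan
    if degenerate.any():
        logger.info("fit_lmm: %d zero-variance markers skipped",
                    int(degenerate.sum()))

    # null-model variance components at the fitted delta
    mu0 = (w * one * uy).sum() / (w * one * one).sum()
    sigma_g2 = float((w * (uy - mu0 * one) ** 2).sum() / n)
    ids = marker_ids if marker_ids is not None else list(range(X.shape[1]))
    table = pd.DataFrame(dict(marker=ids, beta=beta, se=se, p=p)).set_index(
        "marker"
    )
    return LmmScanResult(
        table=table, sigma_g2=sigma_g2, sigma_e2=float(sigma_g2 * delta),
        delta=delta, loglik=ll,
    )


def permutation_threshold(
    y: np.ndarray,
    X_markers: np.ndarray,
    K: np.ndarray,
    n_repeats: int = 200,
    subset_size: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> float:
    """Permutation-based genome-wide significance threshold.

    Each repeat draws ``subset_size`` markers without replacement,
    permutes the response across samples, runs the scan, and records the
    minimum p; the threshold is the empirical ``alpha`` quantile of the
    minima.  This is the small-sample alternative to Bonferroni, which
    is far too stringent when tests are correlated.
    """
    if n_repeats < 20:
        raise ValidationError("n_repeats < 20 gives an unstable quantile")
    X = np.asarray(X_markers, dtype=float)
    m = X.shape[1]
    if subset_size > m:
        logger.warning("subset_size %d clipped to %d markers", subset_size, m)
        subset_size = m
    rng = np.random.default_rng(seed)
    minima = np.empty(n_repeats)
    for rep in range(n_repeats):
        cols = rng.choice(m, size=subset_size, replace=False)
        perm = rng.permutation(y.size)
        res = fit_lmm(np.asarray(y)[perm], X[:, cols], K)
        minima[rep] = np.nanmin(res.table["p"].to_numpy())
    return float(np.quantile(minima, alpha))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha / m."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    return alpha / m
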