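"""Distance construction and (partial) Mantel permutation tests.

Isolation by distance compares linearized F_ST (F/(1-F)) with
log-transformed great-circle distance; isolation by environment uses
Euclidean distance on the leading principal components of standardized
bioclimatic variables while controlling for geography.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import ClimateTable, PopulationMap, ValidationError

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    partial: bool = False
    controlled: str | None = None


def geographic_distance(
    popmap: PopulationMap,
    log_transform: bool = False,
    populations: list[str] | None = None,
) -> np.ndarray:
    """Great-circle (haversine) distance matrix in km between sites.

    With ``log_transform`` the natural log is applied to off-diagonal
    entries (the diagonal stays 0); coincident sites then raise, since
    log 0 is undefined — jitter the coordinates or add an offset first.
    """
    pops = populations if populations is not None else list(popmap.sites)
    missing = [p for p in pops if p not in popmap.sites]
    if missing:
        raise ValidationError(f"no coordinates for populations {missing}")
    lonlat = np.asarray([popmap.sites[p][:2] for p in pops], dtype=float)
    lon = np.radians(lonlat[:, 0])[:, None]
    lat = np.radians(lonlat[:, 1])[:, None]
    dlon = lon - lon.T
    dlat = lat - lat.T
    a = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    np.fill_diagonal(d, 0.0)
    if log_transform:
        off = ~np.eye(len(pops), dtype=bool)
        if (d[off] <= 0).any():
            raise ValidationError(
                "coincident sites: log-distance undefined; jitter coordinates "
                "or add a positive offset"
            )
        d[off] = np.log(d[off])
    return d


def select_uncorrelated(climate: ClimateTable, r_max: float = 0.8) -> list[str]:
    """Greedy multicollinearity pruning at |Pearson r| < r_max.

    While any retained pair correlates at |r| >= r_max, the member of the
    worst pair with the larger mean absolute correlation to all other
    retained variables is dropped; ties keep the earlier column.
    """
    cols = list(climate.variables)
    if len(cols) < 2:
        return cols
    X = climate.values[cols].to_numpy(dtype=float)
    keep = list(range(len(cols)))
    while len(keep) > 1:
        R = np.corrcoef(X[:, keep], rowvar=False)
        np.fill_diagonal(R, 0.0)
        absR = np.abs(R)
        if absR.max() < r_max:
            break
        i, j = np.unravel_index(np.argmax(absR), absR.shape)
        mean_i = absR[i].sum() / (len(keep) - 1)
        mean_j = absR[j].sum() / (len(keep) - 1)
        # drop the more redundant variable; on a tie keep the earlier one
        drop = max(i, j) if np.isclose(mean_i, mean_j) else (i if mean_i > mean_j else j)
        del keep[drop]
    return [cols[i] for i in keep]


def environmental_distance(
    climate: ClimateTable, n_pc: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean distance on the first ``n_pc`` principal components.

    Variables are standardized to zero mean, unit variance (zero-variance
    variables dropped with a warning), the correlation matrix is
    eigendecomposed, and distances are taken on the leading scores.
    Returns (distance matrix, explained-variance fractions).
    """
    X = climate.values.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    drop = sd == 0
    if drop.any():
        logger.warning("dropping %d zero-variance climate variables",
                       int(drop.sum()))
        X = X[:, ~drop]
        sd = sd[~drop]
    if n_pc > X.shape[1]:
        raise ValidationError(f"n_pc={n_pc} exceeds {X.shape[1]} usable variables")
    Z = (X - X.mean(axis=0)) / sd
    C = Z.T @ Z / Z.shape[0]
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.clip(vals[order], 0, None), vecs[:, order]
    scores = Z @ vecs[:, :n_pc]
    explained = vals / vals.sum() if vals.sum() > 0 else vals
    diff = scores[:, None, :] - scores[None, :, :]
    D = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(D, 0.0)
    return D, explained


def _check_mantel_input(*mats: np.ndarray) -> int:
    n = mats[0].shape[0]
    for M in mats:
        if M.shape != (n, n):
            raise ValidationError("distance matrices must share dimensions")
        if not np.allclose(M, M.T) or not np.allclose(np.diag(M), 0):
            raise ValidationError("matrices must be symmetric with zero diagonal")
    if n < 4:
        raise ValidationError("need at least 4 sites for a Mantel test")
    return n


def _offdiag(M: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValidationError("degenerate distance matrix (zero variance)")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def mantel(
    A: np.ndarray,
    B: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
    two_sided: bool = False,
) -> MantelResult:
    """Mantel test: Pearson r of off-diagonal entries, permutation null.

    The null permutes rows and columns of B jointly; the one-sided
    (upper-tail) p is (1 + #{r_perm >= r_obs}) / (1 + n_perm).
    """
    A, B = np.asarray(A, float), np.asarray(B, float)
    n = _check_mantel_input(A, B)
    a = _offdiag(A)
    r_obs = _pearson(a, _offdiag(B))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = _pearson(a, _offdiag(B[np.ix_(perm, perm)]))
        if two_sided:
            hits += abs(r_p) >= abs(r_obs) - 1e-15
        else:
            hits += r_p >= r_obs - 1e-15
    p = (1 + hits) / (1 + n_perm)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm)


def partial_mantel(
    A: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
    two_sided: bool = False,
) -> MantelResult:
    """Partial Mantel: correlation of A and B residuals after regressing
    each on C; the null permutes rows/columns of A (raw-matrix scheme)."""
    A, B, C = (np.asarray(M, float) for M in (A, B, C))
    n = _check_mantel_input(A, B, C)
    c = _offdiag(C)
    b = _offdiag(B)
    if c.std() == 0:
        logger.warning("control matrix has zero variance; reduces to simple Mantel")
        res = mantel(A, B, n_perm=n_perm, seed=seed, two_sided=two_sided)
        return MantelResult(r=res.r, p=res.p, n_perm=n_perm, partial=True,
                            controlled="constant")

    def resid(y: np.ndarray) -> np.ndarray:
        slope = np.cov(c, y, ddof=0)[0, 1] / c.var()
        return y - (y.mean() + slope * (c - c.mean()))

    rb = resid(b)
    r_obs = _pearson(resid(_offdiag(A)), rb)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = _pearson(resid(_offdiag(A[np.ix_(perm, perm)])), rb)
        if two_sided:
            hits += abs(r_p) >= abs(r_obs) - 1e-15
        else:
            hits += r_p >= r_obs - 1e-15
    p = (1 + hits) / (1 + n_perm)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, partial=True,
                        controlled="C")
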