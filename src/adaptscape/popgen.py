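"""Per-population diversity, Weir–Cockerham differentiation and PCoA.

The differentiation estimator is the Weir & Cockerham (1984) method-of-
moments theta built from the three variance components *a* (among
populations), *b* (among individuals within populations) and *c* (within
individuals), combined across loci as a ratio of sums.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, PopulationMap, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class DiversityReport:
    """Per-population pi (per-SNP), observed heterozygosity and F_IS."""

    table: pd.DataFrame  # index population; columns n, pi, ho, fis


@dataclass
class FstMatrix:
    populations: list[str]
    theta: np.ndarray  # symmetric, zero diagonal, NaN where undefined
    global_theta: float

    def pair(self, a: str, b: str) -> float:
        i, j = self.populations.index(a), self.populations.index(b)
        return float(self.theta[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.theta, index=self.populations,
                            columns=self.populations)


def _pop_counts(G: GenotypeMatrix, popmap: PopulationMap):
    """Per-population sample sizes, allele frequencies and het fractions.

    Returns (pops, n, p, h): arrays of shape (r, L) for n (genotyped
    individuals), p (alternate-allele frequency) and h (observed
    heterozygote fraction); entries NaN/0 where a population has no call.
    """
    groups = popmap.indices(G.samples)
    pops = list(groups)
    L = G.n_loci
    n = np.zeros((len(pops), L))
    p = np.full((len(pops), L), np.nan)
    h = np.full((len(pops), L), np.nan)
    for k, pop in enumerate(pops):
        d = G.dosage[groups[pop], :]
        obs = d != MISSING
        nk = obs.sum(axis=0)
        n[k] = nk
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(obs, d, 0).sum(axis=0) / (2 * nk)
            h[k] = np.where(obs & (d == 1), 1, 0).sum(axis=0) / nk
    return pops, n, p, h


def diversity_stats(G: GenotypeMatrix, popmap: PopulationMap) -> DiversityReport:
    """Per-population per-SNP nucleotide diversity, H_O and F_IS.

    Per locus within a population with n genotyped diploids and allele
    frequency p: pi = 2pq * 2n/(2n-1) (unbiased), H_O = heterozygote
    fraction, H_E = 2pq.  pi and H_O are averaged over loci with at least
    one call; F_IS = 1 - mean(H_O)/mean(H_E) (ratio of means).
    """
    pops, n, p, h = _pop_counts(G, popmap)
    rows = []
    groups = popmap.indices(G.samples)
    for k, pop in enumerate(pops):
        ok = n[k] > 0
        if not ok.any():
            raise ValidationError(f"population {pop!r} has zero genotyped loci")
        nk, pk, hk = n[k][ok], p[k][ok], h[k][ok]
        he = 2 * pk * (1 - pk)
        pi = he * (2 * nk) / (2 * nk - 1)
        mean_he = float(he.mean())
        fis = 1.0 - float(hk.mean()) / mean_he if mean_he > 0 else np.nan
        rows.append(
            dict(population=pop, n=len(groups[pop]), pi=float(pi.mean()),
                 ho=float(hk.mean()), fis=fis)
        )
    table = pd.DataFrame(rows).set_index("population")
    return DiversityReport(table=table)


def _wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray):
    """Weir–Cockerham per-locus variance components for r populations.

    ``n``, ``p``, ``h`` are (r, L) arrays restricted to loci where every
    population has n > 0.  Returns (a, b, c) arrays of length L.
    """
    r = n.shape[0]
    nbar = n.mean(axis=0)
    nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1)
    pbar = (n * p).sum(axis=0) / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=0) / (r * nbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
    c = hbar / 2
    return a, b, c


def theta_from_counts(n: np.ndarray, p: np.ndarray, h: np.ndarray) -> float:
    """Multi-locus ratio-of-sums theta from per-population count arrays."""
    ok = (n > 0).all(axis=0)
    a, b, c = _wc_components(n[:, ok], p[:, ok], h[:, ok])
    denom = np.nansum(a + b + c)
    if denom == 0:
        return np.nan
    return float(np.nansum(a) / denom)


def per_locus_theta(n: np.ndarray, p: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Per-locus theta a/(a+b+c); NaN where the locus is undefined."""
    a, b, c = _wc_components(n, p, h)
    with np.errstate(invalid="ignore", divide="ignore"):
        th = a / (a + b + c)
    th[(n <= 0).any(axis=0)] = np.nan
    return th


def wc_fst(
    G: GenotypeMatrix,
    popmap: PopulationMap,
    pairs: list[tuple[str, str]] | None = None,
) -> FstMatrix:
    """Global and pairwise Weir–Cockerham theta.

    Pairwise entries use only loci with at least one call in both
    populations; pairs where every locus is skipped get NaN with a
    warning.
    """
    pops, n, p, h = _pop_counts(G, popmap)
    if len(pops) < 2:
        raise ValidationError("wc_fst needs at least two populations")
    global_theta = theta_from_counts(n, p, h)
    k = len(pops)
    theta = np.zeros((k, k))
    want = pairs if pairs is not None else [
        (pops[i], pops[j]) for i in range(k) for j in range(i + 1, k)
    ]
    for a_pop, b_pop in want:
        i, j = pops.index(a_pop), pops.index(b_pop)
        sel = np.asarray([i, j])
        ok = (n[sel] > 0).all(axis=0)
        if not ok.any():
            logger.warning("no shared loci for pair (%s, %s)", a_pop, b_pop)
            theta[i, j] = theta[j, i] = np.nan
            continue
        theta[i, j] = theta[j, i] = theta_from_counts(
            n[sel][:, ok], p[sel][:, ok], h[sel][:, ok]
        )
    return FstMatrix(populations=pops, theta=theta, global_theta=global_theta)


def linearized_fst(theta: np.ndarray) -> np.ndarray:
    """F/(1-F) transform; F >= 1 clamped just below the pole with a warning."""
    theta = np.asarray(theta, dtype=float)
    out = theta.copy()
    cap = 1.0 - 1e-12
    high = theta >= 1.0
    if high.any():
        logger.warning("clamping %d F_ST values >= 1 before linearizing",
                       int(high.sum()))
        out[high] = cap
    return out / (1.0 - out)


def allele_sharing_distance(G: GenotypeMatrix) -> np.ndarray:
    """Individual-level distance: 1 - proportion of shared alleles.

    Per pair, mean over loci typed in both of |d_i - d_j| / 2.
    """
    d = G.dosage.astype(float)
    d[G.dosage == MISSING] = np.nan
    n = G.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(d - d[i]) / 2.0
        out[i] = np.nanmean(diff, axis=1)
    np.fill_diagonal(out, 0.0)
    return (out + out.T) / 2.0


def pcoa(D: np.ndarray, k: int = 2):
    """Classical principal-coordinates analysis (Torgerson scaling).

    Double-centers -D**2/2, eigendecomposes, and returns coordinates on
    the top-k positive axes scaled by sqrt(eigenvalue), plus the full
    eigenvalue spectrum (negative eigenvalues reported, axes dropped).
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValidationError("distance matrix must be symmetric, zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    n_pos = int((vals > 1e-10).sum())
    if k > n_pos:
        logger.warning("pcoa: k=%d exceeds %d positive eigenvalues; truncated",
                       k, n_pos)
        k = n_pos
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    return coords, vals
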