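"""Simulation-null F_ST outlier scan conditioned on heterozygosity.

The scan follows the FDIST logic: simulate a neutral cloud of
(He, F_ST) pairs under an island model whose differentiation parameter is
calibrated to the observed data, bin the cloud by expected
heterozygosity, and flag observed loci whose F_ST sits in the extreme
upper tail of their He bin (divergent selection).  The neutral model is
the Balding–Nichols Beta approximation to island-model drift, which
reproduces the F_ST–heterozygosity relationship the test conditions on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import trim_mean

from .io_formats import GenotypeMatrix, PopulationMap, ValidationError
from .popgen import _pop_counts, per_locus_theta

logger = logging.getLogger(__name__)


@dataclass
class NullCloud:
    he: np.ndarray
    fst: np.ndarray
    F: float
    seed: int | None = None


@dataclass
class OutlierReport:
    table: pd.DataFrame  # columns he, fst, p_upper, q, flagged
    confidence: float
    n_bins: int

    @property
    def flagged_ids(self) -> list[int]:
        return list(self.table.index[self.table["flagged"]])


@dataclass
class CalibrationResult:
    F: float
    observed_mean: float
    trace: list[tuple[float, float]] = field(default_factory=list)


def observed_locus_stats(
    G: GenotypeMatrix, popmap: PopulationMap
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (He, theta) from observed genotypes.

    He is the sample-size-weighted mean-frequency expected heterozygosity
    2*pbar*(1-pbar); theta is the per-locus Weir–Cockerham ratio.
    """
    _, n, p, h = _pop_counts(G, popmap)
    tot = n.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = (n * p).sum(axis=0) / tot
    he = 2 * pbar * (1 - pbar)
    fst = per_locus_theta(n, p, h)
    return he, fst


def simulate_null(
    F: float,
    sample_sizes: list[int],
    n_loci: int,
    seed: int | None = None,
    chunk: int = 200_000,
) -> NullCloud:
    """Neutral (He, F_ST) cloud under the Balding–Nichols island model.

    Ancestral p ~ U(0.01, 0.99); per-population frequencies Beta with
    parameter F; genotype class counts sampled binomially at the observed
    sample sizes; per-locus Weir–Cockerham theta and weighted He.
    """
    if not 0.0 < F < 1.0:
        raise ValidationError(f"F must be in (0, 1), got {F}")
    sizes = np.asarray(sample_sizes, dtype=float)
    r = sizes.size
    rng = np.random.default_rng(seed)
    he_parts, fst_parts = [], []
    remaining = n_loci
    scale = (1.0 - F) / F
    while remaining > 0:
        L = min(chunk, remaining)
        remaining -= L
        p_anc = rng.uniform(0.01, 0.99, L)
        q = rng.beta(
            np.broadcast_to(p_anc * scale, (r, L)),
            np.broadcast_to((1.0 - p_anc) * scale, (r, L)),
        )
        n_ind = np.broadcast_to(sizes[:, None], (r, L)).astype(int)
        # genotype class counts: hom-alt then het among the rest
        n_hom = rng.binomial(n_ind, q**2)
        denom = 1.0 - q**2
        with np.errstate(invalid="ignore", divide="ignore"):
            p_het = np.where(denom > 0, 2 * q * (1 - q) / denom, 0.0)
        n_het = rng.binomial(n_ind - n_hom, np.clip(p_het, 0.0, 1.0))
        n_mat = n_ind.astype(float)
        p_mat = (2 * n_hom + n_het) / (2 * n_mat)
        h_mat = n_het / n_mat
        tot = n_mat.sum(axis=0)
        pbar = (n_mat * p_mat).sum(axis=0) / tot
        he_parts.append(2 * pbar * (1 - pbar))
        fst_parts.append(per_locus_theta(n_mat, p_mat, h_mat))
    return NullCloud(
        he=np.concatenate(he_parts), fst=np.concatenate(fst_parts), F=F,
        seed=seed,
    )


def calibrate_null(
    G: GenotypeMatrix,
    popmap: PopulationMap,
    trim: float = 0.05,
    n_loci: int = 10_000,
    tol: float = 0.005,
    max_iter: int = 30,
    seed: int | None = 0,
) -> CalibrationResult:
    """Bisection on the island-model F matching the observed mean theta.

    The target is the observed trimmed mean of per-locus theta (``trim``
    fraction removed per tail); each candidate F is scored by the same
    trimmed mean over ``n_loci`` simulated loci at the observed sample
    sizes (fixed seed, so the objective is a smooth function of F).
    """
    _, n, p, h = _pop_counts(G, popmap)
    obs = per_locus_theta(n, p, h)
    obs = obs[np.isfinite(obs)]
    target = float(trim_mean(obs, trim))
    sizes = [int(round(x)) for x in n.mean(axis=1)]

    def score(F: float) -> float:
        cloud = simulate_null(F, sizes, n_loci, seed=seed)
        fst = cloud.fst[np.isfinite(cloud.fst)]
        return float(trim_mean(fst, trim))

    lo, hi = 1e-4, 0.95
    trace: list[tuple[float, float]] = []
    s_lo, s_hi = score(lo), score(hi)
    if target <= s_lo:
        return CalibrationResult(F=lo, observed_mean=target, trace=[(lo, s_lo)])
    if target >= s_hi:
        return CalibrationResult(F=hi, observed_mean=target, trace=[(hi, s_hi)])
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        s = score(mid)
        trace.append((mid, s))
        if abs(s - target) < tol:
            return CalibrationResult(F=mid, observed_mean=target, trace=trace)
        if s < target:
            lo = mid
        else:
            hi = mid
    raise ValidationError(
        f"calibration did not converge in {max_iter} iterations; trace={trace}"
    )


def adjust_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fdist_outliers(
    obs_he: np.ndarray,
    obs_fst: np.ndarray,
    null: NullCloud,
    confidence: float = 0.99,
    n_bins: int = 20,
    two_tailed: bool = False,
) -> OutlierReport:
    """Flag loci whose F_ST exceeds the neutral envelope at matched He.

    The null cloud is split into ``n_bins`` equal-count He bins; each
    observed locus gets an empirical upper-tail probability
    (1 + #{null theta in bin >= obs theta}) / (1 + bin count) against its
    bin, is flagged when that probability is <= 1 - confidence (upper
    tail only by default), and receives a BH q-value.
    """
    obs_he = np.asarray(obs_he, float)
    obs_fst = np.asarray(obs_fst, float)
    ok_null = np.isfinite(null.he) & np.isfinite(null.fst)
    nh, nf = null.he[ok_null], null.fst[ok_null]
    edges = np.quantile(nh, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    null_bin = np.clip(np.searchsorted(edges, nh, side="right") - 1, 0, n_bins - 1)
    outside = (obs_he < np.quantile(nh, 0)) | (obs_he > np.quantile(nh, 1))
    if outside.any():
        logger.warning("%d observed loci outside simulated He range; "
                       "nearest bin used", int(outside.sum()))
    obs_bin = np.clip(np.searchsorted(edges, obs_he, side="right") - 1, 0,
                      n_bins - 1)

    p_upper = np.full(obs_fst.size, np.nan)
    for b in range(n_bins):
        in_bin = null_bin == b
        vals = np.sort(nf[in_bin])
        m = vals.size
        sel = obs_bin == b
        if m == 0 or not sel.any():
            continue
        ge = m - np.searchsorted(vals, obs_fst[sel] - 1e-15, side="left")
        p_upper[sel] = (1 + ge) / (1 + m)
    finite = np.isfinite(obs_fst) & np.isfinite(p_upper)
    p_for_q = np.where(finite, p_upper, 1.0)
    q = adjust_fdr(p_for_q)
    alpha = 1.0 - confidence
    thr = alpha / 2 if two_tailed else alpha
    flagged = finite & (p_upper <= thr)
    table = pd.DataFrame(
        dict(he=obs_he, fst=obs_fst, p_upper=p_upper, q=q, flagged=flagged)
    )
    return OutlierReport(table=table, confidence=confidence, n_bins=n_bins)


def intersect_outliers(sets: dict[str, set]) -> dict:
    """Union, k-way intersection and the intersection percentage.

    Returns per-set counts, |union|, |intersection| and
    100 * |intersection| / |union| rounded to one decimal.
    """
    if len(sets) < 2:
        raise ValidationError("need at least two outlier sets")
    named = {k: set(v) for k, v in sets.items()}
    union = set.union(*named.values())
    if not union:
        raise ValidationError("union of outlier sets is empty")
    inter = set.intersection(*named.values())
    return dict(
        per_set={k: len(v) for k, v in named.items()},
        union=len(union),
        intersection=len(inter),
        percent=round(100.0 * len(inter) / len(union), 1),
        intersection_ids=sorted(inter, key=str),
    )
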