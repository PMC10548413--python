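"""Frequency-based ABBA-BABA (Patterson's D) with block-jackknife errors.

For a trio (P1, P2, P3) with derived-allele frequencies p1, p2, p3 per
locus and the outgroup fixed ancestral, each locus contributes
``abba = (1-p1) * p2 * p3`` and ``baba = p1 * (1-p2) * p3``;
``D = (sum abba - sum baba) / (sum abba + sum baba)``.  Standard errors
come from a delete-one jackknife over contiguous locus blocks and
``Z = D / se``; gene flow between P2 and P3 pushes D above zero.  The
Dmin variant takes the trio arrangement with the smallest |D|, a
topology-agnostic lower bound on the introgression signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import MISSING, GenotypeMatrix, PopulationMap, ValidationError


@dataclass
class DStatResult:
    trio: tuple[str, str, str]
    n_abba: float
    n_baba: float
    d: float
    se: float
    z: float
    n_blocks: int
    polarization: str = "global-minor-derived"

    @property
    def significant(self) -> bool:
        return abs(self.z) >= 3.0


def population_frequencies(
    G: GenotypeMatrix,
    popmap: PopulationMap,
    outgroup: str | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Derived-allele frequency per population per locus.

    With an outgroup population, the outgroup's major allele is taken as
    ancestral; otherwise the global minor allele is declared derived.
    Returns (freqs (n_pops, n_loci), population order); the outgroup row
    is excluded from the returned matrix.
    """
    groups = popmap.indices(G.samples)
    pops = list(groups)
    n = np.zeros((len(pops), G.n_loci))
    p = np.zeros((len(pops), G.n_loci))
    for k, pop in enumerate(pops):
        d = G.dosage[groups[pop], :]
        obs = d != MISSING
        nk = obs.sum(axis=0)
        n[k] = nk
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(obs, d, 0).sum(axis=0) / (2 * nk)
    p = np.nan_to_num(p, nan=0.0)
    if outgroup is not None:
        if outgroup not in pops:
            raise ValidationError(f"outgroup {outgroup!r} not in population map")
        og = p[pops.index(outgroup)]
        flip = og > 0.5  # outgroup major allele is ancestral
        keep = [k for k, pop in enumerate(pops) if pop != outgroup]
        p = p[keep]
        pops = [pops[k] for k in keep]
    else:
        tot = (n * p).sum(axis=0)
        counts = n.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            global_af = np.where(counts > 0, tot / counts, 0.0)
        flip = global_af > 0.5
    p[:, flip] = 1.0 - p[:, flip]
    return p, pops


def _jackknife(num: np.ndarray, den: np.ndarray, block_size: int):
    """Ratio-of-sums D with delete-one block jackknife se.

    ``num`` = abba - baba and ``den`` = abba + baba per locus.
    """
    L = num.size
    n_blocks = int(np.ceil(L / block_size))
    if n_blocks < 2:
        raise ValidationError("need at least 2 jackknife blocks")
    tot_num, tot_den = num.sum(), den.sum()
    if tot_den == 0:
        raise ValidationError("D undefined: no ABBA/BABA weight at any locus")
    d = tot_num / tot_den
    loo = np.empty(n_blocks)
    for b in range(n_blocks):
        sl = slice(b * block_size, min((b + 1) * block_size, L))
        dn = tot_den - den[sl].sum()
        loo[b] = (tot_num - num[sl].sum()) / dn if dn != 0 else d
    se = float(np.sqrt((n_blocks - 1) / n_blocks * ((loo - loo.mean()) ** 2).sum()))
    return d, se, n_blocks


def abba_baba(
    freqs: np.ndarray,
    pop_order: list[str],
    trio: tuple[str, str, str],
    block_size: int | None = None,
) -> DStatResult:
    """Patterson's D for one trio from per-population derived frequencies.

    ``block_size`` defaults to about a twentieth of the loci (>= 1), so
    the jackknife uses ~20 contiguous blocks.
    """
    for pop in trio:
        if pop not in pop_order:
            raise ValidationError(f"population {pop!r} absent from frequencies")
    p1, p2, p3 = (freqs[pop_order.index(pop)] for pop in trio)
    abba = (1.0 - p1) * p2 * p3
    baba = p1 * (1.0 - p2) * p3
    if block_size is None:
        block_size = max(1, int(np.ceil(p1.size / 20)))
    d, se, n_blocks = _jackknife(abba - baba, abba + baba, block_size)
    z = d / se if se > 0 else np.inf * np.sign(d) if d != 0 else 0.0
    return DStatResult(
        trio=tuple(trio), n_abba=float(abba.sum()), n_baba=float(baba.sum()),
        d=float(d), se=se, z=float(z), n_blocks=n_blocks,
    )


def dmin(
    freqs: np.ndarray,
    pop_order: list[str],
    trio: tuple[str, str, str],
    block_size: int | None = None,
) -> DStatResult:
    """Minimum-|D| arrangement of the trio, topology-agnostic.

    The three arrangements tested are (P1,P2;P3), (P1,P3;P2), (P2,P3;P1);
    ties keep the earliest arrangement in that canonical order.
    """
    a, b, c = trio
    arrangements = [(a, b, c), (a, c, b), (b, c, a)]
    results = [abba_baba(freqs, pop_order, t, block_size) for t in arrangements]
    best = min(range(3), key=lambda i: (abs(results[i].d), i))
    return results[best]
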