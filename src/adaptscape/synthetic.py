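"""Synthetic landscape, genotype and methylation generators.

These generators reproduce the statistical structure the downstream
analyses assume — an island-model neutral background with Balding–Nichols
per-population allele frequencies, climate-clinal adaptive loci, and a
logit-normal methylation matrix with a spatially structured population
random effect — so the whole pipeline is testable at desk scale without
any sequencing data.  All generators are pure functions of (spec, seed).

Default dimensions mirror a typical range-wide RADseq design: 13
populations of 12 diploids genotyped at thousands of SNPs across five
bioclimatic variables (BIO2, BIO4, BIO8, BIO16, BIO19), with one
bisulfite-sequenced individual per population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io_formats import (
    MISSING,
    ClimateTable,
    GenotypeMatrix,
    MethylationTable,
    PopulationMap,
    ValidationError,
)

DEFAULT_VARIABLES = ("BIO2", "BIO4", "BIO8", "BIO16", "BIO19")

#: linear trend of each default variable on (lon, lat) plus site noise sd,
#: in natural units (deg C * 10 / mm), loosely emulating subtropical China
DEFAULT_GRADIENTS = {
    "BIO2": ((2.0, -1.0), 3.0),
    "BIO4": ((-8.0, 25.0), 30.0),
    "BIO8": ((3.0, -6.0), 8.0),
    "BIO16": ((35.0, -20.0), 60.0),
    "BIO19": ((20.0, -30.0), 40.0),
}

DEFAULT_BASELINES = {
    "BIO2": 80.0,
    "BIO4": 6500.0,
    "BIO8": 250.0,
    "BIO16": 700.0,
    "BIO19": 120.0,
}

#: per-variable displacement applied to the future scenario (warmer, with
#: redistributed rainfall), scaled by the RCP severity factor
DEFAULT_DISPLACEMENT = {
    "BIO2": 4.0,
    "BIO4": 150.0,
    "BIO8": 20.0,
    "BIO16": -60.0,
    "BIO19": -25.0,
}


@dataclass
class LandscapeSpec:
    """Design of one synthetic landscape-genomics study."""

    n_pops: int = 13
    n_per_pop: int = 12
    coords: list[tuple[float, float]] | None = None
    climate_gradient: dict = field(
        default_factory=lambda: dict(DEFAULT_GRADIENTS)
    )
    fst_target: float = 0.19
    n_neutral: int = 5000
    n_adaptive: int = 50
    cline_strength: float = 1.5
    driver_variable: str = "BIO16"
    missing_rate: float = 0.0
    admixture: tuple[str, str, float] | None = None  # (source, target, f)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 2:
            raise ValidationError("need at least two populations")
        if not 0.0 < self.fst_target < 1.0:
            raise ValidationError("fst_target must be in (0, 1)")
        if not np.isfinite(self.cline_strength):
            raise ValidationError("cline_strength must be finite")
        if self.coords is None:
            # sites spread along a SW-NE axis with jitter, like a species
            # range across subtropical China
            rng = np.random.default_rng(self.seed + 10_007)
            lon = np.linspace(107.0, 120.0, self.n_pops)
            lat = 24.0 + 0.35 * (lon - 107.0) + rng.normal(0, 0.8, self.n_pops)
            self.coords = list(zip(lon.round(4), lat.round(4)))
        if len(self.coords) != self.n_pops:
            raise ValidationError("coords length must equal n_pops")


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests."""

    adaptive_locus_ids: list[int] = field(default_factory=list)
    driver_variable: str | None = None
    smv_assoc_ids: list[int] = field(default_factory=list)
    smv_driver_variable: str | None = None
    pop_frequencies: np.ndarray | None = None  # (n_pops, n_loci)
    sigma_g2: float | None = None
    sigma_e2: float | None = None


def _pop_codes(n: int) -> list[str]:
    return [f"P{i + 1:02d}" for i in range(n)]


def simulate_landscape(
    spec: LandscapeSpec, rcp_factor: float = 1.0, scenario: str = "future"
) -> tuple[PopulationMap, ClimateTable, ClimateTable]:
    """Sites, current climate (linear spatial trend + site noise) and a
    future table shifted by a fixed per-variable displacement times
    ``rcp_factor``."""
    rng = np.random.default_rng(spec.seed)
    pops = _pop_codes(spec.n_pops)
    assignments = {
        f"{pop}_{j + 1:02d}": pop
        for pop in pops
        for j in range(spec.n_per_pop)
    }
    alt = rng.uniform(150, 1200, spec.n_pops).round(0)
    sites = {
        pop: (float(lon), float(lat), float(a))
        for pop, (lon, lat), a in zip(pops, spec.coords, alt)
    }
    popmap = PopulationMap(assignments=assignments, sites=sites)

    lon = np.asarray([c[0] for c in spec.coords])
    lat = np.asarray([c[1] for c in spec.coords])
    lon0, lat0 = lon.mean(), lat.mean()
    data = {}
    for var, ((g_lon, g_lat), noise) in spec.climate_gradient.items():
        base = DEFAULT_BASELINES.get(var, 0.0)
        data[var] = (
            base
            + g_lon * (lon - lon0)
            + g_lat * (lat - lat0)
            + rng.normal(0.0, noise, spec.n_pops)
        )
    current = ClimateTable(
        scenario="current", values=pd.DataFrame(data, index=pops)
    )
    fut = current.values.copy()
    for var in fut.columns:
        fut[var] = fut[var] + rcp_factor * DEFAULT_DISPLACEMENT.get(var, 0.0)
    future = ClimateTable(scenario=scenario, values=fut)
    return popmap, current, future


def _balding_nichols(
    rng: np.random.Generator, p_anc: np.ndarray, F: float, n_pops: int
) -> np.ndarray:
    """Per-population frequencies ~ Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    scale = (1.0 - F) / F
    return rng.beta(
        np.broadcast_to(p_anc * scale, (n_pops, p_anc.size)),
        np.broadcast_to((1.0 - p_anc) * scale, (n_pops, p_anc.size)),
    )


def simulate_genotypes(
    spec: LandscapeSpec,
    popmap: PopulationMap,
    climate: ClimateTable,
) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Genotypes under an island-model neutral background plus clinal loci.

    Neutral loci: ancestral frequency ~ U(0.05, 0.95), per-population
    frequency Balding–Nichols at F = ``fst_target``.  Adaptive loci:
    per-population frequency = logistic(a + cline_strength * z) with z the
    standardized driver variable.  Genotypes ~ Binomial(2, freq) per
    individual; optional uniform missingness; optional one-way admixture
    pulse mixing fraction f of a source population's frequencies into a
    target population (for introgression power tests).
    """
    pops = [p for p in _pop_codes(spec.n_pops) if p in climate.sites]
    if len(pops) != spec.n_pops:
        raise ValidationError("climate table does not cover all populations")
    rng = np.random.default_rng(spec.seed + 1)
    n_pops = spec.n_pops

    p_anc = rng.uniform(0.05, 0.95, spec.n_neutral)
    freq_neutral = _balding_nichols(rng, p_anc, spec.fst_target, n_pops)

    freq_adaptive = np.empty((n_pops, spec.n_adaptive))
    if spec.n_adaptive > 0:
        if spec.driver_variable not in climate.variables:
            raise ValidationError(
                f"driver variable {spec.driver_variable!r} not in climate table"
            )
        z = climate.values.loc[pops, spec.driver_variable].to_numpy()
        z = (z - z.mean()) / z.std()
        for j in range(spec.n_adaptive):
            for attempt in range(100):
                a = rng.normal(0.0, 0.8)
                f = expit(a + spec.cline_strength * z)
                if spec.cline_strength == 0.0:
                    # degenerate cline: fall back to the neutral model so the
                    # locus is statistically indistinguishable from background
                    f = _balding_nichols(
                        rng, rng.uniform(0.05, 0.95, 1), spec.fst_target, n_pops
                    )[:, 0]
                if 0.0 < f.mean() < 1.0 and f.std() > 0:
                    freq_adaptive[:, j] = f
                    break
            else:
                raise ValidationError(
                    f"adaptive locus {j} fixed in all populations after 100 tries"
                )

    freqs = np.concatenate([freq_neutral, freq_adaptive], axis=1)
    if spec.admixture is not None:
        src, tgt, f_mix = spec.admixture
        i_src, i_tgt = pops.index(src), pops.index(tgt)
        freqs[i_tgt] = (1.0 - f_mix) * freqs[i_tgt] + f_mix * freqs[i_src]

    n_loci = freqs.shape[1]
    samples = [s for s in popmap.assignments if popmap.assignments[s] in pops]
    pop_of = np.asarray([pops.index(popmap.assignments[s]) for s in samples])
    dosage = rng.binomial(2, freqs[pop_of, :]).astype(np.int8)
    if spec.missing_rate > 0:
        mask = rng.random(dosage.shape) < spec.missing_rate
        dosage[mask] = MISSING

    loci = [("chr1", i * 100) for i in range(n_loci)]
    G = GenotypeMatrix(samples=samples, loci=loci, dosage=dosage)
    truth = SyntheticTruth(
        adaptive_locus_ids=list(range(spec.n_neutral, n_loci)),
        driver_variable=spec.driver_variable if spec.n_adaptive else None,
        pop_frequencies=freqs,
    )
    return G, truth


def _spatial_kinship(popmap: PopulationMap, pops: list[str],
                     range_km: float = 500.0) -> np.ndarray:
    """Exponential-decay covariance over great-circle distance."""
    from .landscape import geographic_distance

    D = geographic_distance(popmap, log_transform=False, populations=pops)
    return np.exp(-D / range_km)


def simulate_methylation(
    spec: LandscapeSpec,
    popmap: PopulationMap,
    climate: ClimateTable,
    n_sites: int = 2000,
    n_assoc: int = 20,
    effect: float = 1.0,
    noise_sd: float = 0.5,
    sigma_g: float = 0.7,
    mean_depth: float = 10.0,
    depth_dispersion: float = 5.0,
    samples_per_pop: int = 1,
    driver_variable: str | None = None,
) -> tuple[MethylationTable, SyntheticTruth]:
    """Methylation proportions with a spatially structured random effect.

    Latent logit-scale model per site: baseline + population effect drawn
    from MVN(0, sigma_g**2 * K_spatial) + individual noise; associated
    sites add ``effect`` times the standardized driver variable.  Depth is
    negative-binomial; the observed level is Binomial(depth, prop)/depth,
    missing where depth is 0.
    """
    if n_assoc > n_sites:
        raise ValidationError("n_assoc cannot exceed n_sites")
    driver = driver_variable or spec.driver_variable
    if driver not in climate.variables:
        raise ValidationError(f"driver variable {driver!r} not in climate table")
    rng = np.random.default_rng(spec.seed + 2)
    pops = list(climate.sites)
    n_ind = len(pops) * samples_per_pop
    samples = [
        f"{pop}_M{j + 1}" for pop in pops for j in range(samples_per_pop)
    ]
    pop_of = np.repeat(np.arange(len(pops)), samples_per_pop)
    for s, k in zip(samples, pop_of):
        popmap.assignments.setdefault(s, pops[k])

    K = _spatial_kinship(popmap, pops)
    Lk = np.linalg.cholesky(K + 1e-9 * np.eye(len(pops)))
    z = climate.values.loc[pops, driver].to_numpy()
    z = (z - z.mean()) / z.std()

    baseline = rng.normal(logit(0.2), 1.0, n_sites)
    u = sigma_g * (Lk @ rng.standard_normal((len(pops), n_sites)))
    assoc = np.zeros(n_sites)
    assoc_ids = list(rng.choice(n_sites, size=n_assoc, replace=False)) if n_assoc else []
    assoc[assoc_ids] = effect
    latent = (
        baseline[None, :]
        + u[pop_of, :]
        + assoc[None, :] * z[pop_of, None]
        + rng.normal(0.0, noise_sd, (n_ind, n_sites))
    )
    prop = expit(latent)

    if mean_depth <= 0:
        depth = np.zeros((n_ind, n_sites), dtype=int)
    else:
        p_nb = depth_dispersion / (depth_dispersion + mean_depth)
        depth = rng.negative_binomial(depth_dispersion, p_nb, (n_ind, n_sites))
    meth_reads = rng.binomial(depth, prop)
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(depth > 0, meth_reads / np.maximum(depth, 1), np.nan)

    contexts = rng.choice(METH_CONTEXT_POOL, size=n_sites,
                          p=(0.5, 0.3, 0.2))
    sites = [(f"scaf_{j // 200 + 1}", (j % 200) * 50 + 10, contexts[j])
             for j in range(n_sites)]
    table = MethylationTable(samples=samples, sites=sites, level=level,
                             depth=depth)
    truth = SyntheticTruth(
        smv_assoc_ids=sorted(int(i) for i in assoc_ids),
        smv_driver_variable=driver if n_assoc else None,
        sigma_g2=sigma_g**2,
        sigma_e2=noise_sd**2,
    )
    return table, truth


METH_CONTEXT_POOL = ("CpG", "CHG", "CHH")
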