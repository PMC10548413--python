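"""SMV calling, methylation/genotype climate-association scans and
feature-proximity annotation.

A single-methylation variant (SMV) is a cytosine position whose
methylation proportion varies across individuals past missingness and
range filters (default: <= 10% missing, range of observed levels >= 10
percentage points).  Both scans use the kinship-corrected mixed model in
:mod:`adaptscape.lmm`, with the climate variable as the response and the
marker (methylation level or genotype dosage) as the explanatory
variable, so that spatially structured relatedness does not masquerade
as climate association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    MISSING,
    ClimateTable,
    FeatureTable,
    GenotypeMatrix,
    MethylationTable,
    PopulationMap,
    ValidationError,
)
from .lmm import fit_lmm, kinship
from .outliers import adjust_fdr

logger = logging.getLogger(__name__)


@dataclass
class SmvMatrix:
    samples: list[str]
    sites: list[tuple[str, int, str]]
    level: np.ndarray  # samples x retained sites, NaN = missing
    filter_log: dict[str, int] = field(default_factory=dict)
    site_ids: list[int] = field(default_factory=list)  # indices into input

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class AssociationHit:
    marker: object
    variable: str
    beta: float
    p: float
    significant: bool
    features: list[tuple[str, int]] = field(default_factory=list)


def call_smvs(
    meth: MethylationTable,
    max_missing: float = 0.10,
    min_range: float = 0.10,
    min_depth: int = 1,
) -> SmvMatrix:
    """Filter cytosine sites into an SMV matrix.

    Rules in order: levels at depth < ``min_depth`` set missing; sites
    with missing fraction > ``max_missing`` dropped; sites whose observed
    level range (max - min) < ``min_range`` dropped.  The filter log
    counts removals per rule.
    """
    for name, thr in (("max_missing", max_missing), ("min_range", min_range)):
        if not 0.0 <= thr <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1]")
    level = meth.level.copy()
    level[meth.depth < min_depth] = np.nan
    n_samples = len(meth.samples)
    miss_frac = np.isnan(level).sum(axis=0) / n_samples
    keep_miss = miss_frac <= max_missing
    with np.errstate(all="ignore"):
        rng = np.nanmax(level, axis=0) - np.nanmin(level, axis=0)
    rng = np.nan_to_num(rng, nan=0.0)
    keep_range = rng >= min_range
    keep = keep_miss & keep_range
    log = {
        "input": meth.n_sites,
        "missing": int((~keep_miss).sum()),
        "range": int((keep_miss & ~keep_range).sum()),
        "kept": int(keep.sum()),
    }
    logger.info("call_smvs: %s", log)
    if not keep.any():
        raise ValidationError(f"no SMV survives the filters ({log})")
    ids = list(np.where(keep)[0])
    return SmvMatrix(
        samples=list(meth.samples),
        sites=[meth.sites[i] for i in ids],
        level=level[:, keep],
        filter_log=log,
        site_ids=[int(i) for i in ids],
    )


def _response_vector(
    samples: list[str], popmap: PopulationMap, climate: ClimateTable,
    variable: str,
) -> np.ndarray:
    if variable not in climate.variables:
        raise ValidationError(f"variable {variable!r} absent from climate table")
    vals = climate.values[variable]
    y = np.empty(len(samples))
    for i, s in enumerate(samples):
        pop = popmap.assignments.get(s)
        if pop is None or pop not in vals.index:
            raise ValidationError(f"no climate row for sample {s!r}")
        y[i] = vals.loc[pop]
    return y


def ewas_scan(
    smvs: SmvMatrix,
    climate: ClimateTable,
    popmap: PopulationMap,
    variables: list[str] | None = None,
    thresholds: dict[str, float] | None = None,
    K: np.ndarray | None = None,
) -> tuple[list[AssociationHit], pd.DataFrame]:
    """Methylation-by-climate EWAS with per-variable thresholds.

    Kinship defaults to the methylation-based estimate from the SMV
    matrix itself.  ``thresholds`` maps variable name to the permutation
    p-value threshold; markers at or below it are significant.  Returns
    (hits, full per-variable scan table).
    """
    variables = variables or climate.variables
    thresholds = thresholds or {}
    if K is None:
        K = kinship(smvs.level, kind="methylation")
    hits: list[AssociationHit] = []
    frames = []
    marker_ids = [f"{c}:{p + 1}" for c, p, _ctx in smvs.sites]
    for var in variables:
        y = _response_vector(smvs.samples, popmap, climate, var)
        res = fit_lmm(y, smvs.level, K, marker_ids=marker_ids)
        thr = thresholds.get(var, 0.0)
        tab = res.table.assign(variable=var, threshold=thr)
        tab["significant"] = tab["p"] <= thr
        frames.append(tab)
        for marker, row in tab[tab["significant"]].iterrows():
            hits.append(AssociationHit(marker=marker, variable=var,
                                       beta=row["beta"], p=row["p"],
                                       significant=True))
    scan = pd.concat(frames).reset_index()
    return hits, scan


def gea_scan(
    G: GenotypeMatrix,
    climate: ClimateTable,
    popmap: PopulationMap,
    variables: list[str] | None = None,
    correction: str = "fdr",
    q_max: float = 0.05,
    thresholds: dict[str, float] | None = None,
    K: np.ndarray | None = None,
) -> tuple[list[AssociationHit], pd.DataFrame]:
    """Genotype-by-climate association scan (LMM-GEA).

    Kinship comes from the genotypes.  Significance is BH q <= ``q_max``
    per variable (``correction='fdr'``, default) or a per-variable
    permutation threshold (``correction='permutation'``).  Returns
    (hits, per-variable scan table with the multi-variable overlap
    recoverable from it).
    """
    if correction not in ("fdr", "permutation"):
        raise ValidationError(f"unknown correction {correction!r}")
    variables = variables or climate.variables
    dosage = G.dosage.astype(float)
    dosage[G.dosage == MISSING] = np.nan
    if K is None:
        K = kinship(dosage, kind="genotype")
    hits: list[AssociationHit] = []
    frames = []
    for var in variables:
        y = _response_vector(G.samples, popmap, climate, var)
        res = fit_lmm(y, dosage, K, marker_ids=list(range(G.n_loci)))
        tab = res.table.assign(variable=var)
        p = tab["p"].to_numpy()
        if correction == "fdr":
            q = adjust_fdr(np.where(np.isfinite(p), p, 1.0))
            tab["q"] = q
            tab["significant"] = np.isfinite(p) & (q <= q_max)
        else:
            thr = (thresholds or {}).get(var, 0.0)
            tab["q"] = np.nan
            tab["significant"] = np.isfinite(p) & (p <= thr)
        frames.append(tab)
        for marker, row in tab[tab["significant"]].iterrows():
            hits.append(AssociationHit(marker=marker, variable=var,
                                       beta=row["beta"], p=row["p"],
                                       significant=True))
    scan = pd.concat(frames).reset_index()
    return hits, scan


def variable_overlap(hits: list[AssociationHit]) -> pd.DataFrame:
    """Per-variable hit counts and pairwise overlaps (Venn-style table)."""
    by_var: dict[str, set] = {}
    for h in hits:
        by_var.setdefault(h.variable, set()).add(h.marker)
    variables = sorted(by_var)
    rows = []
    for v in variables:
        row = {"variable": v, "n_hits": len(by_var[v])}
        for w in variables:
            row[f"shared_{w}"] = len(by_var[v] & by_var[w])
        rows.append(row)
    return pd.DataFrame(rows)


def annotate_proximal(
    hits: list[AssociationHit],
    positions: dict[object, tuple[str, int]],
    features: FeatureTable,
    window: int = 10_000,
) -> list[AssociationHit]:
    """Attach features overlapping or within ``window`` bp of each hit.

    ``positions`` maps marker id to (chrom, pos0).  Feature intervals are
    0-based half-open; the window is inclusive on both flanks (a hit
    exactly ``window`` bp beyond a feature edge still counts).  Distance
    is 0 for overlap, else the bp gap; per hit, features sort by distance
    then feature id.  Hits on chromosomes absent from the feature table
    get empty lists.
    """
    by_chrom: dict[str, pd.DataFrame] = {
        c: df for c, df in features.records.groupby("chrom")
    }
    n_missing_chrom = 0
    for h in hits:
        if h.marker not in positions:
            raise ValidationError(f"no position for hit marker {h.marker!r}")
        chrom, pos = positions[h.marker]
        sub = by_chrom.get(chrom)
        if sub is None:
            n_missing_chrom += 1
            h.features = []
            continue
        start = sub["start"].to_numpy()
        end = sub["end"].to_numpy()
        # gap is 0 when pos in [start, end); window inclusive on both sides
        gap = np.maximum(start - pos, 0) + np.maximum(pos - (end - 1), 0)
        near = gap <= window
        found = sorted(
            zip(sub["feature_id"].to_numpy()[near],
                gap[near].astype(int)),
            key=lambda fe: (fe[1], fe[0]),
        )
        h.features = [(fid, int(d)) for fid, d in found]
    if n_missing_chrom:
        logger.info("annotate_proximal: %d hits on chromosomes without features",
                    n_missing_chrom)
    return hits
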