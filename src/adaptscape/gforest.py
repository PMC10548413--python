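"""Gradient-forest turnover functions and genomic-offset prediction.

Each locus's population allele frequency is regressed on the climate
variables with a random forest (bootstrap per tree, random predictor
subset per split, variance-reduction split criterion).  Loci with
positive out-of-bag R^2 contribute their split impurity decreases —
normalized within locus and weighted by R^2 — to bins along each
predictor's observed range.  The binned importances, cumulatively
summed, are the turnover functions that map raw climate into "genomic
composition" space; the genomic offset of a site is the Euclidean
distance between its transformed current and future climate, and the
forward (migration-load) offset is the minimum distance to any site's
future climate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .io_formats import ClimateTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class TurnoverModel:
    predictors: list[str]
    bin_edges: np.ndarray  # (P, n_bins + 1)
    locus_ids: list
    locus_r2: np.ndarray  # OOB R^2 per locus (may be <= 0)
    locus_bin_importance: np.ndarray  # (n_used, P, n_bins), R^2-weighted
    used_locus_ids: list
    ntree: int
    n_bins: int
    seed: int | None

    def importance_bins(self, subset: list | None = None) -> np.ndarray:
        """(P, n_bins) mean R^2-weighted importance over included loci."""
        if subset is None:
            sel = np.arange(len(self.used_locus_ids))
        else:
            want = set(subset)
            sel = np.asarray(
                [i for i, lid in enumerate(self.used_locus_ids) if lid in want],
                dtype=np.intp,
            )
            if sel.size == 0:
                raise ValidationError("no fitted locus in the requested subset")
        return self.locus_bin_importance[sel].mean(axis=0)

    def overall_importance(self, subset: list | None = None) -> pd.Series:
        bins = self.importance_bins(subset)
        return pd.Series(bins.sum(axis=1), index=self.predictors)

    def cumulative(self, subset: list | None = None) -> np.ndarray:
        """(P, n_bins + 1) cumulative importance at the bin edges (starts 0)."""
        bins = self.importance_bins(subset)
        return np.concatenate(
            [np.zeros((bins.shape[0], 1)), np.cumsum(bins, axis=1)], axis=1
        )


def fit_gradient_forest(
    freqs: pd.DataFrame,
    climate: ClimateTable,
    ntree: int = 500,
    n_bins: int = 201,
    seed: int | None = None,
) -> TurnoverModel:
    """Fit one random forest per locus and bin the split importances.

    ``freqs`` is a populations x loci allele-frequency table whose index
    matches the climate table's sites.  Forests use ceil(P/3) candidate
    predictors per split and leaves of >= 2 samples (sensible at a dozen
    sites); R^2 is the out-of-bag score and loci with R^2 <= 0 are
    excluded from importance aggregation.  Constant-response loci are
    skipped with a log entry; constant predictors can never be split on
    and thus get zero importance.
    """
    if isinstance(freqs, np.ndarray):
        freqs = pd.DataFrame(
            freqs, index=climate.sites, columns=list(range(freqs.shape[1]))
        )
    if list(freqs.index) != climate.sites:
        raise ValidationError("frequency rows must match climate sites")
    n_sites = len(climate.sites)
    if n_sites < 5:
        raise ValidationError("gradient forest needs >= 5 sites")
    predictors = list(climate.variables)
    X = climate.values.to_numpy(dtype=float)
    P = len(predictors)
    edges = np.stack(
        [np.linspace(X[:, j].min(), X[:, j].max(), n_bins + 1) for j in range(P)]
    )
    # guard zero-width ranges so searchsorted stays well defined
    flat = edges[:, -1] == edges[:, 0]
    edges[flat, -1] += 1e-9

    rng = np.random.default_rng(seed)
    max_features = max(1, int(np.ceil(P / 3)))
    locus_ids = list(freqs.columns)
    r2 = np.full(len(locus_ids), np.nan)
    used_ids: list = []
    used_imp: list[np.ndarray] = []
    import warnings

    for li, lid in enumerate(locus_ids):
        y = freqs[lid].to_numpy(dtype=float)
        if y.std() == 0:
            logger.info("locus %s has constant frequency; skipped", lid)
            continue
        rf = RandomForestRegressor(
            n_estimators=ntree,
            max_features=max_features,
            min_samples_leaf=2,
            bootstrap=True,
            oob_score=True,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rf.fit(X, y)
        r2[li] = rf.oob_score_
        if r2[li] <= 0:
            continue
        imp = np.zeros((P, n_bins))
        for est in rf.estimators_:
            tree = est.tree_
            internal = tree.children_left != -1
            if not internal.any():
                continue
            node = np.where(internal)[0]
            wl = tree.weighted_n_node_samples[tree.children_left[node]]
            wr = tree.weighted_n_node_samples[tree.children_right[node]]
            wn = tree.weighted_n_node_samples[node]
            decrease = (
                wn * tree.impurity[node]
                - wl * tree.impurity[tree.children_left[node]]
                - wr * tree.impurity[tree.children_right[node]]
            ) / tree.weighted_n_node_samples[0]
            feat = tree.feature[node]
            thr = tree.threshold[node]
            for f, t, d in zip(feat, thr, decrease):
                if d <= 0:
                    continue
                b = int(np.clip(
                    np.searchsorted(edges[f], t, side="right") - 1, 0,
                    n_bins - 1,
                ))
                imp[f, b] += d
        total = imp.sum()
        if total <= 0:
            continue
        used_ids.append(lid)
        used_imp.append((imp / total) * r2[li])

    if not used_ids:
        logger.warning("no locus with positive OOB R^2; turnover is all zero")
        used_imp_arr = np.zeros((1, P, n_bins))
        used_ids = ["<none>"]
    else:
        used_imp_arr = np.stack(used_imp)
    return TurnoverModel(
        predictors=predictors,
        bin_edges=edges,
        locus_ids=locus_ids,
        locus_r2=r2,
        locus_bin_importance=used_imp_arr,
        used_locus_ids=used_ids,
        ntree=ntree,
        n_bins=n_bins,
        seed=seed,
    )


def transform_climate(
    model: TurnoverModel,
    points: pd.DataFrame,
    subset: list | None = None,
) -> np.ndarray:
    """Map climate vectors through the cumulative-importance functions.

    Linear interpolation within bins; values beyond the fitted range
    clamp to the end values (clamp events logged).  Output has one
    column per predictor.
    """
    missing = [v for v in model.predictors if v not in points.columns]
    if missing:
        raise ValidationError(f"points lack predictors {missing}")
    cum = model.cumulative(subset)
    out = np.empty((len(points), len(model.predictors)))
    n_clamped = 0
    for j, var in enumerate(model.predictors):
        x = points[var].to_numpy(dtype=float)
        lo, hi = model.bin_edges[j, 0], model.bin_edges[j, -1]
        n_clamped += int(((x < lo) | (x > hi)).sum())
        out[:, j] = np.interp(x, model.bin_edges[j], cum[j])
    if n_clamped:
        logger.info("transform_climate: %d values clamped to the fitted range",
                    n_clamped)
    return out


@dataclass
class OffsetMap:
    scenario: str
    sites: list[str]
    local_offset: np.ndarray
    forward_offset: np.ndarray | None = None
    best_destination: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"site": self.sites, "local_offset": self.local_offset}
        if self.forward_offset is not None:
            data["forward_offset"] = self.forward_offset
            data["best_destination"] = self.best_destination
        return pd.DataFrame(data)


def _check_alignment(current: ClimateTable, future: ClimateTable) -> None:
    current.aligned_to(future)


def local_offset(
    model: TurnoverModel,
    current: ClimateTable,
    future: ClimateTable,
    subset: list | None = None,
) -> OffsetMap:
    """Per-site Euclidean distance between transformed current and future
    climate."""
    _check_alignment(current, future)
    tc = transform_climate(model, current.values, subset)
    tf = transform_climate(model, future.values, subset)
    off = np.sqrt(((tc - tf) ** 2).sum(axis=1))
    return OffsetMap(scenario=future.scenario, sites=current.sites,
                     local_offset=off)


def forward_offset(
    model: TurnoverModel,
    current: ClimateTable,
    future: ClimateTable,
    subset: list | None = None,
) -> OffsetMap:
    """Migration-load offset: per site, the minimum distance between its
    transformed current climate and any site's transformed future climate
    (the site itself included, so forward <= local everywhere)."""
    _check_alignment(current, future)
    tc = transform_climate(model, current.values, subset)
    tf = transform_climate(model, future.values, subset)
    diff = tc[:, None, :] - tf[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    best = dist.argmin(axis=1)
    local = np.sqrt(((tc - tf) ** 2).sum(axis=1))
    return OffsetMap(
        scenario=future.scenario,
        sites=current.sites,
        local_offset=local,
        forward_offset=dist.min(axis=1),
        best_destination=[current.sites[i] for i in best],
    )


def offset_report(
    model: TurnoverModel,
    current: ClimateTable,
    futures: list[ClimateTable],
    loci_subset: list | None = None,
) -> tuple[dict[str, OffsetMap], pd.DataFrame]:
    """Offsets for every future scenario plus a per-site ranking table.

    ``loci_subset`` restricts the turnover functions to a locus subset
    (e.g. outlier loci); None uses all fitted loci.  The ranking table
    gives each site's local offset per scenario, its rank within each
    scenario, and whether its offsets increase monotonically across the
    scenario list (ordered by emission severity).
    """
    if loci_subset is not None and len(loci_subset) == 0:
        raise ValidationError("empty locus subset")
    maps: dict[str, OffsetMap] = {}
    cols = {}
    for fut in futures:
        m = forward_offset(model, current, fut, subset=loci_subset)
        maps[fut.scenario] = m
        cols[fut.scenario] = m.local_offset
    tab = pd.DataFrame(cols, index=current.sites)
    ranks = tab.rank(axis=0, ascending=False).astype(int)
    ranks.columns = [f"rank_{c}" for c in ranks.columns]
    mono = (tab.to_numpy()[:, 1:] >= tab.to_numpy()[:, :-1] - 1e-12).all(axis=1) \
        if tab.shape[1] > 1 else np.ones(len(tab), dtype=bool)
    report = pd.concat([tab, ranks], axis=1)
    report["monotone_increasing"] = mono
    report.index.name = "site"
    return maps, report
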