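"""End-to-end orchestration with a single validated config.

The pipeline runs the stages in dependency order — simulate (or load) →
popstats → ibd → dstat → outliers → gea/ewas → annotate → offset — and
writes one TSV per result plus a JSON manifest recording parameters,
per-stage seeds and row counts.  Identical configs give byte-identical
outputs.

Randomness: every stage draws its own seed deterministically from the
master seed as ``SeedSequence([master_seed, stage_index])``, where the
stage index is the stage's position in :data:`STAGE_ORDER`; reordering
the requested stages therefore never changes any stage's stream.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import epigea, gforest, introgression, landscape, lmm, outliers, popgen
from .io_formats import (
    ClimateTable,
    ValidationError,
    read_climate,
    read_features,
    read_methylation,
    read_popmap,
    read_vcf,
    write_table,
)
from .synthetic import (
    LandscapeSpec,
    simulate_genotypes,
    simulate_landscape,
    simulate_methylation,
)

logger = logging.getLogger(__name__)

STAGE_ORDER = (
    "simulate", "popstats", "ibd", "dstat", "outliers", "gea", "ewas",
    "annotate", "offset",
)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "results",
    "stages": list(STAGE_ORDER),
    "inputs": {
        "vcf": None,
        "popmap": None,
        "sites": None,
        "climate": None,
        "climate_future": [],
        "methylation": None,
        "features": None,
    },
    "simulate": {
        "n_pops": 13,
        "n_per_pop": 12,
        "fst_target": 0.19,
        "n_neutral": 5000,
        "n_adaptive": 50,
        "cline_strength": 1.5,
        "driver_variable": "BIO16",
        "missing_rate": 0.02,
        "admixture": None,
        "rcp_factors": [1.0, 1.5, 2.0],
        "meth_sites": 2000,
        "meth_assoc": 20,
        "meth_effect": 1.5,
        "meth_noise_sd": 0.5,
    },
    "popstats": {"pcoa_axes": 2},
    "ibd": {"n_perm": 10_000, "n_pc": 3, "r_max": 0.8},
    "dstat": {"trios": [], "block_size": None, "outgroup": None},
    "outliers": {"confidence": 0.99, "n_null": 100_000, "n_bins": 20,
                 "trim": 0.05},
    "gea": {"q_max": 0.05, "correction": "fdr"},
    "ewas": {"max_missing": 0.10, "min_range": 0.10, "min_depth": 1,
             "n_repeats": 200, "subset_size": 10_000, "alpha": 0.05},
    "annotate": {"window": 10_000},
    "offset": {"ntree": 500, "n_bins": 201, "use_outliers": True,
               "max_loci": None},
}


def _merge_validate(user: dict, default: dict, path: str = "") -> dict:
    out = {}
    for key, dval in default.items():
        here = f"{path}.{key}" if path else key
        if key in user:
            uval = user[key]
            if isinstance(dval, dict) and isinstance(uval, dict):
                out[key] = _merge_validate(uval, dval, here)
            else:
                out[key] = uval
        else:
            out[key] = json.loads(json.dumps(dval)) if isinstance(
                dval, (dict, list)) else dval
    unknown = set(user) - set(default)
    if unknown:
        raise ValidationError(
            f"unknown config keys at {path or '<root>'}: {sorted(unknown)}"
        )
    return out


def resolve_config(user: dict | None = None) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys."""
    return _merge_validate(user or {}, DEFAULT_CONFIG)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    idx = STAGE_ORDER.index(stage)
    ss = np.random.SeedSequence([int(master), idx])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_pipeline(config: dict | None = None) -> dict:
    """Execute the requested stages and return the run manifest."""
    cfg = resolve_config(config)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGE_ORDER if s in cfg["stages"]]
    unknown = set(cfg["stages"]) - set(STAGE_ORDER)
    if unknown:
        raise ValidationError(f"unknown stages {sorted(unknown)}")
    manifest: dict = {"config": cfg, "stages": {}, "seeds": {}}
    master = int(cfg["seed"])

    state: dict = {}
    for stage in stages:
        seed = stage_seed(master, stage)
        manifest["seeds"][stage] = seed
        try:
            rows = _STAGE_FUNCS[stage](cfg, state, out_dir, seed)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = rows
        logger.info("stage %s done: %s", stage, rows)

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg, state, out_dir, seed):
    sc = cfg["simulate"]
    spec = LandscapeSpec(
        n_pops=sc["n_pops"], n_per_pop=sc["n_per_pop"],
        fst_target=sc["fst_target"], n_neutral=sc["n_neutral"],
        n_adaptive=sc["n_adaptive"], cline_strength=sc["cline_strength"],
        driver_variable=sc["driver_variable"],
        missing_rate=sc["missing_rate"],
        admixture=tuple(sc["admixture"]) if sc["admixture"] else None,
        seed=seed,
    )
    popmap, current, _ = simulate_landscape(spec)
    futures = [
        simulate_landscape(spec, rcp_factor=f, scenario=f"rcp_x{f}")[2]
        for f in sc["rcp_factors"]
    ]
    G, truth = simulate_genotypes(spec, popmap, current)
    meth, meth_truth = simulate_methylation(
        spec, popmap, current, n_sites=sc["meth_sites"],
        n_assoc=sc["meth_assoc"], effect=sc["meth_effect"],
        noise_sd=sc["meth_noise_sd"],
    )
    state.update(
        spec=spec, popmap=popmap, climate=current, futures=futures, G=G,
        truth=truth, meth=meth, meth_truth=meth_truth,
    )
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(
            dict(adaptive_locus_ids=truth.adaptive_locus_ids,
                 driver_variable=truth.driver_variable,
                 smv_assoc_ids=meth_truth.smv_assoc_ids),
            fh, indent=2,
        )
    return dict(n_samples=G.n_samples, n_loci=G.n_loci,
                n_meth_sites=meth.n_sites)


def _require(state, key, stage):
    if key not in state:
        raise ValidationError(
            f"stage {stage!r} needs {key!r}; run the producing stage first "
            "or provide it via inputs"
        )
    return state[key]


def _load_inputs(cfg, state):
    """Populate state from file inputs when simulate is not requested."""
    inp = cfg["inputs"]
    if inp["vcf"] and "G" not in state:
        state["G"] = read_vcf(inp["vcf"])
    if inp["popmap"] and "popmap" not in state:
        state["popmap"] = read_popmap(inp["popmap"], inp["sites"])
    if inp["climate"] and "climate" not in state:
        state["climate"] = read_climate(inp["climate"])
    if inp["climate_future"] and "futures" not in state:
        state["futures"] = [
            read_climate(p, scenario=Path(p).stem)
            for p in inp["climate_future"]
        ]
    if inp["methylation"] and "meth" not in state:
        state["meth"] = read_methylation(inp["methylation"])
    if inp["features"] and "features" not in state:
        state["features"] = read_features(inp["features"])


def _stage_popstats(cfg, state, out_dir, seed):
    _load_inputs(cfg, state)
    G = _require(state, "G", "popstats")
    popmap = _require(state, "popmap", "popstats")
    div = popgen.diversity_stats(G, popmap)
    fst = popgen.wc_fst(G, popmap)
    write_table(div.table, out_dir / "diversity.tsv", index=True)
    write_table(fst.to_frame(), out_dir / "fst_pairwise.tsv", index=True)
    (out_dir / "fst_global.txt").write_text(f"{fst.global_theta:.6g}\n")
    lin = popgen.linearized_fst(fst.theta)
    coords, evals = popgen.pcoa(lin, k=cfg["popstats"]["pcoa_axes"])
    pco = pd.DataFrame(
        coords, index=fst.populations,
        columns=[f"axis{i + 1}" for i in range(coords.shape[1])],
    )
    pco.index.name = "population"
    write_table(pco, out_dir / "pcoa.tsv", index=True)
    state["fst"] = fst
    return dict(populations=len(fst.populations),
                global_fst=round(fst.global_theta, 6))


def _stage_ibd(cfg, state, out_dir, seed):
    fst = _require(state, "fst", "ibd")
    popmap = _require(state, "popmap", "ibd")
    climate = _require(state, "climate", "ibd")
    p = cfg["ibd"]
    gen_d = popgen.linearized_fst(fst.theta)
    geo_d = landscape.geographic_distance(
        popmap, log_transform=True, populations=fst.populations
    )
    ibd = landscape.mantel(gen_d, geo_d, n_perm=p["n_perm"], seed=seed)
    keep = landscape.select_uncorrelated(climate, r_max=p["r_max"])
    climate_sel = ClimateTable(
        scenario=climate.scenario,
        values=climate.values.loc[fst.populations, keep],
    )
    env_d, explained = landscape.environmental_distance(
        climate_sel, n_pc=min(p["n_pc"], len(keep))
    )
    ibe = landscape.partial_mantel(gen_d, env_d, geo_d, n_perm=p["n_perm"],
                                   seed=seed + 1)
    tab = pd.DataFrame(
        [
            dict(test="IBD", r=ibd.r, p=ibd.p, n_perm=ibd.n_perm,
                 partial=False),
            dict(test="IBE_partial", r=ibe.r, p=ibe.p, n_perm=ibe.n_perm,
                 partial=True),
        ]
    )
    write_table(tab, out_dir / "mantel.tsv")
    state["ibd"], state["ibe"] = ibd, ibe
    state["selected_variables"] = keep
    return dict(ibd_r=round(ibd.r, 4), ibd_p=ibd.p, ibe_r=round(ibe.r, 4),
                ibe_p=ibe.p, variables=keep)


def _stage_dstat(cfg, state, out_dir, seed):
    G = _require(state, "G", "dstat")
    popmap = _require(state, "popmap", "dstat")
    p = cfg["dstat"]
    freqs, pops = introgression.population_frequencies(
        G, popmap, outgroup=p["outgroup"]
    )
    trios = [tuple(t) for t in p["trios"]]
    if not trios:
        return dict(trios=0)
    rows = []
    for trio in trios:
        res = introgression.dmin(freqs, pops, trio,
                                 block_size=p["block_size"])
        rows.append(dict(p1=res.trio[0], p2=res.trio[1], p3=res.trio[2],
                         n_abba=res.n_abba, n_baba=res.n_baba, d=res.d,
                         se=res.se, z=res.z, n_blocks=res.n_blocks,
                         significant=res.significant))
    tab = pd.DataFrame(rows)
    write_table(tab, out_dir / "dstat.tsv")
    state["dstat"] = tab
    return dict(trios=len(trios),
                significant=int(tab["significant"].sum()))


def _stage_outliers(cfg, state, out_dir, seed):
    G = _require(state, "G", "outliers")
    popmap = _require(state, "popmap", "outliers")
    p = cfg["outliers"]
    cal = outliers.calibrate_null(G, popmap, trim=p["trim"], seed=seed)
    sizes = [
        len(ix) for ix in popmap.indices(G.samples).values()
    ]
    null = outliers.simulate_null(cal.F, sizes, p["n_null"], seed=seed + 1)
    he, fst = outliers.observed_locus_stats(G, popmap)
    rep = outliers.fdist_outliers(he, fst, null, confidence=p["confidence"],
                                  n_bins=p["n_bins"])
    write_table(rep.table, out_dir / "outliers.tsv", index=True)
    state["outlier_report"] = rep
    state["calibrated_F"] = cal.F
    return dict(calibrated_F=round(cal.F, 4), flagged=len(rep.flagged_ids))


def _stage_gea(cfg, state, out_dir, seed):
    G = _require(state, "G", "gea")
    popmap = _require(state, "popmap", "gea")
    climate = _require(state, "climate", "gea")
    p = cfg["gea"]
    variables = state.get("selected_variables") or climate.variables
    hits, scan = epigea.gea_scan(
        G, climate, popmap, variables=variables,
        correction=p["correction"], q_max=p["q_max"],
    )
    write_table(scan, out_dir / "gea_scan.tsv")
    write_table(epigea.variable_overlap(hits), out_dir / "gea_overlap.tsv")
    state["gea_hits"] = hits
    return dict(hits=len(hits),
                unique_loci=len({h.marker for h in hits}))


def _stage_ewas(cfg, state, out_dir, seed):
    meth = _require(state, "meth", "ewas")
    popmap = _require(state, "popmap", "ewas")
    climate = _require(state, "climate", "ewas")
    p = cfg["ewas"]
    smvs = epigea.call_smvs(meth, max_missing=p["max_missing"],
                            min_range=p["min_range"],
                            min_depth=p["min_depth"])
    K = lmm.kinship(smvs.level, kind="methylation")
    variables = state.get("selected_variables") or climate.variables
    thresholds = {}
    for i, var in enumerate(variables):
        y = epigea._response_vector(smvs.samples, popmap, climate, var)
        thresholds[var] = lmm.permutation_threshold(
            y, smvs.level, K, n_repeats=p["n_repeats"],
            subset_size=min(p["subset_size"], smvs.n_sites),
            alpha=p["alpha"], seed=seed + i,
        )
    hits, scan = epigea.ewas_scan(smvs, climate, popmap,
                                  variables=variables,
                                  thresholds=thresholds, K=K)
    write_table(scan, out_dir / "ewas_scan.tsv")
    state["ewas_hits"] = hits
    state["smvs"] = smvs
    state["ewas_thresholds"] = thresholds
    return dict(smvs=smvs.n_sites, hits=len(hits),
                thresholds={k: float(f"{v:.3g}")
                            for k, v in thresholds.items()})


def _stage_annotate(cfg, state, out_dir, seed):
    features = state.get("features")
    if features is None:
        return dict(skipped="no feature table provided")
    window = cfg["annotate"]["window"]
    hits = state.get("gea_hits", []) + state.get("ewas_hits", [])
    G = state.get("G")
    positions = {}
    if G is not None:
        for i, (chrom, pos) in enumerate(G.loci):
            positions[i] = (chrom, pos)
    smvs = state.get("smvs")
    if smvs is not None:
        for chrom, pos, _ctx in smvs.sites:
            positions[f"{chrom}:{pos + 1}"] = (chrom, pos)
    annotated = epigea.annotate_proximal(hits, positions, features,
                                         window=window)
    rows = [
        dict(marker=h.marker, variable=h.variable, p=h.p,
             features=";".join(f"{f}@{d}" for f, d in h.features))
        for h in annotated
    ]
    write_table(pd.DataFrame(rows), out_dir / "annotated_hits.tsv")
    return dict(hits=len(annotated),
                with_features=sum(1 for h in annotated if h.features))


def _stage_offset(cfg, state, out_dir, seed):
    G = _require(state, "G", "offset")
    popmap = _require(state, "popmap", "offset")
    climate = _require(state, "climate", "offset")
    futures = _require(state, "futures", "offset")
    p = cfg["offset"]
    freqs, pops = introgression.population_frequencies(G, popmap)
    freq_df = pd.DataFrame(freqs, index=pops).loc[climate.sites]
    if p["max_loci"] is not None and freq_df.shape[1] > p["max_loci"]:
        rng = np.random.default_rng(seed + 1)
        keep = np.sort(rng.choice(freq_df.shape[1], size=p["max_loci"],
                                  replace=False))
        # keep flagged outliers in the fitted set so the outlier-based
        # offset remains computable
        if "outlier_report" in state:
            keep = np.union1d(keep, state["outlier_report"].flagged_ids)
        freq_df = freq_df.iloc[:, keep]
    model = gforest.fit_gradient_forest(
        freq_df, climate, ntree=p["ntree"], n_bins=p["n_bins"], seed=seed
    )
    subset = None
    if p["use_outliers"] and "outlier_report" in state:
        flagged = state["outlier_report"].flagged_ids
        subset = [i for i in flagged if i in set(model.used_locus_ids)]
        if not subset:
            subset = None
    maps, report = gforest.offset_report(model, climate, futures,
                                         loci_subset=None)
    write_table(report, out_dir / "offsets.tsv", index=True)
    imp = model.overall_importance().rename("importance").to_frame()
    imp.index.name = "variable"
    write_table(imp, out_dir / "importance.tsv", index=True)
    if subset:
        _, rep_out = gforest.offset_report(model, climate, futures,
                                           loci_subset=subset)
        write_table(rep_out, out_dir / "offsets_outliers.tsv", index=True)
    state["turnover_model"] = model
    state["offset_report"] = report
    return dict(
        scenarios=[f.scenario for f in futures],
        top_variable=model.overall_importance().idxmax(),
        n_loci_used=len(model.used_locus_ids),
    )


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "popstats": _stage_popstats,
    "ibd": _stage_ibd,
    "dstat": _stage_dstat,
    "outliers": _stage_outliers,
    "gea": _stage_gea,
    "ewas": _stage_ewas,
    "annotate": _stage_annotate,
    "offset": _stage_offset,
}
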