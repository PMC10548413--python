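"""Isolation by distance and by environment.

Mantel test of linearized F_ST against log great-circle distance (IBD),
then a partial Mantel of genetic distance against PCA-based
environmental distance controlling for geography (IBE), after pruning
collinear climate variables at |r| < .8.
"""

import pandas as pd

from adaptscape.io_formats import ClimateTable, write_table
from adaptscape.landscape import (
    environmental_distance,
    geographic_distance,
    mantel,
    partial_mantel,
    select_uncorrelated,
)
from adaptscape.popgen import linearized_fst, wc_fst

from study_setup import RESULTS, SEED, load_study


def main():
    study = load_study()
    G, popmap, current = study["G"], study["popmap"], study["current"]

    fst = wc_fst(G, popmap)
    gen_d = linearized_fst(fst.theta)
    geo_d = geographic_distance(popmap, log_transform=True,
                                populations=fst.populations)

    ibd = mantel(gen_d, geo_d, n_perm=10_000, seed=SEED)

    keep = select_uncorrelated(current, r_max=0.8)
    clim = ClimateTable(scenario="current",
                        values=current.values.loc[fst.populations, keep])
    env_d, explained = environmental_distance(clim, n_pc=min(3, len(keep)))
    ibe = partial_mantel(gen_d, env_d, geo_d, n_perm=10_000, seed=SEED + 1)

    tab = pd.DataFrame([
        dict(test="IBD", r=ibd.r, p=ibd.p, n_perm=ibd.n_perm),
        dict(test="IBE_partial", r=ibe.r, p=ibe.p, n_perm=ibe.n_perm),
    ])
    write_table(tab, RESULTS / "mantel.tsv")

    print(f"climate variables kept at |r|<.8: {keep}")
    print(f"top-{min(3, len(keep))} PCs explain "
          f"{100 * explained[:3].sum():.0f}% of climate variance")
    print(f"IBD: Mantel r = {ibd.r:.3f}, P = {ibd.p:.4f} "
          f"({ibd.n_perm} permutations)")
    print(f"IBE (controlling geography): r = {ibe.r:.3f}, P = {ibe.p:.4f}")
    verdict = "supported" if ibd.p <= 0.05 else "not supported"
    print(f"-> isolation by distance {verdict} in this landscape")


if __name__ == "__main__":
    main()
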