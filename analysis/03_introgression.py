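"""ABBA-BABA test of a planted admixture pulse.

Generates a six-population island model with a one-way admixture pulse
(30% from P02 into P05), then contrasts the Patterson's D of the true
trio against a no-admixture control trio, with block-jackknife Z
scores and the topology-agnostic Dmin.
"""

import pandas as pd

from adaptscape.introgression import abba_baba, dmin, population_frequencies
from adaptscape.io_formats import write_table
from adaptscape.synthetic import (
    LandscapeSpec,
    simulate_genotypes,
    simulate_landscape,
)

from study_setup import RESULTS, SEED


def main():
    spec = LandscapeSpec(n_pops=6, n_neutral=5000, n_adaptive=0,
                         fst_target=0.2, admixture=("P02", "P05", 0.3),
                         seed=SEED)
    pm, cur, _ = simulate_landscape(spec)
    G, _ = simulate_genotypes(spec, pm, cur)
    freqs, pops = population_frequencies(G, pm)

    rows = []
    for label, trio in [("admixed", ("P06", "P05", "P02")),
                        ("control", ("P06", "P04", "P01"))]:
        res = abba_baba(freqs, pops, trio)
        best = dmin(freqs, pops, trio)
        rows.append(dict(case=label, p1=trio[0], p2=trio[1], p3=trio[2],
                         d=res.d, se=res.se, z=res.z,
                         dmin=best.d, dmin_z=best.z,
                         significant=res.significant))
        print(f"{label} trio {trio}: D = {res.d:+.4f}, Z = {res.z:+.2f} "
              f"({'|Z| >= 3' if res.significant else '|Z| < 3'}); "
              f"Dmin = {best.d:+.4f}")
    write_table(pd.DataFrame(rows), RESULTS / "dstat.tsv")
    print("-> the planted 30% pulse is detected by the correctly arranged "
          "trio; the control trio stays at D ~ 0")


if __name__ == "__main__":
    main()
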