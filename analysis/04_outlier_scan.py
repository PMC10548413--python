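"""Simulation-null F_ST outlier scan.

Calibrates the island-model differentiation parameter to the observed
genome-wide F_ST (trimmed), simulates a neutral (He, F_ST) cloud,
flags loci above the 99% envelope of their heterozygosity bin, and
scores recovery of the planted clinal loci plus the false-positive
rate among neutral loci.
"""

from adaptscape.io_formats import write_table
from adaptscape.outliers import (
    calibrate_null,
    fdist_outliers,
    observed_locus_stats,
    simulate_null,
)

from study_setup import RESULTS, SEED, SPEC, load_study


def main():
    study = load_study()
    G, popmap, truth = study["G"], study["popmap"], study["truth"]

    cal = calibrate_null(G, popmap, seed=SEED)
    sizes = [len(ix) for ix in popmap.indices(G.samples).values()]
    null = simulate_null(cal.F, sizes, 400_000, seed=SEED + 1)
    he, fst = observed_locus_stats(G, popmap)
    rep = fdist_outliers(he, fst, null, confidence=0.99, n_bins=20)
    write_table(rep.table, RESULTS / "outliers.tsv", index=True)

    adaptive = set(truth.adaptive_locus_ids)
    flagged = set(rep.flagged_ids)
    q_hits = set(rep.table.index[rep.table["q"] <= 0.05])
    tp = len(q_hits & adaptive)
    fp_rate = len(flagged - adaptive) / SPEC.n_neutral

    print(f"calibrated neutral F = {cal.F:.3f} "
          f"({len(cal.trace)} bisection steps)")
    print(f"flagged at 99% envelope: {len(flagged)} of {G.n_loci} loci")
    print(f"planted clinal loci recovered at q <= .05: "
          f"{tp}/{len(adaptive)} ({100 * tp / len(adaptive):.0f}%)")
    print(f"neutral loci flagged (false-positive rate): {100 * fp_rate:.2f}%"
          f" at a nominal 1% envelope")


if __name__ == "__main__":
    main()
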