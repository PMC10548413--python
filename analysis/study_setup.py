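"""Shared setup for the numbered analysis scripts.

One synthetic range-wide study, generated deterministically: 13
populations x 12 diploids, 4000 neutral SNPs under an island model at
F_ST 0.19 plus 40 BIO16-clinal loci, five bioclimatic variables, three
nested future-climate scenarios, and a 13-sample methylation matrix
with 20 planted climate-associated sites.  Every script imports this
module so the whole analysis shares a single dataset and seed.
"""

from pathlib import Path

from adaptscape.synthetic import (
    LandscapeSpec,
    simulate_genotypes,
    simulate_landscape,
    simulate_methylation,
)

SEED = 2026
RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"

SPEC = LandscapeSpec(
    n_pops=13,
    n_per_pop=12,
    fst_target=0.19,
    n_neutral=4000,
    n_adaptive=40,
    cline_strength=3.0,
    driver_variable="BIO16",
    missing_rate=0.02,
    seed=SEED,
)

RCP_FACTORS = (1.0, 1.5, 2.0)  # nested emission-severity ladder


def load_study():
    RESULTS.mkdir(parents=True, exist_ok=True)
    popmap, current, _ = simulate_landscape(SPEC)
    futures = [
        simulate_landscape(SPEC, rcp_factor=f, scenario=f"rcp_x{f}")[2]
        for f in RCP_FACTORS
    ]
    G, truth = simulate_genotypes(SPEC, popmap, current)
    return dict(popmap=popmap, current=current, futures=futures, G=G,
                truth=truth)


def load_methylation(popmap, current):
    return simulate_methylation(
        SPEC, popmap, current, n_sites=2000, n_assoc=20, effect=3.0,
        noise_sd=0.4, sigma_g=0.4, mean_depth=100.0,
    )
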