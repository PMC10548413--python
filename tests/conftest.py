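import numpy as np
import pytest

from adaptscape.io_formats import GenotypeMatrix, PopulationMap
from adaptscape.synthetic import (
    LandscapeSpec,
    simulate_genotypes,
    simulate_landscape,
)


@pytest.fixture(scope="session")
def small_landscape():
    """A 13-population landscape with neutral + clinal loci, shared by
    read-only tests."""
    spec = LandscapeSpec(n_neutral=2000, n_adaptive=30, fst_target=0.2,
                         cline_strength=2.5, missing_rate=0.0, seed=11)
    popmap, current, future = simulate_landscape(spec)
    G, truth = simulate_genotypes(spec, popmap, current)
    return dict(spec=spec, popmap=popmap, current=current, future=future,
                G=G, truth=truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_genotypes(rng, n_pops=3, n_per_pop=5, n_loci=4, missing_rate=0.0):
    """Small random genotype matrix + population map for oracle tests."""
    samples = [f"p{i}_s{j}" for i in range(n_pops) for j in range(n_per_pop)]
    assignments = {s: s.split("_")[0] for s in samples}
    dosage = rng.integers(0, 3, size=(len(samples), n_loci)).astype(np.int8)
    if missing_rate:
        mask = rng.random(dosage.shape) < missing_rate
        dosage[mask] = -1
    loci = [("chr1", 10 * (k + 1)) for k in range(n_loci)]
    G = GenotypeMatrix(samples=samples, loci=loci, dosage=dosage)
    popmap = PopulationMap(assignments=assignments)
    return G, popmap


def write_vcf(path, records, samples=("s1", "s2", "s3", "s4", "s5")):
    """Write a minimal VCF v4.2; records = list of (chrom, pos, ref, alt,
    genotypes) with genotypes like '0/1' or './.'."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=chr1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    for chrom, pos, ref, alt, gts in records:
        assert len(gts) == len(samples)
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")
    return str(path)
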