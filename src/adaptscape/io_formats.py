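"""Readers, writers and validated containers for every external file format.

Conventions shared by the whole package:

* genomic coordinates are stored 0-based half-open internally; VCF,
  methylation and 1-based feature tables are converted on read and
  converted back on write;
* missing diploid dosage is encoded by the sentinel ``MISSING`` (-1) in an
  integer matrix, never by NaN, so genotype arrays stay integer-typed;
* tabular output is TSV with floats at six significant digits and a
  deterministic row order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing diploid dosage
MISSING: int = -1

METH_CONTEXTS = ("CpG", "CHG", "CHH")


class ValidationError(ValueError):
    """Raised when an input file violates a documented invariant."""


class EmptyAfterFilteringError(ValidationError):
    """Raised when no locus survives the genotype filters."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes as an individuals x loci dosage matrix.

    ``dosage`` counts copies of the alternate allele (0, 1, 2) with
    :data:`MISSING` for no-calls.  ``loci`` holds ``(chrom, pos0)`` pairs
    with 0-based positions, strictly increasing within each chromosome.
    """

    samples: list[str]
    loci: list[tuple[str, int]]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage)
        if self.dosage.shape != (len(self.samples), len(self.loci)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.samples)}, {len(self.loci)})"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValidationError("dosage values must be 0/1/2 or missing")
        last: dict[str, int] = {}
        for chrom, pos in self.loci:
            if pos < 0:
                raise ValidationError(f"negative position on {chrom}")
            if chrom in last and pos <= last[chrom]:
                raise ValidationError(
                    f"positions not strictly increasing on {chrom} at {pos}"
                )
            last[chrom] = pos

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING


@dataclass
class PopulationMap:
    """Individual-to-population assignment plus per-population site data.

    ``sites`` maps a population code to (longitude, latitude, altitude_m).
    """

    assignments: dict[str, str]
    sites: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pop, (lon, lat, _alt) in self.sites.items():
            if not (-180.0 < lon <= 180.0):
                raise ValidationError(f"longitude out of range for {pop}: {lon}")
            if not (-90.0 <= lat <= 90.0):
                raise ValidationError(f"latitude out of range for {pop}: {lat}")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.assignments.values():
            seen.setdefault(pop)
        return list(seen)

    def indices(self, samples: list[str]) -> dict[str, np.ndarray]:
        """Column indices of ``samples`` grouped by population (input order)."""
        for s in samples:
            if s not in self.assignments:
                raise ValidationError(f"sample {s!r} absent from population map")
        out: dict[str, list[int]] = {}
        for i, s in enumerate(samples):
            out.setdefault(self.assignments[s], []).append(i)
        return {p: np.asarray(ix, dtype=np.intp) for p, ix in out.items()}


@dataclass
class ClimateTable:
    """Per-site bioclimatic variables for one scenario."""

    scenario: str
    values: pd.DataFrame  # index = site/population codes, columns = variables

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValidationError(f"missing cells in climate table {self.scenario!r}")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate climate variable names")

    @property
    def sites(self) -> list[str]:
        return list(self.values.index)

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    def aligned_to(self, other: "ClimateTable") -> None:
        if self.sites != other.sites or self.variables != other.variables:
            raise ValidationError(
                "climate tables misaligned: "
                f"sites {set(self.sites) ^ set(other.sites)}, "
                f"variables {set(self.variables) ^ set(other.variables)}"
            )


@dataclass
class MethylationTable:
    """Per-cytosine methylation proportions with read depth and context."""

    samples: list[str]
    sites: list[tuple[str, int, str]]  # (chrom, pos0, context)
    level: np.ndarray  # float, NaN = missing
    depth: np.ndarray  # int

    def __post_init__(self) -> None:
        self.level = np.asarray(self.level, dtype=float)
        self.depth = np.asarray(self.depth)
        shape = (len(self.samples), len(self.sites))
        if self.level.shape != shape or self.depth.shape != shape:
            raise ValidationError("level/depth shape mismatch")
        if (self.depth < 0).any():
            raise ValidationError("negative read depth")
        for chrom, pos, ctx in self.sites:
            if ctx not in METH_CONTEXTS:
                raise ValidationError(f"unknown context {ctx!r} at {chrom}:{pos}")
        zero = self.depth == 0
        if np.isfinite(self.level[zero]).any():
            logger.warning(
                "coercing %d levels with zero depth to missing",
                int(np.isfinite(self.level[zero]).sum()),
            )
            self.level[zero] = np.nan
        obs = np.isfinite(self.level)
        if ((self.level[obs] < 0) | (self.level[obs] > 1)).any():
            raise ValidationError("methylation level outside [0, 1]")

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class FeatureTable:
    """Genomic intervals (e.g. exons), stored 0-based half-open."""

    records: pd.DataFrame  # columns chrom, start, end, feature_id, annotation

    def __post_init__(self) -> None:
        req = ["chrom", "start", "end", "feature_id"]
        if list(self.records.columns[:4]) != req:
            raise ValidationError(f"feature table needs columns {req}")
        if (self.records["start"] >= self.records["end"]).any():
            raise ValidationError("feature with start >= end")
        if self.records["feature_id"].duplicated().any():
            dup = self.records["feature_id"][self.records["feature_id"].duplicated()]
            raise ValidationError(f"duplicate feature identifiers: {list(dup)[:5]}")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_vcf(
    path: str,
    min_maf: float = 0.01,
    max_missing: float = 0.20,
    max_het: float = 0.50,
) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a dosage matrix.

    Filters, applied in a fixed order to each record: biallelic SNP,
    missing-call rate < ``max_missing``, minor-allele frequency >
    ``min_maf`` (computed over non-missing alleles), observed
    heterozygote fraction among non-missing calls <= ``max_het`` (removes
    collapsed paralogs).  Retention counts are logged.
    """
    from cyvcf2 import VCF

    for name, thr in (("min_maf", min_maf), ("max_missing", max_missing),
                      ("max_het", max_het)):
        if not 0.0 <= thr <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1], got {thr}")

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    loci: list[tuple[str, int]] = []
    columns: list[np.ndarray] = []
    counts = {"total": 0, "non_biallelic_snp": 0, "missing": 0, "maf": 0,
              "het": 0, "kept": 0}
    for rec in vcf:
        counts["total"] += 1
        if len(rec.ALT) != 1 or not rec.is_snp:
            counts["non_biallelic_snp"] += 1
            continue
        gts = rec.genotype.array()[:, :2]
        miss = (gts < 0).any(axis=1)
        dos = np.where(miss, MISSING, (gts > 0).sum(axis=1)).astype(np.int8)
        n = len(dos)
        n_obs = n - int(miss.sum())
        if n_obs == 0 or miss.sum() / n >= max_missing:
            counts["missing"] += 1
            continue
        alt = int(dos[~miss].sum())
        af = alt / (2 * n_obs)
        maf = min(af, 1.0 - af)
        if maf <= min_maf:
            counts["maf"] += 1
            continue
        het = float((dos == 1).sum()) / n_obs
        if het > max_het:
            counts["het"] += 1
            continue
        counts["kept"] += 1
        loci.append((rec.CHROM, rec.POS - 1))  # to 0-based
        columns.append(dos)
    logger.info("read_vcf %s: %s", path, counts)
    if not loci:
        raise EmptyAfterFilteringError(
            f"no locus in {path} survives the filters ({counts})"
        )
    order = np.lexsort(
        (np.asarray([p for _, p in loci]), np.asarray([c for c, _ in loci]))
    )
    # cyvcf2 yields records in file order; sort per chromosome for the
    # strictly-increasing invariant while keeping chromosome blocks stable
    loci_sorted = [loci[i] for i in order]
    dosage = np.stack([columns[i] for i in order], axis=1)
    return GenotypeMatrix(samples=samples, loci=loci_sorted, dosage=dosage)


def read_popmap(path: str, sites_path: str | None = None) -> PopulationMap:
    """Read a ``sample\\tpopulation`` map plus optional site coordinates CSV."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "population"} <= set(df.columns):
        raise ValidationError("population map needs columns: sample, population")
    if df["sample"].duplicated().any():
        dup = df["sample"][df["sample"].duplicated()].iloc[0]
        raise ValidationError(f"sample {dup!r} assigned more than once")
    assignments = dict(zip(df["sample"].astype(str), df["population"].astype(str)))
    sites: dict[str, tuple[float, float, float]] = {}
    if sites_path is not None:
        sdf = pd.read_csv(sites_path)
        need = {"population", "longitude", "latitude", "altitude"}
        if not need <= set(sdf.columns):
            raise ValidationError(f"site table needs columns {sorted(need)}")
        for i, row in sdf.iterrows():
            try:
                sites[str(row["population"])] = (
                    float(row["longitude"]),
                    float(row["latitude"]),
                    float(row["altitude"]),
                )
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    f"malformed coordinate at {sites_path} line {i + 2}: {exc}"
                ) from exc
    return PopulationMap(assignments=assignments, sites=sites)


def read_climate(path: str, scenario: str = "current") -> ClimateTable:
    """Read a ``site,<var>,...`` CSV of bioclimatic values for one scenario."""
    df = pd.read_csv(path)
    if "site" not in df.columns:
        raise ValidationError("climate CSV needs a leading 'site' column")
    df = df.set_index("site")
    df.index = df.index.astype(str)
    return ClimateTable(scenario=scenario, values=df.astype(float))


def read_methylation(path: str) -> MethylationTable:
    """Read a long-format methylation TSV into a samples x sites table.

    Expected columns: chrom, pos (1-based), context, sample, meth_reads,
    total_reads.  Level is meth_reads/total_reads; zero depth gives a
    missing level.
    """
    df = pd.read_csv(path, sep="\t")
    need = {"chrom", "pos", "context", "sample", "meth_reads", "total_reads"}
    if not need <= set(df.columns):
        raise ValidationError(f"methylation TSV needs columns {sorted(need)}")
    if (df["pos"] < 1).any():
        bad = df.index[df["pos"] < 1][0]
        raise ValidationError(f"non-positive position at line {bad + 2}")
    if (df["meth_reads"] > df["total_reads"]).any():
        raise ValidationError("meth_reads exceeds total_reads")
    samples = list(dict.fromkeys(df["sample"].astype(str)))
    site_keys = list(
        dict.fromkeys(zip(df["chrom"].astype(str), df["pos"].astype(int),
                          df["context"].astype(str)))
    )
    s_ix = {s: i for i, s in enumerate(samples)}
    t_ix = {t: j for j, t in enumerate(site_keys)}
    level = np.full((len(samples), len(site_keys)), np.nan)
    depth = np.zeros((len(samples), len(site_keys)), dtype=int)
    for row in df.itertuples(index=False):
        i = s_ix[str(row.sample)]
        j = t_ix[(str(row.chrom), int(row.pos), str(row.context))]
        depth[i, j] = int(row.total_reads)
        if row.total_reads > 0:
            level[i, j] = row.meth_reads / row.total_reads
    sites = [(c, p - 1, ctx) for c, p, ctx in site_keys]  # to 0-based
    return MethylationTable(samples=samples, sites=sites, level=level, depth=depth)


def read_features(path: str, one_based: bool | None = None) -> FeatureTable:
    """Read intervals from BED (0-based half-open) or a 1-based 4-column TSV.

    ``one_based`` defaults to False for ``.bed`` files, True otherwise.
    """
    path = str(path)
    if one_based is None:
        one_based = not path.endswith(".bed")
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValidationError("feature table needs >= 4 columns")
    df = df.iloc[:, :5] if df.shape[1] >= 5 else df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "feature_id", "annotation"][: df.shape[1]]
    if "annotation" not in df.columns:
        df["annotation"] = ""
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if one_based:
        # 1-based inclusive [start, end] -> 0-based half-open [start-1, end)
        df["start"] = df["start"] - 1
    df["feature_id"] = df["feature_id"].astype(str)
    return FeatureTable(records=df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------


def _fmt(v: object) -> str:
    if isinstance(v, (float, np.floating)):
        if math.isnan(v):
            return "NA"
        return f"{v:.6g}"
    return str(v)


def write_table(result: pd.DataFrame, path: str, index: bool = False) -> None:
    """Write a result table as TSV, floats at six significant digits."""
    df = result.reset_index() if index else result
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")
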