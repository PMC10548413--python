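"""SMV filtering, climate-association scans and proximity annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adaptscape.epigea import (
    AssociationHit,
    annotate_proximal,
    call_smvs,
    ewas_scan,
    gea_scan,
    variable_overlap,
)
from adaptscape.io_formats import (
    FeatureTable,
    MethylationTable,
    ValidationError,
)
from adaptscape.synthetic import (
    LandscapeSpec,
    simulate_genotypes,
    simulate_landscape,
    simulate_methylation,
)


def meth_table(level, depth=None):
    n_s, n_t = level.shape
    if depth is None:
        depth = np.where(np.isnan(level), 0, 10).astype(int)
    return MethylationTable(
        samples=[f"s{i}" for i in range(n_s)],
        sites=[("scaf_1", 10 * (j + 1), "CpG") for j in range(n_t)],
        level=level,
        depth=depth,
    )


class TestCallSmvs:
    def test_constant_site_removed_by_range_rule(self):
        level = np.column_stack([np.full(13, 0.3), np.linspace(0, 1, 13)])
        smvs = call_smvs(meth_table(level))
        assert smvs.n_sites == 1
        assert smvs.filter_log["range"] == 1

    def test_high_missingness_site_removed(self):
        good = np.linspace(0, 1, 13)
        bad = good.copy()
        bad[:6] = np.nan  # 46% missing
        smvs = call_smvs(meth_table(np.column_stack([good, bad])))
        assert smvs.n_sites == 1
        assert smvs.filter_log["missing"] == 1

    def test_engineered_fixture_counts_per_rule(self):
        """Six sites: one fails missingness, two fail range, three stay."""
        n = 13
        spread = np.linspace(0.05, 0.95, n)
        sites = {
            "keep1": spread,
            "keep2": spread[::-1],
            "keep3": 0.5 + 0.3 * np.sin(np.arange(n)),
            "miss": np.where(np.arange(n) < 2, spread, np.nan),
            "flat1": np.full(n, 0.40),
            "flat2": np.full(n, 0.41) + 0.04 * (np.arange(n) % 2),
        }
        level = np.column_stack(list(sites.values()))
        smvs = call_smvs(meth_table(level), max_missing=0.10, min_range=0.10)
        assert smvs.n_sites == 3
        assert smvs.filter_log == {"input": 6, "missing": 1, "range": 2,
                                   "kept": 3}

    def test_retention_invariant_to_sample_and_site_order(self, rng):
        level = rng.random((10, 30))
        level[rng.random((10, 30)) < 0.05] = np.nan
        base = call_smvs(meth_table(level))
        perm_s = rng.permutation(10)
        perm_t = rng.permutation(30)
        shuffled = call_smvs(meth_table(level[perm_s][:, perm_t]))
        assert sorted(perm_t[shuffled.site_ids]) == sorted(base.site_ids)

    def test_zero_survivors_is_an_error(self):
        level = np.full((5, 3), 0.5)
        with pytest.raises(ValidationError):
            call_smvs(meth_table(level))


def _meth_setup(effect, noise_sd, seed, n_sites=400, n_assoc=5,
                mean_depth=200.0, sigma_g=0.7):
    spec = LandscapeSpec(n_pops=13, seed=seed)
    pm, cur, _ = simulate_landscape(spec)
    meth, truth = simulate_methylation(
        spec, pm, cur, n_sites=n_sites, n_assoc=n_assoc, effect=effect,
        noise_sd=noise_sd, mean_depth=mean_depth, sigma_g=sigma_g,
    )
    return pm, cur, meth, truth


class TestEwasScan:
    def test_planted_site_recovered_with_low_noise(self):
        """One strongly associated site at high depth, with only
        unstructured background noise, is the top-ranked hit for its
        driver variable."""
        pm, cur, meth, truth = _meth_setup(effect=5.0, noise_sd=0.4,
                                           seed=71, n_assoc=1,
                                           mean_depth=2000.0, sigma_g=0.0)
        smvs = call_smvs(meth, min_depth=1)
        _, scan = ewas_scan(smvs, cur, pm, variables=["BIO16"])
        sub = scan.set_index("marker")
        planted = truth.smv_assoc_ids[0]
        planted_id = f"scaf_{planted // 200 + 1}:{(planted % 200) * 50 + 11}"
        assert planted_id in sub.index
        assert sub.loc[planted_id, "p"] == sub["p"].min()

    def test_zero_thresholds_give_zero_hits(self):
        pm, cur, meth, _ = _meth_setup(effect=2.0, noise_sd=0.3, seed=72)
        smvs = call_smvs(meth)
        hits, _ = ewas_scan(smvs, cur, pm,
                            thresholds={v: 0.0 for v in cur.variables})
        assert hits == []

    def test_null_hit_count_calibrated(self):
        """No planted effects: at a fixed p threshold the per-variable
        hit count stays inside the 99% binomial band."""
        pm, cur, meth, _ = _meth_setup(effect=0.0, noise_sd=0.5, seed=73,
                                       n_sites=800, n_assoc=0)
        smvs = call_smvs(meth)
        alpha = 0.05
        hits, scan = ewas_scan(smvs, cur, pm, variables=["BIO2"],
                               thresholds={"BIO2": alpha})
        m = smvs.n_sites
        half = 2.576 * np.sqrt(alpha * (1 - alpha) * m)
        assert abs(len(hits) - alpha * m) <= half

    def test_unknown_variable_rejected(self):
        pm, cur, meth, _ = _meth_setup(effect=1.0, noise_sd=0.3, seed=74,
                                       n_sites=50, n_assoc=0)
        smvs = call_smvs(meth)
        with pytest.raises(ValidationError, match="BIO99"):
            ewas_scan(smvs, cur, pm, variables=["BIO99"])


class TestGeaScan:
    def test_planted_clinal_loci_recovered_with_fdr_control(self):
        """Adaptive loci driven by BIO16: >= 60% recovered at q <= .05,
        false positives within 5x the BH expectation (pooled seeds)."""
        tp = fp = planted = neutral_total = 0
        for seed in range(3):
            spec = LandscapeSpec(n_neutral=800, n_adaptive=30,
                                 cline_strength=3.0, fst_target=0.15,
                                 seed=500 + seed)
            pm, cur, _ = simulate_landscape(spec)
            G, truth = simulate_genotypes(spec, pm, cur)
            hits, _ = gea_scan(G, cur, pm, variables=["BIO16"], q_max=0.05)
            hit_ids = {h.marker for h in hits}
            adaptive = set(truth.adaptive_locus_ids)
            tp += len(hit_ids & adaptive)
            fp += len(hit_ids - adaptive)
            planted += len(adaptive)
            neutral_total += spec.n_neutral
        assert tp / planted >= 0.6
        # BH at q=.05 admits ~5% of *discoveries* false; cap the neutral
        # flag count at five times that expectation
        assert fp <= max(5, 5 * 0.05 * (tp + fp))

    def test_all_neutral_p_values_uniform(self):
        spec = LandscapeSpec(n_neutral=1000, n_adaptive=0, fst_target=0.1,
                             seed=600)
        pm, cur, _ = simulate_landscape(spec)
        G, _ = simulate_genotypes(spec, pm, cur)
        _, scan = gea_scan(G, cur, pm, variables=["BIO4"])
        ks = stats.kstest(scan["p"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_zero_variance_marker_excluded(self, rng):
        from adaptscape.io_formats import GenotypeMatrix, PopulationMap

        spec = LandscapeSpec(n_pops=6, n_neutral=50, n_adaptive=0, seed=601)
        pm, cur, _ = simulate_landscape(spec)
        G, _ = simulate_genotypes(spec, pm, cur)
        dosage = G.dosage.copy()
        dosage[:, 0] = 1  # constant marker
        G2 = GenotypeMatrix(samples=G.samples, loci=G.loci, dosage=dosage)
        _, scan = gea_scan(G2, cur, pm, variables=["BIO2"])
        assert np.isnan(scan.loc[scan["marker"] == 0, "p"]).all()

    def test_variable_overlap_table_counts(self):
        hits = [
            AssociationHit(marker=1, variable="BIO2", beta=1, p=0.01,
                           significant=True),
            AssociationHit(marker=1, variable="BIO4", beta=1, p=0.01,
                           significant=True),
            AssociationHit(marker=2, variable="BIO4", beta=1, p=0.01,
                           significant=True),
        ]
        tab = variable_overlap(hits).set_index("variable")
        assert tab.loc["BIO4", "n_hits"] == 2
        assert tab.loc["BIO4", "shared_BIO2"] == 1


class TestAnnotateProximal:
    FEATURES = FeatureTable(records=pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr2"],
        "start": [1000, 30_000, 500],
        "end": [2000, 31_000, 900],
        "feature_id": ["exonA", "exonB", "exonC"],
        "annotation": ["", "", ""],
    }))

    def hit(self, marker):
        return AssociationHit(marker=marker, variable="BIO2", beta=0.1,
                              p=0.001, significant=True)

    def test_hit_inside_feature_has_distance_zero(self):
        hits = annotate_proximal([self.hit("m1")], {"m1": ("chr1", 1500)},
                                 self.FEATURES)
        assert hits[0].features[0] == ("exonA", 0)

    def test_window_boundary_inclusive_then_exclusive(self):
        at_window = annotate_proximal(
            [self.hit("m")], {"m": ("chr1", 1999 + 10_000)}, self.FEATURES
        )[0]
        beyond = annotate_proximal(
            [self.hit("m")], {"m": ("chr1", 1999 + 10_001)}, self.FEATURES
        )[0]
        assert ("exonA", 10_000) in at_window.features
        assert all(f != "exonA" for f, _ in beyond.features)

    def test_unknown_chromosome_gives_empty_list(self):
        hits = annotate_proximal([self.hit("m")], {"m": ("chrX", 100)},
                                 self.FEATURES)
        assert hits[0].features == []

    def test_matches_bruteforce_all_pairs_scan(self, rng):
        feats = FeatureTable(records=pd.DataFrame({
            "chrom": ["chr1"] * 15,
            "start": (starts := np.sort(rng.integers(0, 500_000, 15))),
            "end": starts + rng.integers(50, 3000, 15),
            "feature_id": [f"g{i}" for i in range(15)],
            "annotation": [""] * 15,
        }))
        window = 10_000
        hits = [self.hit(f"m{i}") for i in range(20)]
        positions = {f"m{i}": ("chr1", int(p))
                     for i, p in enumerate(rng.integers(0, 520_000, 20))}
        out = annotate_proximal(hits, positions, feats, window=window)
        for h in out:
            _, pos = positions[h.marker]
            expected = set()
            for _, row in feats.records.iterrows():
                gap = max(row["start"] - pos, 0) + max(pos - (row["end"] - 1),
                                                       0)
                if gap <= window:
                    expected.add((row["feature_id"], gap))
            assert set(h.features) == expected

    def test_interval_membership_consistency(self, rng):
        """A feature is listed iff the hit position lies in
        [start - window, end + window)."""
        window = 100
        feats = self.FEATURES
        for pos in rng.integers(0, 45_000, 50):
            h = annotate_proximal([self.hit("m")], {"m": ("chr1", int(pos))},
                                  feats, window=window)[0]
            listed = {f for f, _ in h.features}
            for _, row in feats.records[feats.records.chrom == "chr1"].iterrows():
                should = (row["start"] - window) <= pos < (row["end"] + window)
                assert (row["feature_id"] in listed) == should
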