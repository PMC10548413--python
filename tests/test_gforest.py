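"""Gradient-forest turnover functions and genomic offsets."""

import numpy as np
import pandas as pd
import pytest

from adaptscape.gforest import (
    fit_gradient_forest,
    forward_offset,
    local_offset,
    offset_report,
    transform_climate,
)
from adaptscape.io_formats import ClimateTable, ValidationError


def climate_from(X, names=None, scenario="current"):
    names = names or [f"V{j}" for j in range(X.shape[1])]
    return ClimateTable(
        scenario=scenario,
        values=pd.DataFrame(np.asarray(X, float), columns=names,
                            index=[f"S{i}" for i in range(len(X))]),
    )


@pytest.fixture(scope="module")
def fitted_model():
    """Moderate two-predictor fit reused by the transform/offset tests."""
    rng = np.random.default_rng(42)
    n = 16
    X = np.column_stack([np.linspace(0, 1, n), rng.normal(size=n)])
    clim = climate_from(X, ["grad", "noise"])
    Y = pd.DataFrame(
        {j: np.clip(X[:, 0] * 0.8 + rng.normal(0, 0.05, n), 0, 1)
         for j in range(12)},
        index=clim.sites,
    )
    model = fit_gradient_forest(Y, clim, ntree=150, n_bins=101, seed=7)
    return model, clim


class TestFit:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 3))
        clim = climate_from(X)
        Y = pd.DataFrame(rng.random((12, 6)), index=clim.sites)
        m1 = fit_gradient_forest(Y, clim, ntree=60, n_bins=51, seed=5)
        m2 = fit_gradient_forest(Y, clim, ntree=60, n_bins=51, seed=5)
        assert np.array_equal(m1.locus_bin_importance, m2.locus_bin_importance)
        assert np.array_equal(np.nan_to_num(m1.locus_r2),
                              np.nan_to_num(m2.locus_r2))

    def test_step_function_importance_localizes_at_threshold(self):
        """Responses stepping at t: at least half the cumulative
        importance mass falls in the 10% of bins nearest t."""
        n = 20
        x = np.linspace(0, 1, n)
        t = 0.45
        clim = climate_from(x[:, None], ["V"])
        Y = pd.DataFrame({j: (x > t) * 0.6 + 0.2 for j in range(15)},
                         index=clim.sites)
        model = fit_gradient_forest(Y, clim, ntree=150, n_bins=201, seed=1)
        mass = model.importance_bins()[0]
        centers = (model.bin_edges[0][:-1] + model.bin_edges[0][1:]) / 2
        near = np.abs(centers - t) <= 0.05 * (x.max() - x.min())
        assert mass[near].sum() / mass.sum() >= 0.5

    def test_noise_responses_mostly_rejected_and_spread(self):
        """Pure-noise loci: few achieve positive out-of-bag R^2 and no
        single bin hoards the aggregate mass (10-seed average)."""
        rng = np.random.default_rng(3)
        frac_used = []
        max_over_mean = []
        for seed in range(10):
            # evenly spread predictors keep candidate split points even
            X = np.column_stack(
                [rng.permutation(np.linspace(0, 1, 13)) for _ in range(3)]
            )
            clim = climate_from(X)
            Y = pd.DataFrame(rng.random((13, 15)), index=clim.sites)
            m = fit_gradient_forest(Y, clim, ntree=100, n_bins=11, seed=seed)
            used = [i for i in m.used_locus_ids if i != "<none>"]
            frac_used.append(len(used) / 15)
            bins = m.importance_bins()
            if bins.sum() > 0:
                max_over_mean.append(bins.max() / bins.sum())
        assert np.mean(frac_used) < 0.5
        # noise never produces the sharp localization a real threshold
        # does (compare the step-function test: > 50% mass in one spot)
        assert np.mean(max_over_mean) < 1 / 3

    def test_constant_locus_skipped(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 2))
        clim = climate_from(X)
        Y = pd.DataFrame({0: np.full(10, 0.5), 1: rng.random(10)},
                         index=clim.sites)
        m = fit_gradient_forest(Y, clim, ntree=50, n_bins=11, seed=2)
        assert np.isnan(m.locus_r2[0])

    def test_importance_sum_matches_overall(self, fitted_model):
        model, _ = fitted_model
        bins = model.importance_bins()
        overall = model.overall_importance()
        assert np.allclose(bins.sum(axis=1), overall.to_numpy(), atol=1e-9)

    def test_duplicating_every_locus_leaves_turnover_unchanged(self):
        rng = np.random.default_rng(11)
        X = np.column_stack([np.linspace(0, 1, 12), rng.normal(size=12)])
        clim = climate_from(X)
        base = {j: np.clip(X[:, 0] + rng.normal(0, 0.1, 12), 0, 1)
                for j in range(5)}
        Y1 = pd.DataFrame(base, index=clim.sites)
        Y2 = pd.DataFrame({**base, **{j + 10: v for j, v in base.items()}},
                          index=clim.sites)
        m1 = fit_gradient_forest(Y1, clim, ntree=100, n_bins=21, seed=3)
        m2 = fit_gradient_forest(Y2, clim, ntree=100, n_bins=21, seed=3)
        c1, c2 = m1.cumulative(), m2.cumulative()
        # same loci fitted twice: aggregated (mean) turnover is unchanged
        # up to forest sampling noise
        assert np.allclose(c1[:, -1], c2[:, -1], rtol=0.25, atol=0.02)


class TestTransform:
    def test_zero_at_observed_minimum(self, fitted_model):
        model, clim = fitted_model
        mins = clim.values.min(axis=0).to_frame().T
        assert np.allclose(transform_climate(model, mins), 0.0)

    def test_componentwise_monotone(self, fitted_model):
        model, clim = fitted_model
        lo = clim.values.quantile(0.2).to_frame().T
        hi = clim.values.quantile(0.8).to_frame().T
        assert (transform_climate(model, hi)
                >= transform_climate(model, lo) - 1e-12).all()

    def test_matches_piecewise_linear_oracle_at_midpoints(self, fitted_model):
        model, _ = fitted_model
        cum = model.cumulative()
        j = 0
        edges = model.bin_edges[j]
        mids = (edges[:-1] + edges[1:]) / 2
        pts = pd.DataFrame({model.predictors[0]: mids,
                            model.predictors[1]: model.bin_edges[1][0]})
        got = transform_climate(model, pts)[:, j]
        expected = [
            cum[j][k] + (cum[j][k + 1] - cum[j][k]) * 0.5
            for k in range(len(mids))
        ]
        assert np.allclose(got, expected, atol=1e-12)

    def test_out_of_range_clamps(self, fitted_model):
        model, clim = fitted_model
        beyond = clim.values.max(axis=0).to_frame().T + 100.0
        at_max = clim.values.max(axis=0).to_frame().T
        assert np.allclose(transform_climate(model, beyond),
                           transform_climate(model, at_max))

    def test_missing_predictor_fails(self, fitted_model):
        model, _ = fitted_model
        with pytest.raises(ValidationError):
            transform_climate(model, pd.DataFrame({"grad": [0.5]}))


class TestOffsets:
    def test_identical_future_gives_zero_offsets(self, fitted_model):
        model, clim = fitted_model
        fut = ClimateTable(scenario="same", values=clim.values.copy())
        assert np.allclose(local_offset(model, clim, fut).local_offset, 0.0)
        fwd = forward_offset(model, clim, fut)
        assert np.allclose(fwd.forward_offset, 0.0)

    def test_offsets_nonnegative_and_forward_bounded_by_local(
            self, fitted_model):
        model, clim = fitted_model
        fut = ClimateTable(scenario="f",
                           values=clim.values + [0.3, -0.5])
        res = forward_offset(model, clim, fut)
        assert (res.local_offset >= 0).all()
        assert (res.forward_offset <= res.local_offset + 1e-12).all()

    def test_forward_matches_bruteforce_minimum(self, fitted_model):
        model, clim = fitted_model
        sub = ClimateTable(scenario="c", values=clim.values.iloc[:5])
        fut = ClimateTable(scenario="f",
                           values=sub.values + [0.25, 0.8])
        res = forward_offset(model, sub, fut)
        tc = transform_climate(model, sub.values)
        tf = transform_climate(model, fut.values)
        for i in range(5):
            expected = min(
                np.sqrt(((tc[i] - tf[k]) ** 2).sum()) for k in range(5)
            )
            assert res.forward_offset[i] == pytest.approx(expected,
                                                          abs=1e-12)

    def test_linear_region_offset_scales_with_displacement(self,
                                                           fitted_model):
        """Doubling a displacement that stays inside one bin of the
        turnover function exactly doubles the offset."""
        model, clim = fitted_model
        j = 0
        edges = model.bin_edges[j]
        width = edges[1] - edges[0]
        base = clim.values.copy()
        base[:] = np.nan
        row = clim.values.iloc[[0]].copy()
        row[model.predictors[j]] = edges[10] + 0.05 * width
        cur = ClimateTable(scenario="c", values=row)
        d1 = row.copy()
        d1[model.predictors[j]] += 0.2 * width
        d2 = row.copy()
        d2[model.predictors[j]] += 0.4 * width
        o1 = local_offset(model, cur,
                          ClimateTable(scenario="f1", values=d1)).local_offset
        o2 = local_offset(model, cur,
                          ClimateTable(scenario="f2", values=d2)).local_offset
        assert o2[0] == pytest.approx(2 * o1[0], rel=1e-9)

    def test_site_mismatch_rejected(self, fitted_model):
        model, clim = fitted_model
        fut = ClimateTable(scenario="f", values=clim.values.iloc[:-1])
        with pytest.raises(ValidationError):
            local_offset(model, clim, fut)


class TestOffsetReport:
    def test_nested_displacements_give_monotone_offsets(self, fitted_model):
        """RCP-like scenario ladder (d, 2d, 3d along one predictor):
        every site's offset is non-decreasing across scenarios."""
        model, clim = fitted_model
        d = 0.15
        futures = [
            ClimateTable(scenario=f"rcp{k}",
                         values=clim.values + [k * d, 0.0])
            for k in (1, 2, 3)
        ]
        _, report = offset_report(model, clim, futures)
        assert report["monotone_increasing"].all()

    def test_subset_equal_to_all_is_identical(self, fitted_model):
        model, clim = fitted_model
        fut = ClimateTable(scenario="f", values=clim.values + [0.2, 0.1])
        maps_all, _ = offset_report(model, clim, [fut], loci_subset=None)
        maps_sub, _ = offset_report(model, clim, [fut],
                                    loci_subset=list(model.used_locus_ids))
        assert np.allclose(maps_all["f"].local_offset,
                           maps_sub["f"].local_offset)

    def test_single_scenario_report(self, fitted_model):
        model, clim = fitted_model
        fut = ClimateTable(scenario="only", values=clim.values + [0.1, 0.0])
        _, report = offset_report(model, clim, [fut])
        assert list(report.columns[:1]) == ["only"]
        assert report["monotone_increasing"].all()

    def test_empty_subset_rejected(self, fitted_model):
        model, clim = fitted_model
        fut = ClimateTable(scenario="f", values=clim.values)
        with pytest.raises(ValidationError):
            offset_report(model, clim, [fut], loci_subset=[])
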