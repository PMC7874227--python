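"""Initial guesses, anisotropy estimation, WLS fits and the candidate search."""

import numpy as np
import pytest

import stcoverage as sc
from stcoverage import (
    SpaceTimeVariogram,
    SpaceTimeVariogramModel,
    estimate_st_anisotropy,
    grid_search,
    initial_guesses,
)
from stcoverage.empirical import EmpiricalSTVariogram
from stcoverage.fitting import enumerate_candidates

from conftest import BBOX, separable_truth


def grid_from_rows(row_values, max_dist=30.0, max_lag=12):
    """EmpiricalSTVariogram whose spatial rows are constant at given values."""
    row_values = np.asarray(row_values, dtype=float)
    n_rows = len(row_values)
    edges = np.linspace(0.0, max_dist, n_rows)
    dist = np.concatenate(([0.0], 0.5 * (edges[:-1] + edges[1:])))
    lags = np.arange(max_lag + 1)
    gamma = np.tile(row_values[:, None], (1, len(lags)))
    npairs = np.full(gamma.shape, 10, dtype=np.int64)
    return EmpiricalSTVariogram(
        bin_edges=edges, temporal_lags=lags, gamma=gamma, npairs=npairs, dist=dist
    )


def grid_from_model(model, max_dist=60.0, n_rows=16, max_lag=15, npairs=100):
    """Noise-free empirical grid evaluated exactly from a truth model."""
    edges = np.linspace(0.0, max_dist, n_rows)
    dist = np.concatenate(([0.0], 0.5 * (edges[:-1] + edges[1:])))
    lags = np.arange(max_lag + 1)
    G = sc.evaluate_st(
        model,
        np.broadcast_to(dist[:, None], (len(dist), len(lags))),
        np.broadcast_to(lags[None, :].astype(float), (len(dist), len(lags))),
    )
    return EmpiricalSTVariogram(
        bin_edges=edges,
        temporal_lags=lags,
        gamma=np.asarray(G),
        npairs=np.full(G.shape, npairs, dtype=np.int64),
        dist=dist,
    )


SUM_METRIC_TRUTH = SpaceTimeVariogram(
    "sumMetric",
    spatial=sc.ComponentVariogram("exponential", 0.05, 0.5, 30.0),
    temporal=sc.ComponentVariogram("spherical", 0.02, 0.3, 10.0),
    joint=sc.ComponentVariogram("gaussian", 0.0, 0.4, 25.0),
    st_ani=3.0,
)


class TestInitialGuesses:
    def test_median_rules_on_crafted_rows(self):
        """First-three row means {1,2,3} -> nugget 2; last-five means
        {5,5,6,7,8} -> sill 6; max dist 30 -> range 10; max lag 12 -> 12."""
        emp = grid_from_rows([1, 2, 3, 5, 5, 6, 7, 8])
        init = initial_guesses(emp)
        assert init.nugget == pytest.approx(2.0)
        assert init.sill == pytest.approx(6.0)
        assert init.spatial_range == pytest.approx(10.0)
        assert init.temporal_range == pytest.approx(12.0)

    def test_fallback_with_few_rows(self):
        emp = grid_from_rows([1.0, 3.0])
        init = initial_guesses(emp)
        assert init.nugget == pytest.approx(2.0)  # median of all rows
        assert init.sill == pytest.approx(2.0)

    def test_empty_variogram_raises(self):
        emp = grid_from_rows([1, 2, 3])
        emp.gamma[:] = np.nan
        with pytest.raises(ValueError):
            initial_guesses(emp)


class TestAnisotropy:
    @staticmethod
    def _marginal_grid(kappa):
        """Empirical grid whose pure marginals satisfy d(level) = kappa*u(level)."""
        edges = np.linspace(0.0, 40.0, 11)
        dist = np.concatenate(([0.0], 0.5 * (edges[:-1] + edges[1:])))
        lags = np.arange(13)
        # linear shape: piecewise-linear level interpolation is then exact
        f = lambda x: x / 50.0  # noqa: E731
        gamma = np.full((len(dist), len(lags)), np.nan)
        gamma[1:, 0] = f(dist[1:])
        gamma[0, 1:] = f(kappa * lags[1:])
        gamma[0, 0] = np.nan
        npairs = np.where(np.isfinite(gamma), 50, 0).astype(np.int64)
        return EmpiricalSTVariogram(
            bin_edges=edges, temporal_lags=lags, gamma=gamma, npairs=npairs,
            dist=dist,
        )

    def test_axis_scaling_recovered_exactly(self):
        """Identical marginal shapes with the spatial axis stretched 2x."""
        emp = self._marginal_grid(2.0)
        assert estimate_st_anisotropy(emp) == pytest.approx(2.0, rel=1e-6)

    def test_flat_temporal_marginal_falls_back_to_range_ratio(self):
        emp = self._marginal_grid(2.0)
        emp.gamma[0, 1:] = 0.7  # flat: no level matching possible
        kappa = estimate_st_anisotropy(emp)
        assert kappa == pytest.approx((40.0 / 3.0) / 12.0, rel=1e-9)

    def test_recovers_kappa_from_simulated_metric_field(self):
        """Field simulated from a metric truth with kappa* = 5 km/week."""
        truth = SpaceTimeVariogram(
            "metric",
            joint=sc.ComponentVariogram("exponential", 0.05, 1.0, 30.0),
            st_ani=5.0,
        )
        cat = sc.generate_network(n_stations=25, region=BBOX, seed=0)
        panel = sc.simulate_field(cat, 120, truth, seed=50)
        emp = sc.empirical_st_variogram(panel, cat, max_temporal_lag=20)
        kappa = estimate_st_anisotropy(emp)
        assert abs(kappa - 5.0) / 5.0 <= 0.30


class TestFit:
    def test_exact_sum_metric_surface_recovered(self):
        """Noise-free grid from a known sumMetric model: near-zero WMSE and
        parameters within 1e-3 of truth."""
        emp = grid_from_model(SUM_METRIC_TRUTH)
        res = SpaceTimeVariogramModel(
            emp, "sumMetric", ("exponential", "spherical", "gaussian")
        ).fit()
        assert res.wmse <= 1e-6
        truth_params = {
            "spatial_nugget": 0.05, "spatial_psill": 0.45, "spatial_range": 30.0,
            "temporal_nugget": 0.02, "temporal_psill": 0.28, "temporal_range": 10.0,
            "joint_nugget": 0.0, "joint_psill": 0.4, "joint_range": 25.0,
            "st_ani": 3.0,
        }
        for name, expected in truth_params.items():
            assert res.params[name] == pytest.approx(expected, abs=1e-3), name

    def test_all_zero_variogram_collapses_to_zero_sill(self):
        emp = grid_from_rows([0.0] * 8)
        res = SpaceTimeVariogramModel(
            emp, "separable", ("exponential", "exponential")
        ).fit()
        assert res.wmse <= 1e-10
        assert sc.total_sill(res.model) <= 1e-4

    def test_init_perturbation_barely_moves_the_fit(self):
        """+/-20% perturbations of the start move the fitted spatial range
        by < 5% on the exact-surface fixture (stable local optimum)."""
        emp = grid_from_model(SUM_METRIC_TRUTH)
        base_init = initial_guesses(emp)
        ranges = []
        for fac in (0.8, 1.0, 1.2):
            init = sc.InitialParams(
                nugget=base_init.nugget * fac,
                sill=base_init.sill * fac,
                spatial_range=base_init.spatial_range * fac,
                temporal_range=base_init.temporal_range * fac,
                st_ani=base_init.st_ani * fac,
                nugget_temporal=base_init.nugget_temporal * fac,
                sill_temporal=base_init.sill_temporal * fac,
            )
            res = SpaceTimeVariogramModel(
                emp, "sumMetric", ("exponential", "spherical", "gaussian"),
                init=init,
            ).fit()
            ranges.append(res.params["spatial_range"])
        assert max(ranges) / min(ranges) - 1.0 < 0.05

    def test_wmse_invariant_to_weight_rescaling(self):
        emp = grid_from_model(SUM_METRIC_TRUTH)
        m1 = SpaceTimeVariogramModel(emp, "metric", ("exponential",))
        emp2 = EmpiricalSTVariogram(
            bin_edges=emp.bin_edges, temporal_lags=emp.temporal_lags,
            gamma=emp.gamma, npairs=emp.npairs * 17, dist=emp.dist,
        )
        m2 = SpaceTimeVariogramModel(emp2, "metric", ("exponential",))
        probe = SpaceTimeVariogram(
            "metric", joint=sc.ComponentVariogram("exponential", 0.1, 1.0, 20.0),
            st_ani=2.0,
        )
        assert m1.wmse(probe) == pytest.approx(m2.wmse(probe), rel=1e-12)

    def test_fitted_parameters_respect_bounds(self):
        rng = np.random.default_rng(11)
        emp = grid_from_model(SUM_METRIC_TRUTH)
        emp.gamma = emp.gamma + rng.normal(scale=0.05, size=emp.gamma.shape)
        emp.gamma = np.abs(emp.gamma)
        for structure, families in [
            ("separable", ("exponential", "gaussian")),
            ("productSum", ("spherical", "exponential")),
            ("simpleSumMetric", ("gaussian", "spherical", "exponential")),
        ]:
            res = SpaceTimeVariogramModel(emp, structure, families).fit()
            model = res.model
            for comp in (model.spatial, model.temporal, model.joint):
                if comp is None:
                    continue
                assert comp.nugget >= 0
                assert comp.sill >= comp.nugget
                assert comp.range > 0
            assert res.wmse >= 0

    def test_unknown_structure_or_family_rejected(self):
        emp = grid_from_rows([1, 2, 3, 4, 5])
        with pytest.raises(ValueError):
            SpaceTimeVariogramModel(emp, "kronecker", ("exponential",))
        with pytest.raises(ValueError):
            SpaceTimeVariogramModel(emp, "metric", ("matern",))

    def test_summary_mentions_candidate_and_ranges(self):
        emp = grid_from_model(SUM_METRIC_TRUTH)
        res = SpaceTimeVariogramModel(emp, "metric", ("exponential",)).fit()
        text = res.summary()
        assert "metric:exponential" in text
        assert "spatial range" in text


class TestGridSearch:
    def test_enumeration_counts(self):
        cands = enumerate_candidates()
        assert len(cands) == 75
        by_structure = {}
        for structure, _ in cands:
            by_structure[structure] = by_structure.get(structure, 0) + 1
        assert by_structure == {
            "separable": 9, "productSum": 9, "metric": 3,
            "sumMetric": 27, "simpleSumMetric": 27,
        }

    def test_winner_minimises_wmse_over_leaderboard(self):
        emp = grid_from_model(SUM_METRIC_TRUTH, n_rows=10, max_lag=8)
        search = grid_search(emp, maxiter=120)
        lb = search.leaderboard
        assert len(lb) == 75
        assert search.winner.wmse <= lb["wmse"].min() + 1e-15
        assert lb["wmse"].iloc[0] == pytest.approx(search.winner.wmse)

    def test_separable_truth_ranks_separable_high(self):
        """Replicates simulated from a separable truth put a separable
        candidate in the leaderboard top 5 in >= 80% of 20 seeded runs."""
        truth = separable_truth()
        hits = 0
        for seed in range(20):
            cat = sc.generate_network(n_stations=30, region=BBOX, seed=seed)
            panel = sc.simulate_field(cat, 200, truth, seed=1000 + seed)
            emp = sc.empirical_st_variogram(panel, cat, max_temporal_lag=20)
            lb = grid_search(emp, maxiter=150).leaderboard
            if (lb.head(5)["structure"] == "separable").any():
                hits += 1
        assert hits >= 16
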