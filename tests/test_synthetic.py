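"""Synthetic networks, Gaussian-field realisations, structured missingness."""

import numpy as np
import pytest
import shapely

import stcoverage as sc
from stcoverage import (
    MissingnessSpec,
    SimulationConfig,
    apply_missingness,
    generate_network,
    simulate_field,
)
from stcoverage.synthetic import simulate_dataset, write_measurements_csv
from stcoverage.st_models import SpaceTimeVariogram, evaluate_st, total_sill

from conftest import BBOX, separable_truth


class TestNetwork:
    def test_deterministic_under_seed(self):
        a = generate_network(n_stations=12, region=BBOX, seed=42)
        b = generate_network(n_stations=12, region=BBOX, seed=42)
        assert a.equals(b)
        c = generate_network(n_stations=12, region=BBOX, seed=43)
        assert not a.equals(c)

    def test_points_inside_region(self):
        tri = shapely.Polygon([(-99.3, 19.2), (-98.9, 19.2), (-99.1, 19.6)])
        cat = generate_network(n_stations=30, region=tri, seed=0)
        for lon, lat in cat.itertuples(index=False):
            assert tri.contains(shapely.Point(lon, lat))

    def test_minimum_network(self):
        cat = generate_network(n_stations=2, region=BBOX, seed=0)
        assert len(cat) == 2
        assert cat.index.is_unique

    def test_degenerate_region_rejected(self):
        line = shapely.LineString([(0, 0), (1, 1)]).buffer(0)
        with pytest.raises(ValueError):
            generate_network(n_stations=3, region=line, seed=0)


class TestSimulateField:
    def test_seed_determinism(self):
        cat = generate_network(n_stations=8, region=BBOX, seed=1)
        truth = separable_truth()
        a = simulate_field(cat, 30, truth, seed=7)
        b = simulate_field(cat, 30, truth, seed=7)
        c = simulate_field(cat, 30, truth, seed=8)
        assert a.values.equals(b.values)
        assert not a.values.equals(c.values)

    def test_zero_sill_truth_gives_constant_panel(self):
        cat = generate_network(n_stations=5, region=BBOX, seed=2)
        truth = sc.SpaceTimeVariogram(
            "separable",
            spatial=sc.ComponentVariogram("exponential", 0.0, 1.0, 10.0),
            temporal=sc.ComponentVariogram("exponential", 0.0, 1.0, 5.0),
            sill=0.0,
        )
        panel = simulate_field(cat, 20, truth, seed=3)
        assert np.allclose(panel.values.to_numpy(), 0.0, atol=1e-9)

    def test_dense_cell_limit_enforced(self):
        cat = generate_network(n_stations=30, region=BBOX, seed=1)
        truth = SpaceTimeVariogram(
            "metric",
            joint=sc.ComponentVariogram("exponential", 0.0, 1.0, 10.0),
            st_ani=1.0,
        )
        with pytest.raises(ValueError, match="dense"):
            simulate_field(cat, 1000, truth, seed=0)

    def test_sample_variance_approaches_total_sill(self):
        """With weak correlation relative to the domain, the pooled sample
        variance of a large realisation sits near the total sill."""
        truth = separable_truth(spatial_range=5.0, temporal_range=2.0)
        cat = generate_network(n_stations=30, region=BBOX, seed=5)
        panel = simulate_field(cat, 400, truth, seed=6)
        var = float(np.var(panel.values.to_numpy()))
        assert var == pytest.approx(total_sill(truth), rel=0.25)

    def test_empirical_variogram_tracks_truth(self):
        """Mean relative error of the sample vs truth semivariogram below 20%
        over well-populated cells (npairs >= 30)."""
        truth = separable_truth()
        cat = generate_network(n_stations=30, region=BBOX, seed=0)
        panel = simulate_field(cat, 300, truth, seed=100)
        emp = sc.empirical_st_variogram(panel, cat, max_temporal_lag=20)
        H = np.broadcast_to(emp.dist[:, None], emp.gamma.shape)
        U = np.broadcast_to(
            emp.temporal_lags[None, :].astype(float), emp.gamma.shape
        )
        tg = evaluate_st(truth, H, U)
        m = (emp.npairs >= 30) & np.isfinite(emp.gamma) & (tg > 0)
        rel = np.abs(emp.gamma[m] - tg[m]) / tg[m]
        assert m.sum() > 100
        assert rel.mean() < 0.20

    def test_nonseparable_dense_path_runs(self):
        truth = SpaceTimeVariogram(
            "sumMetric",
            spatial=sc.ComponentVariogram("exponential", 0.0, 0.5, 20.0),
            temporal=sc.ComponentVariogram("spherical", 0.0, 0.3, 6.0),
            joint=sc.ComponentVariogram("gaussian", 0.0, 0.2, 15.0),
            st_ani=4.0,
        )
        cat = generate_network(n_stations=10, region=BBOX, seed=3)
        panel = simulate_field(cat, 40, truth, seed=4)
        assert panel.values.shape == (40, 10)
        assert np.isfinite(panel.values.to_numpy()).all()


class TestMissingness:
    def test_activation_blanks_leading_weeks(self):
        cat = generate_network(n_stations=3, region=BBOX, seed=0)
        panel = simulate_field(cat, 20, separable_truth(), seed=1)
        spec = MissingnessSpec(activation_week={"S01": 10})
        out = apply_missingness(panel, spec, seed=0)
        assert out.values["S01"].iloc[:10].isna().all()
        assert out.values["S01"].iloc[10:].notna().all()
        assert out.values["S00"].notna().all()

    def test_shutdown_and_outage(self):
        cat = generate_network(n_stations=2, region=BBOX, seed=0)
        panel = simulate_field(cat, 30, separable_truth(), seed=1)
        spec = MissingnessSpec(
            shutdown_week={"S00": 25}, outages=[("S01", 5, 8)]
        )
        out = apply_missingness(panel, spec, seed=0)
        assert out.values["S00"].iloc[25:].isna().all()
        assert out.values["S00"].iloc[:25].notna().all()
        assert out.values["S01"].iloc[5:8].isna().all()
        assert out.values["S01"].iloc[8:].notna().all()

    def test_no_op_spec_is_identity(self):
        cat = generate_network(n_stations=4, region=BBOX, seed=0)
        panel = simulate_field(cat, 25, separable_truth(), seed=1)
        out = apply_missingness(panel, MissingnessSpec(), seed=5)
        assert out.values.equals(panel.values)

    def test_dropout_counts_are_binomial(self):
        """Rate 0.1 over 1000 cells: 100 +/- 30 newly missing across seeds."""
        cat = generate_network(n_stations=10, region=BBOX, seed=0)
        panel = simulate_field(cat, 100, separable_truth(), seed=1)
        for seed in range(5):
            out = apply_missingness(
                panel, MissingnessSpec(dropout_rate=0.1), seed=seed
            )
            n_missing = int(out.values.isna().sum().sum())
            assert 70 <= n_missing <= 130

    def test_invalid_dropout_rate_rejected(self):
        with pytest.raises(ValueError):
            MissingnessSpec(dropout_rate=1.0)


class TestDatasetAndIO:
    def test_simulate_dataset_round_trips_through_ingest(self, tmp_path):
        """The generator emits the same CSV dialect the ingest module reads:
        aggregating the expanded hourly records reproduces the panel."""
        cfg = SimulationConfig(
            n_stations=4,
            n_weeks=8,
            truth=separable_truth(),
            missingness=MissingnessSpec(activation_week={"S02": 3}),
            seed=9,
        )
        catalogue, panel = simulate_dataset(cfg)
        # shift to positive concentrations: negatives are sentinel-missing
        # in the CSV dialect
        panel.values = panel.values + 100.0
        table = sc.panel_to_hourly(panel, "NO2")
        path = tmp_path / "meas.csv"
        write_measurements_csv(table, path)
        panel2 = sc.aggregate_weekly(sc.read_measurements(path, "NO2"))
        common = panel.values.dropna(axis=1, how="all").columns
        a = panel.values[common]
        b = panel2.values.reindex(index=a.index, columns=common)
        assert np.allclose(
            a.to_numpy(), b.to_numpy(), equal_nan=True, atol=1e-9
        )

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_stations=1, n_weeks=10, truth=separable_truth())
        with pytest.raises(ValueError):
            SimulationConfig(n_stations=5, n_weeks=1, truth=separable_truth())
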