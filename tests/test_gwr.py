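import numpy as np
import pandas as pd
import pytest

from esbalance.gwr import (
    DesignMatrix,
    gwr_fit,
    ols_fit,
    select_bandwidth,
    vif_screen,
)


def _design(y, X, coords=None, **kw):
    X = pd.DataFrame(X)
    if coords is None:
        rng = np.random.default_rng(0)
        coords = rng.random((len(X), 2))
    return DesignMatrix(np.asarray(y, float), X, coords, **kw)


def _lattice_coords(side):
    u = np.repeat(np.arange(side), side) / side
    v = np.tile(np.arange(side), side) / side
    return np.column_stack([u, v])


class TestOls:
    def test_exact_linear_fit(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        d = _design(2.0 * x + 1.0, {"x": x})
        fit = ols_fit(d)
        assert fit.r2 == pytest.approx(1.0)
        assert np.allclose(fit.residuals, 0.0, atol=1e-10)

    def test_orthogonal_response_zero_slope(self):
        x = np.array([-1.0, 1.0] * 25)
        y = np.array([1.0, 1.0, -1.0, -1.0] * 12 + [1.0, 1.0])
        d = _design(y - y.mean(), {"x": x - x.mean()})
        fit = ols_fit(d)
        assert fit.coefficients["x"] == pytest.approx(0.0, abs=1e-12)

    def test_simulation_recovery_within_three_se(self):
        rng = np.random.default_rng(77)
        x = rng.normal(size=200)
        y = 2.0 * x + 1.0 + rng.normal(0, 0.1, 200)
        fit = ols_fit(_design(y, {"x": x}))
        se_slope = 0.1 / np.sqrt(((x - x.mean()) ** 2).sum())
        assert abs(fit.coefficients["x"] - 2.0) < 3 * se_slope
        assert abs(fit.coefficients["intercept"] - 1.0) < 3 * 0.1 / np.sqrt(200)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        d = _design(rng.normal(size=30), {"a": x, "b": 2 * x})
        with pytest.raises(np.linalg.LinAlgError, match="a"):
            ols_fit(d)


class TestVif:
    def test_orthonormal_predictors_have_unit_vif(self):
        n = 64
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        rng = np.random.default_rng(5)
        y = a + b + rng.normal(0, 0.1, n)
        report, _ = vif_screen(_design(y, {"a": a, "b": b}))
        assert np.allclose(report.table["vif"], 1.0, atol=1e-9)
        assert report.retained == ["a", "b"]

    def test_duplicated_predictor_dropped(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=40)
        y = x + rng.normal(0, 0.1, 40)
        with pytest.raises(np.linalg.LinAlgError):
            # exact duplicate makes the OLS design singular, reported as such
            vif_screen(_design(y, {"a": x, "b": x.copy()}))

    def test_near_duplicate_exceeds_vif_max(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=200)
        near = x + rng.normal(0, 0.01, 200)
        z = rng.normal(size=200)
        y = x + z + rng.normal(0, 0.1, 200)
        report, reduced = vif_screen(
            _design(y, {"a": x, "b": near, "z": z}), vif_max=7.5)
        tab = report.table.set_index("predictor")
        assert tab.loc["a", "vif"] > 7.5
        assert tab.loc["b", "vif"] > 7.5
        assert "z" in report.retained

    def test_screen_keeps_informative_drops_noise(self):
        # ten predictors, two carrying no signal: the screen should retain
        # the eight informative ones (the published screen's shape)
        rng = np.random.default_rng(42)
        n = 300
        X = {f"x{i}": rng.normal(size=n) for i in range(10)}
        y = sum(X[f"x{i}"] for i in range(8)) + rng.normal(0, 0.5, n)
        report, reduced = vif_screen(_design(y, X), alpha=0.01)
        assert report.retained == [f"x{i}" for i in range(8)]
        assert reduced.X.shape[1] == 8


class TestGwr:
    def test_kernel_identity_at_zero_distance(self):
        # a unit at distance zero from the regression point has weight one,
        # so with a tiny bandwidth each local fit passes near its own point
        rng = np.random.default_rng(8)
        x = rng.normal(size=36)
        y = rng.normal(size=36)
        d = _design(y, {"x": x}, coords=_lattice_coords(6))
        fit = gwr_fit(d, bandwidth=0.05)
        assert np.abs(fit.residuals).max() < np.abs(y - y.mean()).max()
        assert fit.r2 > 0.9

    def test_large_bandwidth_reproduces_ols(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=100)
        y = 1.5 * x + rng.normal(0, 0.2, 100)
        d = _design(y, {"x": x}, coords=_lattice_coords(10))
        ols = ols_fit(d)
        fit = gwr_fit(d, bandwidth=1e4)  # >= 100x the domain diameter
        diff = np.abs(fit.coefficients.to_numpy()
                      - ols.coefficients.to_numpy()[None, :])
        assert diff.max() < 1e-6

    def test_local_coefficient_recovery(self):
        rng = np.random.default_rng(42)
        coords = _lattice_coords(20)
        u = coords[:, 0]
        x = rng.normal(size=400)
        beta = 1.0 + u
        y = beta * x + rng.normal(0, 0.05, 400)
        d = _design(y, {"x": x}, coords=coords)
        bw = select_bandwidth(d)
        fit = gwr_fit(d, bw)
        corr = np.corrcoef(fit.coefficients["x"], beta)[0, 1]
        assert corr > 0.95

    def test_gwr_r2_at_least_ols(self):
        rng = np.random.default_rng(10)
        coords = _lattice_coords(10)
        x = rng.normal(size=100)
        y = (1 + coords[:, 0]) * x + rng.normal(0, 0.1, 100)
        d = _design(y, {"x": x}, coords=coords)
        bw = select_bandwidth(d)
        assert gwr_fit(d, bw).r2 >= ols_fit(d).r2

    def test_aicc_improves_under_spatial_variation(self):
        rng = np.random.default_rng(11)
        coords = _lattice_coords(12)
        x = rng.normal(size=144)
        y = (1 + 2 * coords[:, 0]) * x + rng.normal(0, 0.1, 144)
        d = _design(y, {"x": x}, coords=coords)
        bw = select_bandwidth(d)
        assert gwr_fit(d, bw).aicc < ols_fit(d).aicc

    def test_trace_bounds(self):
        rng = np.random.default_rng(12)
        coords = _lattice_coords(8)
        x = rng.normal(size=64)
        y = x + rng.normal(0, 0.1, 64)
        d = _design(y, {"x": x}, coords=coords)
        fit = gwr_fit(d, 0.2)
        assert 2 - 1e-6 < fit.trace_s < 64

    def test_nonpositive_bandwidth_rejected(self):
        rng = np.random.default_rng(13)
        d = _design(rng.normal(size=25), {"x": rng.normal(size=25)},
                    coords=_lattice_coords(5))
        with pytest.raises(ValueError):
            gwr_fit(d, 0.0)


class TestBandwidthSelection:
    def test_constant_process_prefers_wide_bandwidth(self):
        rng = np.random.default_rng(14)
        coords = _lattice_coords(10)
        x = rng.normal(size=100)
        y = 2.0 * x + rng.normal(0, 0.1, 100)  # no spatial variation
        d = _design(y, {"x": x}, coords=coords)
        bw = select_bandwidth(d)
        diameter = np.sqrt(2) * (1 - 1 / 10)
        assert bw > diameter / 2

    def test_strong_gradient_prefers_narrow_bandwidth(self):
        rng = np.random.default_rng(15)
        coords = _lattice_coords(15)
        x = rng.normal(size=225)
        y = (1 + 4 * coords[:, 0]) * x + rng.normal(0, 0.05, 225)
        d = _design(y, {"x": x}, coords=coords)
        bw = select_bandwidth(d)
        diameter = np.sqrt(2) * (1 - 1 / 15)
        assert bw < diameter / 2

    def test_invariant_to_observation_order(self):
        rng = np.random.default_rng(16)
        coords = _lattice_coords(8)
        x = rng.normal(size=64)
        y = (1 + coords[:, 0]) * x + rng.normal(0, 0.1, 64)
        d = _design(y, {"x": x}, coords=coords)
        perm = rng.permutation(64)
        d2 = _design(y[perm], {"x": x[perm]}, coords=coords[perm])
        assert select_bandwidth(d) == pytest.approx(select_bandwidth(d2),
                                                    rel=1e-6)
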