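"""ΔT, windowed coupling slopes, β aggregation and classification."""

import numpy as np
import pytest

from thermoreg import (
    EmptyInputError,
    ThermoClass,
    Treatment,
    beta,
    beta_pooled,
    classify_thermoregulation,
    coupling_metrics,
    coupling_slopes,
    thermal_offset,
)
from thermoreg.coupling import NoValidWindowsError
from thermoreg.types import WindowSlope

from conftest import make_series


class TestThermalOffset:
    def test_sign_convention(self):
        s = make_series([36.0, 34.0], [35.0, 35.5])
        delta, mean = thermal_offset(s)
        assert delta.tolist() == [1.0, -1.5]
        assert mean == pytest.approx(-0.25)

    def test_swapping_channels_negates(self):
        rng = np.random.default_rng(3)
        leaf = 25 + rng.normal(0, 1, 30)
        air = 24 + rng.normal(0, 1, 30)
        d1, m1 = thermal_offset(make_series(leaf, air))
        d2, m2 = thermal_offset(make_series(air, leaf))
        np.testing.assert_allclose(d1, -d2)
        assert m1 == pytest.approx(-m2)

    def test_empty_series_raises(self):
        s = make_series([], [])
        with pytest.raises(EmptyInputError):
            thermal_offset(s)


class TestCouplingSlopes:
    def test_exact_slope_on_collinear_points(self):
        s = make_series([30.0, 30.5, 31.0], [30.0, 31.0, 32.0])
        slopes = coupling_slopes(s, min_points=3)
        retained = [w for w in slopes if w.retained]
        assert len(retained) == 1
        assert retained[0].slope == pytest.approx(0.5, abs=1e-15)
        assert retained[0].r2 == pytest.approx(1.0)

    def test_constant_air_window_skipped(self):
        # Two windows: one sloped, one with a degenerate (constant) regressor.
        minutes = np.concatenate([750 + np.arange(12.0), 780 + np.arange(12.0)])
        air = np.concatenate([30 + 0.1 * np.arange(12.0), np.full(12, 31.0)])
        leaf = air + 1.0
        s = make_series(leaf, air, minutes=minutes)
        slopes = coupling_slopes(s)
        assert [w.retained for w in slopes] == [True, False]
        assert slopes[1].note == "air range too small"

    def test_too_few_points_skipped(self):
        minutes = np.concatenate([750 + np.arange(15.0), [785.0, 786.0]])
        air = np.concatenate([20 + 0.1 * np.arange(15.0), [22.0, 23.0]])
        s = make_series(air, air, minutes=minutes)
        slopes = coupling_slopes(s)
        assert slopes[0].retained and not slopes[1].retained

    def test_no_valid_windows_names_plant(self):
        s = make_series([20.0, 20.0], [25.0, 25.0], plant_id="XYZ-1")
        with pytest.raises(NoValidWindowsError, match="XYZ-1"):
            coupling_slopes(s)

    def test_windows_partition_left_anchored(self):
        minutes = 750 + np.arange(90.0)  # exactly three 30-min windows
        air = 25 + np.sin(np.arange(90.0) / 7.0)
        s = make_series(air, air, minutes=minutes)
        slopes = coupling_slopes(s)
        assert [w.start_minute for w in slopes] == [750.0, 780.0, 810.0]
        assert all(w.n_points == 30 for w in slopes)


class TestBeta:
    def test_mean_of_retained_slopes(self):
        ws = [
            WindowSlope(750, 0.9, 30, 0.9),
            WindowSlope(780, 1.1, 30, 0.9),
            WindowSlope(810, float("nan"), 3, float("nan"), retained=False),
        ]
        assert beta(ws) == pytest.approx(1.0)

    def test_single_window(self):
        assert beta([WindowSlope(750, 0.73, 30, 0.8)]) == pytest.approx(0.73)

    def test_identity_series_gives_beta_one_and_zero_offset(self):
        minutes = 750 + np.arange(60.0)
        air = 25 + np.sin(np.arange(60.0) / 5.0)
        s = make_series(air, air, minutes=minutes)
        cm = coupling_metrics(s)
        assert cm.beta == pytest.approx(1.0, abs=1e-12)
        assert cm.delta_t_mean == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(cm.delta_t_series, 0.0, atol=1e-12)

    def test_pooled_alternative(self):
        minutes = 750 + np.arange(60.0)
        air = 25 + 0.05 * np.arange(60.0)
        leaf = 2.0 + 0.8 * air
        s = make_series(leaf, air, minutes=minutes)
        assert beta_pooled(s) == pytest.approx(0.8, abs=1e-12)
        cm = coupling_metrics(s, method="pooled")
        assert cm.beta == pytest.approx(0.8, abs=1e-12)


class TestClassification:
    @pytest.mark.parametrize(
        "b,expected",
        [
            (1.0, ThermoClass.POIKILOTHERM),
            (0.8, ThermoClass.LIMITED_HOMEOTHERM),
            (1.3, ThermoClass.MEGATHERM),
            (0.9, ThermoClass.POIKILOTHERM),   # boundary |β−1| = ε inclusive
            (1.1, ThermoClass.POIKILOTHERM),
            (0.89999, ThermoClass.LIMITED_HOMEOTHERM),
            (1.10001, ThermoClass.MEGATHERM),
        ],
    )
    def test_boundaries(self, b, expected):
        assert classify_thermoregulation(b) == expected

    def test_custom_epsilon(self):
        assert classify_thermoregulation(1.2, epsilon=0.25) == ThermoClass.POIKILOTHERM

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_thermoregulation(float("nan"))


class TestInvariances:
    def _series(self, seed=0, n=120, slope=0.9, offset=1.5, noise=0.2):
        rng = np.random.default_rng(seed)
        air = 25 + np.cumsum(rng.normal(0, 0.2, n))
        air = np.clip(air, 18, 40)
        leaf = air.mean() + offset + slope * (air - air.mean()) + rng.normal(0, noise, n)
        return make_series(leaf, air, minutes=750 + np.arange(float(n)))

    def test_shift_both_channels_preserves_slopes_and_offset(self):
        s = self._series()
        shifted = make_series(s.t_leaf + 3.0, s.t_air + 3.0, minutes=s.minutes)
        a = coupling_metrics(s)
        b_ = coupling_metrics(shifted)
        assert b_.beta == pytest.approx(a.beta, abs=1e-10)
        assert b_.delta_t_mean == pytest.approx(a.delta_t_mean, abs=1e-10)

    def test_shift_leaf_only_moves_offset_not_slopes(self):
        s = self._series()
        shifted = make_series(s.t_leaf + 2.5, s.t_air, minutes=s.minutes)
        a = coupling_metrics(s)
        b_ = coupling_metrics(shifted)
        assert b_.beta == pytest.approx(a.beta, abs=1e-10)
        assert b_.delta_t_mean == pytest.approx(a.delta_t_mean + 2.5, abs=1e-10)

    @pytest.mark.parametrize("sigma,tol", [(0.5, 0.12), (0.1, 0.03), (0.01, 0.003)])
    def test_beta_recovery_improves_as_noise_shrinks(self, sigma, tol):
        """Mean estimated β over replicates approaches the generating slope."""
        errs = []
        for seed in range(100):
            cm = coupling_metrics(self._series(seed=seed, slope=0.9, noise=sigma))
            errs.append(cm.beta - 0.9)
        assert abs(np.mean(errs)) < tol

    def test_recovery_slope_1p2_sigma_0p2(self):
        """Generating slope 1.2, σ = 0.2 °C, 150 min: mean β within 0.1."""
        betas = [
            coupling_metrics(self._series(seed=s, n=150, slope=1.2, noise=0.2)).beta
            for s in range(200)
        ]
        assert abs(np.mean(betas) - 1.2) < 0.1
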