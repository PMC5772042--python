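"""Ventricular pumping function, volume and aortic waveforms, and
intramyocardial coupling."""

import math

import numpy as np
import pytest

from coroflow.drivers import (
    LV_DEFAULTS,
    DriverSet,
    ImCoupling,
    VentricleParams,
    activation,
    default_aortic_pressure,
    default_driver_set,
    default_volume_waveform,
    intramyocardial_pressure,
    phase_discontinuity,
    ventricular_pressure,
)
from coroflow.patient import TABLE_VENTRICLE


@pytest.mark.parametrize(
    "t_frac,expected",
    [(0.0, 0.0), (0.25, 1.0), (0.5, 2.0), (1.0, 0.0)],
)
def test_activation_reference_points(t_frac, expected):
    ts = 0.3
    assert activation(t_frac * ts, ts) == pytest.approx(expected, abs=1e-12)


def test_activation_bounded_and_rejects_bad_ts():
    ts = 0.24
    sigma = [activation(t, ts) for t in np.linspace(0, ts, 100)]
    assert min(sigma) >= 0 and max(sigma) <= 2
    with pytest.raises(ValueError):
        activation(0.1, 0.0)


class TestVentricularPressure:
    def _lv(self, **kw):
        base = dict(Rv=0.08, U0=50.0, Ed=0.10, V0=11.29, E=0.0, ts=0.24)
        base.update(kw)
        return VentricleParams(**base)

    def test_diastole_at_reference_volume_is_zero(self):
        lv = self._lv()
        vol = default_volume_waveform(lv.V0, 0.0, lv.ts, 0.8, residual=0.0)
        assert ventricular_pressure(0.5, lv, vol) == pytest.approx(0.0)

    def test_diastolic_passive_elastance(self):
        # Ed = 0.10 mmHg/ml, V − V0 = 100 ml -> 10 mmHg
        lv = self._lv()
        vol = default_volume_waveform(lv.V0, 0.0, lv.ts, 0.8, residual=100.0)
        assert ventricular_pressure(0.5, lv, vol) == pytest.approx(10.0)

    def test_peak_systolic_activation(self):
        # at mid-systole σ = 2, so with V = V0 and V̇ = 0, P = 2·U0 = 100
        lv = self._lv()
        vol = default_volume_waveform(lv.V0, 0.0, lv.ts, 0.8, residual=0.0)
        assert ventricular_pressure(lv.ts / 2, lv, vol) == pytest.approx(100.0)

    def test_phase_discontinuity_reported_finite(self):
        drv = default_driver_set()
        j0, jts = phase_discontinuity(drv.lv_params, drv.lv_volume)
        assert math.isfinite(j0) and math.isfinite(jts)
        assert j0 >= 0 and jts >= 0

    def test_default_lv_peak_is_physiological(self):
        """With the default elastance the pumping function peaks just
        above systolic aortic pressure (it must eject against 120 mmHg)."""
        drv = default_driver_set()
        t = np.linspace(0, drv.period, 1600)
        p = [ventricular_pressure(ti, drv.lv_params, drv.lv_volume) for ti in t]
        assert 115 <= max(p) <= 140

    def test_tabulated_parameters_match_driver_defaults(self):
        for key in ("Rv", "U0", "Ed", "V0"):
            assert LV_DEFAULTS[key] == TABLE_VENTRICLE["lv"][key]


class TestIntramyocardialPressure:
    @pytest.mark.parametrize(
        "pv,factor,expected",
        [(120.0, 1 / 3, 40.0), (120.0, 0.5, 60.0), (0.0, 0.5, 0.0)],
    )
    def test_fractions(self, pv, factor, expected):
        assert intramyocardial_pressure(pv, factor) == pytest.approx(expected)

    def test_other_fraction_needs_override(self):
        with pytest.raises(ValueError):
            intramyocardial_pressure(100.0, 0.25)
        assert intramyocardial_pressure(
            100.0, 0.25, allow_any_factor=True
        ) == pytest.approx(25.0)

    def test_chamber_label_validated(self):
        with pytest.raises(ValueError):
            ImCoupling("atrium", 0.5)


class TestVolumeWaveform:
    def test_zero_stroke_is_constant(self):
        vol = default_volume_waveform(10.0, 0.0, 0.24, 0.8)
        t = np.linspace(0, 0.8, 50)
        assert np.ptp([vol.volume(ti) for ti in t]) == 0.0
        assert all(vol.dvdt(ti) == 0.0 for ti in t)

    def test_cycle_volume_balance(self):
        vol = default_volume_waveform(11.29, 70.0, 0.24, 0.8)
        t = np.linspace(0, 0.8, 20001)
        net = np.trapezoid([vol.dvdt(ti) for ti in t], t)
        assert abs(net) < 1e-5 * 70.0  # quadrature-limited
        # the ejected and refilled volumes are exactly the stroke volume
        assert vol.volume(0.0) - vol.volume(0.24) == pytest.approx(70.0)
        assert vol.volume(0.8 - 1e-12) == pytest.approx(vol.volume(0.0))

    def test_volume_stays_above_reference(self):
        vol = default_volume_waveform(11.29, 70.0, 0.24, 0.8)
        vmin = min(vol.volume(ti) for ti in np.linspace(0, 0.8, 400))
        assert vmin >= 11.29

    def test_peak_ejection_rate_inside_systole(self):
        ts = 0.24
        vol = default_volume_waveform(11.29, 70.0, ts, 0.8)
        t = np.linspace(0, 0.8, 4000, endpoint=False)
        rates = np.array([vol.dvdt(ti) for ti in t])
        assert t[np.argmax(np.abs(rates))] < ts

    def test_rejects_bad_stroke(self):
        with pytest.raises(ValueError):
            default_volume_waveform(10.0, -1.0, 0.24, 0.8)


class TestAorticPressure:
    def test_bounds_and_degenerate(self):
        wf = default_aortic_pressure(0.8, 80.0, 120.0, 0.24)
        vals = np.array([wf(t) for t in np.linspace(0, 0.8, 5000)])
        assert vals.min() == pytest.approx(80.0, abs=0.5)
        assert vals.max() == pytest.approx(120.0, abs=0.5)
        assert 80.0 < vals.mean() < 120.0
        const = default_aortic_pressure(0.8, 95.0, 95.0, 0.24)
        assert all(const(t) == 95.0 for t in np.linspace(0, 0.8, 20))

    def test_rejects_inverted_pressures(self):
        with pytest.raises(ValueError):
            default_aortic_pressure(0.8, 120.0, 80.0, 0.24)

    def test_upstroke_lags_activation_onset(self):
        # isovolumic contraction: aortic pressure still near diastolic
        # just after t = 0
        wf = default_aortic_pressure(0.8, 80.0, 120.0, 0.24)
        assert wf(0.02) == pytest.approx(80.0, abs=2.0)


class TestDriverSetPeriodicity:
    def test_all_waveforms_exactly_periodic(self):
        drv = default_driver_set()
        T = drv.period
        for t in np.linspace(0.0, T, 37):
            assert drv.aortic(t + T) == pytest.approx(drv.aortic(t), abs=1e-12)
            assert drv.lv_volume(t + T) == pytest.approx(
                drv.lv_volume(t), abs=1e-12
            )
            assert drv.ventricular_pressure_mmhg(
                "lv", t + T
            ) == pytest.approx(
                drv.ventricular_pressure_mmhg("lv", t), abs=1e-12
            )

    def test_mismatched_periods_rejected(self):
        drv = default_driver_set()
        bad_vol = default_volume_waveform(11.29, 70.0, 0.24, 0.9)
        with pytest.raises(ValueError):
            DriverSet(
                lv_params=drv.lv_params,
                rv_params=drv.rv_params,
                lv_volume=bad_vol,
                rv_volume=drv.rv_volume,
                aortic=drv.aortic,
                venous=drv.venous,
                period=0.8,
            )

    def test_im_map_factor_validated(self):
        drv = default_driver_set()
        with pytest.raises(ValueError):
            DriverSet(
                lv_params=drv.lv_params,
                rv_params=drv.rv_params,
                lv_volume=drv.lv_volume,
                rv_volume=drv.rv_volume,
                aortic=drv.aortic,
                venous=drv.venous,
                im_map={"x": ImCoupling("lv", 0.9)},
                period=0.8,
            )
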