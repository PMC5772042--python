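"""Stenosis scaling, head-loss element, network validation, and the
assembled state equations."""

import dataclasses
import math

import numpy as np
import pytest

from coroflow.drivers import default_driver_set
from coroflow.network import (
    HeadLossSpec,
    NetworkError,
    NetworkSpec,
    SegmentSpec,
    Terminal,
    alpha_from_percent,
    apply_stenosis,
    assemble_odes,
    headloss_resistance,
    loss_coefficient,
)
from coroflow.simulate import SimulationConfig, integrate
from coroflow.units import MMHG_PA, VesselRLC, convert_units


class TestStenosisScaling:
    def test_identity_at_full_area(self):
        rlc = VesselRLC(R=2.0, L=0.5, C=0.1)
        assert apply_stenosis(rlc, 1.0) == rlc

    @pytest.mark.parametrize(
        "alpha,fr,fc,fl",
        [(0.5, 4.0, 0.5**1.5, 2.0), (0.25, 16.0, 0.125, 4.0)],
    )
    def test_exact_power_laws(self, alpha, fr, fc, fl):
        rlc = VesselRLC(R=2.0, L=0.5, C=0.1)
        s = apply_stenosis(rlc, alpha)
        assert s.R == pytest.approx(rlc.R * fr, rel=1e-12)
        assert s.C == pytest.approx(rlc.C * fc, rel=1e-12)
        assert s.L == pytest.approx(rlc.L * fl, rel=1e-12)

    def test_out_of_range_rejected(self):
        rlc = VesselRLC(R=1.0)
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                apply_stenosis(rlc, bad)

    @pytest.mark.parametrize(
        "p,convention,expected",
        [(50, "area", 0.5), (50, "radius", 0.25), (0, "area", 1.0),
         (0, "radius", 1.0), (90, "area", 0.1)],
    )
    def test_alpha_from_percent(self, p, convention, expected):
        assert alpha_from_percent(p, convention) == pytest.approx(expected)

    def test_alpha_from_percent_range(self):
        with pytest.raises(ValueError):
            alpha_from_percent(100.0)
        with pytest.raises(ValueError):
            alpha_from_percent(-1.0)


class TestHeadLoss:
    @pytest.mark.parametrize("re,expected", [(100, 2.88), (288, 1.0), (144, 2.0)])
    def test_loss_coefficient(self, re, expected):
        assert loss_coefficient(re) == pytest.approx(expected, rel=1e-12)

    def test_loss_coefficient_domain(self):
        with pytest.raises(ValueError):
            loss_coefficient(0.0)

    def test_zero_flow_zero_resistance(self):
        assert headloss_resistance(0.0, 7e-6, 1040.0, 2.88) == 0.0

    def test_reference_magnitude(self):
        # ξ = 2.88, ρ = 1040 kg/m³, ostium radius 1.5 mm, q = 2 ml/s
        A = math.pi * (1.5e-3) ** 2
        rh = headloss_resistance(2e-6, A, 1040.0, 2.88)
        assert convert_units(rh, "R_SI", "R_clinical") == pytest.approx(
            0.45, abs=0.005
        )

    def test_proportional_to_flow_and_sign_symmetric(self):
        A = 7e-6
        r1 = headloss_resistance(1e-6, A, 1040.0, 2.88)
        assert headloss_resistance(2e-6, A, 1040.0, 2.88) == pytest.approx(2 * r1)
        assert headloss_resistance(-1e-6, A, 1040.0, 2.88) == pytest.approx(r1)


def _seg(name, a, b, R=1.0, L=0.0, C=0.0, **kw):
    return SegmentSpec(
        name, a, b,
        rlc=VesselRLC(
            R=convert_units(R, "R_clinical", "R_SI"),
            L=convert_units(L, "L_clinical", "L_SI"),
            C=convert_units(C, "C_clinical", "C_SI"),
        ),
        **kw,
    )


class TestValidation:
    def test_disconnected_graph_rejected(self):
        net = NetworkSpec(
            [_seg("a", "AORTA", "VEIN"), _seg("b", "x", "y", C=0.1)], {}
        )
        with pytest.raises(NetworkError, match="connected"):
            net.validate()

    def test_dangling_leaf_rejected(self):
        net = NetworkSpec([_seg("a", "AORTA", "dead")], {})
        with pytest.raises(NetworkError, match="leaf"):
            net.validate()

    def test_leaf_with_terminal_or_compliance_accepted(self):
        NetworkSpec(
            [_seg("a", "AORTA", "end")], {"end": Terminal(Z=1e9)}
        ).validate()
        NetworkSpec([_seg("a", "AORTA", "end", C=0.01)], {}).validate()

    def test_conflicting_element_definitions_rejected(self):
        with pytest.raises(NetworkError, match="exactly one"):
            SegmentSpec("x", "a", "b")

    def test_headloss_on_resistive_branch_rejected(self):
        net = NetworkSpec(
            [_seg("a", "AORTA", "VEIN",
                  headloss=HeadLossSpec(area=7e-6))],
            {},
        )
        with pytest.raises(NetworkError, match="head loss"):
            assemble_odes(net, default_driver_set())

    def test_pure_inductive_junction_rejected(self):
        net = NetworkSpec(
            [
                _seg("a", "AORTA", "j", L=0.1),
                _seg("b", "j", "VEIN", L=0.1),
            ],
            {},
        )
        with pytest.raises(NetworkError, match="junction"):
            assemble_odes(net, default_driver_set())


class TestAssembledSystem:
    def _drivers(self, p_aortic, venous=0.0):
        return dataclasses.replace(
            default_driver_set(p_dia=p_aortic, p_sys=p_aortic, venous=venous),
            im_map={},
        )

    def test_series_resistors_ohmic_flow(self):
        net = NetworkSpec(
            [_seg("r1", "AORTA", "m", R=1.0), _seg("r2", "m", "VEIN", R=3.0)],
            {},
        )
        sys_ = assemble_odes(net, self._drivers(100.0))
        flows = sys_.segment_flows(0.0, sys_.initial_state())
        q_expect = 100.0 / 4.0 * 1e-6  # ml/s in m³/s
        assert flows["r1"] == pytest.approx(q_expect, rel=1e-12)
        assert flows["r2"] == pytest.approx(q_expect, rel=1e-12)

    def test_kirchhoff_residual_at_junction(self):
        net = NetworkSpec(
            [
                _seg("r1", "AORTA", "m", R=1.0),
                _seg("r2", "m", "VEIN", R=3.0),
                _seg("r3", "m", "VEIN", R=5.0),
            ],
            {},
        )
        sys_ = assemble_odes(net, self._drivers(90.0))
        assert sys_.kirchhoff_residual(0.0, sys_.initial_state()) < 1e-9

    def test_zero_drivers_zero_state_is_fixed_point(self):
        net = NetworkSpec(
            [
                _seg("a", "AORTA", "n1", R=1.0, L=0.1, C=0.01),
                _seg("b", "n1", "VEIN", R=2.0, L=0.05, C=0.02),
            ],
            {},
        )
        drv = self._drivers(0.0, venous=0.0)
        sys_ = assemble_odes(net, drv)
        x0 = sys_.initial_state()
        for t in (0.0, 0.1, 0.5):
            assert np.allclose(sys_.rhs(t, x0), 0.0, atol=1e-14)
        # and the integrator stays there
        t, y, _ = integrate(net, drv, 0.4, SimulationConfig(), n_samples=50)
        assert np.max(np.abs(y)) < 1e-12

    def test_linearity_superposition(self, fixture_network, fixture_drivers):
        """Without head loss and stenoses the network is linear: doubling
        every source amplitude doubles all flows."""
        net = fixture_network.without_headloss()
        cfg = SimulationConfig(method="DOP853", rtol=1e-12, dt_max=2e-3)
        drv1 = fixture_drivers
        ao = drv1.aortic
        drv2 = dataclasses.replace(
            drv1,
            aortic=lambda t: 2.0 * ao(t),
            venous=2.0 * drv1.venous,
            lv_params=dataclasses.replace(
                drv1.lv_params,
                U0=2 * drv1.lv_params.U0,
                E=2 * drv1.lv_params.E,
                Ed=2 * drv1.lv_params.Ed,
                Rv=2 * drv1.lv_params.Rv,
            ),
            rv_params=dataclasses.replace(
                drv1.rv_params,
                U0=2 * drv1.rv_params.U0,
                E=2 * drv1.rv_params.E,
                Ed=2 * drv1.rv_params.Ed,
                Rv=2 * drv1.rv_params.Rv,
            ),
        )
        t1, y1, s1 = integrate(net, drv1, 0.8, cfg, n_samples=80)
        t2, y2, s2 = integrate(net, drv2, 0.8, cfg, n_samples=80)
        nq = len(s1.ind_names)
        q1, q2 = y1[:nq], y2[:nq]
        scale = np.max(np.abs(q2))
        assert np.max(np.abs(2.0 * q1 - q2)) / scale < 1e-8

    def test_headloss_adds_flow_dependent_resistance(self):
        A = 7e-6
        net_hl = NetworkSpec(
            [_seg("a", "AORTA", "VEIN", R=1.0, L=0.05,
                  headloss=HeadLossSpec(area=A, xi=2.88))],
            {},
        )
        net_plain = NetworkSpec(
            [_seg("a", "AORTA", "VEIN", R=1.0, L=0.05)], {}
        )
        drv = self._drivers(100.0)
        cfg = SimulationConfig()
        _, y_hl, s_hl = integrate(net_hl, drv, 2.0, cfg, n_samples=100)
        _, y_pl, _ = integrate(net_plain, drv, 2.0, cfg, n_samples=100)
        q_hl, q_pl = y_hl[0, -1], y_pl[0, -1]
        assert q_hl < q_pl
        # steady state satisfies P = (R + ξρq/(2A²))·q
        p_si = 100.0 * MMHG_PA
        r_si = convert_units(1.0, "R_clinical", "R_SI")
        resid = p_si - (r_si + headloss_resistance(q_hl, A, 1040.0, 2.88)) * q_hl
        assert abs(resid) / p_si < 1e-6

    def test_dynamic_xi_mode_constant_resistance(self):
        # ξ = 288/Re with Re from the mean velocity collapses to
        # R_h = 144 μ/(A·D)
        A = 7e-6
        D = math.sqrt(4 * A / math.pi)
        net = NetworkSpec(
            [_seg("a", "AORTA", "VEIN", R=1.0, L=0.05,
                  headloss=HeadLossSpec(area=A, dynamic=True))],
            {},
        )
        drv = self._drivers(100.0)
        _, y, s = integrate(net, drv, 2.0, SimulationConfig(), n_samples=50)
        q = y[0, -1]
        r_si = convert_units(1.0, "R_clinical", "R_SI")
        rh = 144.0 * 4e-3 / (A * D)
        assert q == pytest.approx(100.0 * MMHG_PA / (r_si + rh), rel=1e-6)
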