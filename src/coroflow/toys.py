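"""Catalog of tiny analytically solvable circuits used to validate the
solver, plus the built-in patient network under its default drivers.

Every toy comes with its closed-form reference (``oracle``): the exact
steady flow, relaxation trace, or sinusoidal transfer the simulated
network must reproduce.  Toy parameters are taken in clinical units
(mmHg, s, ml) for convenience and converted internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Callable

from .drivers import DriverSet, VentricleParams, default_volume_waveform
from .network import NetworkSpec, SegmentSpec, Terminal
from .patient import default_fixture_drivers, load_patient_fixture
from .units import PhysicalConstants, VesselRLC, convert_units

__all__ = ["ToyNetwork", "TOY_CATALOG", "generate_toy"]


@dataclass
class ToyNetwork:
    """A toy circuit with its drivers and closed-form reference.

    ``oracle`` maps quantity names to values or callables of time; units
    are clinical (ml/s for flows, mmHg for pressures, s for times).
    """

    name: str
    network: NetworkSpec
    drivers: DriverSet
    oracle: dict[str, Any]
    description: str


def _flat_drivers(
    aortic: Callable[[float], float], venous: float = 0.0, period: float = 0.8
) -> DriverSet:
    """Drivers with a prescribed aortic waveform and inert ventricles
    (no intramyocardial coupling anywhere)."""
    ts = 0.3 * period
    lv = VentricleParams(Rv=0.0, U0=0.0, Ed=0.0, V0=10.0, ts=ts)
    vol = default_volume_waveform(10.0, 0.0, ts, period, residual=0.0)
    return DriverSet(
        lv_params=lv,
        rv_params=lv,
        lv_volume=vol,
        rv_volume=vol,
        aortic=aortic,
        venous=venous,
        im_map={},
        period=period,
    )


def _single_r(R: float = 1.0, P: float = 100.0) -> ToyNetwork:
    R_si = convert_units(R, "R_clinical", "R_SI")
    net = NetworkSpec(
        segments=[SegmentSpec("R1", "AORTA", "VEIN", rlc=VesselRLC(R=R_si))],
        terminals={},
    )
    return ToyNetwork(
        name="single_R",
        network=net,
        drivers=_flat_drivers(lambda t: P),
        oracle={"q_R1": P / R},
        description=f"one resistor: steady q = P/R = {P / R:g} ml/s",
    )


def _series_rr(R1: float = 1.0, R2: float = 3.0, P: float = 100.0) -> ToyNetwork:
    r1 = convert_units(R1, "R_clinical", "R_SI")
    r2 = convert_units(R2, "R_clinical", "R_SI")
    net = NetworkSpec(
        segments=[
            SegmentSpec("R1", "AORTA", "mid", rlc=VesselRLC(R=r1)),
            SegmentSpec("R2", "mid", "VEIN", rlc=VesselRLC(R=r2)),
        ],
        terminals={},
    )
    q = P / (R1 + R2)
    return ToyNetwork(
        name="series_RR",
        network=net,
        drivers=_flat_drivers(lambda t: P),
        oracle={"q_R1": q, "q_R2": q, "p_mid": P * R2 / (R1 + R2)},
        description="two resistors in series with an algebraic midpoint",
    )


def _rc_node(R: float = 1.0, C: float = 0.05, P: float = 100.0) -> ToyNetwork:
    r = convert_units(R, "R_clinical", "R_SI")
    c = convert_units(C, "C_clinical", "C_SI")
    net = NetworkSpec(
        segments=[SegmentSpec("feed", "AORTA", "cap", rlc=VesselRLC(R=r, C=c))],
        terminals={},
    )
    tau = R * C

    def p_of_t(t: float) -> float:
        return P * (1.0 - math.exp(-t / tau))

    return ToyNetwork(
        name="rc_node",
        network=net,
        drivers=_flat_drivers(lambda t: P),
        oracle={"p_cap": p_of_t, "tau": tau},
        description="RC charging from rest: p(t) = P(1 − e^(−t/RC))",
    )


def _rl_segment(
    R: float = 1.0,
    L: float = 0.05,
    p_mean: float = 100.0,
    p_amp: float = 20.0,
    period: float = 0.8,
) -> ToyNetwork:
    r = convert_units(R, "R_clinical", "R_SI")
    li = convert_units(L, "L_clinical", "L_SI")
    omega = 2.0 * math.pi / period
    net = NetworkSpec(
        segments=[SegmentSpec("RL", "AORTA", "VEIN", rlc=VesselRLC(R=r, L=li))],
        terminals={},
    )
    amp = p_amp / math.sqrt(R**2 + (omega * L) ** 2)
    phase = math.atan2(omega * L, R)

    def q_ss(t: float) -> float:
        return p_mean / R + amp * math.sin(omega * t - phase)

    return ToyNetwork(
        name="rl_segment",
        network=net,
        drivers=_flat_drivers(
            lambda t: p_mean + p_amp * math.sin(omega * t), period=period
        ),
        oracle={
            "q_RL": q_ss,
            "amplitude": amp,
            "phase": phase,
            "omega": omega,
        },
        description="R–L branch under a sinusoidal pressure: "
        "|q| = |Δp|/√(R² + ω²L²), phase lag atan(ωL/R)",
    )


def _windkessel3(
    Rc: float = 0.5, Rp: float = 2.0, C: float = 0.05, P: float = 100.0
) -> ToyNetwork:
    rc = convert_units(Rc, "R_clinical", "R_SI")
    rp = convert_units(Rp, "R_clinical", "R_SI")
    c = convert_units(C, "C_clinical", "C_SI")
    net = NetworkSpec(
        segments=[SegmentSpec("prox", "AORTA", "wk", rlc=VesselRLC(R=rc, C=c))],
        terminals={"wk": Terminal(Z=rp)},
    )
    p_inf = P * Rp / (Rc + Rp)
    tau = C * Rc * Rp / (Rc + Rp)
    return ToyNetwork(
        name="windkessel3",
        network=net,
        drivers=_flat_drivers(lambda t: P),
        oracle={
            "p_wk": p_inf,
            "q_prox": P / (Rc + Rp),
            "tau": tau,
        },
        description="three-element windkessel: characteristic resistance, "
        "compliant node, peripheral bed",
    )


def _fixture_coronary() -> ToyNetwork:
    const = PhysicalConstants()
    net = load_patient_fixture(const)
    return ToyNetwork(
        name="fixture_coronary",
        network=net,
        drivers=default_fixture_drivers(const),
        oracle={},
        description="built-in 17-branch patient coronary network with "
        "structured-tree beds, ostial head loss and intramyocardial "
        "coupling",
    )


TOY_CATALOG: dict[str, Callable[..., ToyNetwork]] = {
    "single_R": _single_r,
    "series_RR": _series_rr,
    "rc_node": _rc_node,
    "rl_segment": _rl_segment,
    "windkessel3": _windkessel3,
    "fixture_coronary": _fixture_coronary,
}


def generate_toy(name: str, **params: float) -> ToyNetwork:
    """Build a catalog circuit with its closed-form reference.

    Raises ``KeyError`` listing the catalog for an unknown name.
    """
    try:
        builder = TOY_CATALOG[name]
    except KeyError:
        raise KeyError(
            f"unknown toy network {name!r}; catalog: {sorted(TOY_CATALOG)}"
        ) from None
    return builder(**params)
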