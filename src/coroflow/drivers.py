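"""Time-periodic pressure generators for the coronary network.

The coronary inlets hang off the aorta, whose pressure is prescribed as a
smooth periodic waveform; the bed outflows drain to a constant venous
(right-atrial) pressure.  Vessels embedded in the heart wall additionally
feel the *intramyocardial pressure* — a fraction (one third or one half,
depending on location) of the pressure of the ventricle whose wall they
run in — applied as the external reference pressure of their compliance.
That compressive coupling is what squeezes coronary flow during systole
and makes left-tree flow diastole-dominant.

Ventricular pressure follows a two-phase pumping function over the cardiac
cycle: in systole

    P_v = U0·σ(t) + E·(V − V0) + Rv·V̇,   σ(t) = 1 − cos(2πt/ts),

and in diastole P_v = Ed·(V − V0), with peak isovolumetric pressure U0,
time-varying elastance E, passive elastance Ed, reference volume V0,
myocardial resistance Rv and systolic duration ts.  No ventricular volume
trace is prescribed by the physiology tables, so a smooth
ejection/filling waveform with configurable stroke volume stands in for
V(t); see :func:`default_volume_waveform`.

Parameters in this module are expressed in the clinical units the
physiology literature prints (mmHg, ml, s).  :class:`DriverSet` converts
to SI at the boundary with the circuit solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

from .units import MMHG_PA

__all__ = [
    "VentricleParams",
    "VolumeWaveform",
    "ImCoupling",
    "DriverSet",
    "activation",
    "ventricular_pressure",
    "intramyocardial_pressure",
    "default_volume_waveform",
    "default_aortic_pressure",
    "default_driver_set",
    "phase_discontinuity",
]

#: Admissible intramyocardial fractions of ventricular pressure.
IM_FACTORS = (1.0 / 3.0, 0.5)


@dataclass(frozen=True)
class VentricleParams:
    """Pumping-function parameters of one ventricle (clinical units).

    Attributes
    ----------
    Rv : float
        Myocardial resistance (mmHg·s/ml).
    U0 : float
        Peak isovolumetric pressure (mmHg); systolic pressure generation
        is U0·σ(t) with σ peaking at 2.
    Ed : float
        Passive (diastolic) elastance (mmHg/ml).
    V0 : float
        Reference (zero-pressure) volume (ml).
    E : float
        Systolic elastance (mmHg/ml).  The class default is 0 (pure
        activation-driven pressure generation); the driver-set defaults
        use a nonzero value chosen so peak ventricular pressure exceeds
        the aortic pressure it ejects against — see ``LV_DEFAULTS``.
    ts : float
        Systolic duration (s).
    """

    Rv: float
    U0: float
    Ed: float
    V0: float
    E: float = 0.0
    ts: float = 0.24

    def __post_init__(self) -> None:
        for name in ("Rv", "U0", "Ed", "V0", "E"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.ts <= 0:
            raise ValueError("ts must be positive")


#: Left/right ventricle defaults (mmHg, ml, s): Rv, U0 (peak isovolumetric
#: pressure, = half the peak of U0·σ), passive elastance Ed and reference
#: volume V0 are the tabulated physiology values.  The systolic elastance
#: E is chosen so that, with the default volume waveform, peak LV
#: pressure reaches ≈125 mmHg — just above the 120 mmHg systolic aortic
#: pressure it must eject against (U0·σ alone peaks near 63 mmHg once the
#: Rv·V̇ ejection drag is subtracted, which cannot open the aortic
#: valve); E_rv is scaled down by the same ratio as the passive
#: elastances (0.03/0.10).
LV_DEFAULTS = dict(Rv=0.0800, U0=50.0, Ed=0.10, V0=11.29, E=0.7)
RV_DEFAULTS = dict(Rv=0.0175, U0=24.0, Ed=0.03, V0=3.33, E=0.21)


def activation(t: float, ts: float) -> float:
    """Activation function σ(t) = 1 − cos(2πt/ts), in [0, 2], with
    σ(0) = σ(ts) = 0 and peak 2 at t = ts/2."""
    if ts <= 0:
        raise ValueError("ts must be positive")
    return 1.0 - math.cos(2.0 * math.pi * t / ts)


@dataclass(frozen=True)
class VolumeWaveform:
    """Periodic ventricular volume trace V(t) with analytic derivative.

    ``volume`` and ``dvdt`` are callables of time in seconds returning ml
    and ml/s; both are periodic with ``period`` and C¹ across phase
    boundaries.
    """

    volume: Callable[[float], float]
    dvdt: Callable[[float], float]
    period: float

    def __call__(self, t: float) -> float:
        return self.volume(t)


def default_volume_waveform(
    V0: float,
    stroke: float,
    ts: float,
    period: float,
    *,
    residual: float = 50.0,
) -> VolumeWaveform:
    """Smooth ejection/filling volume waveform.

    The ventricle ejects the stroke volume over the systolic interval
    [0, ts] along a half-cosine and refills over [ts, period] along
    another, so V is C¹-periodic, ∮dV = 0, and the peak |V̇| falls at
    mid-ejection.  Volume stays between ``V0 + residual`` (end-systolic)
    and ``V0 + residual + stroke`` (end-diastolic), so V ≥ V0 throughout.

    ``stroke = 0`` degenerates to a constant volume.
    """
    if stroke < 0:
        raise ValueError("stroke must be nonnegative")
    if not 0 < ts < period:
        raise ValueError("need 0 < ts < period")
    if residual < 0:
        raise ValueError("residual must be nonnegative")
    v_es = V0 + residual
    v_ed = v_es + stroke
    td = period - ts

    def volume(t: float) -> float:
        u = t % period
        if u < ts:
            return v_ed - stroke * 0.5 * (1.0 - math.cos(math.pi * u / ts))
        return v_es + stroke * 0.5 * (1.0 - math.cos(math.pi * (u - ts) / td))

    def dvdt(t: float) -> float:
        u = t % period
        if u < ts:
            return -stroke * 0.5 * math.pi / ts * math.sin(math.pi * u / ts)
        return stroke * 0.5 * math.pi / td * math.sin(math.pi * (u - ts) / td)

    return VolumeWaveform(volume=volume, dvdt=dvdt, period=period)


def ventricular_pressure(
    t: float,
    params: VentricleParams,
    vol: VolumeWaveform,
) -> float:
    """Two-phase ventricular pumping function, in mmHg.

    Systole (t mod period < ts): P = U0·σ(t) + E·(V − V0) + Rv·V̇.
    Diastole: P = Ed·(V − V0).  The piecewise form is discontinuous at
    the phase switch in general; see :func:`phase_discontinuity`.
    """
    u = t % vol.period
    V = vol.volume(u)
    if u < params.ts:
        return (
            params.U0 * activation(u, params.ts)
            + params.E * (V - params.V0)
            + params.Rv * vol.dvdt(u)
        )
    return params.Ed * (V - params.V0)


def intramyocardial_pressure(
    Pv: float, factor: float, *, allow_any_factor: bool = False
) -> float:
    """Intramyocardial pressure as a fraction of ventricular pressure.

    The fraction is one third or one half depending on where the vessel
    sits in the heart wall; other values are rejected unless
    ``allow_any_factor`` is set.
    """
    if not allow_any_factor and not any(
        math.isclose(factor, f, rel_tol=1e-9) for f in IM_FACTORS
    ):
        raise ValueError(
            f"intramyocardial fraction must be 1/3 or 1/2, got {factor!r}"
            " (pass allow_any_factor=True to override)"
        )
    return factor * Pv


def phase_discontinuity(
    params: VentricleParams, vol: VolumeWaveform
) -> tuple[float, float]:
    """Magnitudes (mmHg) of the pumping-function jumps at the
    diastole→systole switch (t = 0) and systole→diastole switch (t = ts)."""
    eps = 1e-9 * vol.period
    at_onset = abs(
        ventricular_pressure(0.0, params, vol)
        - ventricular_pressure(vol.period - eps, params, vol)
    )
    at_end = abs(
        ventricular_pressure(params.ts, params, vol)
        - ventricular_pressure(params.ts - eps, params, vol)
    )
    return at_onset, at_end


def default_aortic_pressure(
    period: float,
    p_dia: float = 80.0,
    p_sys: float = 120.0,
    ts: float | None = None,
    delay: float | None = None,
) -> Callable[[float], float]:
    """Smooth periodic aortic pressure (mmHg) with a physiological
    diastolic runoff.

    The upstroke begins ``delay`` after the onset of ventricular
    activation at t = 0 — the isovolumic contraction time, defaulting to
    0.075·period (60 ms at a 0.8 s cycle) — since the aortic valve only
    opens once ventricular pressure exceeds aortic.  The ejection phase
    then runs a half-sine rise from ``p_dia`` to the peak ``p_sys``,
    a quarter-cosine fall to the incisura level
    p_dia + 0.7·(p_sys − p_dia), and a windkessel-like exponential decay
    back to exactly ``p_dia`` at the wrap, so the waveform is continuous
    and periodic with min ``p_dia`` and max ``p_sys``.
    ``p_dia = p_sys`` degenerates to a constant.
    """
    if p_sys < p_dia:
        raise ValueError("p_sys must be >= p_dia")
    if ts is None:
        ts = 0.3 * period
    if not 0 < ts <= period:
        raise ValueError("need 0 < ts <= period")
    if delay is None:
        delay = 0.075 * period
    pulse = p_sys - p_dia
    tp = 0.4 * ts          # time of peak after the upstroke begins
    p_es = p_dia + 0.7 * pulse  # incisura (end-systolic) level
    td = period - ts
    k = 3.0                # diastolic decay rate (dimensionless)
    ek = math.exp(-k)

    def waveform(t: float) -> float:
        u = (t - delay) % period
        if u < tp:
            return p_dia + pulse * math.sin(0.5 * math.pi * u / tp)
        if u < ts:
            return p_es + (p_sys - p_es) * math.cos(
                0.5 * math.pi * (u - tp) / (ts - tp)
            )
        if td <= 0:
            return p_dia
        # exponential-shaped decay hitting p_dia exactly at the wrap
        w = (math.exp(-k * (u - ts) / td) - ek) / (1.0 - ek)
        return p_dia + (p_es - p_dia) * w

    return waveform


@dataclass(frozen=True)
class ImCoupling:
    """Intramyocardial coupling of one network node: which ventricle
    drives it (``"lv"`` or ``"rv"``) and the pressure fraction."""

    chamber: str
    factor: float

    def __post_init__(self) -> None:
        if self.chamber not in ("lv", "rv"):
            raise ValueError("chamber must be 'lv' or 'rv'")


@dataclass(frozen=True)
class DriverSet:
    """All pressure generators of one simulation, sharing one period.

    Attributes
    ----------
    lv_params, rv_params : VentricleParams
        Pumping-function parameters of each ventricle (clinical units).
    lv_volume, rv_volume : VolumeWaveform
        Prescribed ventricular volume traces.
    aortic : callable
        Aortic pressure waveform, mmHg as a function of time (s).
    venous : float
        Constant right-atrial (venous sink) pressure, mmHg.
    im_map : mapping
        Node label → :class:`ImCoupling` for compliant nodes squeezed by
        the myocardium; nodes absent from the map feel no external
        pressure.
    period : float
        Cardiac period (s).
    """

    lv_params: VentricleParams
    rv_params: VentricleParams
    lv_volume: VolumeWaveform
    rv_volume: VolumeWaveform
    aortic: Callable[[float], float]
    venous: float
    im_map: Mapping[str, ImCoupling] = field(default_factory=dict)
    period: float = 0.8

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        for wf in (self.lv_volume, self.rv_volume):
            if not math.isclose(wf.period, self.period, rel_tol=1e-12):
                raise ValueError("all driver waveforms must share one period")
        for node, c in self.im_map.items():
            intramyocardial_pressure(1.0, c.factor)  # validates the factor

    # --- SI-facing surface used by the circuit solver -------------------

    def ventricular_pressure_mmhg(self, chamber: str, t: float) -> float:
        if chamber == "lv":
            return ventricular_pressure(t, self.lv_params, self.lv_volume)
        if chamber == "rv":
            return ventricular_pressure(t, self.rv_params, self.rv_volume)
        raise ValueError("chamber must be 'lv' or 'rv'")

    def aortic_pa(self, t: float) -> float:
        return self.aortic(t) * MMHG_PA

    def venous_pa(self) -> float:
        return self.venous * MMHG_PA

    def im_pressure_pa(self, node: str, t: float) -> float:
        """External (intramyocardial) pressure at a node, Pa; zero for
        nodes without coupling."""
        c = self.im_map.get(node)
        if c is None:
            return 0.0
        pv = self.ventricular_pressure_mmhg(c.chamber, t)
        return intramyocardial_pressure(pv, c.factor) * MMHG_PA

    @property
    def ts(self) -> float:
        """Systolic duration shared by the ventricles (s)."""
        return self.lv_params.ts


def default_driver_set(
    *,
    period: float = 0.8,
    ts: float | None = None,
    p_dia: float = 80.0,
    p_sys: float = 120.0,
    venous: float = 5.0,
    stroke: float = 70.0,
    im_map: Mapping[str, ImCoupling] | None = None,
) -> DriverSet:
    """Driver set with the tabulated ventricle parameters and conventional
    hemodynamic defaults.

    Systolic duration defaults to 0.3·period (the physiological fraction
    of the cycle); aortic pressure to an 80/120 mmHg pulse; the venous
    sink to 5 mmHg; stroke volume to 70 ml for both ventricles.
    """
    if ts is None:
        ts = 0.3 * period
    lv = VentricleParams(ts=ts, **LV_DEFAULTS)
    rv = VentricleParams(ts=ts, **RV_DEFAULTS)
    return DriverSet(
        lv_params=lv,
        rv_params=rv,
        lv_volume=default_volume_waveform(lv.V0, stroke, ts, period),
        rv_volume=default_volume_waveform(rv.V0, stroke, ts, period),
        aortic=default_aortic_pressure(period, p_dia, p_sys, ts),
        venous=venous,
        im_map=dict(im_map or {}),
        period=period,
    )
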