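"""Config-file reading and writing.

A network definition is a single YAML document with blocks ``constants``,
``segments``, ``terminals``, ``sources``, ``drivers`` and ``simulation``.
Values are typed in clinical units exactly as the physiology tables print
them — R in mmHg·s/ml, L in mmHg·s²/ml, C in ml/mmHg, pressures in mmHg,
diameters in mm, lengths in cm — and are converted to SI once, at parse
time.  Unknown keys are rejected with the offending key named.

Segment element values are given either directly (``R``/``L``/``C``) or
as geometry (``D_mm``/``l_cm``), not both.  A terminal takes either a
direct impedance ``Z`` (mmHg·s/ml) or a structured-tree root radius
``r0_mm`` from which the impedance is computed at load time.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .drivers import (
    LV_DEFAULTS,
    RV_DEFAULTS,
    DriverSet,
    ImCoupling,
    VentricleParams,
    default_aortic_pressure,
    default_volume_waveform,
)
from .network import HeadLossSpec, NetworkSpec, SegmentSpec, Terminal
from .structured_tree import terminal_impedance_from_radius
from .simulate import SimulationConfig
from .units import (
    ConfigurationError,
    PhysicalConstants,
    VesselGeometry,
    VesselRLC,
    convert_units,
)

__all__ = ["DriverConfig", "LoadedModel", "parse_config", "write_config"]


@dataclass(frozen=True)
class DriverConfig:
    """Scalar driver settings from which a :class:`DriverSet` is built."""

    period: float = 0.8
    ts: float = 0.24
    p_dia: float = 80.0
    p_sys: float = 120.0
    venous: float = 5.0
    stroke: float = 70.0
    #: aortic upstroke delay (isovolumic contraction, s); None = 0.075·period
    ao_delay: float | None = None
    lv: VentricleParams = field(
        default_factory=lambda: VentricleParams(ts=0.24, **LV_DEFAULTS)
    )
    rv: VentricleParams = field(
        default_factory=lambda: VentricleParams(ts=0.24, **RV_DEFAULTS)
    )
    im_map: Mapping[str, ImCoupling] = field(default_factory=dict)

    def build(self) -> DriverSet:
        return DriverSet(
            lv_params=self.lv,
            rv_params=self.rv,
            lv_volume=default_volume_waveform(
                self.lv.V0, self.stroke, self.ts, self.period
            ),
            rv_volume=default_volume_waveform(
                self.rv.V0, self.stroke, self.ts, self.period
            ),
            aortic=default_aortic_pressure(
                self.period, self.p_dia, self.p_sys, self.ts, self.ao_delay
            ),
            venous=self.venous,
            im_map=dict(self.im_map),
            period=self.period,
        )


@dataclass(frozen=True)
class LoadedModel:
    """Everything a run needs: network, driver settings, integrator
    settings and physical constants."""

    network: NetworkSpec
    driver_config: DriverConfig
    simulation: SimulationConfig
    constants: PhysicalConstants

    @property
    def drivers(self) -> DriverSet:
        return self.driver_config.build()


def _only_keys(block: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in {where}"
        )


def _parse_constants(block: Mapping[str, Any] | None) -> PhysicalConstants:
    if block is None:
        return PhysicalConstants()
    _only_keys(block, {"mu", "rho", "G", "wall_ratio", "t_cycle"}, "constants")
    return PhysicalConstants(**{k: float(v) for k, v in block.items()})


def _parse_segment(
    entry: Mapping[str, Any], const: PhysicalConstants
) -> SegmentSpec:
    where = f"segment {entry.get('name', '?')!r}"
    _only_keys(
        entry,
        {"name", "from", "to", "R", "L", "C", "D_mm", "l_cm", "headloss",
         "stenosis"},
        where,
    )
    for key in ("name", "from", "to"):
        if key not in entry:
            raise ConfigurationError(f"{where}: missing key {key!r}")
    has_rlc = "R" in entry
    has_geom = "D_mm" in entry or "l_cm" in entry
    if has_rlc and has_geom:
        raise ConfigurationError(
            f"{where}: give R/L/C or D_mm/l_cm, not both"
        )
    if not has_rlc and not has_geom:
        raise ConfigurationError(f"{where}: no element values or geometry")
    rlc = geom = None
    if has_rlc:
        rlc = VesselRLC(
            R=convert_units(float(entry["R"]), "R_clinical", "R_SI"),
            L=convert_units(float(entry.get("L", 0.0)), "L_clinical", "L_SI"),
            C=convert_units(float(entry.get("C", 0.0)), "C_clinical", "C_SI"),
        )
    else:
        if "D_mm" not in entry or "l_cm" not in entry:
            raise ConfigurationError(f"{where}: geometry needs D_mm and l_cm")
        D = float(entry["D_mm"]) * 1e-3
        geom = VesselGeometry(
            D=D, l=float(entry["l_cm"]) * 1e-2, h=const.wall_ratio * D
        )
    hl = None
    if "headloss" in entry and entry["headloss"] is not None:
        hb = entry["headloss"]
        _only_keys(hb, {"area_mm2", "xi", "dynamic"}, f"{where} headloss")
        if "area_mm2" not in hb:
            raise ConfigurationError(f"{where}: headloss needs area_mm2")
        hl = HeadLossSpec(
            area=float(hb["area_mm2"]) * 1e-6,
            xi=float(hb.get("xi", 2.88)),
            dynamic=bool(hb.get("dynamic", False)),
        )
    sten = entry.get("stenosis")
    return SegmentSpec(
        name=str(entry["name"]),
        from_node=str(entry["from"]),
        to_node=str(entry["to"]),
        rlc=rlc,
        geometry=geom,
        headloss=hl,
        stenosis=None if sten is None else float(sten),
    )


def _parse_terminal(
    entry: Mapping[str, Any], const: PhysicalConstants
) -> tuple[str, Terminal]:
    where = f"terminal {entry.get('node', '?')!r}"
    _only_keys(entry, {"node", "Z", "r0_mm"}, where)
    if "node" not in entry:
        raise ConfigurationError(f"{where}: missing key 'node'")
    if ("Z" in entry) == ("r0_mm" in entry):
        raise ConfigurationError(f"{where}: give exactly one of Z or r0_mm")
    if "Z" in entry:
        term = Terminal(Z=convert_units(float(entry["Z"]), "R_clinical", "R_SI"))
    else:
        r0 = float(entry["r0_mm"]) * 1e-3
        ti = terminal_impedance_from_radius(r0, mu=const.mu)
        term = Terminal(Z=ti.Z, r0=r0)
    return str(entry["node"]), term


def _parse_ventricle(
    block: Mapping[str, Any] | None, defaults: VentricleParams, ts: float
) -> VentricleParams:
    if block is None:
        return replace(defaults, ts=ts)
    _only_keys(block, {"Rv", "U0", "Ed", "V0", "E"}, "ventricle block")
    kw = {k: float(v) for k, v in block.items()}
    return replace(defaults, ts=ts, **kw)


def _parse_drivers(block: Mapping[str, Any] | None) -> DriverConfig:
    base = DriverConfig()
    if block is None:
        return base
    _only_keys(
        block,
        {"period", "ts", "aortic", "venous", "stroke", "lv", "rv", "im"},
        "drivers",
    )
    period = float(block.get("period", base.period))
    ts = float(block.get("ts", 0.3 * period))
    p_dia, p_sys, ao_delay = base.p_dia, base.p_sys, base.ao_delay
    if "aortic" in block and block["aortic"] is not None:
        ab = block["aortic"]
        _only_keys(ab, {"p_dia", "p_sys", "delay"}, "drivers.aortic")
        p_dia = float(ab.get("p_dia", p_dia))
        p_sys = float(ab.get("p_sys", p_sys))
        if ab.get("delay") is not None:
            ao_delay = float(ab["delay"])
    im: dict[str, ImCoupling] = {}
    for entry in block.get("im") or []:
        _only_keys(entry, {"node", "chamber", "factor"}, "drivers.im entry")
        factor = entry["factor"]
        if isinstance(factor, str):  # allow "1/3", "1/2"
            num, _, den = factor.partition("/")
            factor = float(num) / float(den or 1)
        im[str(entry["node"])] = ImCoupling(
            chamber=str(entry.get("chamber", "lv")), factor=float(factor)
        )
    return DriverConfig(
        period=period,
        ts=ts,
        p_dia=p_dia,
        p_sys=p_sys,
        venous=float(block.get("venous", base.venous)),
        stroke=float(block.get("stroke", base.stroke)),
        ao_delay=ao_delay,
        lv=_parse_ventricle(block.get("lv"), base.lv, ts),
        rv=_parse_ventricle(block.get("rv"), base.rv, ts),
        im_map=im,
    )


def _parse_simulation(block: Mapping[str, Any] | None) -> SimulationConfig:
    if block is None:
        return SimulationConfig()
    allowed = {"dt_max", "n_cycles_max", "periodicity_tol", "n_samples",
               "method", "rtol"}
    _only_keys(block, allowed, "simulation")
    kw: dict[str, Any] = dict(block)
    for k in ("dt_max", "periodicity_tol", "rtol"):
        if k in kw:
            kw[k] = float(kw[k])
    for k in ("n_cycles_max", "n_samples"):
        if k in kw:
            kw[k] = int(kw[k])
    return SimulationConfig(**kw)


def parse_config(path: str | Path) -> LoadedModel:
    """Read a YAML network definition into a validated model."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    _only_keys(
        doc,
        {"constants", "segments", "terminals", "sources", "drivers",
         "simulation"},
        "document",
    )
    const = _parse_constants(doc.get("constants"))
    segments = [_parse_segment(e, const) for e in doc.get("segments") or []]
    terminals = dict(
        _parse_terminal(e, const) for e in doc.get("terminals") or []
    )
    sources = doc.get("sources") or {}
    _only_keys(sources, {"aortic", "venous"}, "sources")
    net = NetworkSpec(
        segments=segments,
        terminals=terminals,
        aortic_node=str(sources.get("aortic", "AORTA")),
        venous_node=str(sources.get("venous", "VEIN")),
    )
    net.validate(const)
    return LoadedModel(
        network=net,
        driver_config=_parse_drivers(doc.get("drivers")),
        simulation=_parse_simulation(doc.get("simulation")),
        constants=const,
    )


def _segment_to_dict(s: SegmentSpec) -> dict[str, Any]:
    d: dict[str, Any] = {"name": s.name, "from": s.from_node, "to": s.to_node}
    if s.rlc is not None:
        d["R"] = convert_units(s.rlc.R, "R_SI", "R_clinical")
        d["L"] = convert_units(s.rlc.L, "L_SI", "L_clinical")
        d["C"] = convert_units(s.rlc.C, "C_SI", "C_clinical")
    else:
        d["D_mm"] = s.geometry.D * 1e3
        d["l_cm"] = s.geometry.l * 1e2
    if s.headloss is not None:
        d["headloss"] = {
            "area_mm2": s.headloss.area * 1e6,
            "xi": s.headloss.xi,
            "dynamic": s.headloss.dynamic,
        }
    if s.stenosis is not None:
        d["stenosis"] = s.stenosis
    return d


def write_config(model: LoadedModel, path: str | Path) -> None:
    """Write a model back out as the YAML config format (clinical units).

    ``parse_config(write_config(m)) == m`` up to floating-point rounding
    of the unit conversions.
    """
    dc = model.driver_config
    doc: dict[str, Any] = {
        "constants": asdict(model.constants),
        "segments": [_segment_to_dict(s) for s in model.network.segments],
        "terminals": [
            (
                {"node": node, "r0_mm": t.r0 * 1e3}
                if t.r0 is not None
                else {"node": node,
                      "Z": convert_units(t.Z, "R_SI", "R_clinical")}
            )
            for node, t in model.network.terminals.items()
        ],
        "sources": {
            "aortic": model.network.aortic_node,
            "venous": model.network.venous_node,
        },
        "drivers": {
            "period": dc.period,
            "ts": dc.ts,
            "aortic": (
                {"p_dia": dc.p_dia, "p_sys": dc.p_sys}
                if dc.ao_delay is None
                else {"p_dia": dc.p_dia, "p_sys": dc.p_sys,
                      "delay": dc.ao_delay}
            ),
            "venous": dc.venous,
            "stroke": dc.stroke,
            "lv": {k: getattr(dc.lv, k) for k in ("Rv", "U0", "Ed", "V0", "E")},
            "rv": {k: getattr(dc.rv, k) for k in ("Rv", "U0", "Ed", "V0", "E")},
            "im": [
                {"node": n, "chamber": c.chamber, "factor": c.factor}
                for n, c in dc.im_map.items()
            ],
        },
        "simulation": asdict(model.simulation),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
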