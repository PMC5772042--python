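"""Circuit-graph data model and assembly of the governing equations.

Each vessel segment is a lumped cell between two named nodes: a series
resistance R and inertance L carrying the segment flow q, with the
compliance C shunted at the distal node (inverted-L cell — the minimal
arrangement consistent with the per-segment momentum and continuity
relations

    −Δp = L dq/dt + R q,        q = C dp/dt).

Terminal beds attach as pure resistances Z between a node and the venous
pressure rail.  Compliant nodes store volume against an external
(intramyocardial) reference pressure, so their state is the *transmural*
pressure.  Nodes with no compliance are algebraic Kirchhoff junctions and
segments with L = 0 are algebraic resistive branches; both are eliminated
by a (pre-factorised) linear nodal solve inside the right-hand side, so
the integrated system is a pure ODE.

Two nonlinear modifiers act on a segment:

* **Stenosis** — a uniform area reduction to the fraction α = A_s/A_0
  rescales the lumped values, R → R·α⁻², C → C·α^(3/2), L → L·α⁻¹.
* **Head loss** — an abrupt cross-section change (the coronary ostia)
  drops Δp = ξρv²/2, i.e. a variable resistance R_h = ξρ|q|/(2A²)
  proportional to the flow; |q| keeps the drop opposing the flow when it
  reverses in early systole.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .drivers import DriverSet
from .units import (
    MMHG_PA,
    PhysicalConstants,
    VesselGeometry,
    VesselRLC,
    rlc_from_geometry,
)

__all__ = [
    "NetworkError",
    "HeadLossSpec",
    "SegmentSpec",
    "Terminal",
    "NetworkSpec",
    "ODESystem",
    "apply_stenosis",
    "alpha_from_percent",
    "loss_coefficient",
    "headloss_resistance",
    "assemble_odes",
]


class NetworkError(ValueError):
    """Raised for an ill-posed network definition."""


def apply_stenosis(rlc: VesselRLC, alpha: float) -> VesselRLC:
    """Lumped values of a uniformly narrowed vessel.

    α = A_s/A_0 ∈ (0, 1] is the stenotic-to-normal area fraction;
    R → R·α⁻², C → C·α^(3/2), L → L·α⁻¹, so α = 1 is the identity.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"stenosis area fraction must be in (0, 1], got {alpha}")
    return VesselRLC(
        R=rlc.R * alpha**-2,
        L=rlc.L / alpha,
        C=rlc.C * alpha**1.5,
    )


def alpha_from_percent(p: float, convention: str = "area") -> float:
    """Area fraction α from a percent stenosis ``p``.

    Under the ``"area"`` convention α = 1 − p/100.  The clinical grading
    is by radius ratio, so under ``"radius"`` α = (1 − p/100)².
    """
    if not 0 <= p < 100:
        raise ValueError(f"percent stenosis must be in [0, 100), got {p}")
    if convention == "area":
        return 1.0 - p / 100.0
    if convention == "radius":
        return (1.0 - p / 100.0) ** 2
    raise ValueError(f"unknown stenosis convention {convention!r}")


def loss_coefficient(Re: float) -> float:
    """Empirical minor-loss coefficient ξ = 288/Re for an abrupt
    constriction of diameter ratio 0.5 (ξ = 2.88 at Re = 100)."""
    if Re <= 0:
        raise ValueError("Reynolds number must be positive")
    return 288.0 / Re


def headloss_resistance(q: float, A: float, rho: float, xi: float) -> float:
    """Flow-proportional resistance R_h = ξρ|q|/(2A²) of the head loss
    Δp = ξρv²/2 at a cross-section of area ``A`` (SI units)."""
    if A <= 0:
        raise ValueError("area must be positive")
    return xi * rho * abs(q) / (2.0 * A**2)


@dataclass(frozen=True)
class HeadLossSpec:
    """Head-loss element at a segment inlet.

    ``area`` is the ostial cross-section (m²).  With ``dynamic=False``
    the loss coefficient is the constant ``xi``; with ``dynamic=True``
    ξ = 288/Re is re-evaluated from the instantaneous mean velocity,
    which makes R_h = 144μ/(A·D) a flow-independent resistance.
    """

    area: float
    xi: float = 2.88
    dynamic: bool = False

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("head-loss area must be positive")
        if self.xi <= 0:
            raise ValueError("xi must be positive")


@dataclass(frozen=True)
class SegmentSpec:
    """One named vessel segment (directed edge) of the circuit graph.

    Element values are given either directly as ``rlc`` (SI) or as
    ``geometry`` to be converted through the Poiseuille relations —
    exactly one of the two.  ``stenosis`` is the area fraction α of an
    optional uniform narrowing.
    """

    name: str
    from_node: str
    to_node: str
    rlc: VesselRLC | None = None
    geometry: VesselGeometry | None = None
    headloss: HeadLossSpec | None = None
    stenosis: float | None = None

    def __post_init__(self) -> None:
        if (self.rlc is None) == (self.geometry is None):
            raise NetworkError(
                f"segment {self.name!r}: give exactly one of rlc or geometry"
            )
        if self.from_node == self.to_node:
            raise NetworkError(f"segment {self.name!r}: self-loop")
        if self.stenosis is not None and not 0 < self.stenosis <= 1:
            raise NetworkError(
                f"segment {self.name!r}: stenosis fraction must be in (0, 1]"
            )

    def effective_rlc(self, const: PhysicalConstants) -> VesselRLC:
        """Element values after geometry conversion and stenosis scaling."""
        rlc = self.rlc if self.rlc is not None else rlc_from_geometry(
            self.geometry, const
        )
        if self.stenosis is not None:
            rlc = apply_stenosis(rlc, self.stenosis)
        return rlc

    def with_stenosis(self, alpha: float | None) -> "SegmentSpec":
        return replace(self, stenosis=alpha)


@dataclass(frozen=True)
class Terminal:
    """Small-vessel bed at a node: steady impedance ``Z`` (Pa·s/m³) to
    the venous rail, optionally tagged with the structured-tree root
    radius ``r0`` (m) it was computed from."""

    Z: float
    r0: float | None = None

    def __post_init__(self) -> None:
        if self.Z <= 0:
            raise ValueError("terminal impedance must be positive")


@dataclass(frozen=True)
class NetworkSpec:
    """Directed circuit graph of segments with terminal beds and the
    source bindings (aortic pressure node, venous sink node)."""

    segments: tuple[SegmentSpec, ...]
    terminals: Mapping[str, Terminal]
    aortic_node: str = "AORTA"
    venous_node: str = "VEIN"

    def __init__(
        self,
        segments: Sequence[SegmentSpec],
        terminals: Mapping[str, Terminal],
        aortic_node: str = "AORTA",
        venous_node: str = "VEIN",
    ) -> None:
        object.__setattr__(self, "segments", tuple(segments))
        object.__setattr__(self, "terminals", dict(terminals))
        object.__setattr__(self, "aortic_node", aortic_node)
        object.__setattr__(self, "venous_node", venous_node)

    @property
    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.segments:
            seen.setdefault(s.from_node)
            seen.setdefault(s.to_node)
        seen.setdefault(self.venous_node)
        return list(seen)

    def segment(self, name: str) -> SegmentSpec:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(f"no segment named {name!r}")

    def with_segment_stenosis(self, name: str, alpha: float | None) -> "NetworkSpec":
        """Copy of the network with a stenosis applied to one segment."""
        self.segment(name)  # existence check
        segs = [
            s.with_stenosis(alpha) if s.name == name else s for s in self.segments
        ]
        return NetworkSpec(segs, self.terminals, self.aortic_node, self.venous_node)

    def without_headloss(self) -> "NetworkSpec":
        segs = [replace(s, headloss=None) for s in self.segments]
        return NetworkSpec(segs, self.terminals, self.aortic_node, self.venous_node)

    def allclose(self, other: "NetworkSpec", rel_tol: float = 1e-9) -> bool:
        """Structural equality with floating-point tolerance on element
        values (the clinical↔SI unit round trip is not bit-exact)."""

        def close(a, b):
            if a is None or b is None:
                return a is b
            return math.isclose(a, b, rel_tol=rel_tol, abs_tol=1e-300)

        if (
            self.aortic_node != other.aortic_node
            or self.venous_node != other.venous_node
            or len(self.segments) != len(other.segments)
            or set(self.terminals) != set(other.terminals)
        ):
            return False
        for s, o in zip(self.segments, other.segments):
            if (s.name, s.from_node, s.to_node) != (o.name, o.from_node, o.to_node):
                return False
            if (s.rlc is None) != (o.rlc is None):
                return False
            if s.rlc is not None and not all(
                close(getattr(s.rlc, f), getattr(o.rlc, f)) for f in "RLC"
            ):
                return False
            if s.geometry is not None and not all(
                close(getattr(s.geometry, f), getattr(o.geometry, f))
                for f in ("D", "l", "h")
            ):
                return False
            if (s.headloss is None) != (o.headloss is None):
                return False
            if s.headloss is not None and not (
                close(s.headloss.area, o.headloss.area)
                and close(s.headloss.xi, o.headloss.xi)
                and s.headloss.dynamic == o.headloss.dynamic
            ):
                return False
            if not close(s.stenosis, o.stenosis):
                return False
        for n, t in self.terminals.items():
            u = other.terminals[n]
            if not (close(t.Z, u.Z) and close(t.r0, u.r0)):
                return False
        return True

    def validate(self, const: PhysicalConstants = PhysicalConstants()) -> None:
        """Raise :class:`NetworkError` on an ill-posed definition."""
        if not self.segments:
            raise NetworkError("network has no segments")
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise NetworkError("duplicate segment names")
        nodes = set(self.nodes)
        if self.aortic_node == self.venous_node:
            raise NetworkError("aortic and venous nodes must differ")
        for n in (self.aortic_node, self.venous_node):
            if n not in nodes:
                raise NetworkError(f"source node {n!r} not in the graph")
        for n in self.terminals:
            if n not in nodes:
                raise NetworkError(f"terminal node {n!r} not in the graph")
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for s in self.segments:
            g.add_edge(s.from_node, s.to_node)
        # terminals drain to the venous rail
        for n in self.terminals:
            g.add_edge(n, self.venous_node)
        # a venous node touched by no element is just a reference rail
        if g.degree(self.venous_node) == 0:
            g.remove_node(self.venous_node)
        if not nx.is_connected(g):
            raise NetworkError("network graph is not connected")
        # every dead end must be able to pass or store flow
        cap = {n: 0.0 for n in nodes}
        for s in self.segments:
            cap[s.to_node] += s.effective_rlc(const).C
        sources = {self.aortic_node, self.venous_node}
        for n in nodes:
            if n not in g:
                continue
            if g.degree(n) == 1 and n not in sources:
                if n not in self.terminals and cap.get(n, 0.0) == 0.0:
                    raise NetworkError(
                        f"leaf node {n!r} has no terminal bed, compliance or source"
                    )


def assemble_odes(
    net: NetworkSpec,
    drivers: DriverSet,
    const: PhysicalConstants = PhysicalConstants(),
) -> "ODESystem":
    """Build the right-hand side of the network state equations.

    State ordering: flows of inductive segments (m³/s), then transmural
    pressures of compliant nodes (Pa).
    """
    net.validate(const)
    return ODESystem(net, drivers, const)


class ODESystem:
    """Assembled network equations.

    The state x = (q, π) stacks the inductive-segment flows q and the
    compliant-node transmural pressures π = p − p_im.  Algebraic nodes
    (no compliance) and resistive branches (no inertance) are eliminated
    at every evaluation by a pre-factorised linear nodal solve.
    """

    def __init__(
        self, net: NetworkSpec, drivers: DriverSet, const: PhysicalConstants
    ) -> None:
        self.net = net
        self.drivers = drivers
        self.const = const

        self.node_names = net.nodes
        self._nid = {n: i for i, n in enumerate(self.node_names)}
        n_nodes = len(self.node_names)

        # node compliance: shunt C of every segment sits at its distal node
        c_node = np.zeros(n_nodes)
        ind: list[tuple[SegmentSpec, VesselRLC]] = []
        res: list[tuple[SegmentSpec, VesselRLC]] = []
        for s in net.segments:
            rlc = s.effective_rlc(const)
            c_node[self._nid[s.to_node]] += rlc.C
            if rlc.L > 0:
                ind.append((s, rlc))
            else:
                if s.headloss is not None:
                    raise NetworkError(
                        f"segment {s.name!r}: head loss on a purely resistive "
                        "(L = 0) branch is not supported"
                    )
                res.append((s, rlc))

        self.ind_names = [s.name for s, _ in ind]
        self.res_names = [s.name for s, _ in res]
        self._ind_from = np.array([self._nid[s.from_node] for s, _ in ind], int)
        self._ind_to = np.array([self._nid[s.to_node] for s, _ in ind], int)
        self._ind_R = np.array([r.R for _, r in ind])
        self._ind_L = np.array([r.L for _, r in ind])
        # head loss: R_eff = R + hl_const + hl_coef·|q|
        hl_coef = np.zeros(len(ind))
        hl_const = np.zeros(len(ind))
        for i, (s, _) in enumerate(ind):
            h = s.headloss
            if h is None:
                continue
            if h.dynamic:
                # ξ = 288/Re with Re from the instantaneous mean velocity
                # collapses to a constant resistance 144 μ/(A·D)
                D = math.sqrt(4.0 * h.area / math.pi)
                hl_const[i] = 144.0 * const.mu / (h.area * D)
            else:
                hl_coef[i] = h.xi * const.rho / (2.0 * h.area**2)
        self._hl_coef = hl_coef
        self._hl_const = hl_const

        self._res_from = np.array([self._nid[s.from_node] for s, _ in res], int)
        self._res_to = np.array([self._nid[s.to_node] for s, _ in res], int)
        self._res_R = np.array([r.R for _, r in res])

        self._term_nodes = np.array(
            [self._nid[n] for n in net.terminals], int
        )
        self._term_Zinv = np.array(
            [1.0 / t.Z for t in net.terminals.values()]
        )
        # a bed embedded in contracting muscle drains against venous plus
        # tissue (intramyocardial) pressure, not venous pressure alone —
        # the squeeze throttles systolic perfusion instead of aiding it
        self._term_im_lv = np.zeros(len(self._term_nodes))
        self._term_im_rv = np.zeros(len(self._term_nodes))
        for j, name in enumerate(net.terminals):
            c = drivers.im_map.get(name)
            if c is not None:
                (self._term_im_lv if c.chamber == "lv" else self._term_im_rv)[
                    j
                ] = c.factor

        self._i_ao = self._nid[net.aortic_node]
        self._i_ven = self._nid[net.venous_node]
        known = {self._i_ao, self._i_ven}

        self._comp_idx = np.array(
            [i for i in range(n_nodes) if c_node[i] > 0 and i not in known], int
        )
        self._comp_C = c_node[self._comp_idx]
        self.comp_names = [self.node_names[i] for i in self._comp_idx]
        # intramyocardial coupling factors per compliant node
        self._im_lv = np.zeros(len(self._comp_idx))
        self._im_rv = np.zeros(len(self._comp_idx))
        for j, name in enumerate(self.comp_names):
            c = drivers.im_map.get(name)
            if c is not None:
                (self._im_lv if c.chamber == "lv" else self._im_rv)[j] = c.factor

        self._alg_idx = np.array(
            [
                i
                for i in range(n_nodes)
                if c_node[i] == 0 and i not in known
            ],
            int,
        )

        # nodal conductance matrix over resistive branches and terminals
        G = np.zeros((n_nodes, n_nodes))
        for i in range(len(res)):
            a, b, g = self._res_from[i], self._res_to[i], 1.0 / self._res_R[i]
            G[a, a] += g
            G[b, b] += g
            G[a, b] -= g
            G[b, a] -= g
        for i, zi in zip(self._term_nodes, self._term_Zinv):
            G[i, i] += zi
            G[i, self._i_ven] -= zi
        self._G = G
        if len(self._alg_idx):
            g_aa = G[np.ix_(self._alg_idx, self._alg_idx)]
            diag = np.abs(np.diag(g_aa))
            if np.any(diag == 0):
                bad = self.node_names[self._alg_idx[int(np.argmin(diag))]]
                raise NetworkError(
                    f"junction {bad!r} has neither compliance nor any "
                    "resistive path; pure-inductive junctions are not supported"
                )
            self._other_idx = np.array(
                [i for i in range(n_nodes) if i not in set(self._alg_idx)], int
            )
            self._g_ao = G[np.ix_(self._alg_idx, self._other_idx)]
            self._lu = lu_factor(g_aa)

        self.n_state = len(ind) + len(self._comp_idx)
        self.state_names = [f"q:{n}" for n in self.ind_names] + [
            f"p_tm:{n}" for n in self.comp_names
        ]
        #: per-component magnitude scale, for absolute solver tolerances
        self.state_scale = np.concatenate(
            [np.full(len(ind), 1e-6), np.full(len(self._comp_idx), 1e4)]
        )

    # ------------------------------------------------------------------

    def initial_state(self) -> np.ndarray:
        return np.zeros(self.n_state)

    def split_state(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        nq = len(self.ind_names)
        return x[:nq], x[nq:]

    def node_pressures(self, t: float, x: np.ndarray) -> np.ndarray:
        """Absolute pressure at every node (Pa), algebraic nodes solved."""
        q, pi = self.split_state(x)
        p = np.zeros(len(self.node_names))
        p[self._i_ao] = self.drivers.aortic_pa(t)
        p[self._i_ven] = self.drivers.venous_pa()
        if len(self._comp_idx):
            p[self._comp_idx] = pi + self._im_pressure(t)
        if len(self._alg_idx):
            inj = self._inductive_injection(q)
            if len(self._term_nodes):
                inj[self._term_nodes] += self._term_Zinv * self._term_im(t)
            rhs = inj[self._alg_idx] - self._g_ao @ p[self._other_idx]
            p[self._alg_idx] = lu_solve(self._lu, rhs)
        return p

    def _im_pressure(self, t: float) -> np.ndarray:
        """Intramyocardial (external) pressure at compliant nodes, Pa."""
        out = np.zeros(len(self._comp_idx))
        if np.any(self._im_lv):
            out += self._im_lv * (
                self.drivers.ventricular_pressure_mmhg("lv", t) * MMHG_PA
            )
        if np.any(self._im_rv):
            out += self._im_rv * (
                self.drivers.ventricular_pressure_mmhg("rv", t) * MMHG_PA
            )
        return out

    def _term_im(self, t: float) -> np.ndarray:
        """Tissue (intramyocardial) back-pressure seen by each bed, Pa."""
        out = np.zeros(len(self._term_nodes))
        if np.any(self._term_im_lv):
            out += self._term_im_lv * (
                self.drivers.ventricular_pressure_mmhg("lv", t) * MMHG_PA
            )
        if np.any(self._term_im_rv):
            out += self._term_im_rv * (
                self.drivers.ventricular_pressure_mmhg("rv", t) * MMHG_PA
            )
        return out

    def _inductive_injection(self, q: np.ndarray) -> np.ndarray:
        inj = np.zeros(len(self.node_names))
        np.add.at(inj, self._ind_to, q)
        np.add.at(inj, self._ind_from, -q)
        return inj

    def segment_flows(self, t: float, x: np.ndarray) -> dict[str, float]:
        """Instantaneous flow (m³/s) through every segment by name."""
        q, _ = self.split_state(x)
        p = self.node_pressures(t, x)
        out = dict(zip(self.ind_names, q))
        if len(self._res_R):
            qr = (p[self._res_from] - p[self._res_to]) / self._res_R
            out.update(zip(self.res_names, qr))
        return out

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        q, _ = self.split_state(x)
        p = self.node_pressures(t, x)

        r_eff = self._ind_R + self._hl_const + self._hl_coef * np.abs(q)
        dq = (p[self._ind_from] - p[self._ind_to] - r_eff * q) / self._ind_L

        net_in = self._inductive_injection(q)
        if len(self._res_R):
            qr = (p[self._res_from] - p[self._res_to]) / self._res_R
            np.add.at(net_in, self._res_to, qr)
            np.add.at(net_in, self._res_from, -qr)
        if len(self._term_nodes):
            net_in[self._term_nodes] -= (
                p[self._term_nodes] - p[self._i_ven] - self._term_im(t)
            ) * self._term_Zinv
        dpi = net_in[self._comp_idx] / self._comp_C
        return np.concatenate([dq, dpi])

    def kirchhoff_residual(self, t: float, x: np.ndarray) -> float:
        """Worst current-balance residual at algebraic junctions,
        relative to the largest incident flow magnitude there."""
        if not len(self._alg_idx):
            return 0.0
        q, _ = self.split_state(x)
        p = self.node_pressures(t, x)
        net_in = self._inductive_injection(q)
        mags = np.abs(self._inductive_injection(np.abs(q)))
        if len(self._res_R):
            qr = (p[self._res_from] - p[self._res_to]) / self._res_R
            np.add.at(net_in, self._res_to, qr)
            np.add.at(net_in, self._res_from, -qr)
            aqr = np.abs(qr)
            np.add.at(mags, self._res_to, aqr)
            np.add.at(mags, self._res_from, aqr)
        if len(self._term_nodes):
            qt = (
                p[self._term_nodes] - p[self._i_ven] - self._term_im(t)
            ) * self._term_Zinv
            net_in[self._term_nodes] -= qt
            mags[self._term_nodes] += np.abs(qt)
        scale = np.maximum(mags[self._alg_idx], 1e-300)
        return float(np.max(np.abs(net_in[self._alg_idx]) / scale))
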