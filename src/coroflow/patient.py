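"""Built-in patient-specific coronary network.

The fixture encodes a 17-branch coronary tree segmented from CT
angiography of an adult male (heart rate 75 bpm, cardiac cycle 0.8 s)
following the AHA segment convention: the right coronary artery (RCA)
ending in the posterior descending (PDA) and posterolateral (PLA)
branches, and the left main (LMCA) splitting into the left anterior
descending chain (LAD, LAD1–LAD4) with a diagonal (DIAG) and the
circumflex chain (LCX, LCX1–LCX3) with three obtuse marginals
(MARG1–MARG3).

Element values are the published per-branch R/L/C estimates, stored
verbatim in clinical units (mmHg·s/ml, mmHg·s²/ml, ml/mmHg).  Ten
vascular beds attach where the imaging study placed them, each defined by
its structured-tree root radius; bed impedances are computed from those
radii by :mod:`coroflow.structured_tree` at load time (published
impedance values are kept alongside for trend comparison).  Head-loss
elements sit at the two coronary ostia (LMCA and RCA inlets), with the
ostial area derived from each inlet segment's own (R, L)-implied
diameter.

The published network closes the loop through the systemic and pulmonary
circulations, but no element values are available for that outer loop;
here it is replaced by a prescribed aortic pressure source and a constant
venous sink, which is the boundary the coronary sub-network actually
sees.
"""

from __future__ import annotations

from typing import Mapping

from .drivers import DriverSet, ImCoupling, default_driver_set
from .network import HeadLossSpec, NetworkSpec, SegmentSpec, Terminal
from .structured_tree import terminal_impedance_from_radius
from .units import PhysicalConstants, convert_units, geometry_from_rl

__all__ = [
    "TABLE_RLC",
    "TABLE_VENTRICLE",
    "TABLE_TERMINALS",
    "TOPOLOGY",
    "AORTIC_NODE",
    "VENOUS_NODE",
    "distal_node",
    "load_patient_fixture",
    "default_fixture_drivers",
]

#: Per-branch lumped values, clinical units (mmHg·s/ml, mmHg·s²/ml,
#: ml/mmHg), verbatim from the CT-based estimates.  The inductance column
#: is interpreted in mmHg·s²/ml, the dimensionally consistent inertance
#: unit.  Only the RCA row is mutually consistent with the Poiseuille
#: relations under the default constants; values are preserved as
#: printed, not re-derived.
TABLE_RLC: Mapping[str, tuple[float, float, float]] = {
    "RCA": (1.64, 0.12, 0.0064),
    "PDA": (2.31, 0.079, 0.011),
    "PLA": (1.31, 0.064, 0.017),
    "LMCA": (0.14, 0.018, 0.0035),
    "LAD": (0.5, 0.144, 0.0017),
    "LAD1": (0.24, 0.023, 0.0023),
    "LAD2": (0.87, 0.067, 0.0045),
    "LAD3": (0.43, 0.031, 0.00018),
    "LAD4": (0.63, 0.041, 0.0019),
    "DIAG": (3.19, 0.12, 0.0013),
    "LCX": (0.17, 0.16, 0.0017),
    "LCX1": (0.14, 0.013, 0.0013),
    "LCX2": (0.19, 0.017, 0.00015),
    "LCX3": (0.38, 0.033, 0.0027),
    "MARG1": (0.71, 0.049, 0.0027),
    "MARG2": (1.17, 0.064, 0.0021),
    "MARG3": (1.94, 0.081, 0.0016),
}

#: Ventricular pumping-function parameters (Rv mmHg·s/ml, U0 mmHg,
#: Ed mmHg/ml, V0 ml).
TABLE_VENTRICLE: Mapping[str, Mapping[str, float]] = {
    "lv": {"Rv": 0.0800, "U0": 50.0, "Ed": 0.10, "V0": 11.29},
    "rv": {"Rv": 0.0175, "U0": 24.0, "Ed": 0.03, "V0": 3.33},
}

#: Vascular beds: branch → (root radius r0 in mm, published structured-
#: tree impedance in mmHg·s/ml).  The published impedances cannot be
#: reproduced from the stated tree constants (see docs/methods.md); the
#: bed impedances used in simulation are recomputed from r0, and the
#: published column is retained for rank-order comparison.
TABLE_TERMINALS: Mapping[str, tuple[float, float]] = {
    "PLA": (1.25, 46.9),
    "PDA": (1.26, 53.8),
    "LAD1": (0.89, 108.7),
    "LAD3": (0.71, 289.8),
    "LAD4": (0.77, 251.9),
    "MARG1": (1.08, 67.4),
    "MARG2": (0.86, 116.7),
    "MARG3": (0.79, 226.3),
    "LCX3": (0.77, 251.7),
    "DIAG": (1.07, 70.6),
}

AORTIC_NODE = "AORTA"
VENOUS_NODE = "VEIN"


def distal_node(branch: str) -> str:
    """Node label at the distal end of a named branch."""
    return f"n_{branch}"


#: Branch → parent branch (None = fed from the aorta).  Chains follow the
#: AHA numbering; each diagonal/marginal leaves the chain after the
#: like-numbered chain segment (DIAG after LAD1, MARGk after LCXk).
TOPOLOGY: Mapping[str, str | None] = {
    "RCA": None,
    "PDA": "RCA",
    "PLA": "RCA",
    "LMCA": None,
    "LAD": "LMCA",
    "LAD1": "LAD",
    "DIAG": "LAD1",
    "LAD2": "LAD1",
    "LAD3": "LAD2",
    "LAD4": "LAD3",
    "LCX": "LMCA",
    "LCX1": "LCX",
    "MARG1": "LCX1",
    "LCX2": "LCX1",
    "MARG2": "LCX2",
    "LCX3": "LCX2",
    "MARG3": "LCX3",
}

#: Branches whose ostium carries a head-loss element.
_HEADLOSS_INLETS = ("LMCA", "RCA")

#: Left-tree vessels run in the LV wall (intramyocardial fraction 1/2 of
#: LV pressure); right-tree vessels in the RV wall (1/3 of RV pressure).
_RIGHT_TREE = ("RCA", "PDA", "PLA")


def _ostial_area(branch: str, const: PhysicalConstants) -> float:
    """Ostial cross-section (m²) from the inlet segment's (R, L)-implied
    diameter."""
    import math

    r_cl, l_cl, _ = TABLE_RLC[branch]
    R = convert_units(r_cl, "R_clinical", "R_SI")
    L = convert_units(l_cl, "L_clinical", "L_SI")
    geom = geometry_from_rl(R, L, const)
    return math.pi * geom.D**2 / 4.0


def load_patient_fixture(
    const: PhysicalConstants = PhysicalConstants(),
    *,
    headloss: bool = True,
    xi: float = 2.88,
) -> NetworkSpec:
    """The 17-branch patient coronary network.

    Segment R/L/C are the published clinical values converted to SI;
    terminal impedances are structured-tree values computed from the
    published root radii; head-loss elements (constant ξ, default 2.88)
    sit at the LMCA and RCA ostia unless ``headloss=False``.
    """
    from .units import VesselRLC

    segments = []
    for name, parent in TOPOLOGY.items():
        r_cl, l_cl, c_cl = TABLE_RLC[name]
        rlc = VesselRLC(
            R=convert_units(r_cl, "R_clinical", "R_SI"),
            L=convert_units(l_cl, "L_clinical", "L_SI"),
            C=convert_units(c_cl, "C_clinical", "C_SI"),
        )
        hl = None
        if headloss and name in _HEADLOSS_INLETS:
            hl = HeadLossSpec(area=_ostial_area(name, const), xi=xi)
        segments.append(
            SegmentSpec(
                name=name,
                from_node=AORTIC_NODE if parent is None else distal_node(parent),
                to_node=distal_node(name),
                rlc=rlc,
                headloss=hl,
            )
        )

    terminals = {}
    for branch, (r0_mm, _z_published) in TABLE_TERMINALS.items():
        r0 = r0_mm * 1e-3
        ti = terminal_impedance_from_radius(r0, mu=const.mu)
        terminals[distal_node(branch)] = Terminal(Z=ti.Z, r0=r0)

    return NetworkSpec(
        segments=segments,
        terminals=terminals,
        aortic_node=AORTIC_NODE,
        venous_node=VENOUS_NODE,
    )


def default_fixture_im_map() -> dict[str, ImCoupling]:
    """Intramyocardial coupling for every fixture node: half of LV
    pressure on the left tree, a third of RV pressure on the right."""
    im = {}
    for branch in TOPOLOGY:
        if branch in _RIGHT_TREE:
            im[distal_node(branch)] = ImCoupling("rv", 1.0 / 3.0)
        else:
            im[distal_node(branch)] = ImCoupling("lv", 0.5)
    return im


def default_fixture_drivers(
    const: PhysicalConstants = PhysicalConstants(),
) -> DriverSet:
    """Driver set matched to the fixture: tabulated ventricle parameters,
    80/120 mmHg aortic pulse, 5 mmHg venous sink, and the default
    intramyocardial map."""
    return default_driver_set(period=const.t_cycle, im_map=default_fixture_im_map())
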