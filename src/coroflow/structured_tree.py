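"""Steady root impedance of small-vessel beds via the symmetric
structured-tree model.

Each terminal coronary branch feeds a self-similar bed: a vessel of radius
``r`` bifurcates into two equal daughters of radius ``α·r`` until the
diameter falls below a cutoff ``d_min``; every vessel has length ``λ·r``
and Poiseuille resistance 8μλ/(πr³).  For steady flow the bed collapses to
a single resistance, the *root impedance* Z, attached between the branch
outlet and the venous pressure.

Two equal daughters in parallel halve the impedance, so generation ``k``
of the tree contributes (8μλ/(πr0³))·(2α³)^(−k) in series and

    Z(N) = (8μλ/(πr0³)) · Σ_{k=0}^{N−1} (2α³)^(−k)

for a tree of N generations.  This positive geometric-series form is the
default engine; it is checked against an explicit leaf-to-root recursion.
A commonly printed closed form,

    Z = (8μλ/(πr0³)) · (2α³ − (1/2α)^N) / (2α³ − 1),

is retained for comparison (:func:`eq8_closed_form`) but is
sign-inconsistent for α < 2^(−1/3) — its denominator is negative while
every physical contribution is positive — and therefore is not used to
compute bed impedances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "StructuredTreeParams",
    "TerminalImpedance",
    "alpha_from_taper",
    "generations_to_cutoff",
    "poiseuille_resistance",
    "root_impedance_series",
    "root_impedance_recursive",
    "eq8_closed_form",
    "terminal_impedance_from_radius",
]


@dataclass(frozen=True)
class StructuredTreeParams:
    """Parameters of a symmetric structured tree.

    Attributes
    ----------
    r0 : float
        Root radius (m).
    alpha : float
        Daughter/parent radius ratio, in (0, 1).  The default 0.778 is
        2^(−1/k) for arterial taper exponent k = 2.76.
    lam : float
        Length-to-radius ratio λ of small arteries (dimensionless).
    d_min : float
        Terminal diameter cutoff (m); bifurcation stops once the vessel
        diameter drops below it.  Default 0.01 mm.
    mu : float
        Blood viscosity (Pa·s).
    """

    r0: float
    alpha: float = 0.778
    lam: float = 50.0
    d_min: float = 1e-5
    mu: float = 4e-3

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if not 0 < self.d_min < 2 * self.r0:
            raise ValueError("d_min must satisfy 0 < d_min < 2·r0")
        if self.mu <= 0:
            raise ValueError("mu must be positive")


@dataclass(frozen=True)
class TerminalImpedance:
    """Steady root impedance Z (Pa·s/m³) of a bed with ``N`` generations
    rooted at radius ``r0`` (m)."""

    Z: float
    N: int
    r0: float

    def __post_init__(self) -> None:
        if self.Z <= 0:
            raise ValueError("Z must be positive")
        if self.N < 1:
            raise ValueError("N must be at least 1")


def alpha_from_taper(exponent: float) -> float:
    """Radius ratio α = 2^(−1/k) of a symmetric bifurcation obeying the
    taper law r_p^k = 2·r_d^k.

    ``k = 3`` is Murray's law (α ≈ 0.794); ``k = 2.76`` gives α ≈ 0.778.
    """
    if exponent <= 0:
        raise ValueError("taper exponent must be positive")
    return 2.0 ** (-1.0 / exponent)


def generations_to_cutoff(p: StructuredTreeParams) -> int:
    """Smallest N ≥ 1 such that the generation-N diameter 2·α^N·r0 falls
    below the cutoff ``d_min``."""
    n = 1
    d = 2.0 * p.alpha * p.r0
    while d >= p.d_min:
        n += 1
        d *= p.alpha
    return n


def poiseuille_resistance(r: float, mu: float, lam: float) -> float:
    """Steady resistance 8μλ/(πr³) of one structured-tree vessel of radius
    ``r`` and length λ·r."""
    return 8.0 * mu * lam / (math.pi * r**3)


# 2α³ within this distance of 1 is treated as the Murray limit, where the
# geometric series degenerates to N equal terms.
_MURRAY_TOL = 1e-12


def root_impedance_series(p: StructuredTreeParams, N: int) -> TerminalImpedance:
    """Root impedance of an N-generation symmetric tree by the geometric
    series Z = (8μλ/(πr0³)) · Σ_{k=0}^{N−1} (2α³)^(−k)."""
    if N < 1:
        raise ValueError("N must be at least 1")
    base = poiseuille_resistance(p.r0, p.mu, p.lam)
    g = 2.0 * p.alpha**3
    if abs(g - 1.0) < _MURRAY_TOL:
        total = float(N)
    else:
        ratio = 1.0 / g
        total = (ratio**N - 1.0) / (ratio - 1.0)
    return TerminalImpedance(Z=base * total, N=N, r0=p.r0)


def root_impedance_recursive(p: StructuredTreeParams) -> TerminalImpedance:
    """Root impedance by explicit leaf-to-root recursion.

    The tree is truncated at the first generation below the diameter
    cutoff, with zero load beyond the leaves (the capillary/venous
    reference is absorbed into the venous sink).  Two equal daughters
    combine in parallel, 1/Z_p = 2/Z_d, and each vessel adds its own
    Poiseuille resistance in series.  Agrees with
    ``root_impedance_series(p, generations_to_cutoff(p))`` to rounding.
    """
    n = generations_to_cutoff(p)
    z = 0.0  # load distal to the leaves
    for k in range(n - 1, -1, -1):
        r = p.alpha**k * p.r0
        z = poiseuille_resistance(r, p.mu, p.lam) + z / 2.0
    return TerminalImpedance(Z=z, N=n, r0=p.r0)


def eq8_closed_form(p: StructuredTreeParams, N: int) -> float:
    """The printed closed form Z = (8μλ/πr0³)·(2α³ − (1/2α)^N)/(2α³ − 1),
    evaluated verbatim.

    For α < 2^(−1/3) the denominator 2α³ − 1 is negative and the formula
    returns negative values for N ≥ 1; it is provided for documentation
    and comparison only.  At the Murray limit 2α³ = 1 the singular
    expression is replaced by its limit N · 8μλ/(πr0³).
    """
    if N < 0:
        raise ValueError("N must be nonnegative")
    base = poiseuille_resistance(p.r0, p.mu, p.lam)
    g = 2.0 * p.alpha**3
    if abs(g - 1.0) < _MURRAY_TOL:
        return base * N
    return base * (g - (1.0 / (2.0 * p.alpha)) ** N) / (g - 1.0)


def terminal_impedance_from_radius(
    r0: float,
    *,
    alpha: float = 0.778,
    lam: float = 50.0,
    d_min: float = 1e-5,
    mu: float = 4e-3,
) -> TerminalImpedance:
    """Default bed-impedance engine: geometric series truncated at the
    diameter cutoff.  ``r0`` in metres; result in Pa·s/m³."""
    p = StructuredTreeParams(r0=r0, alpha=alpha, lam=lam, d_min=d_min, mu=mu)
    return root_impedance_series(p, generations_to_cutoff(p))
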