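# Methods

## Model overview

`coroflow` solves a lumped-parameter (0D) electrical analogue of the
coronary circulation.  A network is a directed graph of vessel segments;
each segment is an *inverted-L* cell: a series resistance R and
inertance L carrying the segment flow, with the compliance C shunted at
the distal node.  The per-segment momentum and continuity relations

    −Δp = L dq/dt + R q,        q = C dp/dt

assemble into a system of ODEs whose state stacks the flows of inductive
segments and the *transmural* pressures π = p − p_im of compliant nodes
(p_im is the external intramyocardial pressure, zero for nodes outside
the heart wall).  Nodes without compliance are algebraic Kirchhoff
junctions and segments without inertance are algebraic resistive
branches; both are eliminated at every right-hand-side evaluation by a
pre-factorised linear nodal solve, so the integrated system is a pure
ODE (a junction touched only by inductive segments is rejected as
ill-posed rather than integrated as a higher-index DAE).

The inverted-L cell is a choice: with per-branch (R, L, C) triples the
circuit cell per vessel is underdetermined (L-, T- and π-cells are all
consistent with the two governing relations).  The inverted-L is the
minimal cell that keeps one flow and one pressure state per segment.

### Units

All internal computation is in SI (Pa, s, m³).  Clinical units — mmHg,
ml, mm, cm, as physiology tables print them — exist only at the I/O
boundary (config files, CLI output, the built-in tables) and are
converted exactly once at parse/load time, using 1 mmHg = 133.322 Pa.

### Geometry relations

Segments may be specified by geometry instead of element values through
the Poiseuille-tube relations R = 128μl/(πD⁴), C = πD³l/(4Gh),
L = 4ρl/(πD²) with h = 0.08·D.  The inversion D² = 32μL/(ρR),
l = LπD²/(4ρ) recovers (D, l) from a printed (R, L) pair; it is used to
derive the ostial cross-sections for the head-loss elements and to
check the built-in tables.  Of the built-in per-branch rows only the
RCA row is mutually consistent with these relations under the default
constants (recomputed C = 0.0064 ml/mmHg matches the printed value at
two significant figures); the other rows are stored verbatim and are
deliberately not "repaired".

Default constants: μ = 4×10⁻³ Pa·s, ρ = 1.04×10³ kg/m³, G = 2×10⁵ Pa,
h/D = 0.08, cardiac period 0.8 s (75 bpm).

## Structured-tree outflow beds

Each terminal branch drains through a symmetric structured tree: a
vessel of radius r has length λ·r (λ = 50) and splits into two equal
daughters of radius α·r, with α = 2^(−1/k) for taper exponent k = 2.76,
i.e. α ≈ 0.778; bifurcation stops once the diameter falls below
d_min = 0.01 mm.  Only steady (zero-frequency) flow is considered, so
each vessel contributes its Poiseuille resistance 8μλ/(πr³), parallel
daughters halve, and the root impedance of an N-generation tree is the
geometric series

    Z = (8μλ/πr₀³) · Σ_{k=0}^{N−1} (2α³)^(−k).

Two engines compute Z — this series and an explicit leaf-to-root
recursion with zero distal load beyond the cutoff — and are
cross-checked to 1e-12 relative agreement in the tests.  A widely
printed closed form, Z = (8μλ/πr₀³)·(2α³ − (1/2α)^N)/(2α³ − 1), is
retained as `eq8_closed_form` for documentation: its denominator is
negative for α < 2^(−1/3), so at α = 0.778 it yields negative
impedances and cannot be the production engine.  The published bed
impedances for the ten fixture radii are likewise not reproducible from
the stated constants (the cutoff rule gives N = 22 and
Z ≈ 86.7 mmHg·s/ml at r₀ = 1.25 mm, versus a published 46.9); the
package therefore recomputes all bed impedances from the root radii and
asserts only that the published *rank order* is preserved — which it
is, including the inversion where a slightly larger root radius gains a
whole extra generation and ends up with the larger impedance.

## Drivers

**Ventricular pumping function.**  Over each cycle the ventricle
pressure follows the two-phase form

    P_v = U0·σ(t) + E·(V − V0) + Rv·V̇     (systole, t < ts)
    P_v = Ed·(V − V0)                      (diastole)

with σ(t) = 1 − cos(2πt/ts).  Tabulated parameters: LV Rv = 0.08
mmHg·s/ml, U0 = 50 mmHg, Ed = 0.10 mmHg/ml, V0 = 11.29 ml; RV 0.0175,
24, 0.03, 3.33.  The systolic duration ts is not tabulated; it defaults
to 0.3·period, the conventional systolic fraction, and is a config
parameter.  The piecewise form is discontinuous at the phase switches
in general; `phase_discontinuity` reports the jump magnitudes, and the
integrator restarts at every switch.

**Systolic elastance default.**  The systolic elastance E has no
tabulated value.  With E = 0 the pumping function peaks near 63 mmHg
(U0·σ reaches 100 mmHg but the ejection drag Rv·V̇ subtracts ≈37), so
the model LV could not eject against an 80/120 mmHg aorta and the
intramyocardial squeeze would be too weak to shape coronary flow.  The
default is therefore chosen by a closure argument: E such that peak LV
pressure lands just above the systolic aortic pressure it must eject
against, giving E_lv = 0.7 mmHg/ml (peak ≈125 mmHg); E_rv = 0.21 scales
by the same ratio as the passive elastances (0.03/0.10).  Both are
plain config parameters.

**Volume waveform.**  No ventricular volume trace is prescribed by the
tables, so a smooth stand-in supplies V(t): half-cosine ejection of the
stroke volume (default 70 ml) over [0, ts] and half-cosine refilling
over [ts, period], C¹-periodic with zero net volume per cycle, riding
on an end-systolic volume of V0 + 50 ml (ejection fraction ≈0.53).

**Aortic pressure.**  The coronary inlets see a prescribed aortic
waveform (the systemic/pulmonary loop that would close the circuit has
no usable element values, so an open-loop pressure source replaces it).
The default is an 80/120 mmHg pulse with physiological structure:
half-sine upstroke to the 120 mmHg peak, quarter-cosine fall to an
incisura at 108 mmHg, then an exponential diastolic runoff ending at
exactly 80 mmHg at the wrap.  The upstroke is delayed by 0.075·period
(60 ms at 0.8 s) after the onset of ventricular activation — the
isovolumic contraction time, within the textbook 50–90 ms range — since
the aortic valve opens only once P_lv exceeds aortic pressure.  This
delay also produces the characteristic early-systolic dip of left
coronary flow: the wall squeezes before the perfusion pressure rises.

**Intramyocardial coupling.**  Each coupled node is assigned a chamber
and a fraction: the default map uses ½ of LV pressure for the left tree
(LAD/LCX territories lie in the LV wall) and ⅓ of RV pressure for the
right tree.  Fractions other than ⅓ and ½ require an explicit override
flag.  The coupling enters in two places:

1. *Compliance reference*: storage is transmural,
   C·d(p − p_im)/dt = net inflow.
2. *Bed back-pressure*: a terminal bed at a coupled node drains as
   (p − p_ven − p_im)/Z — the microcirculation is embedded in the same
   contracting muscle, so its effective downstream pressure is venous
   plus tissue pressure (the vascular-waterfall concept).  With
   venous-only back-pressure the squeeze would *pump* the beds forward
   in systole, inverting the physiological systolic impediment; the
   waterfall form restores it and yields diastole-dominant left-tree
   flow together with the relatively systolic right-tree flow.

The venous sink is a constant right-atrial pressure, default 5 mmHg.

## Head loss and stenosis

The abrupt cross-section change at the two coronary ostia dissipates
Δp = ξρv²/2.  As a resistance this is R_h = ξρ|q|/(2A²), proportional
to the flow; |q| (rather than q) keeps the drop opposing the flow when
early-systolic reversal occurs.  The default is the constant ξ = 2.88
(constriction diameter ratio 0.5 at Re = 100, from the empirical law
ξ = 288/Re); an optional dynamic mode re-evaluates ξ = 288/Re from the
instantaneous mean velocity, which algebraically collapses to the
constant resistance 144μ/(A·D).  Ostial areas in the fixture come from
each inlet segment's own (R, L)-implied diameter (RCA ≈3.0 mm,
LMCA ≈4.0 mm).  Head loss on a purely resistive (L = 0) branch would
make the nodal elimination nonlinear and is rejected.

A stenosis narrows a whole named segment uniformly to the area fraction
α = A_s/A₀, rescaling R → R·α⁻², C → C·α^{3/2}, L → L·α⁻¹.  Percent
stenosis converts as α = 1 − p/100 under the area convention and
α = (1 − p/100)² under the clinical radius convention.

**FFR** is computed from cycle-mean pressures (the clinical definition)
as mean(p_distal)/mean(p_proximal) across the stenosed segment;
relative flow normalises the stenosed cycle-mean segment flow by the
0 % baseline of the same network, head loss included.  Terminal
impedances are not modified under stenosis (no hyperemia model).

## The patient fixture

The built-in network has 17 branches following the AHA segmentation:
RCA → {PDA, PLA}; LMCA → {LAD chain LAD–LAD1–LAD2–LAD3–LAD4 with DIAG
off LAD1; LCX chain LCX–LCX1–LCX2–LCX3 with MARG1/2/3 off LCX1/2/3}.
Ten structured-tree beds attach at the tabulated branches (three of
them — LAD1, LAD3, LCX3 — at junction nodes rather than leaves, which
the solver supports).  Per-branch R/L/C are stored verbatim in clinical
units; the inductance column is interpreted in mmHg·s²/ml, the
dimensionally consistent inertance unit.  Exact junction placement of
the diagonal/marginal branches is not fully determined by the source
imaging description; the rule used is "branch leaves after the
like-numbered chain segment", with the unnumbered DIAG placed after
LAD1 (the first diagonal conventionally arises from the proximal LAD).

## Numerics

* Integrator: `scipy.integrate.solve_ivp`, LSODA by default,
  `max_step` = 2 ms, rtol 1e-8, per-component atol scaled to typical
  magnitudes (1e-6 m³/s for flows, 1e4 Pa for pressures, × 1e-10).
  Each cycle is integrated in two spans split at the systole/diastole
  switch so the driver discontinuity never sits inside a solver step.
* Periodic steady state: cycles are compared on a uniform 256-sample
  grid; convergence is declared when the scaled relative L2 difference
  between successive cycle trajectories drops below 1e-4 (the fixture
  converges in ~6 cycles from rest).  Non-convergence raises an error
  carrying the per-cycle difference history; non-finite states raise
  with the offending time.
* The algebraic subsystem is linear by construction (head loss is
  confined to inductive branches), assembled once as a nodal
  conductance matrix and LU-factorised; Kirchhoff residuals at
  junctions are at rounding level (< 1e-9 relative, asserted in tests).
* Degenerate circuits with no state at all (purely resistive toys) skip
  the integrator and evaluate the algebraic solution directly.

Problem sizes used in the shipped tests and the acceptance script —
256 samples/cycle, ≤40 cycles, a 5-point stenosis sweep, 120 random
draws for the tree-engine cross-check — were chosen so the full suite
exercises every path at desk scale; the fixture network itself is small
(34 states), so none of these limits bind.

## What the toy catalog does and does not show

The toy circuits (`single_R`, `series_RR`, `rc_node`, `rl_segment`,
`windkessel3`) each carry an exact closed form — Ohmic series flow, RC
relaxation, R–L sinusoidal amplitude/phase transfer, windkessel levels
— and validate the assembly/elimination/integration machinery to
sub-percent accuracy.  They are linear and driven by simple sources, so
they do not exercise the head-loss nonlinearity, the intramyocardial
coupling, or the phase-switch discontinuity; those paths are covered by
directional checks on the patient fixture (head loss strictly reduces
right-tree inflow; left-tree flow is diastole-dominant; FFR and
relative flow fall monotonically with stenosis severity).

## Known limitations

* Rigid tubes: no wave propagation, no pulse-wave velocity, and less
  "wavy" waveforms than catheter measurements.
* Open-loop: prescribed aortic pressure and constant venous pressure
  instead of a closed systemic/pulmonary circulation; no baroreflex, no
  autoregulation, no hyperemia.
* Steady-flow bed impedances (no frequency-dependent structured tree);
  symmetric trees only.
* The ventricular volume waveform is prescribed, not coupled to the
  ejection dynamics; the pumping function's piecewise form is
  discontinuous at the phase switches.
* The published bed-impedance values are not recoverable from the
  published tree constants (see above); simulations use the recomputed,
  self-consistent values.
* Uniform-narrowing stenosis of whole named segments; no focal-lesion
  subdivision or post-stenotic pressure-recovery model.
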