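# Methods

## Model

Blood is treated as incompressible and Newtonian (ρ = 1.06 g/cm³,
μ = 0.035 P) flowing in thin-walled elastic vessels. Each segment carries
the cross-sectionally averaged mass and momentum balances

    ∂A/∂t + ∂Q/∂x = 0
    ∂Q/∂t + ∂(Q²/A)/∂x = −(A/ρ) ∂P/∂x + f/ρ

with the friction term f = −2(ζ+2)πμU of an axisymmetric power-law velocity
profile of order ζ (default ζ = 9, a blunt large-artery profile; ζ = 2 is
Poiseuille). The wall obeys the tube law

    P = P_dia + (β/A_d)(√A − √A_d),   β = (4/3)√π·E·h,

whose stiffness is set through the diastolic pulse wave velocity

    c_d² = (2/3ρ)·Eh/r_d = (2/3ρ)(k₁ e^{k₂ r_d} + k₃),

with empirical coefficients (k₁, k₂, k₃) = (3×10⁶ g s⁻² cm⁻¹, −9 cm⁻¹,
33.7×10⁴ g s⁻² cm⁻¹) for systemic and (20×10⁶, −22.5, 86.5×10⁴) for
coronary arteries. These two relations are mutually consistent:
ρc_d² = A_d (dP/dA)|_{A_d} holds identically, and the test suite asserts it
for random tapered segments. Radius tapers linearly along a segment;
integral segment properties (viscous resistance R_v = ∫2(ζ+2)πμ/Ā² dx,
volume compliance C_v = (1/ρ)∫Ā/c̄² dx) use composite-trapezoid quadrature
on a 51–101 point grid, which keeps the quadrature error below 0.1% for the
tapers that occur in arterial trees.

All internal computation is CGS (the stiffness coefficients above are
printed in CGS); file I/O and reports use mmHg, ml/s and mm
(1 mmHg = 1333.22 dyn/cm²).

## Numerical scheme

The 1D equations are advanced with the explicit MacCormack
predictor–corrector (forward differences in the predictor, backward in the
corrector), treating the pressure-gradient and friction terms as sources
evaluated consistently with each sweep's differencing direction. Because
the pressure — not the area — is differenced, a network at P = P_dia
everywhere is an exact discrete equilibrium even with tapered vessels.

The time step is set once per cardiac cycle from the CFL condition
dt = CFL·min(dx/(|U| + c)) (default CFL 0.9) and then rounded so an integer
number of steps covers the period. Wave speed grows during systole; if the
Courant number exceeds one mid-cycle, the cycle restarts from its saved
initial state with the step shrunk accordingly (an explicit `dt_override`
aborts instead, since the user asked for that step). Default grid spacing
is 0.25 cm.

Vessel ends couple through junction systems solved by Newton iteration at
each step: one outgoing Riemann invariant per port (W± = U ± 4c for the
√A tube law, extrapolated first-order along the characteristic from the
adjacent interior node), conservation of mass, and continuity of total
pressure P + ½ρU². The Newton residuals are scaled per equation class and
iterated to 10⁻¹² relative, which keeps the junction mass defect below
10⁻¹⁰ of peak flow in practice. Stenotic spans are removed from the grid;
the two cut faces form a two-port junction whose pressure equation carries
the empirical loss ΔP = K_v Q + K_e Q|Q|. The default coefficient rule is
the Young–Tsai-type form (K_v from the geometry and length of the
constriction, K_t = 1.52 for the expansion term); both coefficients are
stored explicitly in the network file so any other rule can be substituted
bit-exactly.

Outlet Windkessels are integrated with the Crank–Nicolson rule inside the
boundary Newton solve (second order: the zero-inflow pressure decay matches
exp(−t/R₂C) to ~10⁻⁸ relative at solver step sizes). The coronary outlet is
the chain R_a → C_a (to P_out) → R_m → C_m (to γ_im·P_lv(t)) → R_v → P_out:
the intramyocardial capacitor is referenced to a scaled left-ventricular
pressure, which raises the outlet's apparent impedance during systole. γ_im
defaults to 1 and the state vector uses v = P_m − γ_im·P_lv so the LV
pressure never needs numerical differentiation. Hyperaemia divides all
coronary outlet resistances by α (defaults: 3 for healthy outlets, 1.25
distal of a stenosis).

Initial state is P = P_dia, Q = 0 with Windkessel capacitors charged to
P_dia. Cycles repeat until the relative L2 change of pressure between
consecutive cycles at every output site falls below `periodicity_tol`
(default 10⁻³, at most 20 cycles; non-convergence is flagged on the result,
not raised). The final cycle is resampled to 1000 uniform points, which
fixes N_t for all error metrics.

## Method 1 — algebraic reduction

The steady, linearized network is solved by Picard iteration: with areas
frozen, segments are resistors R_v(Ā) (plus the chord-linearized stenosis
resistance K_v + K_e|Q̄|, whose fixed point reproduces the nonlinear drop
exactly), outlets are their series resistance to P_out, and the inflow
imposes the time-averaged flow. Each sweep is one linear nodal-analysis
solve; node pressures update the areas through the tube law until the
maximum relative pressure change is below 10⁻⁸ (typically 4–6 sweeps). The
dynamic-head terms ½ρU² are dropped from the junction equations at this
mean-flow linearization state; this is what makes each sweep linear, and
the converged solve matches an independent dense nodal-analysis oracle to
better than 10⁻¹⁰ on random trees and looped networks.

A cut face then gets: lumped resistance R = (P̄ − P_out)/Q̄; proximal
resistance R₁ = Z_c = ρc̄/Ā evaluated from the steady state at the face
(R₂ = R − Z_c; an error is raised if R ≤ Z_c — the cut is too close to the
periphery to lump); and lumped compliance combining distal volume
compliances C_v with the terminal formula

    C_t = (C_v R₂ + C_v R₁ + C R₂ + C_v R_v)/(R₂ + R₁ + R_v)

for WK3-terminated vessels and C_t = C_v + C_a + C_m for coronary
terminals. All contributions add in parallel (plain capacitance sum):
arterial compliances share the external reference pressure, so a parallel
combination is the physically consistent rule; the combiner is a single
function that can be swapped if a different series/parallel convention is
wanted. Truncation is supported where the entire distal side of a junction
is removed, so the parent's distal face becomes the outlet; removing some
branches of a junction while keeping others is rejected with a clear error.
Lumped coronary beds are split R_a:R_m:R_v = 0.32:0.52:0.16 and
C_a:C_m = 0.11:0.89 (configurable; plausible ratios for a coronary
microcirculation whose detailed split is itself a modelling choice).

## Method 2 — optimization-based reduction

Each truncated site is fitted independently. The WK3 ODE
C dP_c/dt = Q − (P_c − P_out)/R₂, P = P_c + R₁Q is driven by the baseline
1D flow at the cut face; cycles are marched (Crank–Nicolson, the site's own
1000-point grid) until the start-of-cycle state drifts less than 10⁻⁸,
mirroring how the 1D solver reaches periodicity. The optimizer is
Nelder–Mead on log-transformed θ = (R₁/R₂, C) with R₁ + R₂ held at
(P_avg − P_out)/Q_avg from the baseline time averages — a two-parameter
subset chosen because the three WK3 parameters are not jointly identifiable
from a single pressure trace once the total resistance is pinned by the
means. The objective is the average relative pressure error ε_P,avg;
Method 1 supplies the initial guess (R₁ = Z_c, C = C_lumped), and the
returned objective can never exceed the initial one. On noiseless data
generated by a known WK3 the fit recovers θ to ~10⁻⁷ relative with
objective ~10⁻¹¹. Coronary cut faces keep the Method 1 parameters (the
fitting route is defined for WK3 outlets).

## Error metrics and indices

ε_P,avg is the mean pointwise relative pressure error; ε_Q,avg normalizes
by the baseline's cycle maximum (flow crosses zero); ε_P,sys, ε_P,dia, ε_PP
compare cycle extrema; ε_P,aug compares augmentation pressure
P_sys − P_infl normalized by baseline pulse pressure. The early-systolic
inflection point is found on a Savitzky–Golay-smoothed signal (2nd-order,
7-point window at 1000 samples/cycle): among zero crossings of the second
derivative between the diastolic foot and the systolic peak — the flat
diastolic baseline, where the second derivative is numerical noise, is
excluded — a −→+ crossing (the shoulder of an augmented wave) is preferred,
falling back to the first +→− crossing for non-augmented waves; a waveform
with neither reports the metric as undefined rather than zero. iFR is the
mean distal/proximal pressure ratio over the last 30% of the cycle; FFR the
cycle-mean ratio under hyperaemia. Input impedance is the harmonic-wise
ratio of Fourier coefficients, with harmonics below 10⁻¹² of the flow
spectrum's maximum omitted. When two waveforms are compared on different
grids, the baseline grid wins and the reduced waveform is interpolated
periodically.

## Topology optimization

Candidates are compositions of junction-level truncations: for every
junction whose distal side (the connected component not containing the
inflow after the junction is removed — this handles loops such as a
cerebral ring) contains no protected segment, that side may be removed.
Candidates are ordered by retained artery count; the optimizer simulates
the baseline once (with output sites at every potential cut face), builds
each candidate with Method 1 or 2, simulates it and evaluates the metric —
a single metric, a named sum (e.g. ε_P,sys + ε_P,dia), averaged over the
quantity-of-interest sites. In exhaustive mode (default) every candidate is
evaluated, giving a minimality certificate; a first-feasible ascending scan
is available for larger networks. Ties among equal-size feasible candidates
break on the lower achieved error. The pipeline contains no randomness, so
fixed inputs give identical outcomes.

## Synthetic fixtures

The test fixtures are deliberately small, not anatomically realistic:
a 10 cm aorta-like single vessel (r = 1 cm), symmetric binary trees with
Murray-consistent daughter radii (r·2^(−1/3), lengths halving), a
four-arc ring with two outlet stubs (loop handling), and a four-segment
coronary toy with one 75%-area stenosis and two coronary Windkessel
outlets sized by Murray's law from 4.5% of cardiac output. The inflow is a
half-sine ejection (default 60 bpm, ET 0.3 s, SV 70 ml — a normal resting
state); LV pressure is a squared-sine systolic bump. Outlet resistances
target a 100 mmHg mean root pressure at the nominal mean flow, and the WK3
time constant R₂C is set to 0.35 s so the toys reach periodicity in ~6
cycles; real arterial beds have slower diastolic decay (~1.3 s), so toy
pulse pressures are larger than physiological. Consequently, passing tests
demonstrate the correctness of the numerics and the reduction machinery —
conservation, convergence to closed forms, oracle agreement, the relative
ordering of the two methods — not the clinical accuracy of any particular
anatomical model, which depends entirely on the user-supplied network data.
The coronary total compliance defaults to 10⁻⁵ cm⁵/dyn (~0.013 ml/mmHg), a
plausible bed value exposed as a parameter because it is normally
identified from a heart-model fit that is outside this package's scope.

## Numerical choices and limitations

* Output sites snap to the nearest grid node; sites inside a removed
  stenotic span snap to the nearer cut face.
* `rescale_inflow` identifies the ejection interval as the contiguous
  positive-flow support containing the cycle maximum, rescales it to the
  new ejection time starting at t = 0, and normalizes the integral to the
  stroke volume exactly; waveforms whose ejection does not start at t = 0
  are shifted there.
* Ageing enforces its resistance (×1.1) and compliance (÷2) targets exactly
  by a Brent solve on the WK3 R₂ scale factor and a closed-form rescale of
  the WK compliances; the 1D compliance bookkeeping uses the diastolic
  reference state, the package's convention for whole-network compliance.
* The steady solve's areas and the pulsatile solution's time-averaged areas
  differ slightly (the mean state sits above diastole); lumped compliances
  therefore carry a few-percent linearization-state uncertainty, visible as
  an ~O(10%) difference between diastolic-convention network totals before
  and after truncation.
* No viscoelastic wall behaviour, no venous return, no closed-loop heart
  coupling, and no 3D geometry processing. Vessel collapse (P far below
  diastolic) raises an error rather than switching to a collapsed tube law.
* The junction model assumes quasi-1D flow at bifurcations; energy losses
  at normal junctions are neglected (ΔP = 0), as is conventional.
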