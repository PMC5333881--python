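# Methods

This note documents the model, its parameters and numerical choices, what
the synthetic geometry does and does not emulate, and the known
limitations. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## 1. The reduced-order model

The study question — how regional, age-associated changes in aortic
geometry and biaxial wall stiffness shape hemodynamic surrogates of
stiffening — is posed here in a distributed 1D (cross-sectionally
averaged) framework rather than 3D fluid–structure interaction. The 1D
reduction retains the physics that set the four metrics of interest
(compliance-dominated wave propagation, tapering and branching
reflections, lumped distal beds) and discards secondary flow, wall shear
distributions, and curvature pressure losses.

### Governing equations

Per vessel, with area A(x,t), flow Q(x,t), pressure P(x,t):

    ∂A/∂t + ∂Q/∂x = 0
    ∂Q/∂t + ∂(Q²/A)/∂x + (A/ρ) ∂P/∂x = −K_R Q/A,   K_R = 8πμ/ρ

(flat velocity profile α = 1, Poiseuille-type friction; ρ = 1060 kg/m³,
μ = 4.0 mPa·s — standard blood values, configurable). The wall closure is
the linearized membrane + external support equilibrium

    P = P_ref + (A − A_ref)/(dA/dP) + (c_s/2πR) ∂A/∂t
    dA/dP = 2πR / (K_θθ h/R² + k_s)

anchored at the in vivo (MAP) state: A_ref = πR² with R the tabulated in
vivo inner radius, P_ref the station MAP interpolated along the aorta.
The corresponding wave speed, c = √((K_θθ h/R + k_s R)/(2ρ)), is the
Moens–Korteweg form generalized by perivascular support stiffness k_s.
Linearization is justified by the near-linear pressure–area response of
aged human aortas over the diastolic–systolic range; it is exact for the
wave-speed bookkeeping the study rests on. The axial stiffness K_zz is
carried in the data model but does not enter the radial-motion tube law —
a deliberate restriction to radial tethering.

### Wall properties

The default ("table") mode drives the simulation directly with the bundled
station table: inner radius, thickness, MAP, EP, in vivo stretches, and
biaxial incremental stiffness (K_θθ, K_zz) at the ascending (s = 0.12),
proximal descending (s = 0.4) and infrarenal (s = 0.88) stations for ages
40/60/75, linearized at transmural pressure TP = MAP − EP. Values are
interpolated linearly in normalized arc length s and extrapolated
constantly beyond the outer stations, through the iliacs. Carotid and
subclavian arteries receive isotropic age-dependent stiffness (0.55/0.75/
0.95 MPa at 40/60/75 — a sparse-literature trend, flagged approximate and
configurable); mesenteric, celiac, renal and the remaining muscular
branches are age-invariant at the 75-yo infrarenal stiffness (muscular
arteries do not stiffen appreciably with age).

The constitutive path implements the four-fiber-family strain energy
(neo-Hookean matrix + axial, circumferential and ±45° diagonal
exponential fiber families), membrane Cauchy stress under
incompressibility, the thin-wall equilibrium solve, and small-on-large
incremental moduli K_i = λ_i ∂σ_i/∂λ_i computed from analytic second
derivatives (validated against central finite differences to 1e-5
relative). It exists for users who supply fitted fiber parameters; no
fitting to experimental biaxial data is performed here.

Note: the tabulated 60-yo circumferential stiffness dips ~5% from ATA
(0.75 MPa) to DTA (0.71 MPa) before rising threefold to the IAA, so the
"stiffness increases along the aorta" pattern holds strictly only at 40
and 75 and distal of the DTA at 60.

## 2. Synthetic geometry and virtual aging

The baseline 30-yo tree is idealized (no imaging): a tapered trunk of
0.50 m root-to-bifurcation arc length parameterized by s ∈ [0, 1], iliac
extension to s = 1.27, and 15 outlets (4 supra-aortic, celiac trunk
splitting into hepatic/gastric/splenic, superior/inferior mesenteric, two
renals, and external/internal iliacs per side) at fixed take-off
coordinates. Trunk radii follow the tabulated stations exactly (knot-based
piecewise-linear profile); branch calibers and lengths are
literature-typical defaults. The combined iliac/aortic area ratio defaults
to ≈0.85, making the aortic bifurcation a net positive (closed-type)
reflector, as in humans. A legacy-VTK centerline file can override trunk
length and tortuosity.

Virtual aging, compounding geometrically per decade with fractional-decade
exponents (1+f)^(Δage/10):

* length: f = 3% ascending, 7% arch, 5% descending thoracic; abdominal
  aorta, iliacs and branches unchanged;
* radii: station radii move exactly onto the target-age table, the scale
  factor interpolated linearly in s between stations (constant outside);
  branch radii scale with the factor at their take-off;
* height: the straight root-to-bifurcation distance shrinks 1%/decade
  (configurable) at preserved arc length — in 1D this is tortuosity
  metadata only; its pressure cost is absorbed by the distal-resistance
  calibration, exactly as curvature losses are absorbed in the source
  workflow;
* thickness and stiffness: taken from the target-age table at assignment.

What the generator does *not* emulate: subject-specific cross-sectional
shape, 3D curvature and branch angles, aortic-root motion, and
inter-subject variability. Passing tests therefore validate the method's
internal physics and its response to prescribed regional changes — not
anatomical fidelity of any individual.

### Inflow

Only the mean (5.79 L/min) and heart rate (60 bpm) of the measured inflow
are available, so the generator uses a standard physiologic morphology: a
skewed systolic lobe (quarter-sine rise to peak at 30% of the 0.33 s
ejection, quarter-cosine fall), a 5%-of-stroke reverse lobe at valve
closure, zero diastolic flow. The peak (≈482 mL/s) follows from the mean
alone and is independent of the skew. The fast initial acceleration is
physiologically standard and essential for the measurement model: it gives
the pressure upstroke a sharp foot so foot-to-foot transit measures
propagation. The same waveform drives all ages (resting cardiac output is
nearly age-invariant).

### Outlet boundary conditions

Each outlet carries a three-element Windkessel from the bundled table
(proximal resistance and compliance age-invariant; distal resistance
tabulated per age — the parameter that rises with aging). The printed
compliance column is dimensionally garbled in its source; taken at face
value it implies a diastolic network time constant of ≈4.1 s, incompatible
with the classical human value (1.5–2.5 s) and with the source study's own
computed diastolic pressures. The printed values are therefore retained as
the relative distribution across outlets, rescaled by a single
age-invariant factor (0.38) such that R_total × (ΣC + distributed tree
compliance) = 2.0 s for the 40-yo model. The distal reference pressure is
0 (venous), configurable.

## 3. Numerics

* **Scheme.** Richtmyer two-step Lax–Wendroff (second order), target
  spacing dx = 7.5 mm, CFL 0.8 against c + 2 m/s. A halved dx changes root
  pulse pressure by < 1% (self-convergence test).
* **Boundaries.** Linearized characteristics with the characteristic foot
  interpolated a fraction ν = cΔt/dx into the boundary cell — information
  crosses junctions at the physical speed. Junctions impose a common
  static pressure and exact mass balance (static rather than total
  pressure: the ~½ρu² difference is sub-mmHg here and junction losses are
  absorbed by calibration). Outlets use a Crank–Nicolson capacitor update;
  a single-vessel run matches the exact 0D RCR response to < 1%.
* **Wall damping.** The support damping c_s enters as a Kelvin–Voigt
  Q-diffusion. Default 200 Pa·s/m per region: the smallest doubling-ladder
  value keeping pressure energy above 20 Hz below 1% of pulsatile energy
  at every probe (`choose_damping` implements the search); it perturbs
  foot speeds by < 2%.
* **Initialization and periodicity.** Pressures start at the MAP profile,
  flows at zero, capacitors at their 0D steady estimate; cycles are run
  (minimum 6, maximum 12) until the cycle-to-cycle pressure change at all
  probes falls below 50 Pa (≈0.4 mmHg). Probes retain the final two cycles
  so every station's upstroke lies inside a centered one-period analysis
  window.
* **Foot detection.** Intersecting-tangent: horizontal tangent at the
  diastolic minimum meets the tangent at the maximum systolic gradient;
  the gradient is 3-point smoothed and its maximum parabolic-refined to
  sub-sample resolution. Degenerate (flat) waveforms raise a specific
  error.

## 4. Calibration

1. **Windkessel:** all distal resistances are scaled by one common factor
   (preserving flow splits to < 1%) so the steady 0D prediction
   Q̄·R_total matches the age-specific target MAP within 1 mmHg.
2. **External support:** k_s is piecewise-constant over three aortic
   regions (ATA s < 0.25, DTA 0.25–0.66, IAA > 0.66; upper branches
   inherit ATA, lower branches IAA). The abdominal region is pinned to
   zero (its computed EP is ≈0). The search variable is the ATA value,
   with DTA at half of it (the published EP pattern puts the DTA between
   the ATA and the unsupported abdomen); PWV(k_s) is monotone, so a
   doubling bracket plus log-space secant/bisection converges in ≲10
   simulations to |PWV − target| < 0.2 m/s (tolerances: EP consistency
   0.5 mmHg, 20 iterations max — chosen as defaults, none are published).
3. **External pressure accounting.** The support is anchored to carry the
   tabulated station EP at the tabulated (in vivo, MAP) radius — the only
   anchor consistent with table mode, where the stiffness is valid exactly
   at that state. The computed EP at a station is then
   EP_anchor + k_s·(time-mean radius − reference radius); the
   self-consistency check verifies the converged simulation actually
   returns to the anchored state (it does, to ≲0.5 mmHg, because the
   Windkessel tuning pins the mean pressure). Under this convention
   k_s = 0 carries nothing, and a stiffer support pins the vessel to the
   anchored state rather than to its unloaded radius; the textbook rigid
   limit "EP → full mean pressure" corresponds to the alternative
   zero-transmural-pressure anchor, which constitutive mode approaches as
   EP is re-derived each iteration.
4. **Constitutive mode** re-linearizes the wall at TP = MAP − EP after
   each simulation through a callback, letting the anchor follow the
   computed EP until PWV and EP jointly converge.

## 5. Design choices that were genuinely open

* Aging compounding is geometric with fractional-decade exponents ("per
  10 years" statements compose self-consistently under composition).
* Pearson correlations use population normalization (identical to the
  sample convention for a correlation coefficient).
* Per-segment PWV is measured between the segment's end stations over the
  segment's centerline arc length; segment metrics (PP, D, ΔW, MAP) are
  evaluated at the segment's arc-length midpoint. A direct-distance PWV
  mode with the conventional 0.8 correction factor is provided.
* The carotid probe for carotid-to-iliac PWV sits at the middle of the
  (12 cm) common carotid segment.
* MAP is reported both as the time-averaged pressure (used for Windkessel
  tuning and the station summary) and via the clinical formula
  P_dia + PP/3 (which underestimates the time average by a few mmHg for
  the simulated waveform shapes).

## 6. Problem sizes

The standard study discretizes each age model into ≈240 nodes
(dx = 7.5 mm, 29 segments) and ≈3500 time steps per cardiac cycle; a
converged run costs a few seconds, a full per-age calibration ≈6–10 runs,
and the three-age study a few minutes on one CPU. These sizes are the
package defaults; halving dx or the CFL number reproduces the headline
metrics to within the tolerances quoted above.

## 7. Known limitations

* The 1D reduction cannot reproduce foot-shape effects of local 3D wave
  reflection at branch ostia or curvature. One documented consequence: at
  40 the per-segment PWV profile rises along the aorta essentially with
  the local characteristic speed, so its spatial correlation with
  stiffness stays high (r ≈ 0.94), whereas the 3D source study reports a
  near-flat profile (r ≈ 0.31) at that age. The decorrelation does emerge
  with age in this model (r ≈ 0.73 at 60, 0.41 at 75), and PP/D/ΔW
  correlations match throughout — the qualitative conclusion that PWV is
  the geometry-confounded outlier is reproduced, but the 40-yo magnitude
  of the effect is not attainable kinematically: with the tabulated
  stiffness profile fixed and k_s ≥ 0 only able to raise local speeds,
  every admissible support distribution leaves a rising speed profile.
* ΔW ignores cyclic axial lengthening, which matters in the ascending
  aorta; the value is computed and reported there with that caveat.
* Branch wall properties and baseline branch geometry are literature-
  typical defaults, not subject-specific data.
* No wave-intensity analysis, no aortic-root motion, no organ-contact
  modelling.
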