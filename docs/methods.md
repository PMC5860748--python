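# Methods

This note documents the physical model, the synthetic-data generator, the
numerical choices, and the limits of what the tests demonstrate.

## Physical model

The bundle is idealised as a homogeneous elastic rod of bending stiffness
κ (J·m), contour length L, and diameter d, moving transversely in a
Newtonian fluid of viscosity η at low Reynolds number. Force balance
between wormlike-chain bending elasticity and local (resistive-force)
drag gives

    ζ (y_t − u) = −κ y_xxxx,   ζ = 4πη / (ln(L/d) + 0.84),

where ζ is the perpendicular slender-body drag per unit length. The drag
formula is the standard low-Reynolds cylinder result; it depends on
geometry only through ln(L/d), so modest uncertainty in the
(sub-resolution) diameter perturbs ζ weakly. It is isolated in
`drag_coefficient` and can be swapped without touching anything else.
The background flow u is zero by default: in the emulated experiment the
trap moves the bead, not the fluid.

Sinusoidal driving at angular frequency ω = 2πf selects the hydrodynamic
length l_ω = (κ/ζω)^(1/4). Nondimensionalising x by l_ω and inserting
exp(ikη − iωt) yields k⁴ = i; the first-quadrant root k = C̃ + iS̃ =
exp(iπ/8) ≈ 0.9239 + 0.3827i. The end-driven steady state is the
superposition of an outgoing wave (decay constant S̃) and its reflection
by the medium (decay constant C̃); the middle-driven solution carries the
extra (cos + sin) factors and mirror symmetry about the drive point. All
formulas use ω internally; user-facing metadata records Hz.

Internally the complex amplitude representation y = Re[Z(η) e^(−iωt)]
with Z(η) = ½[e^((iC̃−S̃)η) + e^((−iS̃−C̃)η)] is used for fitting, since
the band-pass returns exactly this Z.

## Finite-difference solver

`solve_pde` integrates the fourth-order equation with Crank–Nicolson in
time and the second-order five-point stencil for y_xxxx, via a sparse LU
factorisation of the constant-coefficient system (the scheme is
unconditionally stable; preconditions only enforce resolution: ≥ 10
nodes per l_ω, ≥ 20 steps per period; defaults are 15 nodes per l_ω and
200 steps per period). Boundary conditions: prescribed displacement plus
zero curvature at the driven node (a torque-free drive — the analytic
solution satisfies y_ηη(0) = 0 identically), mirror symmetry (zero
slope) instead for middle drive, and a force- and torque-free far end
(y_xx = y_xxx = 0), since the distal end of the bundle is unconstrained.
The rod starts from rest with a half-cosine amplitude ramp over the
first period to suppress the start-up transient; one transient period is
discarded before steady-state comparisons.

Verification against the closed form at L = 8 l_ω gives 0.998% relative
L2 — the floor is physical, not numerical: the closed form assumes a
semi-infinite rod, and the free-end reflection of the finite rod
contributes most of the residual (0.24% at L = 16 l_ω, grid-converged).

## Synthetic recordings

The generator emulates CCD fluorescence recordings of a
rhodamine-labelled bundle with a 2 µm bead at the drive point. Default
conditions, chosen once as representative of this class of experiment:

| parameter | default | rationale |
|---|---|---|
| κ | 5.5×10⁻²⁴ J·m | persistence length ≈ 1.3 mm: tens of weakly coupled actin filaments |
| L, d | 20 µm, 60 nm | bundle spanning ~80% of the field of view; sub-resolution thickness |
| η | 50 mPa·s | methylcellulose-crowded buffer |
| drive | y₀ = 1 µm, 0.04–2.5 Hz | standard amplitude; sweep range set by camera exposure (fast end) and photobleaching (slow end) |
| camera | 100 nm px, PSF σ 150 nm, 50 ms min exposure | typical 100× epifluorescence |
| photometry | peak 200 photons/px, background 20, read σ 3, bleach 0.005 s⁻¹ | SNR ≈ 13, minutes-scale usable recording |

With these values l_ω spans 1.4–3.9 µm across the sweep, satisfying the
≥ 6 l_ω field-of-view precondition that `render_stack` enforces. Frame
timing mimics the camera: fast drives are limited by the 50 ms exposure
(8 frames/period at 2.5 Hz), slow drives are sub-sampled to ≤ 32
frames/period; the interval always divides the period exactly so Fourier
windows stay commensurate.

Each frame integrates the analytic contour over the exposure by ≥ 8
sub-samples (motion blur is real at the fast end: 50 ms is an eighth of
the 2.5 Hz period), convolves transversely with the Gaussian PSF, draws
the bead as a bright disk, bleaches the signal (not the background)
exponentially, then applies Poisson shot noise and Gaussian read noise
from a mandatory seed. Because both waves of the solution oscillate at
ω, exposure averaging scales the deflection by a constant sinc factor
without distorting its spatial shape — so the stored ground truth is the
exposure-averaged contour, which is what is actually in the image; the
blur is absorbed into the fitted amplitude and cannot bias l_ω. Bundle
thickness enters only via brightness and drag, never as resolvable
width.

What the generator does *not* emulate: thermal contour undulations
(the band-pass removes their in-band remnant in real data, but the
synthetic noise is purely photometric), bead rotation or trap
compliance (the bead is a kinematic boundary condition), diameter
variation along the bundle, defects/kinks, bundle merging dynamics, and
camera nonlinearities. Passing tests therefore demonstrate correctness
of the measurement chain, not robustness against every real-data
pathology.

## Contour tracking

Preprocessing rotates the deflection direction onto the image y-axis
(angle supplied or estimated from the column-centroid line of the first
frame, bead vicinity masked) and optionally crops to the anticipated
amplitude band; a band that would cut the contour is an error, not a
silent truncation. Filtering smooths mildly along x (Gaussian, σ = 1 px)
and emphasises horizontal lines along y by subtracting the
second-derivative-of-Gaussian response (σ = 1 px, weight 1) — the goal
(ridge emphasis) is fixed, the kernel is configurable.

Per column the intensity peak is refined by a least-squares parabola
over a 5 px window. The parabola is fitted to the *logarithm* of the
background-subtracted profile: for a Gaussian line profile the
log-profile is exactly parabolic, which removes the pull-toward-integer
bias (up to 0.08 px on a σ = 1.5 px line) that a plain-intensity
parabola shows; measured bias of the default is < 0.01 px, and
`log_profile=False` restores the plain variant. Columns without a peak
above max(5 counts, 4 robust noise SDs) are flagged invalid rather than
fabricated. Peak ambiguity is resolved by temporal continuity: the
search window (±10 px) follows the previous frame's position, the first
frame uses the global maximum. Columns within 2 bead radii of the drive
are excluded; frames with > 50% failed columns are flagged. Coordinates
are 0-based pixel indices reported at pixel centres, x increasing away
from the drive.

Measured accuracy on default synthetics: 0.02 px RMS noiseless,
0.05–0.08 px at default SNR, no detectable systematic bias.

## Band-pass and decay fit

The "band pass" is a discrete Fourier projection at exactly the drive
frequency over a whole number of periods, with the first and last
periods excluded (transients and edge effects); for a known drive
frequency this is a zero-ripple band-pass and is exact on noiseless
sinusoids. Columns with > 10% tracking gaps are dropped, smaller gaps
interpolated linearly in time.

The decay fit minimises residuals of the complex amplitude profile
(default) or its envelope (fallback), with free parameters l_ω,
amplitude y₀, an x-origin offset (the effective drive point is hidden
behind the bead exclusion; it can be pinned), and a global phase.
Complex-mode fitting uses the phase information that the two-wave
interference imprints near the drive. Parameters are nondimensionalised
(lengths in units of the initial decay-length estimate, amplitude in
units of the peak) so the trust-region optimiser treats length-, 
amplitude- and phase-like unknowns on equal footing; the initial l_ω
comes from a log-linear fit of the envelope mid-range using the
asymptotic decay constant S̃. Fits spanning < 2 fitted decay lengths are
flagged non-identifiable; < 8 valid columns is an error. Uncertainties
come from the Jacobian at the optimum.

## Sweep analysis and classification

κ_eff = l_ω⁴ω is recomputed per frequency (the identity is enforced to
1e-12 in `SweepResult`); κ = ζκ_eff is added when rod geometry and
viscosity are known. Exponents come from OLS in log10-log10 space; by
linearity of OLS the κ-vs-ω exponent equals 4×(l_ω-vs-ω exponent) + 1
exactly, which the tests assert.

Classification needs an explicit rule where eyeballing a log-log plot
would be used at the bench: |exponent + 1/4| ≤ 0.05 + 2 SE →
wormlike chain; otherwise a κ_eff-vs-l_ω exponent within 0.2 + 2 SE of
+2 earns the shear-coupled-bundle label, else free power law. Fewer
than 3 frequencies is "indeterminate"; fewer than 4 frequencies or less
than a decade of span triggers a low-power warning, never a silent
default. Note that for a measured sweep the three thick-bundle scalings
(κ_eff ∝ ω^(−1/2), κ_eff ∝ l_ω², and the identity κ_eff = l_ω⁴ω) cannot
hold simultaneously; the classifier keys on the κ_eff-vs-l_ω exponent,
and the synthetic bundle-like generator uses κ(ω) ∝ ω^(−1) so that this
exponent is 2. The long-recording stability check fits l_ω in sliding
windows and reports the linear drift slope with its standard error.

## Problem sizes and defaults in tests

The test suite and examples use 128×256 px stacks, 5–7 periods per
recording, 5–8 frequencies per sweep, and 20 replicate sweeps for the
classification-rate check — sizes at which every statistical margin in
the assertions is comfortably resolved while a full run of the suite
stays in the minutes range. Seeds are fixed throughout; rendering is
bitwise reproducible for a given seed.

## Known limitations

- The analytic profile assumes a semi-infinite rod; for rods shorter
  than ~8 l_ω the free-end reflection biases the fit (the solver can
  quantify this case-by-case).
- Local drag only: no hydrodynamic self-interaction or wall effects.
- One roughly x-aligned contour per stack; no crossing-filament
  segmentation (non-orthogonal bundles are out of scope, as in the
  emulated assay).
- Single drive frequency per recording; no broadband excitation.
- No passive (thermal-fluctuation) stiffness estimation and no
  microscopic bundle mechanics (crosslinker shear fields, inter-filament
  friction); bundle coupling appears only as phenomenological scaling.
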