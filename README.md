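# bundlerheo

Active microrheology of individual semiflexible filament bundles — e.g.
actin bundles held by depletion forces — from driven-oscillation
recordings.

Bulk rheology needs isotropic networks, and passive fluctuation analysis
of a single bundle gives only a static bending stiffness. This package
implements the *active* alternative: a bead attached to one end of the
bundle is wiggled sinusoidally by an optical trap, the bending wave it
launches decays along the contour under viscous drag, and the decay
length directly encodes the bending stiffness *at that drive frequency*.
Sweeping the frequency yields a rheological spectrum of a single,
strongly anisotropic structure, and distinguishes a wormlike chain
(one frequency-independent stiffness) from coupled-bundle mechanics
(stiffness growing with the probed length scale).

## Model

A weakly bending rod at low Reynolds number obeys the overdamped beam
equation

    ζ (∂y/∂t − u) = −κ ∂⁴y/∂x⁴

with bending stiffness κ (J·m), transverse slender-body drag per unit
length ζ = 4πη/(ln(L/d) + 0.84) (Pa·s), and background flow u (0 in a
quiescent sample). Driving one end at angular frequency ω introduces the
single length scale of the problem, the **hydrodynamic length**

    l_ω = (κ / (ζ ω))^(1/4),

over which the oscillation amplitude decays. With η = x/l_ω, the
steady end-driven solution is the two-wave form

    y(η,t) = y₀/2 [ e^(−S̃η) cos(C̃η − ωt) + e^(−C̃η) cos(S̃η + ωt) ],

where C̃ + iS̃ ≈ 0.92 + 0.38i is the first-quadrant root of the
dispersion relation k⁴ = i. Fitting this profile to the measured
per-position oscillation amplitude gives l_ω, hence the drag-normalised
effective stiffness

    κ_eff = κ/ζ = l_ω⁴ · ω   (m⁴/s),

and κ in J·m when ζ is known. Across a sweep, l_ω ∝ ω^(−1/4) (flat
κ_eff) is the wormlike-chain signature; κ_eff ∝ l_ω² is the signature of
a shear-coupled bundle whose mode stiffness scales as κ_n ∝ q_n^(−2).

## What's in the box

- `core` — closed-form solutions, dispersion constants, drag, and a
  Crank–Nicolson finite-difference solver for the full driven PDE.
- `imaging` — a synthetic fluorescence microscope: truth-annotated
  16-bit TIFF stacks of a driven bundle with attached bead, exposure
  motion blur, photobleaching, Poisson + read noise. TIFF + JSON
  sidecar + truth CSV round trips.
- `tracking` — rotation/crop preprocessing, line-enhancing filters, and
  subpixel parabola-vertex contour tracking into a kymograph y(x,t).
- `oscillation` — drive-frequency Fourier projection (band-pass) and the
  complex-amplitude decay fit for l_ω.
- `sweep` — κ_eff spectra, log-log power-law fits, WLC/WLB regime
  classification, long-recording stability (drift) checks.
- `cli` — `bundlerheo simulate | track | analyze | sweep | selftest`,
  a thin shell pipeline over the library with human-readable
  intermediates.

## Worked example

`python examples/03_single_recording.py` renders a 7-period recording at
0.7 Hz of the default bundle (κ = 5.5×10⁻²⁴ J·m, 20 µm contour, 50 mPa·s
medium, 1 µm drive amplitude, 200-photon peak signal) and analyses it:

```
rendered 203 frames of 128x256 px (7 periods at 0.7 Hz)
tracking error vs ground truth  : 0.053 px RMS
columns used after band-pass    : 181 (bead vicinity excluded, first/last periods dropped)

hydrodynamic length  fitted     : 1.908 um (+/- 0.001)
hydrodynamic length  true       : 1.907 um
drive amplitude      fitted     : 1.004 um (set: 1.000)
effective stiffness  kappa_eff  : 5.835e-23 m^4/s (true kappa/zeta = 5.820e-23)
  kappa = 5.514e-24 J*m (set: 5.500e-24)
```

The fitted decay length matches the ground truth to 0.1%, and the
recovered stiffness to ~0.3% — the imaging, tracking, band-pass and
fitting chain is quantitatively closed. `examples/04_frequency_sweep.py`
runs the same pipeline across 0.04–2.5 Hz and prints the recovered
l_ω-vs-ω exponent (−0.249 for a constant-κ bundle) plus the regime
classification for a wormlike chain and for a thickened, shear-coupled
bundle.

The equivalent shell pipeline:

```bash
bundlerheo simulate --out run/ --frequency 0.7 --seed 42
bundlerheo track    --stack run/stack --out run/kymo.csv
bundlerheo analyze  --kymograph run/kymo.csv --drive-hz 0.7 --out run/result
```

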