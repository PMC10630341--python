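# Methods

## The imaging model

`lenspol` models a lens-less polarization-sensitive microscope: a
programmable LED array (9×9 elements, 4 mm pitch, ~400 mm from the object)
sequentially illuminates a thin, transparent, optically anisotropic
specimen with circularly polarized quasi-monochromatic light
(λ = 514.5 nm).  The transmitted light is intensity-modulated by a random
binary amplitude mask (50% open, 27.6 µm feature = 8 sensor pixels) and
recorded by a division-of-focal-plane (DoFP) polarization camera
(3.45 µm pixels, 2048×2448) whose 2×2 micro-polarizer mosaic samples
analyzer angles ψ ∈ {0°, 45°, 90°, 135°}.

A thin birefringent specimen is described per pixel by its retardance
δ(x, y) and optic-axis orientation θ(x, y) through the unitary Jones matrix

    J_s = R(θ) · diag(e^{iδ/2}, e^{−iδ/2}) · R(−θ),

diattenuation being neglected for thin samples.  With circular input
E_in = √(I/2)·(1, i)ᵀ and an ideal analyzer at ψ, the four channel
intensities are

    (I_0, I_45, I_90, I_135) = I/2 · (1 − sinδ sin2θ, 1 + sinδ cos2θ,
                                      1 + sinδ sin2θ, 1 − sinδ cos2θ).

Two normalized differences invert this closed form:

    Q1 = (I_90 − I_0)/(I_90 + I_0)     = sinδ sin2θ
    Q2 = (I_45 − I_135)/(I_45 + I_135) = sinδ cos2θ
    δ  = asin √(Q1² + Q2²),   θ = ½·atan2(Q1, Q2).

Note that with the intensity model above the Q2 difference must be taken
as (I_45 − I_135); the opposite ordering, which sometimes appears in the
polarimetry literature, flips its sign and breaks the round trip.  The
package uses the algebraically consistent form throughout, so the
forward model → Q maps → (δ, θ) chain is exact to machine precision
(verified on a 100×100 parameter grid).

Conventions and numerical choices:

* δ inversion is restricted to [0, π/2] (the sinδ ambiguity cannot be
  resolved from a single wavelength); Q1² + Q2² > 1 (possible under
  noise) is clipped to π/2 and flagged, never wrapped.
* θ is reported in [0°, 180°); the two-argument arctangent avoids
  quadrant loss.  Pixels with Q1 = Q2 = 0 have undefined orientation and
  are flagged.
* Channel-sum denominators are guarded at 1e−12 and flagged, not zeroed.
* Input handedness is fixed to E_in ∝ (1, i); the opposite handedness
  flips the sign of both Q maps (θ → −θ) and is available as a flag.

## Propagation and geometry

Free-space propagation uses the band-limited angular-spectrum method
(evanescent cutoff plus the local-frequency band limit of the sampled
transfer phase).  The standalone operator zero-pads by a factor 2 by
default to suppress periodic wrap-around; the simulator and the
reconstruction engine run unpadded on 128–512 px grids because at a
3.45 µm pitch and mm-scale gaps the diffraction spread is tens of pixels,
far below the wrap-around scale — and because simulator and engine then
share the exact same operator, making the inverse problem self-consistent.
At this pitch every representable spatial frequency propagates, so the
periodic operator is exactly unitary; the fixed-point and round-trip
tests exploit this.

Each LED is modelled as a tilted plane wave (direction cosines from its
4 mm-pitch offset at 400 mm standoff); across the few-mm field of view
the sphericity of the wavefront is negligible compared with the tilt.
The maximum on-axis tilt is atan(16/400) = 2.29°, the corner tilt 3.24°.
The object–mask and mask–sensor gaps are not hardware-calibrated
quantities; they default to 1.0 mm and 1.5 mm and are configurable.

Coordinates: origin at the grid center, x right (columns), y down (rows);
all modules share this convention.

## Synthetic scenes

* `random_binary_mask` — block-random {0, 1} mask, feature size an integer
  number of pixels, open fraction enforced exactly at the block level by a
  seeded permutation (default 50%, matching a unity transparent-to-blocking
  area ratio).
* `siemens_star` — alternating birefringent sectors (default δ = π/4) with
  the optic axis along each sector's bisector azimuth (mod π); a small
  isotropic core disc keeps the n_sectors/2 wedges disjoint.
* `needle_crystal` — a rotated rectangle with δ = δ₀ and θ along the
  needle axis, emulating a monosodium-urate-like crystal whose fast axis
  lies along the needle (default δ₀ = 0.272 rad, the value recovered for a
  0.236 µm MSU crystal; the physical slab formula δ = 2πΔn·d/λ with
  Δn = 0.1 gives 0.288 rad).
* `usaf_like_target` — binary three-bar amplitude groups (bar width w ⇒
  spectral peak at 1/(2w)), the isotropic resolution/demosaicing target.

Targets are generated at the grid pitch with hard edges (no sub-pixel
anti-aliasing).  What the generators do *not* emulate: partial spatial and
temporal coherence of real LEDs, sensor angular response, pixel-aperture
integration, mask fabrication errors, and LED intensity/position
miscalibration.  Passing the end-to-end tests therefore demonstrates the
correctness and self-consistency of the algorithm chain, not robustness
to every experimental nonideality.

## Forward simulation

Per LED and per analyzer angle: the analyzed scalar exit wave (Jones
projection of the tilted circular input) propagates to the mask, is
multiplied by the binary pattern, propagates to the sensor, and its
squared modulus is sampled through the mosaic (default layout
[[90°, 45°], [135°, 0°]], a common commercial arrangement; configurable).
Because propagation is component-wise linear and the analyzer is a fixed
projector, analyzing at the object plane is exactly equivalent to
propagating the Jones vector and analyzing at the sensor; the scalar form
is used (and the equivalence is tested).  Optional noise: Poisson shot
noise at a configurable photon scale plus Gaussian read noise, clipped at
zero, seeded.

## Demosaicing

`demosaic_bilinear` interpolates each channel independently from its own
sparse parity (normalized 3×3 tent convolution; measured sites preserved;
linear surfaces exact).

`demosaic_newton_polynomial` is a two-stage difference-domain scheme.
Stage 1 interpolates every channel to the full grid with directional
stride-2 four-point cubic (Newton-polynomial) stencils — horizontal,
vertical, and two diagonal stencils fused by inverse-gradient weights.
Stage 2 exploits the strong inter-channel correlation of DoFP data: the
estimate at a missing site is the *co-located raw measurement* plus a
smoothed interpolation (Gaussian σ = 2 px, normalized over the sparse
sampling) of the channel-difference samples (target channel minus the
stage-1 estimate of the guide channel at the target's own sites).  The
full-resolution structure common to all four channels — here dominated by
the mask-diffraction pattern — is thus taken from the raw frame and never
interpolated; residual errors scale with the small, slowly varying
polarization contrast.  Polynomial surfaces up to total degree three are
reproduced exactly; outputs are clipped to the raw frame's range; borders
use parity-preserving reflection.  Other published DoFP methods (PCDP,
ICPC, EARI) can be plugged in through the same frame-in/four-grids-out
interface but are not implemented.

## Phase retrieval

`reconstruct_channel` is an ePIE-style sequential projection solver with
the *known* binary mask as the modulator.  Per LED: multiply the object
estimate by the LED's tilt ramp, propagate to the mask, modulate,
propagate to the sensor, replace the modeled amplitude with the measured
one, propagate the correction back, update the field before the mask
(step size 1.0 by default), and back-propagate to update the object.
LED order is fixed row-major for bit-reproducibility (a seeded shuffle is
optional); stopping is a fixed epoch count (default 50), not a tolerance.
Optional ePIE refinement of the modulator exists but is off by default —
the mask is known by design.  An `upsample` factor reconstructs on a finer
grid with the amplitude constraint applied after intensity binning to
sensor pixels (default 1).

**Weighting of interpolated samples.**  A DoFP sensor measures each
channel at only one pixel parity; the other 75% of each demosaiced frame
is an estimate.  Early experiments showed that enforcing interpolated
values at full strength biases the recovery: the interpolation low-passes
the channel-difference structure carried on the mask speckle, and since
that bias is common to all frames the LED averaging cannot remove it
(orientation errors of 10–20° on weakly retarding objects).  The engine
therefore applies the amplitude constraint with weight 1 at each
channel's truly measured parity and a reduced weight (`interp_weight`,
default 0.1) at interpolated sites.  The measured quarter of every frame
(81 frames ≈ 20 true measurements per object pixel per channel) anchors
the solution, while the demosaiced estimates still guide convergence — so
demosaicing quality measurably affects reconstruction fidelity, as the
method comparison shows.  Full-resolution (non-mosaicked) data is always
fully weighted.

On noise-free, model-consistent data the residual falls by many orders of
magnitude within 50 epochs and the recovered maps match the generator to
machine precision; the recovered object carries an arbitrary global phase
per channel (gauge).

## Pipeline

`run_pipeline`: split + demosaic each raw frame → four per-channel
measurement stacks → four reconstructions → channel intensities |O_ψ|² at
the object plane → Q maps → (δ, θ) maps, as in the reconstruct-then-invert
ordering of the imaging chain.  The per-channel global phase gauge is
fixed by subtracting the circular mean phase over the image border
(outer 5% by default, assumed background) before the four phase maps are
averaged into the mean-phase map.  Rendering encodes θ as hue (cyclic
over 180°) and δ as brightness (full at π/2); orientation overlays show
the δ-weighted circular mean orientation per non-overlapping window
(70 µm default), suppressed where mean δ ≤ 0.05 rad.

## Uncertainty

First-order propagation of independent fluctuations ΔQ1, ΔQ2 through the
inversion gives

    var(θ) ≈ ⟨ΔQ²⟩ / (8 Q0²),    var(δ) ≈ ⟨ΔQ²⟩ / (2 (1 − Q0²)),

with Q0² = Q1² + Q2² and ⟨ΔQ²⟩ = ΔQ1² + ΔQ2².  The formulas diverge at
Q0 → 0 (orientation undefined) and Q0 → 1 (δ → π/2); these poles are
flagged as infinite variance.  A Monte-Carlo harness (draw noisy Q maps,
re-invert, take sample variances; the orientation variance is computed on
π-periodic deviations) agrees with the formulas to well within 15% for
noise sd ≤ 0.02 and δ₀ ∈ [0.3, 1.2] at n = 10⁵ trials.

## Benchmark scenarios and problem sizes

The standard evaluation scenarios (module `lenspol.benchmarks`, also run
by `scripts/acceptance.py`) use reduced grids chosen so that the scoring
statistics are stable: the Siemens-star recovery runs at 256² with the
full 9×9 LED array and 50 epochs; the eight-angle needle rotation series
and the demosaicing comparison run at 128² (20 and 30 epochs — orientation
medians and the SSIM ranking are converged well before that).  FoV/SBP
accounting rounds the sensor side lengths to 0.01 mm before multiplying
(7.07 mm × 8.45 mm = 59.74 mm²) and reports the SBP to two significant
figures (9.9 MP at a 2.46 µm half-pitch).

## Known limitations

* Single-wavelength inversion limits δ to [0, π/2]; strongly retarding
  samples alias.
* The plane-wave LED model ignores wavefront sphericity and finite LED
  extent; no self-calibration of LED angles or intensities.
* The thin-specimen Jones model excludes diattenuation, scattering and
  multi-layer (tomographic) structure.
* Real-sensor effects (pixel aperture, angular response, fixed-pattern
  noise) are not modelled.
* The quantitative recovery bands quoted above are for the noise-free,
  model-consistent simulation conditions of the benchmark scenarios.
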