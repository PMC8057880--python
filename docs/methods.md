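# Methods

This note records the models, parameter defaults and numerical choices
behind `eics-mri`, and what the synthetic experiments do and do not show.

## Sampling geometry

A radial trajectory is a set of full-diameter spokes through the k-space
origin.  Angles are reduced modulo 180° (a diameter at θ and θ+180° is the
same line); each spoke carries `n_readout = N` samples on the grid
`(−N/2 … N/2−1)/N` cycles/pixel, which includes the exact DC point for even
N.  Azimuthal Nyquist for an N×N image needs `round(π/2·N)` uniform spokes
(402 at N = 256), and the spoke budget for a sampling ratio r is
`round(r · nyquist)`, rounding half away from zero (the printed budgets
12/20/28/36 at 3/5/7/9% never fall on a half).

Mask triples are built by generating one schedule of 3n angles (uniform
spacing 180/3n, or golden-angle increments 180°/φ ≈ 111.246°) and assigning
angle *i* to mask *i* mod 3.  Round-robin assignment keeps the three angle
sets disjoint while each mask inherits the schedule's angular statistics;
for golden angles this preserves per-mask temporal incoherence.  Whether a
clinical sequence would share one angular offset across the triple is not
determined by the sampling theory; the offset is a parameter with default 0.

**Density compensation.**  The DCF is the polar area element (Ram-Lak
ramp): `w = π·N·|k|/n_spokes`, with the DC sample — shared by every
full-diameter spoke — assigned a quarter of the first nonzero-|k| weight,
the area of the central disc of radius half a radial step.  Correctness is
asserted behaviorally: the spectrum of the density-compensated point-spread
function is flat over the sampled disc to < 5% at Nyquist.  Note that full-
diameter spokes never sample |k| > 0.5: the spectral corners of the
Cartesian grid are unobservable, the PSF is an Airy pattern with an ~18%
shoulder on the pixel adjacent to its peak, and any reconstruction is
band-limited to the inscribed disc.  Tests of "perfect" recovery therefore
use band-limited (Gaussian-smoothed) targets; sharp-edged targets retain an
irreducible Gibbs mismatch (≈ 8% ℓ2 at N = 32, SSIM ceiling ≈ 0.87).

## NUFFT

Forward (type-2) evaluation is oversampled-FFT gridding: deapodize, zero-pad
to a 2N grid, centered FFT, then sparse Kaiser-Bessel interpolation (width
4) at the sample locations; the adjoint applies the exact conjugate
transposes in reverse, so the operator pair satisfies the inner-product
identity to machine precision.  The kernel shape parameter is 1.03× the
Beatty closed form: the published constant minimizes worst-case aliasing,
while the slightly larger value — found by a one-time numerical sweep, the
way fast-NUFFT libraries tune their kernel constants — balances
smooth-image against broadband error and holds both near 7×10⁻⁴ relative ℓ2
versus the direct nonuniform DFT (tolerance 10⁻³ in tests).  Deapodization
uses the kernel's closed-form continuous Fourier transform.  Normalization
is `s(k) = (1/N) Σ_n x[n] exp(−2πi k·(n − N/2))`.

## Sample sets and interpolation

Set algebra needs a notion of location equality across masks, which the
continuous coordinates do not provide.  Sample keys are the coordinates
quantized to 10⁻⁶ cycles/pixel, applied identically at every creation site;
with full-diameter spokes the only cross-mask collision is DC, which every
spoke contains, so an acquired slice stores `n_spokes·(n_readout−1)+1`
unique locations.  The interpolation `T_int = (L⊖T) ⊕ T ⊕ (R⊖T)` copies
values verbatim (no averaging); the three union parts are disjoint by
construction (⊖T removes the shared DC), giving the exact count identity
`|T_int| = |T| + |L⊖T| + |R⊖T|` and a target-slice share of just over one
third (33.4% for 12 spokes at N = 128; the remaining two thirds split
evenly between L and R).  In degenerate direct calls where parts do
collide, the earlier-listed part wins (target first) and a warning is
logged.  Stack boundaries have one neighbor; they degrade to the
two-slice rule with that neighbor, which is logged per run.  Interslice
gaps decimate the source stack first (keep every (gap+1)-th slice) and then
treat the result as contiguous; the stack-level effective sampling ratio
falls from r to r/(gap+1).

## Reconstruction

Per slice, Fletcher–Reeves nonlinear conjugate gradient minimizes

    ‖W^{1/2}(F_u x − y)‖₂² + λ₁‖Ψx‖₁ + λ₂ TV(x)

* **Data term.**  W is the trajectory's DCF; the undersampling operator
  carries its density compensation, which preconditions the radial normal
  operator (the heavily oversampled k-space center otherwise pushes its
  condition number so high that unweighted NCG stalls at ~8% error on a
  consistent Nyquist system).  `weighted_data=False` restores the plain
  residual.  For interpolated slices the operator is built on the combined
  sample set with an effective-diameter-count ramp DCF.
* **Regularizers.**  Ψ is Daubechies-4 with 4 periodized decomposition
  levels (orthogonal: Parseval holds to 10⁻⁸), TV is isotropic with forward
  differences and zero last-row/column.  Both nonsmooth terms are smoothed
  as √(|c|² + μ) with μ = 10⁻¹⁵ inside gradients and line searches; reported
  objective terms are unsmoothed.  λ₁ = λ₂ = 0.002·max|adjoint_dcf(y)| by
  default, scaling regularization with image intensity; the weights are
  freely configurable.
* **Iterations.**  Default 60 (30 in the scaled-down comparison
  experiments); Armijo backtracking (α = 0.01, β = 0.6) starts from the
  data-term-optimal step, which reduces to exact line search — hence plain
  CG — in the least-squares limit; restart on non-descent or every 50
  iterations.  The smoothed objective is nonincreasing along the accepted
  trace; a non-finite objective raises a solver error carrying the trace.
  The gradient matches central finite differences to 10⁻⁴ on random complex
  16×16 inputs.

## Quality metrics

Full-reference metrics consume magnitudes normalized by the ground-truth
maximum; no-reference metrics rescale internally.  SSIM is the standard
sliding Gaussian-window mean (11×11, σ = 1.5, k₁ = 0.01, k₂ = 0.03) via
scikit-image, with a literal single-window "global" mode for closed-form
unit tests.  FSIM is implemented from its published algorithm: phase
congruency from a single-sided log-Gabor bank (4 scales, 4 orientations,
minimum wavelength 6, σ_onf 0.55) with a Rayleigh-based noise threshold,
Scharr gradient magnitude, similarity constants T₁ = 0.85 and T₂ = 160 on a
0–255 scale, pooled by the pointwise-max PC map.  The sharpness index
compares TV(x) with the TV distribution over random-phase resamples of x
(Fourier modulus kept, Hermitian phases randomized; 100 seeded resamples):
SI = −log₁₀ Φ̄((μ_TV − TV)/σ_TV), evaluated in log space so very sharp
images score in the hundreds; a printed-literal variant −log₁₀ z is
available under `mode="literal"`.  Monte-Carlo resampling was chosen over
the closed-form TV-moment approximation because it is simpler, seedable and
directly testable.  PIQE scores 16×16 blocks of the MSCN image (7×7
Gaussian window, stabilizer 1): blocks with variance ≥ 0.1 are spatially
active; active blocks are flagged for edge artifacts (any 6-pixel edge
segment with std < 0.1) or noise (center/block deviation ratio within 0.35
of 1 — a simplified homogeneity test standing in for the original
center-surround criterion); distortions are scaled to 0–100 and pooled as
(ΣD + 1)/(N_SA + 1), so a flat image (no active blocks) scores exactly 1
and the score cannot exceed 100.

## Synthetic phantom

Slice 0 superposes a large head ellipse and 7 random interior ellipses with
signed intensities; each subsequent slice perturbs every ellipse's center
and axes by Gaussian steps of std `drift·N` (orientation by 2·drift rad) —
a random walk, so pixelwise interslice correlation decays with slice
distance, which is what makes the interslice-gap experiment meaningful.
Defaults: 24 slices, N = 128, drift = 0.004, noise σ = 0.01, 8 ellipses — a
desk-scale stand-in for a 320×320×256 clinical knee stack.  The phantom has
piecewise-constant anatomy (ideal for TV), no coil sensitivities, no
relaxation contrast and image-domain (not k-space) noise; passing tests
show the geometry/algebra/solver chain works and that relative method
orderings hold under realistic interslice correlation, not that clinical
image quality is reproduced.

## Experiment scale

The comparison experiments run cs/fics/eics at 3% golden-angle sampling of
the default phantom with 30 NCG iterations per slice (~10 s per method on
one core); the ordering check uses 5 phantom seeds and requires the
eics ≥ fics ≥ cs ordering (orientation-corrected per metric) in at least 4.
These sizes are the package's defaults for desk-scale reproduction; all are
configurable upward.

## Known limitations

* Single-channel magnitude data only; no parallel imaging, coil maps or
  complex-valued ground truth.
* 2-D slices; no 3-D or dynamic trajectories.
* The interpolation copies neighbor samples verbatim; no weighting by slice
  distance or data consistency.
* FSIM and PIQE are independent reimplementations from the published
  algorithm descriptions; absolute values can differ from the original
  MATLAB scores (PIQE in particular returns 1, not 100, on a flat image by
  the empty-sum convention adopted here), while relative orderings are
  preserved.
* The sharpness index of streaky undersampled reconstructions can exceed
  that of clean images; SI is reported but not used in ordering assertions.
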