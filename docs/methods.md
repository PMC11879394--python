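# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the built-in simulation study does and does
not demonstrate.

## Image formation model

A multifocal scan frame is modelled as

```
I_i(r) = h_det ⊗ ( P_i(r) · O(r) ) + B(r) + noise
```

where `O` is the object, `P_i` the illumination pattern of frame `i`
(pinhole disks at the scan positions convolved with the excitation PSF,
peak-normalized with one global constant so the model is linear across
frames), `h_det` the detection PSF, and `B` a frame-independent additive
plane standing in for out-of-focus light. Convolutions are zero-padded
FFT convolutions ('same' mode); kernels are odd-sized so that correlation
with the flipped kernel is the exact adjoint, which the deconvolution
solvers rely on (dot-test exact to machine precision).

**PSFs.** Both paths use an isotropic Gaussian approximation with lateral
`FWHM = 0.51 λ/NA` and axial `FWHM_z = 1.77 n λ/NA²` (n = 1.515). This is
the standard Gaussian stand-in for the diffraction-limited PSF: it is
analytically checkable (Gaussian product and convolution identities anchor
the √2 reassignment result) and adequate for resolution metrology at the
few-percent level. Vectorial, aberrated or depth-varying PSFs are out of
scope, and the simulator makes no attempt to reproduce instrument-specific
blur (a real instrument's measured widefield resolution is generally worse
than `0.51 λ/NA`).

**Units and coordinates.** Everything works in sample-plane nanometres;
fast scan axis = +x = image columns, slow axis = +y = rows, origin at the
field centre, pixel centres at integer indices. One Airy unit (AU) is
`1.22 λ_em/NA`. The default pinhole magnification maps a 40 µm physical
pinhole to 0.5 AU at the sample.

## Study conditions (simulator defaults)

The generator's defaults reproduce the method's operating point: 640/680 nm
excitation/emission, NA 1.49, 32.5 nm object grid, 0.5 AU pinhole diameter
at a 1:3 diameter:pitch ratio (pitch 1.5 AU), 0.25 AU scan step, and tilted
1-D scans of 49 frames (tilt `arctan(1/7) = 8.13°`) or 25 frames
(`arctan(1/5) = 11.31°`; the reported operating tilt of 11.1° agrees to
within the rounding of the lattice convention). Reducing 49 → 25 frames at
fixed slow-axis sampling enlarges the step by `√50/√26 ≈ 1.39`. A
"coverage step" helper (`pitch·√(n²+1)/n²`) gives the exactly commensurate
step for which the n²-frame scan tiles each lattice unit cell uniformly;
the summed excitation is then flat to <0.5%.

**SNR definition.** The method's SNR convention is not published, so the
simulator defines and records it: `10·log10(mean(signal²)/σ²_noise)` over
the signal support (pixels above 1% of the maximum). Gaussian noise hits
the requested SNR exactly by construction; Poisson noise chooses the photon
scale so the support-averaged shot variance matches. Gaussian noise is
added without a camera offset, so noisy stacks may contain negative
excursions; the reconstruction stages tolerate them (RL-type solvers clamp
the measured data at zero).

**What the phantoms do not emulate:** thick-sample 3-D defocus scattering,
camera gain/read-noise calibration, speckle, photobleaching, or drift. A
passing simulation study therefore validates the *reconstruction
machinery*, not the instrument; headline resolutions on real specimens are
outside what a desk-scale simulation can reproduce.

## OLID

Out-of-focus light is scan-invariant while in-focus pixels are modulated as
spots sweep past. OLID takes the per-pixel spectrum along the frame axis
and multiplies the zero-frequency bin by `dc_attenuation` (default 0 =
full removal, the published recipe says only "attenuate"; the factor is
exposed and logged). Removal of any frame-constant component is then exact
(< machine epsilon), idempotent, and linear. Negative excursions are
clamped by default. Note that for a frame-constant background matched-filter
spot localization is barely affected; OLID's practical benefit appears for
*structured* out-of-focus backgrounds, which is how the paired
localization-improvement property is evaluated.

## Spot localization

Candidates come from correlation with the excitation kernel followed by
3-point log-Gaussian peak interpolation (exact for sampled Gaussians;
<0.03 px error on noise-free interior spots). Edge-clipped spots are
excluded and instead *predicted* by a global least-squares fit of lattice
vectors + origin + constant per-frame step through all candidate/lattice
index assignments, with 3·rms outlier rejection (robust to ≥10% spurious
candidates; step recovered to <0.01 px under 0.3 px jitter). On simulated
data the geometry-predicted grid (calibration path) may be used directly.

## Pixel reassignment

Sub-images of radius `R` are cut around every predicted spot, windowed,
and pasted centred at **twice** the spot coordinate on a canvas with 2×
the (upsampled) input dimensions; a detected photon at offset δ from its
spot thus moves to `c + δ/2` in sample coordinates. Numerical choices that
matter:

* **Band-limited upsampling** (factor 2 default, 4 for PSF metrology)
  before extraction mitigates integer-placement error.
* **Sub-pixel splat pasting**: the residual fractional paste shift is
  distributed bilinearly over the four neighbouring placements. Naive
  nearest-index pasting carries up to 0.75 px placement error and biased
  the reassigned PSF several percent wide.
* **Gaussian apodization**: sub-images are always windowed with a Gaussian
  of σ = R/2. A hard-edged window leaves ragged truncation artifacts in
  the accumulated canvas; for matched excitation/detection widths a
  centred Gaussian window provably does not change the reassigned PSF
  width (the window terms cancel in the Gaussian algebra). A digital
  pinhole of `sigma_rel·σ_base` simply tightens this window.
* **Weight normalization**: pinhole/window masks are accumulated into a
  weight map and the canvas is divided by it where weights are
  significant, removing scan-density shading.
* **Window radius**: default `3·σ_base`, capped at `pitch/2 − 1` px to
  avoid cross-talk with neighbouring spots (the cap applies at the default
  0.5 AU/1:3 geometry and warns; an explicitly larger radius errors).
  Below ~1.2 AU pitch the detection-PSF tail of a bright structure leaks
  into neighbouring windows regardless — pitch, window and spot size trade
  off against each other.
* `σ_base` is fitted from the aligned (cubic-spline shifted),
  background-subtracted average of spot cut-outs; linear interpolation
  would blur the average and bias σ upward by several percent.

The PR canvas of a point source narrows by √2 for equal excitation and
detection widths (verified to within ~1.5% across sub-pixel source
positions; measured on marginal profiles, which average sampling noise
without changing a Gaussian's width). At the standard 49-frame scan the
canvas retains ±5% sampling combs at twice the scan-sample spacing — the
discontinuity artifact that grows with scan step and that the
multi-image deconvolution stage is designed to remove; the flat-field
uniformity property is accordingly verified in the dense-sampling regime
(same preset, 0.8 AU pitch, flat to ~2%).

The MC-ISM image is the Richardson–Lucy deconvolution of the PR canvas
with the effective PR PSF (Gaussian of
`σ = hypot(σ_spot, σ_det)/input_pixel` canvas px, or measured from a
simulated bead).

## Deconvolution

* **RL / joint RL**: multiplicative EM with an ε-guard (1e-12) on all
  divisions and a flat-field denominator (adjoint of a unit image). jRL
  shares one estimate across all frames/patterns and reduces *exactly*
  (bit-for-bit) to single-image RL for one frame with a uniform pattern.
  Initialization is the mean of the measured data; flux is conserved
  through iterations for interior-supported images.
* **FISTA-GS** minimizes
  `½ Σ_i ‖A_i O_i − I_i‖² + λ‖Σ_i O_i‖₁` over nonnegative per-frame
  components. The step is `1/L` with `L` from 30 power iterations on the
  block normal operator. On the nonnegative feasible set the group penalty
  is linear, so the exact prox of penalty + constraint is the elementwise
  shifted projection `max(· − λ·step, 0)`; the unconstrained prox (mean /
  zero-sum decomposition with a soft-thresholded mean) is kept as a
  separate documented primitive. Momentum restarts whenever the objective
  would increase, making the recorded objective non-increasing; ten
  consecutive non-improving steps raise an error suggesting a smaller
  step. Default 100 iterations (jRL 50) or relative objective change
  <1e-6.
* **λ default**: the method's value is unpublished. A sweep on synthetic
  line pairs showed `λ = 1e-3·max(measured)` leaves the fitted pair
  separation unbiased while `1e-2·max` compressed it by ~19%; 1e-3 is the
  logged default.
* Patterns for real data are synthesized from the fitted spot grid and
  σ_base; for simulations the generator's true patterns may be injected
  (both paths are exposed).

## Metrology

* FWHM by Gaussian fit (`2.3548·σ`); multi-modal profiles are redirected
  to the bi-Gaussian fit. `marginal_fwhm` integrates out one axis first —
  unchanged width for separable peaks, much lower sampling noise.
* Bi-Gaussian line-pair fit: two equal-width Gaussians + offset; the dip
  contrast is the background-subtracted model value midway between the
  fitted peaks over the mean peak value. *Resolved* means the fitted
  separation is within 20% of nominal **and** dip ≤ 0.75 (Rayleigh-like:
  Gaussians at the Rayleigh spacing 0.61λ/NA dip to ≈0.73; a pair one
  FWHM apart dips only to ≈0.94 and does not count).
* PSNR uses `10·log10(max(ref)²/MSE)` (∞ for identical images); SSIM uses
  the standard constants with a 7 px window after jointly rescaling both
  images to [0, 1]. Cross-method comparisons first apply an affine
  least-squares intensity match since reconstructions carry arbitrary
  scales.
* FRC: rings one frequency-pixel wide, fixed 1/7 threshold (half-bit
  available), resolution linearly interpolated at the first crossing;
  no crossing reports Nyquist with a flag. The recommended split is
  odd/even-frame reconstructions.

## Benchmark experiments

`mcism.benchmarks` holds the three standard verification runs used by the
test suite and `scripts/acceptance.py` (64×64 object grids at 32.5 nm;
seconds to a minute each on one core):

1. **Point-source gain** — equal-PSF, point-pinhole 49-frame scan;
   PR gain ≈ √2, PR + RL(40) gain ≈ 3.6 (≥ 2).
2. **Frame-reduced line pairs** — noise-free 25-frame scan at the 1.39×
   step; FISTA-GS resolves 140 nm (and down to 120 nm, the smallest
   spacing scanned).
3. **Digital pinhole at 10 dB** — 49-frame line-pair stacks with Gaussian
   noise; the MC-ISM pipeline (PR with a `sigma_rel = 1` pinhole + RL)
   resolves 170 nm in the majority of seeds, and the pinhole strictly
   improves the dip contrast over the no-pinhole pipeline on paired
   seeds. PR *without* the deconvolution step has an effective FWHM of
   ≈178 nm at these optics and cannot meet the 0.75-dip criterion at
   170 nm — the low-SNR resolving claim belongs to the deconvolved
   MC-ISM image, which is what this benchmark runs.

## Known limitations

* 2-D only: phantoms, PSFs and reconstructions are single-plane; axial
  widths are modelled but no 3-D stack simulation is provided.
* The Gaussian PSF approximation underestimates Airy sidelobes; absolute
  resolutions are correct at the few-percent level, not sub-percent.
* PR canvases at coarse scan sampling carry periodic combs (see above);
  quantitative flat-field work should use dense sampling or the
  deconvolution reconstructions.
* The light-dose accounting of the illumination (per-pixel integral of
  the patterns) is exposed raw; no claim is made about dose ratios
  against other structured-illumination schemes, whose reference patterns
  are not modelled here.
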