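# mcism

Simulation and reconstruction toolkit for **multi-confocal image scanning
microscopy (MC-ISM)**: super-resolution imaging with a scanned pinhole-array
illumination and camera detection.

MC-ISM excites the sample with a square lattice of diffraction-limited spots
(pinhole diameter ~0.5 AU, diameter:pitch 1:3), sweeps the lattice with a
single galvanometer along one axis — the lattice is tilted by arctan(1/n) so
that n² frames cover every unit cell uniformly — and records each frame on a
camera. This package implements the full computational side of the method
for users who want to reconstruct such data or study the design space in
simulation:

* **Forward simulator** — phantoms (line pairs, beads, filaments, plates,
  shells), illumination patterns, image formation
  `I_i = h ⊗ (P_i · O) + background`, Gaussian/Poisson noise at a
  controlled SNR.
* **OLID preprocessing** — optical lock-in detection: per-pixel Fourier
  filtering along the frame axis removes the scan-invariant (out-of-focus)
  component while keeping the modulated in-focus signal.
* **Pixel reassignment (PR)** — spot localization (matched filter + global
  lattice/trajectory fit), sub-image extraction, Gaussian digital pinholes,
  and reassignment of every sub-image to twice its spot coordinate on a 2×
  canvas, which narrows the effective PSF by up to √2; Richardson–Lucy
  deconvolution of the canvas (the MC-ISM image) reaches a 2× gain.
* **Frame-reduction deconvolution** — joint Richardson–Lucy and FISTA-GS,
  an accelerated proximal-gradient solver for

  ```
  min_{O_i ≥ 0}  ½ Σ_i ‖h ⊗ (P_i·O_i) − I_i‖₂² + λ ‖Σ_i O_i‖₁
  ```

  which exploits the overlap between detector-pixel effective PSFs to
  reconstruct from 25 instead of 49 frames (scan step enlarged by
  √50/√26 ≈ 1.39 at fixed slow-axis sampling).
* **Metrology** — FWHM and bi-Gaussian line-pair fits (dip-contrast
  resolvability), PSNR/SSIM, Fourier ring correlation.

## Worked example

Resolution gain of pixel reassignment on a simulated point source (equal
excitation/detection PSFs, 49-frame tilted scan, no noise):

```python
from mcism.benchmarks import point_source_resolution

r = point_source_resolution(seed=0)
print(f"widefield FWHM : {r['fwhm_widefield_nm']:.1f} nm")
print(f"PR FWHM        : {r['fwhm_pr_nm']:.1f} nm   (gain {r['pr_gain']:.3f})")
print(f"MC-ISM FWHM    : {r['fwhm_mcism_nm']:.1f} nm   (gain {r['mcism_gain']:.2f})")
```

prints

```
widefield FWHM : 235.6 nm
PR FWHM        : 168.0 nm   (gain 1.402)
MC-ISM FWHM    : 65.7 nm   (gain 3.59)
```

The widefield width is the diffraction limit 0.51·λ/NA ≈ 233 nm at 680 nm /
NA 1.49; pixel reassignment narrows it by ≈ √2 (the analytic limit for
matched excitation and detection widths), and Richardson–Lucy deconvolution
of the reassigned canvas goes beyond the 2× target.

The same pipeline is available from the shell:

```bash
mcism simulate --config run.yaml --out raw.tif
mcism olid --in raw.tif --out olid.tif --dc 0.0
mcism reconstruct fista --config run.yaml --in olid.tif --out recon/
mcism geometry --config run.yaml --check
```

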