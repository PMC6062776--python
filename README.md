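# corticox

A toolkit for dual-modality cortical hemodynamics analysis:

- **Speckle flowmetry** (`corticox.speckle`) — windowed speckle contrast
  (K = σ/⟨I⟩, box-filter fast path), inversion of the single-exposure
  speckle model `K(T, τc) = sqrt(β·(e^{-2x} − 1 + 2x)/(2x²))`, `x = T/τc`,
  for per-pixel correlation times, and baseline-relative blood flow
  (rCBF = τc,initial/τc) over regions of interest. Includes an analytic
  finite-window bias correction (`debias_contrast`) for the few-percent
  downward bias of small-window contrast estimates.
- **Lifetime oximetry** (`corticox.lifetime`) — mono-exponential fitting of
  averaged phosphorescence decays `I(t) = A + B e^{−t/τ}` (after a 2-µs
  instrument offset) and Stern–Volmer conversion
  `pO2 = (1/τ − 1/τ0)/kq` with bundled constants
  (kq = 291.014 mmHg⁻¹s⁻¹, τ0 = 47 µs), optionally overridden by a
  monotone (τ, pO2) calibration table.
- **Patterning geometry** (`corticox.patterning`) — camera↔DMD affine
  coregistration from control points, binary-mask rasterization into DMD
  space (608×684), tile-grid ROI generation in physical units, and
  pulse-train / acquisition scheduling with feasibility checks.
- **Vessel optics** (`corticox.optics`) — scattering-free Beer–Lambert
  transmittance through a hemoglobin-filled vessel, with bundled compendium
  extinction coefficients at the 445- and 637-nm laser lines (overridable
  via CSV).
- **Simulation** (`corticox.simulate`) — synthetic speckle stacks with
  prescribed τc maps (gamma-distributed integrated intensity, shape 1/K²),
  noisy decays at prescribed pO2, and scripted occlusion sessions with
  ground-truth timecourses.
- **I/O + pipeline** (`corticox.io`, `corticox.pipeline`) — TIFF/PNG/CSV/JSON
  readers and writers, and an end-to-end session runner that emits maps,
  timecourses and a reproducibility manifest.

## Command line

The `corticox` umbrella command exposes each stage:

```sh
corticox simulate speckle stack.tif --tau-c 5e-3 --seed 1
corticox speckle contrast stack.tif K.tif --window 7 --average-n 45
corticox speckle flow stack.tif tau.tif
corticox speckle rcbf stack.tif rois/ out.csv --baseline baseline.tif

corticox simulate decay decay.csv --po2 80
corticox lifetime fit decay.csv --offset-us 2
corticox lifetime po2 decay.csv

corticox register estimate points.csv affine.json
corticox register apply mask.png affine.json dmd_mask.png
corticox tiles make tiles/ --cols 12 --rows 8 --width-mm 1.2 --height-mm 1.0 \
    --pixel-scale 0.0025
corticox schedule plan --pattern-rate 10 --decays 200 --n-patterns 96
corticox optics transmittance --wavelength 637

corticox simulate session session/ --seed 1
corticox pipeline run --config session.json
```

## Notes

- Contrast uses the population standard deviation over the window and flags
  border pixels invalid rather than padding. `debias_contrast` applies the
  first-order gamma-model correction `E[K̂] ≈ K·(1 − 3(1+K²)/(4N))`; it is
  recommended (and used by the pipeline default) before model inversion.
- The bundled hemoglobin extinction values are standard tabulated
  compendium values on the tetramer basis, linearly interpolated to 445 and
  637 nm. The 445-nm entry sits on the steep Soret flank and is sensitive
  to the source table; use `--extinctions` / `ChromophoreSpectrum.from_csv`
  to supply a preferred table.
- Simulated speckle pixels are statistically independent; spatial speckle
  correlation is deliberately not modeled.
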