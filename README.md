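# mmfscope

A desk-scale simulation and analysis toolkit for **holographic
multimode-fibre (MMF) laser-scanning endo-microscopy** — the class of
instrument that images deep brain tissue through a single hair-thin
step-index fibre by measuring the fibre's transmission matrix and
synthesising scanning foci by digital holography.

It is written for two audiences: instrument builders who want a testable
software model of the calibration / refocusing / scanning chain before
touching hardware, and analysts who need the published data-processing
algorithms (depth stitching, kymograph blood-flow velocimetry) as plain,
tested Python functions.

## What it models

Light transport through an ideal step-index MMF is spanned by its guided
LP modes.  In the weakly guiding approximation the LP(l, m) modes solve

```
u·J_{l+1}(u)/J_l(u) = w·K_{l+1}(w)/K_l(w),   u² + w² = V²,
V = π·d·NA/λ
```

with Bessel-J cores and Bessel-K cladding tails; the guided-mode count
approaches V²/2 (≈ 28 000 for the 100 µm, NA 0.37 fibre at 488 nm).  A
seeded ground-truth operator `T = P_out·U·D(βL)·P_in` stands in for the
physical fibre: modal propagation phases `D` followed by a random
unitary `U` that scrambles the modes, rendered on a field grid.

On top of that the package implements:

* **Calibration** — transmission-matrix acquisition by phase-shifting
  interferometry (`I_k = |E + r·e^{iθ_k}|²`, solved per pixel in least
  squares) and focus synthesis by phase conjugation of a TM row, with
  focus metrology (Rayleigh radius = first minimum of the azimuthally
  averaged intensity, power ratio, enhancement).
* **Holography** — tilted-plane-wave input bases, kinoforms, and
  Lee-style binary off-axis (DMD) encoding/decoding.
* **Refocusing** — exact angular-spectrum propagation
  `Ẽ(kx,ky) ↦ Ẽ·exp(i·z·√(k²n² − kx² − ky²))` applied to fields or to
  every TM column, giving focal-plane ladders without recalibration.
* **Scanning** — raster frames, multi-plane z-stacks and line-scan
  kymographs of synthetic 3-D fluorophore scenes.
* **Stitching** — contrast-floor subtraction (mean of the 1% darkest
  pixels), drift-speed estimation from overlapping scans (normalised
  cross-correlation, parabolic sub-pixel refinement) and pixel-by-pixel
  4-D → 3-D assembly with overlap averaging.
* **Velocimetry** — red-blood-cell flow speed from kymographs by the
  morphing estimator: per-row affine normalisation, integer-pixel
  counter-shifts of a ±4-column window per candidate velocity, mean
  row-wise standard deviation as the match metric, and a second-order
  polynomial fit through the metric minimum.
* **Phantoms** — seeded generators (beads, neurones, vessels, RBC
  kymographs, drifting records) that always return their ground truth.

## Worked example

```python
import numpy as np
import mmfscope as m

spec  = m.FiberSpec(core_diameter=20.0, na=0.37, wavelength=0.488)
grid  = m.FieldGrid(n_pixels=128, pitch=0.25)          # µm
modes = m.solve_modes(spec, grid)
basis = m.make_input_basis(300, grid, spec)
op    = m.ground_truth_operator(modes, basis, coupling_strength=1.0, seed=1)
tm    = m.acquire_tm(op, basis)                        # 4-step interferometry
out, report = m.synthesize_focus(tm, op, grid.index_of(0.0, 0.0))
print(len(modes), round(report.rayleigh_radius, 3), round(report.enhancement))
```

prints

```
571 0.868 491
```

— the 20 µm fibre guides 571 mode orientations, and the synthesised
focus has a measured Rayleigh radius of 0.868 µm (the analytic
diffraction limit 0.61·λ/NA is 0.80 µm; the excess is residual speckle
from controlling 571 modes with 300 inputs) at an intensity enhancement
of ≈ 490 over the remaining background.

Flow velocimetry on a synthetic record:

```python
from mmfscope.phantoms import make_rbc_kymograph, modulated_velocity
k, v_true = make_rbc_kymograph(modulated_velocity(3.0), n_lines=1000, seed=0)
trace = m.velocity_trace(k)                  # px/line
phys  = m.to_physical(trace, k)              # µm/s
f, p  = m.power_spectrum(phys)
```

The power spectrum shows the phantom's cardiac (8 Hz) and respiratory
(2 Hz) modulation peaks.

The same stages are scriptable from a shell (`mmfscope --help`):
`simulate-fiber`, `calibrate`, `refocus`, `scan`, `stitch`, `flow`,
`phantom`, `spectra`.

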