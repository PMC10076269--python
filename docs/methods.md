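# Methods

This note documents the models, the numerical choices, and the known
limits of `mmfscope`.  All lengths are micrometres, wavenumbers rad/µm,
and image arrays are row-major with row 0 at the top; axial z is
positive away from the distal fibre facet.

## Fibre model

The fibre is a step-index multimode fibre treated in the weakly guiding
(scalar LP-mode) approximation.  For azimuthal order l the radial
profiles are J_l(u·r/a) in the core and K_l(w·r/a)/K_l(w)·J_l(u) in the
cladding, with u and w linked by u² + w² = V², V = π·d·NA/λ, and the
dispersion relation u·J_{l+1}(u)/J_l(u) = w·K_{l+1}(w)/K_l(w).  The
solver brackets sign changes of an overflow-safe form of this equation
on a fine u-grid (step 0.02) and refines each root with Brent's method;
the Bessel-K ratio is evaluated by upward recurrence (R_i = 2i/w +
1/R_{i-1}) because `kve` overflows at high order and small argument.
Counting uses the cutoff form — LP(l, m) is guided exactly when V
exceeds the m-th zero of J_{l-1} (counting the origin for l = 0) — which
is exact and fast even at V ≈ 240.

The scalar model ignores vectorial corrections although NA 0.37 is not
deeply weakly guiding.  This is an accepted modelling error: the
quantities the package is judged on (Rayleigh radius, mode count,
square-law scaling) are NA/λ-level.  A single polarisation is simulated;
the instrument's dual-polarisation path appears only as the ×2 factor in
the mode count.  The cladding index defaults to 1.45 (fused silica) and
the calibration/tissue medium to 1.33; neither is printed by typical
fibre datasheets at this precision, and both are configuration values.

**Ground-truth operator.**  `T = P_out·U·D(βL)·P_in`, where `P_in`
projects input fields onto the mode basis, `D` applies propagation
phases over the fibre length (27 mm default, phases reduced mod 2π),
and `U` is a seeded random unitary.  `U` is the fractional power `W^c`
of a Haar draw `W`, computed through the complex Schur form, so the
coupling strength c interpolates from the identity (c = 0) to full
Haar mixing (c = 1) while staying exactly unitary.  This reproduces the
"total scrambling" character of modal transport without modelling any
specific bend geometry.

## Calibration and focus metrology

The transmission matrix is acquired column by column: each basis element
(a unit-power truncated plane wave whose tilt lies on a uniform lattice
inside the NA disk, spiral-ordered from zero tilt) propagates through
the operator; the output interferes with a unit plane-wave reference at
phase steps {0, π/2, π, 3π/2} (any ≥ 3 distinct steps are accepted, the
solver is linear least squares per pixel); the complex field follows
from C = E·conj(r).  Noiseless acquisition reproduces the operator to
1e−8, and a global reference phase φ multiplies the matrix by e^{−iφ} —
the usual interferometric gauge freedom.

Foci are synthesised by phase conjugation of a TM row.  The focus report
measures: peak position; the Rayleigh radius as the first local minimum
of the azimuthally averaged intensity (sampled on rings by bilinear
interpolation at Δr = pitch/5, 96 angles, refined by a parabola through
the minimum); the power fraction inside that radius; and the
enhancement, peak intensity over the mean background *inside the
fibre-core projection* but outside twice the Rayleigh radius — outside
the core the field is structurally dark and would inflate the figure.

With ~300 control inputs against 571 mode orientations (20 µm core),
the measured radius sits ≈ 8% above the analytic 0.61·λ/NA = 0.80 µm:
the uncontrolled mode fraction leaves residual speckle that partially
fills the first minimum and biases it outward.  The bias shrinks with
more basis elements; it cancels to < 5% when comparing cores at fixed
NA, which is the sense in which resolution is independent of core size.

## Refocusing

Angular-spectrum propagation with the exact square-root kernel (Fresnel
available behind a flag), evanescent components zeroed by default (or
raising, per policy).  Propagation runs circularly on the native grid:
because every fibre grid keeps at least a 2× lateral margin around the
core, wrap-around is negligible for |z| up to tens of µm, while the
transform stays exactly unitary and refocus(+z)∘refocus(−z) is the
identity to round-off.  Optional zero-padding (`pad_factor`) exists for
fields that fill their grid; note that padding followed by cropping
discards out-diffracted light and breaks exact invertibility at the
1e−4 level.  Refocused matrices carry their new plane position in
`calibration_plane_z`; planes behind the calibration plane are negative
(virtual) positions, which the ladder of focal planes uses freely.

## Scanning

A frame is built focus by focus (serpentine row-major order): the
phase-conjugation focus for each scan position is pushed through the
ground-truth operator, propagated to every scene slab holding
fluorophores, and the signal is Σ density·|E|²·voxel volume — uniform
collection efficiency, since the instrument's high NA makes collection
spatially flat at this scale and no spatial collection model is
published.  Poisson noise (seeded) and a full-well clip model the
detector.  Scan positions snap to the output grid; scanning finer than
the calibrated output sampling aliases, so plans should use the grid
pitch.  Line mode scans an arbitrary trajectory once per sweep and
stacks sweeps into a kymograph; a drift velocity can translate the
scene between sweeps.

## Stitching

Given z-stacks acquired while the probe advances steadily: (1) subtract
per scan the mean of the ⌈1%⌉ darkest pixels, clamping at zero; (2)
estimate one global speed as the mean over consecutive stack pairs of
the per-plane shift, where each shift maximises the normalised
cross-correlation of overlapping rows over integer offsets (≥ 25%
overlap enforced) with parabolic sub-pixel refinement — peak-locking
bias of this refinement is a few hundredths of a pixel; (3) map stack i,
local row r to global row round(i·speed + r) and average multiply
measured voxels.  Nearest-voxel binning (not interpolation) preserves
the exact-averaging semantics; the sample-count map is returned.  A
leading-stack exclusion count covers the non-uniform entry phase.  The
method assumes pure axial progression; rotation and lateral drift are
out of scope.

## Velocimetry

Rows are affinely normalised to mean 0, std 1 (any common target is
equivalent; zero-variance rows are flagged out).  For column c and
candidate v (default grid −10…10 px/line, step 0.25), the columns at
offsets δ ∈ [−w, w] (w = 4 by default, the centre column included) are
shifted by round(v·δ) pixels; rows pushed out of range are cropped, not
wrapped, since wrapping fabricates coherence.  The metric is the mean
over retained rows of the standard deviation across the window; the
estimate is a parabola through the minimum sample and its neighbours,
ties broken toward smaller |v|.

Two validity guards matter in practice.  `min_valid_rows` (default a
quarter of the rows, at least 8) rejects candidates whose large shifts
crop the record to a handful of rows — on noiseless backgrounds such
candidates can reach spuriously zero metric and flip the estimate's
sign.  `min_active_rows` (default 2) flags as gaps the columns whose
evaluation window shows no intensity variation in any row: such windows
contain no streak and carry no velocity information; with real noisy
data this guard is inert and gaps simply widen the estimator variance.

**Pass band.**  The window acts approximately as a least-squares slope
fit over 2w+1 lines, with amplitude transfer ≈ 1 − (Σδ⁴/3Σδ²)·ω′² for
per-line angular frequency ω′.  At a 1 kHz line rate and w = 4 this
crosses 0.9 near 36 Hz; the measured curve (10 seeds) crosses at
≈ 40 Hz and falls to ≈ 0.5 by 100 Hz.  A 100 Hz modulation period
equals the 9-line window span, so no straight-streak fit over that
window can recover it at 0.9 amplitude — widening or narrowing the
window trades this band edge against robustness on sparse traces, and
the acceptance sweep reports the measured edge rather than asserting a
nominal one.

Unit closure: v[µm/s] = v[px/line] · pixel pitch · line rate.  Spectra
are mean-removed periodograms; gaps are linearly interpolated first and
flagged.

## Phantoms

All generators are deterministic under a fixed seed and return their
ground truth; noise is applied last.  Beads are single voxels (PSF
tests); neurones are 5–15 µm ellipsoid somata with ≈ 1 µm dendrite
tubes and spine bumps; vessels are 3–10 µm tubes, optionally
hollow-walled.  RBC kymographs advance streaks by the integrated
velocity profile; by default cells recirculate on a periodic line
(steady flow), and a streaming mode (`wrap=False`) produces genuinely
sparse records.  Dark-on-bright contrast imitates unlabelled cells in
fluorescent plasma; per-row gains imitate the row response differences
of real records.  Cardiac/respiratory modulation defaults (8 Hz / 2 Hz,
depths 20% / 10%) are synthetic placeholders for mouse-like rhythms.
Drift records sample the scene density directly (ideal imaging) — the
stitcher consumes geometry and intensities, and diffraction-limited
imaging is exercised separately by the scan engine; this is why
stitched-volume recovery tests can demand sub-percent RMSE.

What the phantoms do **not** contain: tissue scattering and
depth-dependent aberrations, photobleaching, calcium-indicator kinetics,
vessel pulsatility beyond the imposed velocity modulation, and non-rigid
tissue motion.  Passing tests therefore validate the algorithms under
their stated geometric and statistical assumptions, not end-to-end
performance on in-vivo records.

## Problem sizes

Defaults are desk-scale by design: 64²–128² field grids, 20 µm cores
(571 mode orientations), ~300 input elements, 600–8000-line kymographs,
15–30-stack drift records.  The full-size instrument configuration
(100 µm core, 21 000 inputs, ≥ 10⁵ outputs) is reachable through the
same configuration surface but is not exercised by the test suite.
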