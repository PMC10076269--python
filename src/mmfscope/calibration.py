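"""Transmission-matrix acquisition by phase-shifting interferometry and
focus synthesis with quality metrics.

The transmission matrix (TM) is measured column by column: each input
basis element is sent through the (simulated) fibre, interfered with a
reference wave at several known phase steps, and the complex output field
is recovered per pixel by least squares.  Phase conjugation of a TM row
then yields a diffraction-limited focus at the corresponding output
sample; :func:`focus_metrics` quantifies it (Rayleigh radius, power
ratio, enhancement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .fiber import ForwardOperator
from .grid import FieldGrid
from .holography import InputBasis, phase_conjugate_kinoform

__all__ = [
    "TransmissionMatrix",
    "FocusReport",
    "psi_reconstruct",
    "acquire_tm",
    "synthesize_focus",
    "focus_metrics",
    "default_phase_steps",
]

#: 4-step phase-shifting schedule used by default.
default_phase_steps = (0.0, np.pi / 2, np.pi, 3 * np.pi / 2)


@dataclass
class TransmissionMatrix:
    """Calibrated complex map from input basis elements to output samples.

    ``matrix`` has shape (n_output_samples, n_input_elements); output
    samples are the flattened pixels of ``output_grid``.
    ``calibration_plane_z`` is the axial position of the plane the matrix
    describes, in µm from the distal facet.
    """

    matrix: np.ndarray
    output_grid: FieldGrid
    input_basis: InputBasis
    wavelength: float
    calibration_plane_z: float = 0.0
    medium_index: float = 1.33

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != self.output_grid.n_samples:
            raise ValueError("matrix rows inconsistent with output grid")
        if self.matrix.shape[1] != self.input_basis.n_elements:
            raise ValueError("matrix columns inconsistent with input basis")

    @property
    def n_outputs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class FocusReport:
    """Quality metrics of a synthesised focus."""

    peak_position: tuple[float, float]  # (y, x) µm
    power_ratio: float
    enhancement: float
    rayleigh_radius: float  # µm; NaN when no first minimum was found


def psi_reconstruct(
    intensity_frames,
    reference: np.ndarray,
    phase_steps=default_phase_steps,
) -> np.ndarray:
    """Recover the complex field E from interference intensities.

    Solves, per pixel and in least squares, I_k = |E + r e^{iθ_k}|² for
    the frames ``intensity_frames`` recorded at reference phases
    ``phase_steps``.  Exact (to round-off) for noiseless frames with the
    4-step schedule.  Pixels with zero reference amplitude are flagged
    NaN with a warning.
    """
    frames = np.asarray(intensity_frames, dtype=float)
    steps = np.asarray(phase_steps, dtype=float)
    if frames.ndim < 1 or len(frames) < 3:
        raise ValueError("need at least 3 phase-shifted frames")
    if len(frames) != len(steps):
        raise ValueError("one phase step per frame required")
    wrapped = np.mod(steps, 2 * np.pi)
    if len(np.unique(np.round(wrapped, 9))) != len(steps):
        raise ValueError("phase steps must be distinct modulo 2π")
    reference = np.asarray(reference, dtype=complex)
    if frames.shape[1:] != reference.shape:
        raise ValueError("frames and reference must share a grid")

    # I_k = a + 2 cosθ_k · Re C + 2 sinθ_k · Im C, with C = E conj(r)
    design = np.stack([np.ones_like(steps), 2 * np.cos(steps), 2 * np.sin(steps)], axis=1)
    flat = frames.reshape(len(steps), -1)
    sol, *_ = np.linalg.lstsq(design, flat, rcond=None)
    c = (sol[1] + 1j * sol[2]).reshape(reference.shape)

    out = np.empty(reference.shape, dtype=complex)
    bad = reference == 0
    if np.any(bad):
        warnings.warn("zero reference amplitude: flagged invalid pixels as NaN")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = c / np.conj(reference)
    out[bad] = np.nan
    return out


def simulate_psi_frames(
    output_field: np.ndarray,
    reference: np.ndarray,
    phase_steps=default_phase_steps,
    rng: np.random.Generator | None = None,
    noise_sigma: float = 0.0,
) -> np.ndarray:
    """Interferogram stack |E + r e^{iθ_k}|², optionally with Gaussian
    intensity noise."""
    steps = np.asarray(phase_steps, dtype=float)
    frames = np.stack(
        [np.abs(output_field + reference * np.exp(1j * th)) ** 2 for th in steps]
    )
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        frames = frames + rng.normal(scale=noise_sigma, size=frames.shape)
    return frames


def acquire_tm(
    forward: ForwardOperator,
    basis: InputBasis,
    reference: np.ndarray | None = None,
    phase_steps=default_phase_steps,
    demod_reference: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    medium_index: float = 1.33,
) -> TransmissionMatrix:
    """Measure the TM of ``forward`` by phase-shifting interferometry.

    Column j is the PSI reconstruction of the output produced by basis
    element j.  ``demod_reference`` (defaults to ``reference``) is the
    wave assumed during demodulation; passing a phase-shifted copy of the
    true reference reproduces the interferometer's global-phase
    covariance.
    """
    grid = forward.grid
    if reference is None:
        reference = np.ones(grid.shape, dtype=complex)
    if demod_reference is None:
        demod_reference = reference
    cols = np.empty((grid.n_samples, basis.n_elements), dtype=complex)
    for j in range(basis.n_elements):
        e_j = np.zeros(basis.n_elements)
        e_j[j] = 1.0
        out = forward.apply(e_j)
        frames = simulate_psi_frames(out, reference, phase_steps, rng=rng,
                                     noise_sigma=noise_sigma)
        cols[:, j] = psi_reconstruct(frames, demod_reference, phase_steps).ravel()
    return TransmissionMatrix(
        matrix=cols,
        output_grid=grid,
        input_basis=basis,
        wavelength=forward.modes.spec.wavelength,
        calibration_plane_z=0.0,
        medium_index=medium_index,
    )


def synthesize_focus(tm: TransmissionMatrix, forward: ForwardOperator, target: int):
    """Push the phase-conjugation kinoform for ``target`` through the
    ground-truth operator; returns (output field, FocusReport)."""
    kino = phase_conjugate_kinoform(tm, target)
    out = forward.apply(kino.coefficients)
    report = focus_metrics(out, target, tm.output_grid,
                           core_radius=forward.modes.spec.core_radius)
    return out, report


def radial_intensity_profile(
    field: np.ndarray,
    grid: FieldGrid,
    center: tuple[float, float],
    dr: float | None = None,
    r_max: float | None = None,
    n_angles: int = 96,
):
    """Azimuthally averaged intensity about ``center`` (pixel indices)."""
    intensity = np.abs(field) ** 2
    if dr is None:
        dr = grid.pitch / 5.0
    if r_max is None:
        r_max = grid.extent / 2.0
    radii = np.arange(0.0, r_max, dr)
    angles = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    cy, cx = center
    rr, aa = np.meshgrid(radii / grid.pitch, angles, indexing="ij")
    ys = cy + rr * np.sin(aa)
    xs = cx + rr * np.cos(aa)
    samples = map_coordinates(intensity, [ys, xs], order=1, mode="constant")
    return radii, samples.mean(axis=1)


def _first_local_minimum(radii: np.ndarray, profile: np.ndarray) -> float:
    """First local minimum of the radial profile after the central peak,
    refined by a parabola through the minimum and its neighbours."""
    for i in range(1, len(profile) - 1):
        if profile[i] <= profile[i - 1] and profile[i] < profile[i + 1]:
            if i == 1 and profile[0] <= profile[1]:
                continue  # still on the flat top
            y0, y1, y2 = profile[i - 1], profile[i], profile[i + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            return float(radii[i] + delta * (radii[1] - radii[0]))
    return float("nan")


def focus_metrics(
    field: np.ndarray,
    target: int,
    grid: FieldGrid,
    core_radius: float | None = None,
) -> FocusReport:
    """Quantify a focus: Rayleigh radius (peak to first minimum of the
    azimuthally averaged profile), power inside that radius, and peak /
    mean-background enhancement.

    Background is measured outside twice the Rayleigh radius, restricted
    to the fibre-core projection when ``core_radius`` is given (outside
    the core the field is structurally dark).
    """
    intensity = np.abs(field) ** 2
    if intensity.max() == 0:
        raise ValueError("zero field has no focus")
    peak_flat = int(np.argmax(intensity))
    cy, cx = divmod(peak_flat, grid.n_pixels)
    radii, profile = radial_intensity_profile(field, grid, (cy, cx))
    r1 = _first_local_minimum(radii, profile)
    if np.isnan(r1):
        warnings.warn("no radial minimum within the grid; radius undefined")

    n = grid.n_pixels
    y, x = grid.coords()
    py, px = grid.position_of(peak_flat)
    rr = np.hypot(x - px, y - py)
    total = intensity.sum()
    if np.isnan(r1):
        power_ratio = float("nan")
        enhancement = float("nan")
    else:
        power_ratio = float(intensity[rr <= r1].sum() / total)
        bg = rr > 2 * r1
        if core_radius is not None:
            bg &= np.hypot(x, y) <= core_radius
        bg_mean = intensity[bg].mean() if np.any(bg) else np.nan
        enhancement = float(intensity.max() / bg_mean) if bg_mean else float("nan")
    return FocusReport(
        peak_position=(py, px),
        power_ratio=power_ratio,
        enhancement=enhancement,
        rayleigh_radius=r1,
    )
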