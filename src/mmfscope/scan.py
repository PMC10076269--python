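"""Laser-scanning fluorescence imaging of synthetic 3-D scenes.

A frame is built focus by focus: for every scan position the phase
conjugation focus is synthesised through the ground-truth operator, its
excitation intensity is propagated through the depth of the scene, and
the collected signal is the density-weighted integral of that intensity.
Collection efficiency is uniform (signal ∝ excitation × density), which
is adequate for a high-NA fibre whose collection the instrument never
spatially resolves.

Raster frames use a row-major serpentine scan order; line mode scans an
arbitrary trajectory of focus positions once per sweep, producing a
kymograph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .calibration import TransmissionMatrix
from .fiber import ForwardOperator
from .grid import FieldGrid
from .refocus import RefocusSpec, propagate_field
from .velocimetry import Kymograph

__all__ = [
    "Scene",
    "ScanPlan",
    "Frame",
    "ZStack",
    "scan_frame",
    "scan_zstack",
    "scan_line",
    "roi_traces",
]


@dataclass
class Scene:
    """3-D fluorophore-density grid.

    ``density`` is indexed (z, y, x) and non-negative; ``voxel_size`` is
    (dz, dy, dx) in µm; ``origin`` is the physical position (z, y, x) of
    voxel (0, 0, 0) relative to the distal facet / fibre axis.
    """

    density: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    channel: str = "ch0"

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.ndim != 3:
            raise ValueError("density must be a 3-D array")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")

    def z_planes(self) -> np.ndarray:
        """Axial positions (µm) of the scene's z slices."""
        return self.origin[0] + np.arange(self.density.shape[0]) * self.voxel_size[0]


@dataclass
class ScanPlan:
    """Scan geometry: raster field of view or line trajectory.

    ``field_of_view`` is (height, width) in µm, ``pixel_pitch`` the focus
    step, ``plane_offsets`` the focal-plane ladder in µm, ``rate`` the
    frame rate (raster) or line rate (line mode) in Hz.  ``trajectory``
    lists (y, x) focus positions for line mode.
    """

    mode: str = "raster"
    field_of_view: tuple[float, float] = (10.0, 10.0)
    pixel_pitch: float = 0.5
    plane_offsets: tuple[float, ...] = (0.0,)
    rate: float = 1.0
    trajectory: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("raster", "line"):
            raise ValueError("mode must be 'raster' or 'line'")
        if not np.all(np.isfinite(self.plane_offsets)):
            raise ValueError("plane offsets must be finite")
        if self.mode == "line":
            if self.trajectory is None or len(self.trajectory) == 0:
                raise ValueError("line mode needs a non-empty trajectory")
            self.trajectory = np.asarray(self.trajectory, dtype=float)

    def raster_shape(self) -> tuple[int, int]:
        h, w = self.field_of_view
        return (max(int(round(h / self.pixel_pitch)), 1),
                max(int(round(w / self.pixel_pitch)), 1))

    def raster_positions(self) -> np.ndarray:
        """(y, x) focus positions in serpentine order, shape (n, 2)."""
        ny, nx = self.raster_shape()
        ys = (np.arange(ny) - (ny - 1) / 2) * self.pixel_pitch
        xs = (np.arange(nx) - (nx - 1) / 2) * self.pixel_pitch
        pos = []
        for i, y in enumerate(ys):
            row = xs if i % 2 == 0 else xs[::-1]
            pos.extend((y, x) for x in row)
        return np.array(pos)


@dataclass
class Frame:
    data: np.ndarray
    plan: ScanPlan
    plane_z: float
    timestamp: float = 0.0


@dataclass
class ZStack:
    frames: list[Frame]

    def __post_init__(self) -> None:
        self.frames = sorted(self.frames, key=lambda f: f.plane_z)

    @property
    def plane_offsets(self) -> list[float]:
        return [f.plane_z for f in self.frames]

    def as_array(self) -> np.ndarray:
        return np.stack([f.data for f in self.frames])


def _tm_for_plane(tm_ladder, z: float, tol: float = 1e-6) -> TransmissionMatrix:
    if isinstance(tm_ladder, TransmissionMatrix):
        tm_ladder = [tm_ladder]
    if isinstance(tm_ladder, dict):
        tm_ladder = list(tm_ladder.values())
    for tm in tm_ladder:
        if abs(tm.calibration_plane_z - z) <= tol:
            return tm
    raise KeyError(f"no transmission matrix for plane offset {z} µm")


def _focus_fields(tm: TransmissionMatrix, forward: ForwardOperator,
                  positions: np.ndarray) -> np.ndarray:
    """Phase-conjugation foci for many positions at once.

    Returns an (n_positions, n, n) complex array of the fields the
    ground-truth operator actually produces.
    """
    grid = tm.output_grid
    targets = [grid.index_of(y, x) for y, x in positions]
    rows = np.conj(tm.matrix[targets, :])
    norms = np.linalg.norm(rows, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("dark target row; focus undefined")
    coeffs = rows / norms
    n = grid.n_pixels
    fields = (forward.matrix @ coeffs.T).T.reshape(len(targets), n, n)
    return fields


def _excitation_signal(
    focus_fields: np.ndarray,
    focal_z: float,
    scene: Scene,
    grid: FieldGrid,
    wavelength: float,
    medium_index: float,
) -> np.ndarray:
    """Signal per focus: Σ_voxels density · |excitation|², propagating
    each focus field to every scene slab that holds fluorophores."""
    signals = np.zeros(len(focus_fields))
    zs = scene.z_planes()
    dz, dy, dx = scene.voxel_size
    ny, nx = scene.density.shape[1:]
    # scene voxel centres in grid pixel coordinates
    yy = (scene.origin[1] + np.arange(ny) * dy) / grid.pitch + grid.n_pixels // 2
    xx = (scene.origin[2] + np.arange(nx) * dx) / grid.pitch + grid.n_pixels // 2
    gy, gx = np.meshgrid(yy, xx, indexing="ij")
    voxel_volume = dz * dy * dx
    for iz, z in enumerate(zs):
        slab = scene.density[iz]
        if not np.any(slab):
            continue
        spec = RefocusSpec(z=z - focal_z, medium_index=medium_index)
        for i, f in enumerate(focus_fields):
            ez = f if spec.z == 0 else propagate_field(f, grid, wavelength, spec)
            exc = np.abs(ez) ** 2
            sampled = map_coordinates(exc, [gy, gx], order=1, mode="constant")
            signals[i] += float(np.sum(slab * sampled)) * voxel_volume
    return signals


def _apply_detector(signal: np.ndarray, noise_seed, full_well) -> np.ndarray:
    out = signal
    if noise_seed is not None:
        rng = np.random.default_rng(noise_seed)
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if full_well is not None:
        out = np.clip(out, None, full_well)
    return out


def scan_frame(
    tm_ladder,
    forward: ForwardOperator,
    scene: Scene,
    plan: ScanPlan,
    noise_seed: int | None = None,
    full_well: float | None = None,
    plane_z: float | None = None,
    timestamp: float = 0.0,
) -> Frame:
    """Raster-scan one focal plane of the scene.

    For each scan position the focus is synthesised from the calibrated
    matrix for that plane and pushed through the ground-truth operator;
    the signal integrates density × excitation intensity over the scene
    volume.  Optional Poisson noise (seeded) and full-well clipping model
    the detector.
    """
    if plan.mode != "raster":
        raise ValueError("scan_frame needs a raster plan")
    if plane_z is None:
        plane_z = plan.plane_offsets[0]
    tm = _tm_for_plane(tm_ladder, plane_z)
    positions = plan.raster_positions()
    half = min(plan.field_of_view) / 2
    if half > forward.modes.spec.core_radius:
        warnings.warn("field of view extends beyond the fibre core projection")
    fields = _focus_fields(tm, forward, positions)
    signals = _excitation_signal(
        fields, tm.calibration_plane_z, scene, tm.output_grid,
        tm.wavelength, tm.medium_index,
    )
    signals = _apply_detector(signals, noise_seed, full_well)
    ny, nx = plan.raster_shape()
    img = np.empty((ny, nx))
    idx = 0
    for i in range(ny):
        row = signals[idx:idx + nx]
        img[i] = row if i % 2 == 0 else row[::-1]
        idx += nx
    return Frame(data=img, plan=plan, plane_z=plane_z, timestamp=timestamp)


def scan_zstack(
    tm_ladder,
    forward: ForwardOperator,
    scene: Scene,
    plan: ScanPlan,
    noise_seed: int | None = None,
    full_well: float | None = None,
    timestamp: float = 0.0,
) -> ZStack:
    """One frame per plane offset of the plan, ordered by plane."""
    frames = []
    for i, z in enumerate(plan.plane_offsets):
        seed = None if noise_seed is None else noise_seed + i
        frames.append(
            scan_frame(tm_ladder, forward, scene, plan, noise_seed=seed,
                       full_well=full_well, plane_z=z, timestamp=timestamp)
        )
    return ZStack(frames=frames)


def scan_line(
    tm_ladder,
    forward: ForwardOperator,
    scene: Scene,
    plan: ScanPlan,
    n_sweeps: int,
    drift_velocity: tuple[float, float, float] = (0.0, 0.0, 0.0),
    noise_seed: int | None = None,
    full_well: float | None = None,
) -> Kymograph:
    """Sweep a line trajectory repeatedly, one column per sweep.

    ``drift_velocity`` (vz, vy, vx) in µm/s translates the scene between
    sweeps, so moving structures appear as tilted streaks.  The line rate
    from the plan is stored on the returned kymograph.
    """
    if plan.mode != "line":
        raise ValueError("scan_line needs a line plan")
    plane_z = plan.plane_offsets[0]
    tm = _tm_for_plane(tm_ladder, plane_z)
    positions = np.asarray(plan.trajectory, dtype=float)
    fields = _focus_fields(tm, forward, positions)
    data = np.empty((len(positions), n_sweeps))
    vz, vy, vx = drift_velocity
    base_origin = scene.origin
    rng = np.random.default_rng(noise_seed) if noise_seed is not None else None
    for s in range(n_sweeps):
        t = s / plan.rate
        moved = Scene(
            density=scene.density,
            voxel_size=scene.voxel_size,
            origin=(base_origin[0] + vz * t, base_origin[1] + vy * t,
                    base_origin[2] + vx * t),
            channel=scene.channel,
        )
        sig = _excitation_signal(fields, tm.calibration_plane_z, moved,
                                 tm.output_grid, tm.wavelength, tm.medium_index)
        if rng is not None:
            sig = rng.poisson(np.clip(sig, 0, None)).astype(float)
        if full_well is not None:
            sig = np.clip(sig, None, full_well)
        data[:, s] = sig
    # pixel pitch along the trajectory: mean spacing of its points
    if len(positions) > 1:
        pitch = float(np.mean(np.linalg.norm(np.diff(positions, axis=0), axis=1)))
    else:
        pitch = 1.0
    return Kymograph(data=data, line_rate=plan.rate, pixel_pitch=pitch)


def roi_traces(records: list[Kymograph], background_index: int) -> np.ndarray:
    """Background-subtracted mean-intensity time series per ROI.

    ``records`` holds one kymograph per scanned trajectory, one of which
    (``background_index``) samples a dark reference region.  Each trace
    is mean-over-line-pixels of the ROI minus the same for the
    background, per sweep; ROI order is preserved.
    """
    if len(records) < 2:
        raise ValueError("need at least one ROI and one background record")
    n_sweeps = records[0].data.shape[1]
    for r in records:
        if r.data.shape[1] != n_sweeps:
            raise ValueError("sweep-count mismatch between records")
    bg = records[background_index].data.mean(axis=0)
    traces = [r.data.mean(axis=0) - bg
              for i, r in enumerate(records) if i != background_index]
    return np.stack(traces)
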