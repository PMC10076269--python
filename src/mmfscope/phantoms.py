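"""Seeded synthetic-data generators for every pipeline stage.

Each generator emulates the statistical structure of the instrument's
in-vivo data — fluorescent neurones and vessels on a dark background,
red-blood-cell streaks with cardiac/respiratory velocity modulation,
constant-speed tissue drift through the field of view — and always
returns its ground truth alongside the data, so recovery can be tested
without any external download.  All generators are deterministic under a
fixed seed; noise is applied last.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .scan import Frame, ScanPlan, Scene, ZStack
from .stitch import ScanRecord
from .velocimetry import Kymograph

__all__ = [
    "PhantomSpec",
    "make_scene",
    "make_rbc_kymograph",
    "make_drift_record",
]

#: Synthetic defaults for mouse-like cardiovascular modulation; the
#: record they imitate prints no rates, these are plausible placeholders.
DEFAULT_HEART_HZ = 8.0
DEFAULT_BREATH_HZ = 2.0
DEFAULT_HEART_DEPTH = 0.20
DEFAULT_BREATH_DEPTH = 0.10


@dataclass
class PhantomSpec:
    """What to generate and with which noise.

    ``kind`` is one of beads / neurons / vessels; geometry parameters go
    in ``params`` (sensible defaults per kind); ``noise`` is none /
    poisson / gaussian with ``noise_level`` interpreted as photons per
    density unit (poisson) or additive sigma (gaussian).
    """

    kind: str
    params: dict = field(default_factory=dict)
    noise: str = "none"
    noise_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise not in ("none", "poisson", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise!r}")


def _apply_noise(density: np.ndarray, spec: PhantomSpec,
                 rng: np.random.Generator) -> np.ndarray:
    if spec.noise == "none":
        return density
    if spec.noise == "poisson":
        lam = np.clip(density * spec.noise_level, 0, None)
        return rng.poisson(lam).astype(float) / max(spec.noise_level, 1e-12)
    return np.clip(density + rng.normal(scale=spec.noise_level,
                                        size=density.shape), 0, None)


def _scene_grids(params: dict):
    shape = params.get("shape", (16, 64, 64))
    voxel = params.get("voxel_size", (1.0, 0.5, 0.5))
    origin = params.get("origin", (0.0,
                                   -shape[1] * voxel[1] / 2,
                                   -shape[2] * voxel[2] / 2))
    return shape, voxel, origin


def _beads(params, rng) -> np.ndarray:
    shape, voxel, _ = _scene_grids(params)
    n_points = params.get("n_points", 5)
    amplitude = params.get("amplitude", 1.0)
    density = np.zeros(shape)
    if "positions" in params:
        pts = np.asarray(params["positions"], dtype=int)
    else:
        pts = np.stack([rng.integers(1, s - 1, size=n_points) for s in shape],
                       axis=1)
    for z, y, x in pts:
        density[z, y, x] = amplitude
    return density


def _tube(density: np.ndarray, p0, p1, radius_vox: float, value: float) -> None:
    """Rasterise a cylindrical tube between two voxel-space points."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    n_steps = max(int(np.linalg.norm(p1 - p0) * 2), 2)
    r = int(math.ceil(radius_vox))
    zz, yy, xx = np.meshgrid(*[np.arange(-r, r + 1)] * 3, indexing="ij")
    ball = (zz**2 + yy**2 + xx**2) <= radius_vox**2
    for t in np.linspace(0, 1, n_steps):
        c = np.rint(p0 + t * (p1 - p0)).astype(int)
        sl = []
        bl = []
        ok = True
        for ax, cc in enumerate(c):
            lo, hi = cc - r, cc + r + 1
            blo = max(0, -lo)
            bhi = ball.shape[ax] - max(0, hi - density.shape[ax])
            lo, hi = max(lo, 0), min(hi, density.shape[ax])
            if lo >= hi:
                ok = False
                break
            sl.append(slice(lo, hi))
            bl.append(slice(blo, bhi))
        if ok:
            region = density[tuple(sl)]
            np.maximum(region, value * ball[tuple(bl)], out=region)


def _neurons(params, rng) -> np.ndarray:
    shape, voxel, _ = _scene_grids(params)
    n_somata = params.get("n_somata", 3)
    n_dendrites = params.get("n_dendrites_per_soma", 2)
    density = np.zeros(shape)
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    for _ in range(n_somata):
        c = np.array([rng.uniform(0.1 * s, 0.9 * s) for s in shape])
        # somata 5-15 µm across; semi-axes in voxels per axis
        diam = rng.uniform(5.0, 15.0)
        semi = np.array([diam / 2 / v for v in voxel]) * rng.uniform(0.8, 1.2, 3)
        mask = (((zz - c[0]) / semi[0]) ** 2 + ((yy - c[1]) / semi[1]) ** 2
                + ((xx - c[2]) / semi[2]) ** 2) <= 1.0
        np.maximum(density, mask * rng.uniform(0.7, 1.0), out=density)
        for _ in range(n_dendrites):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            length = rng.uniform(10, 30) / np.mean(voxel)
            end = c + direction * length
            radius = 0.5 / np.mean(voxel)  # ≈1 µm diameter dendrite
            _tube(density, c, end, max(radius, 0.6), rng.uniform(0.3, 0.6))
            # spine bumps along the dendrite
            for _ in range(rng.integers(1, 4)):
                t = rng.uniform(0.3, 0.9)
                s = np.rint(c + direction * length * t).astype(int)
                if np.all((s >= 0) & (s < np.array(shape))):
                    density[tuple(s)] = max(density[tuple(s)], 0.8)
    return density


def _vessels(params, rng) -> np.ndarray:
    shape, voxel, _ = _scene_grids(params)
    n_vessels = params.get("n_vessels", 2)
    hollow = params.get("hollow", False)
    density = np.zeros(shape)
    for _ in range(n_vessels):
        diam = rng.uniform(3.0, 10.0)
        radius = diam / 2 / np.mean(voxel)
        p0 = np.array([rng.uniform(0, s) for s in shape])
        direction = rng.normal(size=3)
        direction[0] *= 0.3  # vessels run mostly laterally
        direction /= np.linalg.norm(direction)
        p1 = p0 + direction * max(shape) * 1.5
        _tube(density, p0, p1, radius, 1.0)
        if hollow:
            lumen = np.zeros_like(density)
            _tube(lumen, p0, p1, max(radius - 1.5 / np.mean(voxel), 0.5), 1.0)
            density[lumen > 0] = 0.15
    return density


def make_scene(spec: PhantomSpec) -> Scene:
    """Generate a 3-D fluorophore-density scene.

    beads: isolated sub-resolution points (PSF tests); neurons: ellipsoid
    somata with dendrite tubes and spine bumps; vessels: lateral tubes,
    optionally hollow-walled.  Background is exactly zero.
    """
    rng = np.random.default_rng(spec.seed)
    makers = {"beads": _beads, "neurons": _neurons, "vessels": _vessels}
    if spec.kind not in makers:
        raise ValueError(f"unknown phantom kind {spec.kind!r}")
    shape, voxel, origin = _scene_grids(spec.params)
    density = makers[spec.kind](spec.params, rng)
    density = _apply_noise(density, spec, rng)
    return Scene(density=density, voxel_size=tuple(voxel), origin=tuple(origin),
                 channel=spec.params.get("channel", "ch0"))


def make_rbc_kymograph(
    v_profile,
    n_lines: int = 1000,
    n_pixels: int = 64,
    streak_density: float = 0.08,
    contrast_sign: int = -1,
    streak_width: float = 2.0,
    row_gains: np.ndarray | str | None = None,
    noise: str = "none",
    noise_level: float = 0.0,
    line_rate: float = 1000.0,
    pixel_pitch: float = 0.5,
    seed: int = 0,
    wrap: bool = True,
):
    """Synthesise a red-blood-cell line-scan record with known velocity.

    ``v_profile`` is a scalar, an array per column, or a callable of
    time (s) giving velocity in px/line.  Cells advance by the integrated
    velocity; with ``wrap`` they recirculate around the periodic line
    (steady flow), otherwise they stream through once, which produces
    genuinely sparse records at low ``streak_density``.  With
    ``contrast_sign=-1`` cells are dark streaks in bright plasma, the
    appearance of unlabelled cells in FITC-dextran; per-row gains emulate
    the row-to-row response differences of real records.

    Returns ``(Kymograph, v_true)`` with ``v_true`` in px/line per column.
    """
    if n_lines < 2:
        raise ValueError("need at least 2 lines")
    rng = np.random.default_rng(seed)
    t = np.arange(n_lines) / line_rate
    if callable(v_profile):
        v = np.asarray([float(v_profile(ti)) for ti in t])
    else:
        v = np.broadcast_to(np.asarray(v_profile, dtype=float), (n_lines,)).copy()
    disp = np.concatenate([[0.0], np.cumsum(v[:-1])])  # px, at each column

    rows = np.arange(n_pixels)
    base = np.ones((n_pixels, n_lines)) if contrast_sign < 0 else np.zeros((n_pixels, n_lines))
    sigma = streak_width / 2.354  # FWHM -> sigma
    if wrap:
        n_cells = max(int(round(streak_density * n_pixels)), 1)
        p0 = rng.uniform(0, n_pixels, size=n_cells)
    else:
        lo = min(disp.min(), 0.0) - n_pixels
        hi = max(disp.max(), 0.0) + n_pixels
        span = (hi - lo) + n_pixels
        n_cells = max(int(round(streak_density * span)), 1)
        p0 = rng.uniform(-hi, n_pixels - lo, size=n_cells)
    amp = rng.uniform(0.6, 1.0, size=n_cells)
    for c in range(n_cells):
        centre = p0[c] + disp  # (n_lines,)
        if wrap:
            centre = centre % n_pixels
            d = np.abs(rows[:, None] - centre[None, :])
            d = np.minimum(d, n_pixels - d)  # periodic line
        else:
            d = np.abs(rows[:, None] - centre[None, :])
        streak = amp[c] * np.exp(-0.5 * (d / sigma) ** 2)
        base += contrast_sign * streak
    base = np.clip(base, 0.0, None)

    if row_gains is None:
        gains = np.ones(n_pixels)
    elif isinstance(row_gains, str) and row_gains == "random":
        gains = rng.uniform(0.5, 2.0, size=n_pixels)
    else:
        gains = np.asarray(row_gains, dtype=float)
    data = base * gains[:, None]

    if noise == "poisson":
        data = rng.poisson(np.clip(data * noise_level, 0, None)) / max(noise_level, 1e-12)
    elif noise == "gaussian":
        data = data + rng.normal(scale=noise_level, size=data.shape)
    elif noise != "none":
        raise ValueError(f"unknown noise model {noise!r}")

    k = Kymograph(data=data, line_rate=line_rate, pixel_pitch=pixel_pitch)
    return k, v


def modulated_velocity(mean: float, depth_heart: float = DEFAULT_HEART_DEPTH,
                       depth_breath: float = DEFAULT_BREATH_DEPTH,
                       f_heart: float = DEFAULT_HEART_HZ,
                       f_breath: float = DEFAULT_BREATH_HZ,
                       extra: list[tuple[float, float]] | None = None):
    """Velocity profile v(t) with cardiac and respiratory modulation."""
    extra = extra or []

    def v(t: float) -> float:
        out = mean * (1.0
                      + depth_heart * math.sin(2 * math.pi * f_heart * t)
                      + depth_breath * math.sin(2 * math.pi * f_breath * t))
        for f, depth in extra:
            out += mean * depth * math.sin(2 * math.pi * f * t)
        return out

    return v


def make_drift_record(
    scene: Scene,
    speed: float,
    plan: ScanPlan,
    frame_rate: float = 0.3,
    n_stacks: int = 10,
    noise: str = "none",
    noise_level: float = 0.0,
    seed: int = 0,
) -> ScanRecord:
    """Image a scene drifting through the field of view at constant speed.

    Stacks are sampled directly from the density grid (ideal imaging; the
    stitcher needs geometry and intensities, not diffraction): stack *i*
    sees the scene window starting ``speed / frame_rate · i`` µm along
    the drift (row) axis.  Raises when the per-stack advance exceeds the
    frame extent (no overlap left to stitch).
    """
    ny, nx = plan.raster_shape()
    dz, dy, dx = scene.voxel_size
    step_um = speed / frame_rate
    step_px = step_um / dy
    if step_px >= ny:
        raise ValueError("drift per stack exceeds the frame extent: no overlap")
    rng = np.random.default_rng(seed)
    n_sc_rows = scene.density.shape[1]
    need = int(math.ceil((n_stacks - 1) * step_px)) + ny
    if n_sc_rows < need:
        raise ValueError(
            f"scene too short along the drift axis: {n_sc_rows} rows < {need}")
    planes = []
    zs = scene.z_planes()
    for z in plan.plane_offsets:
        iz = int(np.argmin(np.abs(zs - z)))
        planes.append(scene.density[iz])
    stacks = []
    from scipy.ndimage import shift as nd_shift

    for i in range(n_stacks):
        off = i * step_px
        i0 = int(math.floor(off))
        frac = off - i0
        frames = []
        for z, plane in zip(plan.plane_offsets, planes):
            window = plane[i0:i0 + ny + 1, :nx]
            if frac > 1e-12:
                img = nd_shift(window, (-frac, 0), order=1,
                               mode="nearest")[:ny]
            else:
                img = window[:ny].copy()
            if noise == "poisson":
                img = rng.poisson(np.clip(img * noise_level, 0, None)) / max(noise_level, 1e-12)
            elif noise == "gaussian":
                img = np.clip(img + rng.normal(scale=noise_level, size=img.shape), 0, None)
            frames.append(Frame(data=img, plan=plan, plane_z=z,
                                timestamp=i / frame_rate))
        stacks.append(ZStack(frames=frames))
    return ScanRecord(stacks=stacks, frame_rate=frame_rate,
                      nominal_speed=speed, probe_geometry="side")
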