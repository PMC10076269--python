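"""Input-modulation basis and kinoform synthesis.

The calibration input set is a family of truncated plane waves whose
transverse tilts sample the fibre NA disk — the practical choice when the
modulator is a digital micro-mirror device (DMD) driven with gratings.
A focus kinoform is obtained by phase-conjugating one row of the
transmission matrix.  A Lee-style binary off-axis encoder/decoder models
the DMD's binary amplitude modulation: the first diffraction order at the
carrier frequency carries the complex field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fiber import FiberSpec
from .grid import FieldGrid, normalize_power

__all__ = [
    "InputBasis",
    "Modulation",
    "CarrierSpec",
    "make_input_basis",
    "phase_conjugate_kinoform",
    "binarize_lee",
    "decode_first_order",
]


@dataclass
class InputBasis:
    """Ordered set of unit-power tilted plane waves on the proximal facet.

    ``tilts`` holds the transverse wavenumber (ky, kx) of each element in
    rad/µm; all tilts lie inside the fibre NA disk, ordered spiralling out
    from zero tilt.
    """

    grid: FieldGrid
    spec: FiberSpec
    tilts: np.ndarray  # (n_elements, 2) as (ky, kx)
    _fields: np.ndarray = field(repr=False, default=None)

    @property
    def n_elements(self) -> int:
        return len(self.tilts)

    def element(self, j: int) -> np.ndarray:
        return self.field_matrix()[:, j].reshape(self.grid.shape)

    def field_matrix(self) -> np.ndarray:
        """Basis fields as columns of an ``(n_pixels^2, n)`` array."""
        if self._fields is None:
            y, x = self.grid.coords()
            aperture = (np.hypot(x, y) <= self.spec.core_radius)
            cols = []
            for ky, kx in self.tilts:
                f = np.exp(1j * (kx * x + ky * y)) * aperture
                cols.append(normalize_power(f, self.grid).ravel())
            self._fields = np.stack(cols, axis=1)
        return self._fields


def max_distinguishable_tilts(grid: FieldGrid, spec: FiberSpec) -> int:
    """Number of grid-resolvable tilts inside the NA disk."""
    k_na = spec.k0 * spec.na
    dk = 2.0 * math.pi / grid.extent
    return max(int(math.pi * k_na**2 / dk**2), 1)


def make_input_basis(n_elements: int, grid: FieldGrid, spec: FiberSpec) -> InputBasis:
    """Uniform disk sampling of tilt wavenumber space inside the NA.

    Tilts sit on a square lattice in k-space whose pitch is chosen so the
    NA disk holds at least ``n_elements`` points; the first ``n_elements``
    in a spiral order (radius, then angle) are used.  Element 0 is always
    the flat (zero-tilt) field.
    """
    if n_elements < 1:
        raise ValueError("n_elements must be >= 1")
    n_max = max_distinguishable_tilts(grid, spec)
    if n_elements > n_max:
        raise ValueError(
            f"n_elements {n_elements} exceeds the {n_max} tilts this grid "
            "can distinguish inside the NA"
        )
    k_na = spec.k0 * spec.na
    # lattice pitch so that ~1.3 * n_elements points fall in the disk
    dk = k_na * math.sqrt(math.pi / (1.3 * n_elements))
    dk = min(dk, k_na)  # always include the origin neighbourhood
    m = int(math.ceil(k_na / dk))
    qs = np.arange(-m, m + 1) * dk
    kyy, kxx = np.meshgrid(qs, qs, indexing="ij")
    kr = np.hypot(kxx, kyy)
    inside = kr <= k_na
    pts = np.stack([kyy[inside], kxx[inside]], axis=1)
    radii = np.hypot(pts[:, 0], pts[:, 1])
    angles = np.mod(np.arctan2(pts[:, 0], pts[:, 1]), 2 * math.pi)
    order = np.lexsort((angles, np.round(radii / dk * 2).astype(int)))
    pts = pts[order]
    if len(pts) < n_elements:  # safety margin failed; densify
        return make_input_basis_dense(n_elements, grid, spec, dk * 0.8)
    return InputBasis(grid=grid, spec=spec, tilts=pts[:n_elements])


def make_input_basis_dense(n_elements, grid, spec, dk):
    k_na = spec.k0 * spec.na
    m = int(math.ceil(k_na / dk))
    qs = np.arange(-m, m + 1) * dk
    kyy, kxx = np.meshgrid(qs, qs, indexing="ij")
    kr = np.hypot(kxx, kyy)
    inside = kr <= k_na
    pts = np.stack([kyy[inside], kxx[inside]], axis=1)
    radii = np.hypot(pts[:, 0], pts[:, 1])
    angles = np.mod(np.arctan2(pts[:, 0], pts[:, 1]), 2 * math.pi)
    order = np.lexsort((angles, np.round(radii / dk * 2).astype(int)))
    pts = pts[order]
    if len(pts) < n_elements:
        return make_input_basis_dense(n_elements, grid, spec, dk * 0.8)
    return InputBasis(grid=grid, spec=spec, tilts=pts[:n_elements])


@dataclass
class Modulation:
    """A modulation-plane pattern: complex field or binary mirror map."""

    field: np.ndarray
    kind: str = "complex"  # "complex" | "binary"
    coefficients: np.ndarray | None = None  # input-basis weights, if known

    def __post_init__(self) -> None:
        if self.kind not in ("complex", "binary"):
            raise ValueError(f"unknown modulation kind {self.kind!r}")
        if self.kind == "binary":
            vals = np.unique(self.field)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("binary modulation must take values {0, 1}")


@dataclass(frozen=True)
class CarrierSpec:
    """Off-axis carrier for binary (DMD-style) hologram encoding.

    ``frequency`` is the carrier in cycles per pixel along (y, x); its
    magnitude must lie in (0, 0.5].  ``filter_radius_frac`` sets the
    Fourier-filter disk radius for decoding as a fraction of the carrier
    magnitude.  The default of 0.1 cycles/px (10 mirrors per fringe)
    keeps the duty-cycle quantisation noise of the binary pattern low
    enough for faithful first-order encoding of smooth modulations.
    """

    frequency: tuple[float, float] = (0.0, 0.1)
    filter_radius_frac: float = 0.3

    @property
    def magnitude(self) -> float:
        return math.hypot(*self.frequency)

    def __post_init__(self) -> None:
        if not 0 < self.magnitude <= 0.5:
            raise ValueError("carrier magnitude must lie in (0, 0.5] cycles/pixel")


def upsample_field(field: np.ndarray, factor: int) -> np.ndarray:
    """Band-limited upsampling by Fourier zero-padding.

    Binary off-axis encoding needs the carrier to clear the modulation's
    band; on the facet-resolution grid the band nearly fills Nyquist, so
    patterns are synthesised on a finer plane — the physical situation,
    where the modulator has many more mirrors than the fibre resolves.
    """
    n = field.shape[0]
    spec = np.fft.fftshift(np.fft.fft2(field))
    big = np.zeros((n * factor, n * factor), dtype=complex)
    lo = (n * factor - n) // 2
    big[lo:lo + n, lo:lo + n] = spec
    return np.fft.ifft2(np.fft.ifftshift(big)) * factor**2


def downsample_field(field: np.ndarray, factor: int) -> np.ndarray:
    """Inverse of :func:`upsample_field` (Fourier crop)."""
    n_big = field.shape[0]
    n = n_big // factor
    spec = np.fft.fftshift(np.fft.fft2(field))
    lo = (n_big - n) // 2
    small = spec[lo:lo + n, lo:lo + n]
    return np.fft.ifft2(np.fft.ifftshift(small)) / factor**2


def project_onto_basis(field: np.ndarray, basis: InputBasis) -> np.ndarray:
    """Least-squares coefficients of a field in the input basis."""
    coeffs, *_ = np.linalg.lstsq(basis.field_matrix(), field.ravel(), rcond=None)
    return coeffs


def phase_conjugate_kinoform(tm, target: int) -> Modulation:
    """Kinoform focusing at output sample ``target`` by phase conjugation.

    Returns the unit-power complex modulation Σ_j conj(T[target, j]) b_j.
    Among modulations built from the calibrated row this maximises the
    intensity delivered to the target.
    """
    mat = tm.matrix
    if not 0 <= target < mat.shape[0]:
        raise IndexError(f"target {target} outside {mat.shape[0]} output samples")
    coeffs = np.conj(mat[target, :])
    norm = np.linalg.norm(coeffs)
    if norm == 0:
        raise ValueError("target row is zero; no light reaches this sample")
    coeffs = coeffs / norm
    fields = tm.input_basis.field_matrix()
    grid = tm.input_basis.grid
    f = (fields @ coeffs).reshape(grid.shape)
    f = normalize_power(f, grid)
    return Modulation(field=f, kind="complex", coefficients=coeffs)


def binarize_lee(mod: Modulation, carrier: CarrierSpec) -> Modulation:
    """Lee-style binary off-axis encoding of a complex modulation.

    Mirror ON where cos(2π f·r + arg m) exceeds a duty threshold set by
    the local normalised amplitude A: threshold = sqrt(1 − A²), so the
    first-order diffracted amplitude is ∝ A e^{i arg m}.
    """
    if mod.kind != "complex":
        raise ValueError("binarize_lee expects a complex modulation")
    if carrier.magnitude == 0:
        raise ValueError("zero carrier frequency gives no off-axis separation")
    f = mod.field
    amp = np.abs(f)
    mx = amp.max()
    if mx == 0:
        return Modulation(field=np.zeros(f.shape), kind="binary")
    a = amp / mx
    phase = np.angle(f)
    ny, nx = f.shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    fy, fx = carrier.frequency
    grating = np.cos(2 * np.pi * (fy * yy + fx * xx) + phase)
    # small epsilon keeps the comparison stable where the grating crosses
    # the threshold exactly (e.g. cos at odd multiples of π/2 for a = 1)
    pattern = (grating - np.sqrt(1 - a**2) > 1e-9).astype(np.uint8)
    return Modulation(field=pattern, kind="binary")


def decode_first_order(pattern: Modulation, carrier: CarrierSpec) -> Modulation:
    """Recover the complex field encoded in a binary off-axis hologram.

    Fourier-filters a disk around the carrier frequency and demodulates
    to baseband.  Inverse of :func:`binarize_lee` up to a real scale.
    """
    p = np.asarray(pattern.field, dtype=float)
    ny, nx = p.shape
    spec = np.fft.fft2(p)
    fy = np.fft.fftfreq(ny)
    fx = np.fft.fftfreq(nx)
    fyy, fxx = np.meshgrid(fy, fx, indexing="ij")
    cy, cx = carrier.frequency
    rad = carrier.filter_radius_frac * carrier.magnitude
    # periodic distance to the carrier in frequency space
    dy = (fyy - cy + 0.5) % 1.0 - 0.5
    dx = (fxx - cx + 0.5) % 1.0 - 0.5
    mask = np.hypot(dy, dx) <= rad
    filtered = np.fft.ifft2(spec * mask)
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    demod = filtered * np.exp(-2j * np.pi * (cy * yy + cx * xx))
    return Modulation(field=demod, kind="complex")
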