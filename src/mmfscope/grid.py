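"""Square sampling grid for transverse optical fields.

All lengths are micrometres.  The fibre axis passes through the grid
centre, which for an ``n``-pixel side lies at pixel index ``n // 2``
(the FFT convention), so even grids are centred half a pixel off the
geometric middle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class FieldGrid:
    """Uniformly sampled square grid on which transverse fields live.

    Parameters
    ----------
    n_pixels:
        Number of samples per side.
    pitch:
        Sample spacing in micrometres.
    """

    n_pixels: int
    pitch: float

    def __post_init__(self) -> None:
        if self.n_pixels < 2:
            raise ValueError("grid needs at least 2 pixels per side")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")

    @property
    def extent(self) -> float:
        """Physical side length in micrometres."""
        return self.n_pixels * self.pitch

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_pixels, self.n_pixels)

    @property
    def n_samples(self) -> int:
        return self.n_pixels * self.n_pixels

    def axis(self) -> np.ndarray:
        """1-D coordinate axis (µm) with the origin at ``n // 2``."""
        n = self.n_pixels
        return (np.arange(n) - n // 2) * self.pitch

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """``(y, x)`` coordinate arrays of shape ``(n, n)``."""
        ax = self.axis()
        return np.meshgrid(ax, ax, indexing="ij")

    def radius(self) -> np.ndarray:
        y, x = self.coords()
        return np.hypot(x, y)

    def kaxis(self) -> np.ndarray:
        """Angular spatial frequencies (rad/µm) in FFT order."""
        return 2.0 * np.pi * np.fft.fftfreq(self.n_pixels, d=self.pitch)

    def kgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """``(ky, kx)`` angular-frequency arrays in FFT order."""
        k = self.kaxis()
        return np.meshgrid(k, k, indexing="ij")

    def index_of(self, y: float, x: float) -> int:
        """Flat index of the pixel nearest to physical position ``(y, x)``."""
        n = self.n_pixels
        iy = int(round(y / self.pitch)) + n // 2
        ix = int(round(x / self.pitch)) + n // 2
        if not (0 <= iy < n and 0 <= ix < n):
            raise IndexError(f"position ({y}, {x}) µm outside the grid")
        return iy * n + ix

    def position_of(self, flat_index: int) -> tuple[float, float]:
        """Physical ``(y, x)`` position (µm) of a flat pixel index."""
        n = self.n_pixels
        iy, ix = divmod(int(flat_index), n)
        return ((iy - n // 2) * self.pitch, (ix - n // 2) * self.pitch)


def field_power(field: np.ndarray, grid: FieldGrid) -> float:
    """Total power of a sampled field, ``sum |E|^2 * pitch^2``."""
    return float(np.sum(np.abs(field) ** 2) * grid.pitch**2)


def normalize_power(field: np.ndarray, grid: FieldGrid) -> np.ndarray:
    """Scale a field to unit power."""
    p = field_power(field, grid)
    if p == 0:
        raise ValueError("cannot normalise a zero field")
    return field / np.sqrt(p)
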