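"""Blood-flow velocimetry from line-scan kymographs.

Red blood cells crossing a repeatedly scanned line appear as tilted
streaks in the kymograph (rows = pixels along the line, columns =
successive sweeps); the streak slope is the flow velocity in pixels per
line.  The estimator morphs a window of neighbouring columns — each
shifted vertically by an integer number of pixels to counteract an
assumed velocity — and scores the assumption by the standard deviation
across the window, averaged over rows: the minimum marks the best match,
refined by a second-order polynomial through the minimum and its two
neighbouring candidates.

Before estimation every row is normalised to a common mean and standard
deviation, removing the row-to-row gain structure that tissue scattering
and calibration noise imprint on real records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import periodogram

__all__ = [
    "Kymograph",
    "VelocimetryConfig",
    "VelocityTrace",
    "normalize_rows",
    "velocity_at",
    "velocity_trace",
    "to_physical",
    "power_spectrum",
]


@dataclass
class Kymograph:
    """Line-scan record: rows = trajectory pixels, columns = sweeps."""

    data: np.ndarray
    line_rate: float  # Hz
    pixel_pitch: float  # µm per trajectory pixel
    row_valid: np.ndarray | None = None  # bool per row; None = all valid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise ValueError("kymograph needs a 2-D array with >= 2 columns")
        if self.line_rate <= 0 or self.pixel_pitch <= 0:
            raise ValueError("line_rate and pixel_pitch must be positive")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class VelocimetryConfig:
    """Estimator settings.

    ``half_window`` columns are taken on each side of the evaluated
    column (the window therefore spans 2·half_window + 1 columns,
    including the centre).  ``v_grid`` lists candidate velocities in
    px/line; ``min_valid_rows`` is the smallest number of fully valid
    rows a candidate may be scored on.  Left at None it resolves to a
    quarter of the record's rows (at least 8): large candidate shifts
    crop the record, and scoring a candidate on a handful of surviving
    rows invites spurious minima on noiseless backgrounds.
    """

    half_window: int = 4
    v_grid: np.ndarray = field(
        default_factory=lambda: np.arange(-10.0, 10.0 + 1e-9, 0.25))
    min_valid_rows: int | None = None
    #: Minimum number of rows that actually vary inside the evaluation
    #: window; a window of locally constant rows (no streak crossing it)
    #: carries no velocity information and is flagged as a gap.
    min_active_rows: int = 2

    def __post_init__(self) -> None:
        if self.half_window < 1:
            raise ValueError("half_window must be >= 1")
        v = np.asarray(self.v_grid, dtype=float)
        if v.size == 0 or np.any(np.diff(v) <= 0):
            raise ValueError("v_grid must be non-empty and sorted")
        object.__setattr__(self, "v_grid", v)

    def resolve_min_rows(self, n_rows: int) -> int:
        if self.min_valid_rows is not None:
            return self.min_valid_rows
        return max(8, n_rows // 4)


@dataclass
class VelocityTrace:
    """Per-column velocity estimate with diagnostics."""

    t: np.ndarray  # seconds
    v: np.ndarray  # px/line (or µm/s after to_physical)
    units: str = "px/line"
    valid: np.ndarray | None = None
    metric_curves: np.ndarray | None = None  # (n_candidates, n_columns)
    v_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.t) != len(self.v):
            raise ValueError("t and v must have equal length")
        if self.valid is None:
            self.valid = np.isfinite(self.v)


def normalize_rows(k: Kymograph) -> Kymograph:
    """Affinely map every row to mean 0 and standard deviation 1.

    Zero-variance rows cannot carry velocity information; they are left
    at zero and flagged in ``row_valid`` so the estimator skips them.
    Idempotent.
    """
    data = k.data
    mean = data.mean(axis=1, keepdims=True)
    std = data.std(axis=1, keepdims=True)
    valid = std[:, 0] > 0
    if not np.any(valid):
        raise ValueError("all rows have zero variance")
    out = np.zeros_like(data)
    out[valid] = (data[valid] - mean[valid]) / std[valid]
    if k.row_valid is not None:
        valid = valid & k.row_valid
    return Kymograph(data=out, line_rate=k.line_rate,
                     pixel_pitch=k.pixel_pitch, row_valid=valid)


def _morph_metric_all_columns(data: np.ndarray, row_valid: np.ndarray,
                              cfg: VelocimetryConfig):
    """Metric(v, column) for all interior columns at once.

    For candidate v, the column at window offset δ is shifted vertically
    by round(v·δ) px; rows pushed out of range are cropped, not wrapped.
    Returns (metric array (n_v, n_cols) with NaN where fewer than
    ``min_valid_rows`` rows survive, per-candidate valid-row counts).
    """
    from scipy.ndimage import maximum_filter1d, minimum_filter1d

    n_rows, n_cols = data.shape
    w = cfg.half_window
    offsets = np.arange(-w, w + 1)
    nan_data = data.copy()
    nan_data[~row_valid] = np.nan
    metrics = np.full((len(cfg.v_grid), n_cols), np.nan)
    # columns whose window shows no intensity variation in any row carry
    # no velocity information at all: flag them as gaps up front
    size = 2 * w + 1
    local_range = (maximum_filter1d(data, size, axis=1)
                   - minimum_filter1d(data, size, axis=1))
    active = (local_range > 1e-12) & row_valid[:, None]
    dead_cols = active.sum(axis=0) < cfg.min_active_rows
    for vi, v in enumerate(cfg.v_grid):
        shifts = np.rint(v * offsets).astype(int)
        lo = max(0, -shifts.min())
        hi = n_rows - max(0, shifts.max())
        if hi - lo < 1:
            continue
        n_kept = hi - lo
        stack = np.full((n_kept, n_cols, len(offsets)), np.nan)
        for di, (d, s) in enumerate(zip(offsets, shifts)):
            c_lo, c_hi = max(0, -d), n_cols - max(0, d)
            stack[:, c_lo:c_hi, di] = nan_data[lo + s:hi + s, c_lo + d:c_hi + d]
        row_std = np.std(stack, axis=2)  # NaN wherever any window entry invalid
        counts = np.sum(np.isfinite(row_std), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            m = np.nanmean(row_std, axis=0)
        m[counts < cfg.resolve_min_rows(n_rows)] = np.nan
        metrics[vi] = m
    metrics[:, dead_cols] = np.nan
    return metrics


def _refine_minimum(v_grid: np.ndarray, metric: np.ndarray) -> float:
    """Parabolic refinement through the minimum candidate and its two
    neighbours; ties broken toward smaller |v|."""
    finite = np.isfinite(metric)
    if not np.any(finite):
        return float("nan")
    if finite.sum() > 1 and np.nanmax(metric) - np.nanmin(metric) < 1e-12:
        # flat candidate curve: nothing in the window constrains the
        # velocity (no streak); report a gap instead of a fake estimate
        return float("nan")
    mmin = np.nanmin(metric)
    candidates = np.nonzero(finite & (metric <= mmin + 0.0))[0]
    j = candidates[np.argmin(np.abs(v_grid[candidates]))]
    if j == 0 or j == len(v_grid) - 1:
        return float(v_grid[j])
    if not (np.isfinite(metric[j - 1]) and np.isfinite(metric[j + 1])):
        return float(v_grid[j])
    y0, y1, y2 = metric[j - 1], metric[j], metric[j + 1]
    denom = y0 - 2 * y1 + y2
    if denom <= 0:
        return float(v_grid[j])
    delta = 0.5 * (y0 - y2) / denom
    step = v_grid[j + 1] - v_grid[j]
    return float(v_grid[j] + np.clip(delta, -1, 1) * step)


def velocity_at(k: Kymograph, column: int, cfg: VelocimetryConfig | None = None):
    """Velocity estimate (px/line) and metric curve for one column.

    Edge columns are evaluated with a truncated window.  Raises when no
    candidate retains ``min_valid_rows`` rows.
    """
    if cfg is None:
        cfg = VelocimetryConfig()
    data = k.data
    if not 0 <= column < data.shape[1]:
        raise IndexError("column out of range")
    row_valid = (k.row_valid if k.row_valid is not None
                 else np.ones(data.shape[0], dtype=bool))
    w = cfg.half_window
    offsets = np.arange(max(-w, -column), min(w, data.shape[1] - 1 - column) + 1)
    win = data[:, column + offsets[0]:column + offsets[-1] + 1]
    locally_active = (win.max(axis=1) - win.min(axis=1) > 1e-12) & row_valid
    if locally_active.sum() < cfg.min_active_rows:
        raise ValueError("window shows no intensity variation: gap")
    nan_data = data.copy()
    nan_data[~row_valid] = np.nan
    n_rows = data.shape[0]
    metric = np.full(len(cfg.v_grid), np.nan)
    for vi, v in enumerate(cfg.v_grid):
        shifts = np.rint(v * offsets).astype(int)
        lo = max(0, -shifts.min())
        hi = n_rows - max(0, shifts.max())
        if hi - lo < 1:
            continue
        block = np.stack(
            [nan_data[lo + s:hi + s, column + d] for d, s in zip(offsets, shifts)],
            axis=1,
        )
        row_std = np.std(block, axis=1)
        count = np.sum(np.isfinite(row_std))
        if count >= cfg.resolve_min_rows(n_rows):
            metric[vi] = np.nanmean(row_std)
    if not np.any(np.isfinite(metric)):
        raise ValueError("no candidate velocity retains enough valid rows")
    return _refine_minimum(cfg.v_grid, metric), metric


def velocity_trace(k: Kymograph, cfg: VelocimetryConfig | None = None,
                   keep_metrics: bool = False) -> VelocityTrace:
    """Velocity estimate for every column of a kymograph.

    Row normalisation is applied first if the record is not already
    normalised.  Interior columns are evaluated with the full window in
    a vectorised pass; edge columns use a truncated window.  Columns
    where no candidate survives are NaN and flagged invalid.
    """
    if cfg is None:
        cfg = VelocimetryConfig()
    if k.row_valid is None:
        k = normalize_rows(k)
    data = k.data
    n_cols = data.shape[1]
    row_valid = k.row_valid
    metrics = _morph_metric_all_columns(data, row_valid, cfg)
    v = np.full(n_cols, np.nan)
    w = cfg.half_window
    for c in range(n_cols):
        if w <= c < n_cols - w:
            v[c] = _refine_minimum(cfg.v_grid, metrics[:, c])
        else:
            try:
                v[c], metrics[:, c] = velocity_at(k, c, cfg)
            except ValueError:
                v[c] = np.nan
    t = np.arange(n_cols) / k.line_rate
    return VelocityTrace(
        t=t, v=v, units="px/line", valid=np.isfinite(v),
        metric_curves=metrics if keep_metrics else None,
        v_grid=cfg.v_grid if keep_metrics else None,
    )


def to_physical(trace: VelocityTrace, k: Kymograph) -> VelocityTrace:
    """Convert px/line to µm/s: v · pixel_pitch · line_rate."""
    if trace.units != "px/line":
        raise ValueError("trace is not in px/line units")
    if k.pixel_pitch is None or k.line_rate is None:
        raise ValueError("kymograph lacks pixel_pitch or line_rate metadata")
    return VelocityTrace(
        t=trace.t,
        v=trace.v * k.pixel_pitch * k.line_rate,
        units="um/s",
        valid=trace.valid.copy(),
        metric_curves=trace.metric_curves,
        v_grid=trace.v_grid,
    )


def power_spectrum(trace: VelocityTrace):
    """Mean-removed periodogram of a velocity trace.

    Gaps (invalid columns) are linearly interpolated first; a warning
    reports how many samples were filled.  Frequency resolution is the
    reciprocal record duration.
    """
    v = np.asarray(trace.v, dtype=float)
    t = np.asarray(trace.t, dtype=float)
    if len(v) < 4:
        raise ValueError("trace too short for a spectrum (need >= 4 samples)")
    good = np.isfinite(v)
    if not np.any(good):
        raise ValueError("trace has no valid samples")
    if not np.all(good):
        warnings.warn(f"interpolating {np.sum(~good)} gap samples before FFT")
        v = v.copy()
        v[~good] = np.interp(t[~good], t[good], v[good])
    fs = 1.0 / (t[1] - t[0])
    f, p = periodogram(v - v.mean(), fs=fs)
    return f, p
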