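"""High-level measurement recipes used for validation and benchmarking.

These functions run the full simulation chain end to end — ground-truth
fibre operator, interferometric calibration, kinoform synthesis, focus
metrology, velocimetry on synthetic records — and return the measured
quantities.  They are what the acceptance script and the heavier tests
call; parameters default to the desk-scale study conditions.
"""

from __future__ import annotations

import numpy as np

from .calibration import FocusReport, acquire_tm, synthesize_focus
from .fiber import FiberSpec, ground_truth_operator, solve_modes
from .grid import FieldGrid
from .holography import make_input_basis
from .phantoms import make_rbc_kymograph
from .velocimetry import VelocimetryConfig, velocity_trace

__all__ = [
    "measure_focus_rayleigh",
    "velocimetry_amplitude_transfer",
    "velocimetry_passband_edge",
]


def measure_focus_rayleigh(
    core_um: float = 20.0,
    na: float = 0.37,
    wavelength: float = 0.488,
    n_pixels: int = 128,
    pitch: float = 0.25,
    n_basis: int = 300,
    seed: int = 0,
    coupling: float = 1.0,
) -> FocusReport:
    """Measured Rayleigh radius of a phase-conjugation focus.

    Runs the whole chain: solve the guided modes, build the seeded
    fibre operator, acquire the transmission matrix by 4-step
    phase-shifting interferometry, synthesise a central focus by phase
    conjugation, and report the radius of the first minimum of the
    azimuthally averaged intensity profile.
    """
    spec = FiberSpec(core_diameter=core_um, na=na, wavelength=wavelength)
    grid = FieldGrid(n_pixels, pitch)
    modes = solve_modes(spec, grid)
    basis = make_input_basis(n_basis, grid, spec)
    op = ground_truth_operator(modes, basis, coupling_strength=coupling,
                               seed=seed)
    tm = acquire_tm(op, basis)
    _, report = synthesize_focus(tm, op, grid.index_of(0.0, 0.0))
    return report


def velocimetry_amplitude_transfer(
    frequency: float,
    seeds=range(10),
    line_rate: float = 1000.0,
    n_lines: int = 1000,
    n_pixels: int = 64,
    mean_velocity: float = 3.0,
    depth: float = 0.3,
    half_window: int = 4,
    v_step: float = 0.25,
) -> float:
    """Recovered/true modulation amplitude for a sinusoidal velocity.

    Generates seeded RBC-streak kymographs whose velocity is modulated
    sinusoidally at ``frequency``; the morphing estimator's trace is
    lock-in demodulated at that frequency and the recovered amplitude is
    averaged over the seeds.
    """
    amp = depth * mean_velocity
    cfg = VelocimetryConfig(
        half_window=half_window,
        v_grid=np.arange(-10.0, 10.0 + 1e-9, v_step))
    transfers = []
    for seed in seeds:
        k, _ = make_rbc_kymograph(
            lambda t: mean_velocity + amp * np.sin(2 * np.pi * frequency * t),
            n_lines=n_lines, n_pixels=n_pixels, line_rate=line_rate, seed=seed)
        trace = velocity_trace(k, cfg)
        sl = slice(half_window, -half_window)
        t, v = trace.t[sl], trace.v[sl]
        good = np.isfinite(v)
        lock = 2 * np.abs(np.mean(
            (v[good] - v[good].mean()) * np.exp(-2j * np.pi * frequency * t[good])))
        transfers.append(lock / amp)
    return float(np.mean(transfers))


def velocimetry_passband_edge(
    frequencies=tuple(range(10, 151, 10)),
    seeds=range(10),
    threshold: float = 0.9,
    **kwargs,
) -> tuple[float, dict[float, float]]:
    """Highest tested modulation frequency with amplitude transfer at or
    above ``threshold``, plus the whole measured transfer curve."""
    curve = {}
    edge = 0.0
    for f in frequencies:
        tr = velocimetry_amplitude_transfer(f, seeds=seeds, **kwargs)
        curve[float(f)] = tr
        if tr >= threshold:
            edge = float(f)
    return edge, curve
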