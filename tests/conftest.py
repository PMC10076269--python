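"""Shared fixtures: a small desk-scale fibre bundle reused across tests.

All randomness is seeded; the bundle is session-scoped because mode
solving and calibration dominate the fixture cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import mmfscope as m


@dataclass
class FiberBundle:
    spec: m.FiberSpec
    grid: m.FieldGrid
    modes: m.ModeSet
    basis: m.InputBasis
    op: m.ForwardOperator
    tm: m.TransmissionMatrix


def _build_bundle(core_um: float, n_pixels: int, pitch: float,
                  n_basis: int, seed: int) -> FiberBundle:
    spec = m.FiberSpec(core_diameter=core_um, na=0.37, wavelength=0.488)
    grid = m.FieldGrid(n_pixels, pitch)
    modes = m.solve_modes(spec, grid)
    basis = m.make_input_basis(n_basis, grid, spec)
    op = m.ground_truth_operator(modes, basis, coupling_strength=1.0, seed=seed)
    tm = m.acquire_tm(op, basis)
    return FiberBundle(spec=spec, grid=grid, modes=modes, basis=basis,
                       op=op, tm=tm)


@pytest.fixture(scope="session")
def small_fiber() -> FiberBundle:
    """10 µm core, NA 0.37, 64² grid at 0.3 µm — fast full-chain fixture."""
    return _build_bundle(10.0, 64, 0.3, 60, seed=1)


@pytest.fixture(scope="session")
def medium_fiber_modes():
    """15 µm core on a 96² grid; modes only (operators built per test)."""
    spec = m.FiberSpec(core_diameter=15.0, na=0.37, wavelength=0.488)
    grid = m.FieldGrid(96, 0.25)
    return spec, grid, m.solve_modes(spec, grid)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
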