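"""Guided-mode model of a step-index multimode fibre.

The fibre is treated in the weakly guiding (scalar) approximation, so the
guided modes are the familiar LP_{lm} modes with Bessel-J radial profiles
inside the core and Bessel-K tails in the cladding.  The module also
provides a seeded ground-truth light-transport operator standing in for a
physical fibre plus relay optics: per-mode propagation phases followed by
a random unitary that mixes the modes, rendered on a sampling grid.

Units: lengths in µm unless stated otherwise; propagation constants in
rad/µm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import schur
from scipy.optimize import brentq
from scipy.special import jn_zeros, jv, kve

from .grid import FieldGrid, field_power

__all__ = [
    "FiberSpec",
    "Mode",
    "ModeSet",
    "ForwardOperator",
    "solve_modes",
    "count_modes",
    "count_mode_families",
    "ground_truth_operator",
    "rayleigh_radius_analytic",
]


@dataclass(frozen=True)
class FiberSpec:
    """Step-index multimode fibre parameters.

    Parameters
    ----------
    core_diameter:
        Core diameter in µm.
    na:
        Numerical aperture (dimensionless).
    wavelength:
        Vacuum wavelength in µm.
    n_clad:
        Cladding refractive index; defaults to fused silica.
    length:
        Fibre length in mm (metadata; sets accumulated modal phases).
    """

    core_diameter: float
    na: float
    wavelength: float
    n_clad: float = 1.45
    length: float = 27.0

    def __post_init__(self) -> None:
        if self.core_diameter <= 0:
            raise ValueError("core_diameter must be positive")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if not 0 < self.na < self.n_core:
            raise ValueError("need 0 < NA < n_core")

    @property
    def n_core(self) -> float:
        return math.sqrt(self.n_clad**2 + self.na**2)

    @property
    def core_radius(self) -> float:
        return self.core_diameter / 2.0

    @property
    def k0(self) -> float:
        """Vacuum wavenumber, rad/µm."""
        return 2.0 * math.pi / self.wavelength

    @property
    def v_number(self) -> float:
        """Normalised frequency V = π d NA / λ."""
        return math.pi * self.core_diameter * self.na / self.wavelength


def rayleigh_radius_analytic(wavelength: float, na: float) -> float:
    """Ideal-aperture Rayleigh resolution, 0.61 λ / NA (µm)."""
    return 0.61 * wavelength / na


@dataclass(frozen=True)
class Mode:
    """A single LP mode orientation."""

    l: int
    m: int
    beta: float
    orientation: str  # "cos" or "sin"
    profile: np.ndarray = field(repr=False)


@dataclass
class ModeSet:
    """Ordered guided-mode basis of a fibre on a sampling grid.

    Modes are sorted by descending propagation constant; l = 0 modes
    appear with a single orientation, l > 0 modes with both ``cos`` and
    ``sin`` orientations.  Profiles are power-normalised on the grid.
    """

    spec: FiberSpec
    grid: FieldGrid
    modes: list[Mode]

    def __len__(self) -> int:
        return len(self.modes)

    @property
    def betas(self) -> np.ndarray:
        return np.array([m.beta for m in self.modes])

    def profile_matrix(self) -> np.ndarray:
        """Mode profiles as columns of an ``(n_pixels^2, n_modes)`` array."""
        return np.stack(
            [m.profile.ravel() for m in self.modes], axis=1
        ).astype(np.complex128)


def _k_ratio(l: int, w: np.ndarray) -> np.ndarray:
    """Stable K_{l+1}(w) / K_l(w) by upward recurrence.

    ``kve`` overflows for large order at small argument; the recurrence
    R_i = 2i/w + 1/R_{i-1} starting from R_0 = K_1/K_0 stays finite.
    """
    r = kve(1, w) / kve(0, w)
    for i in range(1, l + 1):
        r = 2.0 * i / w + 1.0 / r
    return r


def _dispersion_values(l: int, u: np.ndarray, v: float) -> np.ndarray:
    """LP characteristic function with the same sign pattern as
    ``u J_{l+1}(u) K_l(w) - w K_{l+1}(w) J_l(u)``, w² = V² - u²
    (divided through by K_l, which is positive)."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    w = np.sqrt(np.clip(v**2 - u**2, 1e-18, None))
    return u * jv(l + 1, u) - w * _k_ratio(l, w) * jv(l, u)


def _count_roots(l: int, v: float, du: float = 0.02) -> int:
    """Brute-force count of guided LP(l, m) solutions by sign changes of
    the characteristic function on a fine u-grid.  Exact but slow at
    large V; :func:`count_mode_families` uses the cutoff form instead."""
    lo = max(float(l) - 2.0, 0.0) + 1e-9  # roots lie above u ≈ l
    n = max(int((v - lo) / du), 8)
    u = np.linspace(lo, v * (1 - 1e-12), n)
    f = _dispersion_values(l, u, v)
    s = np.sign(f)
    s[s == 0] = 1
    return int(np.count_nonzero(np.diff(s)))


def _find_roots(l: int, v: float, du: float = 0.02) -> list[float]:
    """Solve the LP characteristic equation for azimuthal order l:
    bracket sign changes on a fine grid, refine each with brentq."""
    lo = max(float(l) - 2.0, 0.0) + 1e-9
    n = max(int((v - lo) / du), 8)
    u = np.linspace(lo, v * (1 - 1e-12), n)
    f = _dispersion_values(l, u, v)
    s = np.sign(f)
    s[s == 0] = 1
    idx = np.nonzero(np.diff(s))[0]
    roots = []
    for i in idx:
        roots.append(
            brentq(lambda x: float(_dispersion_values(l, x, v)[0]),
                   u[i], u[i + 1], xtol=1e-12)
        )
    return roots


def count_mode_families(spec: FiberSpec) -> dict[int, int]:
    """Number of guided LP(l, m) radial solutions per azimuthal order l.

    Uses the cutoff form of the characteristic equation: LP(l, m) is
    guided exactly when V exceeds the m-th cutoff, the m-th zero of
    J_{l-1} (counting the zero at the origin for l = 0 only).
    """
    v = spec.v_number
    out: dict[int, int] = {}
    l = 0
    while True:
        order = abs(l - 1)
        nt = max(int(v / math.pi) + 2, 1)
        zeros = jn_zeros(order, nt)
        n = int(np.count_nonzero(zeros < v))
        if l == 0:
            n += 1  # LP01 has zero cutoff
        if n == 0:
            break
        out[l] = n
        l += 1
    return out


def count_modes(spec: FiberSpec) -> int:
    """Total guided-mode count: 2 orientations for l > 0 and 2
    polarisations for every spatial mode.

    For a large-V fibre this approaches the estimate V²/2; the 100 µm,
    NA 0.37 fibre at 488 nm supports ≈ 28 000 modes.
    """
    fams = count_mode_families(spec)
    spatial = sum(n * (2 if l > 0 else 1) for l, n in fams.items())
    return 2 * spatial


def _radial_profile(l: int, u: float, w: float, r_norm: np.ndarray) -> np.ndarray:
    """LP radial profile: J_l core, K_l cladding, continuous at r = a."""
    out = np.empty_like(r_norm)
    core = r_norm <= 1.0
    jl_u = jv(l, u)
    out[core] = jv(l, u * r_norm[core])
    # scaled K avoids under/overflow; exponential factors cancel in the ratio
    wk = w * r_norm[~core]
    out[~core] = jl_u * kve(l, wk) * np.exp(w - wk) / kve(l, w)
    return out


def solve_modes(spec: FiberSpec, grid: FieldGrid, max_modes: int | None = None) -> ModeSet:
    """Solve for all guided LP modes of ``spec`` sampled on ``grid``.

    Returns profiles power-normalised on the grid, sorted by descending
    propagation constant β.  Raises if the grid undersamples the NA
    (pitch above λ/(4 NA)) or does not cover the core.
    """
    if grid.pitch > spec.wavelength / (4.0 * spec.na):
        raise ValueError(
            f"grid pitch {grid.pitch} µm exceeds λ/(4 NA) = "
            f"{spec.wavelength / (4 * spec.na):.3f} µm (undersampled)"
        )
    if grid.extent < spec.core_diameter:
        raise ValueError("grid does not cover the fibre core")

    v = spec.v_number
    a = spec.core_radius
    k0 = spec.k0
    y, x = grid.coords()
    r = np.hypot(x, y)
    phi = np.arctan2(y, x)
    r_norm = r / a

    entries: list[tuple[float, int, int, str, np.ndarray]] = []
    l = 0
    while True:
        roots = _find_roots(l, v)
        if not roots and l > 0:
            break
        for m, u in enumerate(roots, start=1):
            w = math.sqrt(max(v**2 - u**2, 0.0))
            beta = math.sqrt((k0 * spec.n_core) ** 2 - (u / a) ** 2)
            rad = _radial_profile(l, u, w, r_norm)
            orientations = ["cos"] if l == 0 else ["cos", "sin"]
            for orient in orientations:
                ang = np.cos(l * phi) if orient == "cos" else np.sin(l * phi)
                prof = (rad * ang).astype(np.complex128)
                p = field_power(prof, grid)
                if p <= 0:
                    continue
                entries.append((beta, l, m, orient, prof / np.sqrt(p)))
        l += 1

    if not entries:
        raise ValueError("no guided mode resolvable on this grid")
    entries.sort(key=lambda e: (-e[0], e[1], e[2], e[3]))
    if max_modes is not None:
        entries = entries[:max_modes]
    modes = [Mode(l=l, m=m, beta=b, orientation=o, profile=p)
             for b, l, m, o, p in entries]
    return ModeSet(spec=spec, grid=grid, modes=modes)


@dataclass
class ForwardOperator:
    """Seeded ground-truth light-transport operator of the simulated fibre.

    ``matrix`` maps input-basis coefficients to the complex output field
    sampled on the grid (flattened).  ``mode_transfer`` is the unitary
    acting inside the guided-mode subspace (propagation phases followed
    by random mode coupling).
    """

    matrix: np.ndarray
    mode_transfer: np.ndarray
    modes: ModeSet
    seed: int
    coupling_strength: float
    input_basis: object = None  # holography.InputBasis; kept generic here

    @property
    def grid(self) -> FieldGrid:
        return self.modes.grid

    def apply(self, coefficients: np.ndarray) -> np.ndarray:
        """Output field (2-D) for the given input-basis coefficients."""
        n = self.grid.n_pixels
        return (self.matrix @ coefficients).reshape(n, n)

    def unitarity_defect(self) -> float:
        """Max-norm of T†T − I for the mode-subspace transfer."""
        g = self.mode_transfer.conj().T @ self.mode_transfer
        return float(np.max(np.abs(g - np.eye(g.shape[0]))))


def _haar_unitary(n: int, rng: np.random.Generator) -> np.ndarray:
    a = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
    q, r = np.linalg.qr(a)
    d = np.diagonal(r)
    return q * (d / np.abs(d))


def _fractional_unitary(w: np.ndarray, c: float) -> np.ndarray:
    """W^c through the complex Schur form; exactly unitary for any c,
    the identity at c = 0 and W itself at c = 1."""
    if c == 0:
        return np.eye(w.shape[0], dtype=complex)
    if c == 1:
        return w
    t, z = schur(w, output="complex")
    phases = np.angle(np.diagonal(t))
    return (z * np.exp(1j * c * phases)) @ z.conj().T


def ground_truth_operator(
    modes: ModeSet,
    input_basis,
    coupling_strength: float = 1.0,
    seed: int = 0,
) -> ForwardOperator:
    """Assemble the simulated fibre operator  P_out · U · D(βL) · P_in.

    ``P_in`` projects input fields onto the mode basis, ``D`` applies the
    per-mode propagation phases over the fibre length, ``U`` is a seeded
    random unitary blending identity (coupling 0) into a Haar draw
    (coupling 1), and ``P_out`` renders the modal field on the grid.
    Deterministic for a fixed seed.
    """
    if len(modes) == 0:
        raise ValueError("empty mode set")
    if not 0 <= coupling_strength <= 1:
        raise ValueError("coupling_strength must lie in [0, 1]")
    grid = modes.grid
    psi = modes.profile_matrix()  # (n_pix, n_modes)
    length_um = modes.spec.length * 1000.0
    # phases modulo 2π of β·L; β·L itself is ~1e8 rad, keep precision sane
    phases = np.mod(modes.betas * length_um, 2.0 * np.pi)
    d = np.exp(1j * phases)

    rng = np.random.default_rng(seed)
    w = _haar_unitary(len(modes), rng)
    u = _fractional_unitary(w, coupling_strength)
    transfer = u * d[np.newaxis, :]  # U @ diag(d)

    basis_fields = input_basis.field_matrix()  # (n_pix, n_basis)
    if basis_fields.shape[0] != grid.n_samples:
        raise ValueError("input basis not sampled on the mode grid")
    p_in = (psi.conj().T @ basis_fields) * grid.pitch**2  # (n_modes, n_basis)
    matrix = psi @ (transfer @ p_in)

    return ForwardOperator(
        matrix=matrix,
        mode_transfer=transfer,
        modes=modes,
        seed=seed,
        coupling_strength=coupling_strength,
        input_basis=input_basis,
    )
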