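"""File formats: HDF5 for complex-valued objects, multi-page TIFF for
image stacks, CSV for traces and spectra, YAML for configurations and
sidecars.

Complex arrays are stored as paired float datasets ``real``/``imag`` so
the files stay language-portable.  Every writer records a schema version
and a content hash; loaders verify both and raise a :class:`SchemaError`
naming the missing field on mismatch.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .calibration import TransmissionMatrix
from .fiber import FiberSpec, ForwardOperator, Mode, ModeSet
from .grid import FieldGrid
from .holography import InputBasis
from .stitch import StitchedVolume
from .velocimetry import Kymograph, VelocityTrace

__all__ = [
    "SchemaError",
    "save_tm",
    "load_tm",
    "save_operator",
    "load_operator_matrix",
    "save_modeset",
    "load_modeset",
    "write_kymograph",
    "read_kymograph",
    "write_trace",
    "read_trace",
    "write_spectrum",
    "write_stitched_volume",
    "matrix_hash",
    "load_config",
    "save_config",
]

SCHEMA_VERSION = 1


class SchemaError(RuntimeError):
    """A file does not carry the fields this schema version requires."""


def matrix_hash(matrix: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(matrix).tobytes()).hexdigest()


def _write_complex(group: h5py.Group, name: str, arr: np.ndarray) -> None:
    g = group.create_group(name)
    g.create_dataset("real", data=np.ascontiguousarray(arr.real))
    g.create_dataset("imag", data=np.ascontiguousarray(arr.imag))


def _read_complex(group: h5py.Group, name: str) -> np.ndarray:
    if name not in group:
        raise SchemaError(f"missing dataset {name!r}")
    g = group[name]
    return np.asarray(g["real"]) + 1j * np.asarray(g["imag"])


def _require_attrs(obj, names):
    for n in names:
        if n not in obj.attrs:
            raise SchemaError(f"missing attribute {n!r}")


def save_tm(path, tm: TransmissionMatrix) -> str:
    """Write a transmission matrix to HDF5; returns its content hash."""
    h = matrix_hash(tm.matrix)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["object"] = "transmission_matrix"
        _write_complex(f, "matrix", tm.matrix)
        f.attrs["wavelength"] = tm.wavelength
        f.attrs["medium_index"] = tm.medium_index
        f.attrs["calibration_plane_z"] = tm.calibration_plane_z
        f.attrs["grid_n_pixels"] = tm.output_grid.n_pixels
        f.attrs["grid_pitch"] = tm.output_grid.pitch
        f.attrs["matrix_sha256"] = h
        f.create_dataset("input_tilts", data=tm.input_basis.tilts)
        spec = tm.input_basis.spec
        for key, val in asdict(spec).items():
            f.attrs[f"fiber_{key}"] = val
    return h


def load_tm(path) -> TransmissionMatrix:
    """Bit-exact inverse of :func:`save_tm`."""
    with h5py.File(path, "r") as f:
        _require_attrs(f, ["schema_version", "wavelength", "medium_index",
                           "calibration_plane_z", "grid_n_pixels",
                           "grid_pitch", "matrix_sha256"])
        if int(f.attrs["schema_version"]) != SCHEMA_VERSION:
            raise SchemaError(
                f"schema version {f.attrs['schema_version']} unsupported")
        matrix = _read_complex(f, "matrix")
        if matrix_hash(matrix) != f.attrs["matrix_sha256"]:
            raise SchemaError("matrix hash mismatch: file corrupted")
        grid = FieldGrid(int(f.attrs["grid_n_pixels"]),
                         float(f.attrs["grid_pitch"]))
        if "input_tilts" not in f:
            raise SchemaError("missing dataset 'input_tilts'")
        spec = FiberSpec(
            core_diameter=float(f.attrs["fiber_core_diameter"]),
            na=float(f.attrs["fiber_na"]),
            wavelength=float(f.attrs["fiber_wavelength"]),
            n_clad=float(f.attrs["fiber_n_clad"]),
            length=float(f.attrs["fiber_length"]),
        )
        basis = InputBasis(grid=grid, spec=spec,
                           tilts=np.asarray(f["input_tilts"]))
        return TransmissionMatrix(
            matrix=matrix,
            output_grid=grid,
            input_basis=basis,
            wavelength=float(f.attrs["wavelength"]),
            calibration_plane_z=float(f.attrs["calibration_plane_z"]),
            medium_index=float(f.attrs["medium_index"]),
        )


def save_operator(path, op: ForwardOperator) -> str:
    """Persist a ground-truth operator (matrix + provenance)."""
    h = matrix_hash(op.matrix)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["object"] = "forward_operator"
        _write_complex(f, "matrix", op.matrix)
        _write_complex(f, "mode_transfer", op.mode_transfer)
        f.attrs["seed"] = op.seed
        f.attrs["coupling_strength"] = op.coupling_strength
        f.attrs["matrix_sha256"] = h
        f.attrs["grid_n_pixels"] = op.grid.n_pixels
        f.attrs["grid_pitch"] = op.grid.pitch
        for key, val in asdict(op.modes.spec).items():
            f.attrs[f"fiber_{key}"] = val
        if op.input_basis is not None:
            f.create_dataset("input_tilts", data=op.input_basis.tilts)
    return h


def load_operator_matrix(path):
    """Matrix + metadata of a stored operator (profiles are regenerated
    from the fibre spec when a full operator is needed)."""
    with h5py.File(path, "r") as f:
        _require_attrs(f, ["seed", "coupling_strength", "matrix_sha256"])
        matrix = _read_complex(f, "matrix")
        if matrix_hash(matrix) != f.attrs["matrix_sha256"]:
            raise SchemaError("matrix hash mismatch: file corrupted")
        meta = dict(f.attrs)
        tilts = np.asarray(f["input_tilts"]) if "input_tilts" in f else None
    return matrix, meta, tilts


def save_modeset(path, modes: ModeSet) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["object"] = "mode_set"
        f.attrs["grid_n_pixels"] = modes.grid.n_pixels
        f.attrs["grid_pitch"] = modes.grid.pitch
        for key, val in asdict(modes.spec).items():
            f.attrs[f"fiber_{key}"] = val
        f.create_dataset("l", data=np.array([m.l for m in modes.modes]))
        f.create_dataset("m", data=np.array([m.m for m in modes.modes]))
        f.create_dataset("beta", data=modes.betas)
        f.create_dataset(
            "orientation",
            data=np.array([m.orientation == "sin" for m in modes.modes]))
        _write_complex(f, "profiles", modes.profile_matrix())


def load_modeset(path) -> ModeSet:
    with h5py.File(path, "r") as f:
        _require_attrs(f, ["grid_n_pixels", "grid_pitch", "fiber_core_diameter"])
        grid = FieldGrid(int(f.attrs["grid_n_pixels"]),
                         float(f.attrs["grid_pitch"]))
        spec = FiberSpec(
            core_diameter=float(f.attrs["fiber_core_diameter"]),
            na=float(f.attrs["fiber_na"]),
            wavelength=float(f.attrs["fiber_wavelength"]),
            n_clad=float(f.attrs["fiber_n_clad"]),
            length=float(f.attrs["fiber_length"]),
        )
        profiles = _read_complex(f, "profiles")
        ls = np.asarray(f["l"])
        ms = np.asarray(f["m"])
        betas = np.asarray(f["beta"])
        sins = np.asarray(f["orientation"])
        n = grid.n_pixels
        modes = [
            Mode(l=int(l), m=int(m), beta=float(b),
                 orientation="sin" if s else "cos",
                 profile=profiles[:, i].reshape(n, n))
            for i, (l, m, b, s) in enumerate(zip(ls, ms, betas, sins))
        ]
    return ModeSet(spec=spec, grid=grid, modes=modes)


def _sidecar(path) -> Path:
    return Path(str(path) + ".yaml")


def write_kymograph(path, k: Kymograph) -> None:
    """Single-page TIFF or CSV plus a YAML sidecar with the metadata."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, k.data.astype(np.float32))
    else:
        np.savetxt(path, k.data, delimiter=",")
    with open(_sidecar(path), "w") as f:
        yaml.safe_dump({"line_rate_hz": float(k.line_rate),
                        "pixel_pitch_um": float(k.pixel_pitch)}, f)


def read_kymograph(path) -> Kymograph:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path).astype(float)
    else:
        data = np.loadtxt(path, delimiter=",")
    side = _sidecar(path)
    if not side.exists():
        raise SchemaError(f"missing sidecar {side}")
    meta = yaml.safe_load(side.read_text())
    for key in ("line_rate_hz", "pixel_pitch_um"):
        if key not in meta:
            raise SchemaError(f"sidecar missing field {key!r}")
    return Kymograph(data=data, line_rate=meta["line_rate_hz"],
                     pixel_pitch=meta["pixel_pitch_um"])


def write_trace(path, trace: VelocityTrace) -> None:
    pd.DataFrame({"t_s": trace.t, "v": trace.v,
                  "valid": trace.valid.astype(int),
                  "units": trace.units}).to_csv(path, index=False)


def read_trace(path) -> VelocityTrace:
    df = pd.read_csv(path)
    for col in ("t_s", "v", "valid"):
        if col not in df.columns:
            raise SchemaError(f"trace file missing column {col!r}")
    units = str(df["units"].iloc[0]) if "units" in df.columns else "px/line"
    return VelocityTrace(t=df["t_s"].to_numpy(), v=df["v"].to_numpy(),
                         units=units, valid=df["valid"].to_numpy().astype(bool))


def write_spectrum(path, freq: np.ndarray, power: np.ndarray) -> None:
    pd.DataFrame({"frequency_hz": freq, "power": power}).to_csv(path, index=False)


def write_stitched_volume(path, vol: StitchedVolume) -> None:
    """Multi-page TIFF (planes) plus an HDF5 sidecar with voxel size,
    speed, and the per-voxel sample-count map."""
    path = Path(path)
    tifffile.imwrite(path, vol.volume.astype(np.float32))
    with h5py.File(str(path) + ".h5", "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["voxel_size"] = vol.voxel_size
        f.attrs["speed_px_per_frame"] = vol.speed_px_per_frame
        f.create_dataset("sample_count", data=vol.sample_count)


def save_config(path, config: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config, f, sort_keys=True)


def load_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise SchemaError("configuration must be a YAML mapping")
    return cfg


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()).hexdigest()[:16]
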