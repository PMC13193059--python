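"""Readers and writers for pipeline artifacts.

Grids (occupancy, dose, kernels) travel as a raw little-endian binary payload
plus a JSON sidecar header carrying pitch, dims, dtype and semantic role --
a self-describing, dependency-free container with bit-exact round trips.
Tabular artifacts (radial kernels, histograms, fit and metric reports) are
headered CSV.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .distributions import EmpiricalDistribution
from .kernel import RadialDoseKernel

__all__ = [
    "GridContainer",
    "RunManifest",
    "read_grid",
    "write_grid",
    "read_radial_kernel",
    "write_radial_kernel",
    "read_histogram",
    "write_histogram",
    "write_report",
    "write_manifest",
]

_ALLOWED_SEMANTICS = ("occupancy", "dose", "kernel")


@dataclass
class GridContainer:
    array: np.ndarray
    pitch_um: float
    semantic: str = "dose"
    provenance: dict | None = None

    def __post_init__(self):
        if self.semantic not in _ALLOWED_SEMANTICS:
            raise ValueError(f"semantic must be one of {_ALLOWED_SEMANTICS}")
        if self.pitch_um <= 0:
            raise ValueError("pitch must be positive")


def write_grid(container: GridContainer, path) -> None:
    """Write array to ``<path>.raw`` with a ``<path>.json`` sidecar."""
    path = Path(path)
    arr = np.ascontiguousarray(container.array)
    raw = path.with_suffix(".raw")
    raw.write_bytes(arr.astype(arr.dtype.newbyteorder("<")).tobytes())
    header = {
        "pitch_um": container.pitch_um,
        "dims": list(arr.shape),
        "dtype": arr.dtype.str.replace(">", "<"),
        "semantic": container.semantic,
        "provenance": container.provenance or {},
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=1))


def read_grid(path) -> GridContainer:
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar header {sidecar}")
    try:
        header = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt sidecar header {sidecar}: {exc}") from exc
    for key in ("pitch_um", "dims", "dtype", "semantic"):
        if key not in header:
            raise ValueError(f"sidecar header missing required field {key!r}")
    data = path.with_suffix(".raw").read_bytes()
    arr = np.frombuffer(data, dtype=np.dtype(header["dtype"]))
    dims = tuple(header["dims"])
    if arr.size != int(np.prod(dims)):
        raise ValueError("payload size does not match header dims")
    return GridContainer(array=arr.reshape(dims).copy(),
                         pitch_um=float(header["pitch_um"]),
                         semantic=header["semantic"],
                         provenance=header.get("provenance") or {})


def write_radial_kernel(kernel: RadialDoseKernel, path) -> None:
    pd.DataFrame({"radius_mm": kernel.radii_mm,
                  "dose_gy_per_decay": kernel.dose_gy_per_decay}).to_csv(
        path, index=False, float_format="%.10e")


def read_radial_kernel(path) -> RadialDoseKernel:
    df = pd.read_csv(path)
    for col in ("radius_mm", "dose_gy_per_decay"):
        if col not in df.columns:
            raise ValueError(f"radial kernel CSV must have column {col!r}")
    radii = df["radius_mm"].to_numpy(dtype=float)
    if np.any(np.diff(radii) <= 0):
        raise ValueError("radii out of order in radial kernel CSV")
    return RadialDoseKernel(radii_mm=radii,
                            dose_gy_per_decay=df["dose_gy_per_decay"].to_numpy(dtype=float),
                            provenance=f"loaded from {Path(path).name}")


def write_histogram(emp: EmpiricalDistribution, path) -> None:
    pd.DataFrame({"bin_lower": emp.bin_edges[:-1],
                  "bin_upper": emp.bin_edges[1:],
                  "probability": emp.probabilities}).to_csv(
        path, index=False, float_format="%.10e")


def read_histogram(path) -> EmpiricalDistribution:
    df = pd.read_csv(path)
    for col in ("bin_lower", "bin_upper", "probability"):
        if col not in df.columns:
            raise ValueError(f"histogram CSV must have column {col!r}")
    lower = df["bin_lower"].to_numpy(dtype=float)
    upper = df["bin_upper"].to_numpy(dtype=float)
    if not np.allclose(lower[1:], upper[:-1]):
        raise ValueError("histogram bins must be contiguous")
    edges = np.append(lower, upper[-1])
    return EmpiricalDistribution(edges, df["probability"].to_numpy(dtype=float))


def write_report(tables: dict, path) -> None:
    """Write named DataFrames as ``<path>/<name>.csv`` (>= 9 significant
    digits for floats)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(path / f"{name}.csv", index=False, float_format="%.9g")


@dataclass
class RunManifest:
    config: dict
    master_seed: int
    stream_seeds: dict
    code_version: str = "0.1.0"
    timestamp: str = ""

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(manifest: RunManifest, path) -> None:
    payload = asdict(manifest)
    payload["config_hash"] = manifest.config_hash
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
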