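"""File formats and run manifests.

Formats:

- XYZ: species symbol + coordinates; the comment line carries the box and
  step index.  Human-friendly; drops velocities and molecule ids.
- LAMMPS-style dump (``ITEM:`` blocks): columns
  ``id mol type x y z vx vy vz`` — the full state; multiple frames per
  file.  Floats are written with repr precision, so write -> read ->
  write is byte-identical.
- CSV profiles/series with a YAML sidecar (``<name>.meta.yaml``) holding
  units, bins and window metadata.
- HDF5 checkpoints of the complete state.
- JSON run manifest: config snapshot, seed, package version, output
  paths, per-stage status.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .builder import SystemState
from .model import Species

__all__ = [
    "write_xyz", "read_xyz", "write_dump", "read_dump", "iter_dump_frames",
    "write_profile_csv", "write_checkpoint", "read_checkpoint", "RunManifest",
]

_SYMBOL = {Species.WATER: "W", Species.HEAD1: "H1", Species.TAIL1: "T1",
           Species.HEAD2: "H2", Species.TAIL2: "T2"}
_FROM_SYMBOL = {v: int(k) for k, v in _SYMBOL.items()}


def _fmt(x: float) -> str:
    return repr(float(x))


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def write_xyz(path, state: SystemState, comment: str = "") -> None:
    box = " ".join(_fmt(b) for b in state.box)
    with open(path, "w") as fh:
        fh.write(f"{state.n_beads}\n")
        fh.write(f"box {box} step {state.step_index} {comment}".rstrip() + "\n")
        for s, (x, y, z) in zip(state.species, state.positions):
            fh.write(f"{_SYMBOL[Species(int(s))]} {_fmt(x)} {_fmt(y)} {_fmt(z)}\n")


def read_xyz(path) -> SystemState:
    with open(path) as fh:
        n = int(fh.readline())
        header = fh.readline().split()
        box = np.array([float(header[1]), float(header[2]), float(header[3])])
        step = int(header[5]) if len(header) > 5 and header[4] == "step" else 0
        species = np.empty(n, dtype=np.int64)
        pos = np.empty((n, 3))
        for i in range(n):
            sym, x, y, z = fh.readline().split()[:4]
            species[i] = _FROM_SYMBOL[sym]
            pos[i] = (float(x), float(y), float(z))
    return SystemState(pos, np.zeros_like(pos), species,
                       np.full(n, -1, dtype=np.int64), box, step)


# ---------------------------------------------------------------------------
# LAMMPS-style dump
# ---------------------------------------------------------------------------

def write_dump(path, state: SystemState, append: bool = False) -> None:
    """One frame in the dump dialect: id mol type x y z vx vy vz.

    ``type`` is the species value + 1 (dump types are 1-based).
    """
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write("ITEM: TIMESTEP\n")
        fh.write(f"{state.step_index}\n")
        fh.write("ITEM: NUMBER OF ATOMS\n")
        fh.write(f"{state.n_beads}\n")
        fh.write("ITEM: BOX BOUNDS pp pp pp\n")
        for b in state.box:
            fh.write(f"{_fmt(0.0)} {_fmt(b)}\n")
        fh.write("ITEM: ATOMS id mol type x y z vx vy vz\n")
        for i in range(state.n_beads):
            x, y, z = state.positions[i]
            vx, vy, vz = state.velocities[i]
            fh.write(
                f"{i + 1} {state.molecule_id[i]} {state.species[i] + 1} "
                f"{_fmt(x)} {_fmt(y)} {_fmt(z)} "
                f"{_fmt(vx)} {_fmt(vy)} {_fmt(vz)}\n"
            )


def _read_dump_frame(fh) -> SystemState | None:
    line = fh.readline()
    while line and not line.startswith("ITEM: TIMESTEP"):
        line = fh.readline()
    if not line:
        return None
    step = int(fh.readline())
    assert fh.readline().startswith("ITEM: NUMBER")
    n = int(fh.readline())
    assert fh.readline().startswith("ITEM: BOX")
    box = np.empty(3)
    for a in range(3):
        lo, hi = fh.readline().split()[:2]
        box[a] = float(hi) - float(lo)
    cols = fh.readline().split()[2:]
    idx = {c: k for k, c in enumerate(cols)}
    pos = np.empty((n, 3))
    vel = np.zeros((n, 3))
    species = np.empty(n, dtype=np.int64)
    molid = np.empty(n, dtype=np.int64)
    order = np.empty(n, dtype=np.int64)
    for r in range(n):
        parts = fh.readline().split()
        order[r] = int(parts[idx["id"]]) - 1
        molid[r] = int(parts[idx["mol"]])
        species[r] = int(parts[idx["type"]]) - 1
        pos[r] = [float(parts[idx[c]]) for c in ("x", "y", "z")]
        if "vx" in idx:
            vel[r] = [float(parts[idx[c]]) for c in ("vx", "vy", "vz")]
    srt = np.argsort(order, kind="stable")
    return SystemState(pos[srt], vel[srt], species[srt], molid[srt], box, step)


def iter_dump_frames(path):
    """Yield every frame of a (possibly multi-frame) dump file."""
    with open(path) as fh:
        while True:
            frame = _read_dump_frame(fh)
            if frame is None:
                return
            yield frame


def read_dump(path) -> list[SystemState]:
    frames = list(iter_dump_frames(path))
    if not frames:
        raise ValueError(f"no frames found in dump file {path}")
    return frames


# ---------------------------------------------------------------------------
# CSV + YAML sidecar
# ---------------------------------------------------------------------------

def write_profile_csv(path, df, metadata: dict | None = None) -> None:
    """Write a DataFrame as CSV with a YAML metadata sidecar.

    Every numeric output carries units metadata; callers pass bins/window
    specifics and this helper stamps the reduced-unit system.
    """
    path = Path(path)
    df.to_csv(path, index=False)
    meta = {"units": {"length": "rc", "time": "tau", "energy": "kBT",
                      "density": "beads/rc^3", "pressure": "kBT/rc^3",
                      "tension": "kBT/rc^2"}}
    meta.update(metadata or {})
    with open(path.with_suffix(path.suffix + ".meta.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# HDF5 checkpoints
# ---------------------------------------------------------------------------

def write_checkpoint(path, state: SystemState, seed: int | None = None,
                     extra: dict | None = None) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("positions", data=state.positions)
        h5.create_dataset("velocities", data=state.velocities)
        h5.create_dataset("species", data=state.species)
        h5.create_dataset("molecule_id", data=state.molecule_id)
        h5.attrs["box"] = state.box
        h5.attrs["step_index"] = state.step_index
        if seed is not None:
            h5.attrs["seed"] = int(seed)
        for k, v in (extra or {}).items():
            h5.attrs[k] = v


def read_checkpoint(path) -> tuple[SystemState, dict]:
    import h5py

    with h5py.File(path, "r") as h5:
        state = SystemState(
            h5["positions"][...], h5["velocities"][...],
            h5["species"][...], h5["molecule_id"][...],
            np.asarray(h5.attrs["box"]), int(h5.attrs["step_index"]),
        )
        attrs = {k: h5.attrs[k] for k in h5.attrs if k not in
                 ("box", "step_index")}
    return state, attrs


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Reproducibility record of one CLI invocation."""

    command: str
    config: dict
    seed: int
    outputs: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    version: str = ""
    created: str = field(default_factory=lambda: time.strftime(
        "%Y-%m-%dT%H:%M:%S"))

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__

    def add_output(self, name: str, path) -> None:
        self.outputs[name] = str(path)

    def set_stage(self, name: str, status: str, **info) -> None:
        self.stages[name] = {"status": status, **info}

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)
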