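"""Initial-configuration builders (the synthetic-data generator).

Three entry points:

- :func:`random_initial_configuration` — the production-style start: every
  lipid built at its idealized internal geometry (bonds at rs, angles at
  theta0) and dropped into the box with a random rigid-body position and
  orientation; water fills the remainder to number density rho; velocities
  are Maxwell-Boltzmann at kBT with the net momentum removed.
- :func:`preassembled_bilayer` — a fast-equilibration fixture: two apposed
  leaflets normal to z (double-tail lipids on top, single-tail below) with
  water outside the membrane slab.
- :func:`synthetic_geometry` — static slab / cylinder / sphere bead
  arrangements used to exercise the morphology classifier.

Random placement does not reject overlaps: DPD conservative forces are
soft and finite at r=0, so overlapping starts relax within a few steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (
    BOND_RS,
    LipidTopology,
    RunConfig,
    Species,
)

__all__ = [
    "SystemState",
    "SystemTopology",
    "random_initial_configuration",
    "preassembled_bilayer",
    "synthetic_geometry",
    "BuildError",
]


class BuildError(ValueError):
    """Raised when a requested configuration cannot be constructed."""


@dataclass
class SystemState:
    """Positions, velocities, species and chain membership of all beads.

    Coordinates are stored wrapped into [0, L) per axis, in rc units;
    velocities in rc/tau.  ``molecule_id`` is -1 for water beads.
    """

    positions: np.ndarray
    velocities: np.ndarray
    species: np.ndarray
    molecule_id: np.ndarray
    box: np.ndarray
    step_index: int = 0

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.species = np.ascontiguousarray(self.species, dtype=np.int64)
        self.molecule_id = np.ascontiguousarray(self.molecule_id, dtype=np.int64)
        self.box = np.asarray(self.box, dtype=np.float64)
        n = self.positions.shape[0]
        if self.positions.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise ValueError("positions and velocities must be (N, 3)")
        if self.species.shape != (n,) or self.molecule_id.shape != (n,):
            raise ValueError("species and molecule_id must be length N")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def wrap(self) -> None:
        """Wrap coordinates into [0, L) in place."""
        self.positions %= self.box

    def copy(self) -> "SystemState":
        return SystemState(
            self.positions.copy(), self.velocities.copy(),
            self.species.copy(), self.molecule_id.copy(),
            self.box.copy(), self.step_index,
        )

    def zero_net_momentum(self) -> None:
        self.velocities -= self.velocities.mean(axis=0, keepdims=True)

    def net_momentum(self, m: float = 1.0) -> np.ndarray:
        return m * self.velocities.sum(axis=0)


@dataclass
class SystemTopology:
    """Flattened bonded interactions and the chain table for a whole system.

    ``chain_start[c] .. chain_start[c] + chain_nbeads[c]`` are the global
    bead indices of chain c; ``chain_type`` is 1 or 2; ``chain_nhead`` the
    head-block size.  ``templates`` maps lipid type to its molecule-local
    :class:`~dpdlipid.model.LipidTopology`.
    """

    bond_ij: np.ndarray
    bond_ks: np.ndarray
    bond_rs: np.ndarray
    angle_ijk: np.ndarray
    angle_k: np.ndarray
    angle_t0: np.ndarray
    chain_start: np.ndarray
    chain_nbeads: np.ndarray
    chain_type: np.ndarray
    chain_nhead: np.ndarray
    templates: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.chain_start.shape[0]

    @classmethod
    def empty(cls) -> "SystemTopology":
        z2 = np.empty((0, 2), dtype=np.int64)
        z3 = np.empty((0, 3), dtype=np.int64)
        zf = np.empty(0, dtype=np.float64)
        zi = np.empty(0, dtype=np.int64)
        return cls(z2, zf, zf, z3, zf.copy(), zf.copy(), zi, zi.copy(),
                   zi.copy(), zi.copy(), {})

    @classmethod
    def from_molecules(cls, molecules: list[LipidTopology]) -> "SystemTopology":
        """Concatenate molecule-local topologies with global bead numbering."""
        bonds, angles = [], []
        starts, nbeads, types, nheads = [], [], [], []
        offset = 0
        templates: dict = {}
        for topo in molecules:
            starts.append(offset)
            nbeads.append(topo.n_beads)
            types.append(topo.lipid_type)
            nheads.append(topo.n_head)
            templates.setdefault(topo.lipid_type, topo)
            for b in topo.bonds:
                bonds.append((b.i + offset, b.j + offset, b.ks, b.rs))
            for a in topo.angles:
                angles.append((a.i + offset, a.j + offset, a.k + offset,
                               a.ktheta, a.theta0))
            offset += topo.n_beads
        if bonds:
            barr = np.array([(i, j) for i, j, _, _ in bonds], dtype=np.int64)
            bks = np.array([ks for _, _, ks, _ in bonds])
            brs = np.array([rs for _, _, _, rs in bonds])
        else:
            barr = np.empty((0, 2), dtype=np.int64)
            bks = brs = np.empty(0)
        if angles:
            aarr = np.array([(i, j, k) for i, j, k, _, _ in angles], dtype=np.int64)
            ak = np.array([kt for *_, kt, _ in angles])
            at0 = np.array([t0 for *_, t0 in angles])
        else:
            aarr = np.empty((0, 3), dtype=np.int64)
            ak = at0 = np.empty(0)
        return cls(
            barr, bks, brs, aarr, ak, at0,
            np.array(starts, dtype=np.int64), np.array(nbeads, dtype=np.int64),
            np.array(types, dtype=np.int64), np.array(nheads, dtype=np.int64),
            templates,
        )


# ---------------------------------------------------------------------------
# Ideal molecule templates (molecule-local coordinates)
# ---------------------------------------------------------------------------

def _template_type1(topo: LipidTopology, rs: float = BOND_RS) -> np.ndarray:
    """Straight rod along +z, bead i at z = i*rs."""
    n = topo.n_beads
    xyz = np.zeros((n, 3))
    xyz[:, 2] = np.arange(n) * rs
    return xyz


def _template_type2(topo: LipidTopology, rs: float = BOND_RS) -> np.ndarray:
    """Head chain along +z; tails kinked at 120 deg then straight along +z.

    The head-head-tail junction and head-tail-tail junction angles both sit
    exactly at their 2pi/3 equilibrium; the two tails splay mirror-
    symmetrically in the molecule's xz-plane.
    """
    nh, nt = topo.n_head, topo.n_tail_per_tail
    n = topo.n_beads
    xyz = np.zeros((n, 3))
    xyz[:nh, 2] = np.arange(nh) * rs
    top = xyz[nh - 1]
    # first tail bead at 60 deg from +z (=> 120 deg from the -z head bond)
    s60, c60 = math.sin(math.pi / 3.0), math.cos(math.pi / 3.0)
    for t, sign in ((0, 1.0), (1, -1.0)):
        i0 = nh + t * nt
        first = top + rs * np.array([sign * s60, 0.0, c60])
        xyz[i0] = first
        for m in range(1, nt):
            xyz[i0 + m] = first + np.array([0.0, 0.0, m * rs])
    return xyz


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a random unit quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _mb_velocities(rng: np.random.Generator, n: int, kBT: float,
                   m: float) -> np.ndarray:
    v = rng.normal(scale=math.sqrt(kBT / m), size=(n, 3))
    v -= v.mean(axis=0, keepdims=True)
    return v


def _molecule_list(config: RunConfig) -> list[LipidTopology]:
    t1, t2 = config.topology_1, config.topology_2
    return [t1] * config.n_lipids_1 + [t2] * config.n_lipids_2


def _species_and_molid(molecules: list[LipidTopology]):
    species = np.concatenate(
        [np.array([int(s) for s in m.species_sequence], dtype=np.int64)
         for m in molecules]
    ) if molecules else np.empty(0, dtype=np.int64)
    molid = np.concatenate(
        [np.full(m.n_beads, c, dtype=np.int64) for c, m in enumerate(molecules)]
    ) if molecules else np.empty(0, dtype=np.int64)
    return species, molid


def _finish_state(lipid_xyz, molecules, config, rng, n_water=None,
                  water_xyz=None):
    """Append water, draw velocities, wrap, and assemble the state."""
    n_total = config.n_total_beads
    n_lipid = lipid_xyz.shape[0]
    if n_water is None:
        n_water = n_total - n_lipid
    if n_water < 0:
        raise BuildError("lipid beads exceed the rho*V bead budget")
    if water_xyz is None:
        water_xyz = rng.uniform(size=(n_water, 3)) * config.box_lengths
    species, molid = _species_and_molid(molecules)
    species = np.concatenate([species, np.full(n_water, int(Species.WATER),
                                               dtype=np.int64)])
    molid = np.concatenate([molid, np.full(n_water, -1, dtype=np.int64)])
    pos = np.vstack([lipid_xyz, water_xyz]) if n_water else lipid_xyz
    vel = _mb_velocities(rng, pos.shape[0], config.params.kBT, config.params.m)
    state = SystemState(pos, vel, species, molid,
                        np.asarray(config.box_lengths), 0)
    state.wrap()
    return state


def random_initial_configuration(
    config: RunConfig, seed: int | None = None
) -> tuple[SystemState, SystemTopology]:
    """Randomly placed ideal-geometry lipids plus water fill.

    Deterministic for a fixed seed (defaults to ``config.seed``).  Returns
    the state together with the flattened system topology.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    molecules = _molecule_list(config)
    box = np.asarray(config.box_lengths)
    chunks = []
    for topo in molecules:
        local = (_template_type1(topo) if topo.lipid_type == 1
                 else _template_type2(topo))
        local = local - local.mean(axis=0)
        rot = _random_rotation(rng)
        com = rng.uniform(size=3) * box
        chunks.append(local @ rot.T + com)
    lipid_xyz = (np.vstack(chunks) if chunks
                 else np.empty((0, 3), dtype=np.float64))
    state = _finish_state(lipid_xyz, molecules, config, rng)
    return state, SystemTopology.from_molecules(molecules)


def preassembled_bilayer(
    config: RunConfig, seed: int | None = None, gap: float = 0.35
) -> tuple[SystemState, SystemTopology]:
    """Two apposed leaflets normal to z; type 2 above, type 1 below.

    Lipids stand on square xy-grids with their tails pointing at the
    membrane midplane z = Lz/2; water is placed outside the membrane slab
    only.  Head order parameter along z is ~1 by construction.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lx, ly, lz = config.box_lengths
    t1, t2 = config.topology_1, config.topology_2
    rs = BOND_RS
    zc = lz / 2.0

    ext1 = (t1.n_beads - 1) * rs
    tmpl2 = _template_type2(t2)
    ext2 = tmpl2[:, 2].max() - tmpl2[:, 2].min()
    z_bottom = zc - gap - ext1
    z_top = zc + gap + ext2
    if z_bottom < 1.0 or z_top > lz - 1.0:
        raise BuildError(
            f"box of height {lz}rc too thin for leaflet extents "
            f"{ext1:.2f}+{ext2:.2f}rc"
        )

    def grid(n: int) -> np.ndarray:
        k = max(1, int(math.ceil(math.sqrt(n))))
        xs = (np.arange(k) + 0.5) * (lx / k)
        ys = (np.arange(k) + 0.5) * (ly / k)
        pts = np.array([(x, y) for x in xs for y in ys])[:n]
        return pts + rng.uniform(-0.05, 0.05, size=pts.shape)

    chunks = []
    # lower leaflet: straight type-1 rods pointing up (tails at midplane)
    for x, y in grid(config.n_lipids_1):
        local = _template_type1(t1)
        local = local + np.array([x, y, z_bottom])
        chunks.append(local)
    # upper leaflet: type-2 templates flipped to point down
    flip = np.diag([1.0, 1.0, -1.0])
    for x, y in grid(config.n_lipids_2):
        local = tmpl2 @ flip
        local = local + np.array([x, y, zc + gap + ext2 - local[:, 2].min()
                                  - ext2])
        chunks.append(local)
    lipid_xyz = np.vstack(chunks)
    molecules = _molecule_list(config)

    # water outside the membrane slab
    n_water = config.n_total_beads - lipid_xyz.shape[0]
    lo, hi = z_bottom - rs, z_top + rs
    outside = lz - (hi - lo)
    if outside <= 0:
        raise BuildError("no room for water outside the membrane slab")
    zw = rng.uniform(size=n_water) * outside
    zw = np.where(zw < lo, zw, zw + (hi - lo))
    water_xyz = np.column_stack([
        rng.uniform(size=n_water) * lx,
        rng.uniform(size=n_water) * ly,
        zw,
    ])
    state = _finish_state(lipid_xyz, molecules, config, rng,
                          n_water=n_water, water_xyz=water_xyz)
    return state, SystemTopology.from_molecules(molecules)


def synthetic_geometry(
    shape: str, config: RunConfig, seed: int = 0
) -> SystemState:
    """Static slab / cylinder / sphere bead arrangements (classifier fixtures).

    Tail beads fill the shape's hydrophobic core at the configured density,
    head beads coat its surfaces, water fills the rest of the box.  Beads
    carry no molecular topology (molecule_id 0.. for lipid shells is not
    meaningful here and is set to -1 for water, 0 for lipid beads).
    """
    rng = np.random.default_rng(seed)
    lx, ly, lz = config.box_lengths
    box = np.array([lx, ly, lz])
    center = box / 2.0
    rho = config.rho
    n_total = config.n_total_beads

    def fill(n, sampler):
        pts = sampler(int(n))
        return pts

    if shape == "slab":
        th = 3.0
        core_v = lx * ly * th
        shell_v = 2 * lx * ly * 0.7
        n_tail = int(rho * core_v)
        n_head = int(rho * shell_v)

        def core(n):
            p = rng.uniform(size=(n, 3)) * [lx, ly, th]
            p[:, 2] += center[2] - th / 2
            return p

        def shell(n):
            p = rng.uniform(size=(n, 3)) * [lx, ly, 0.7]
            half = n // 2
            p[:half, 2] += center[2] + th / 2
            p[half:, 2] = center[2] - th / 2 - p[half:, 2]
            return p

    elif shape == "cylinder":
        r_core = min(ly, lz) / 5.0
        core_v = lx * math.pi * r_core**2
        shell_v = lx * math.pi * ((r_core + 0.7) ** 2 - r_core**2)
        n_tail = int(rho * core_v)
        n_head = int(rho * shell_v)

        def _disk(n, r0, r1):
            r = np.sqrt(rng.uniform(r0**2, r1**2, size=n))
            phi = rng.uniform(0, 2 * math.pi, size=n)
            return np.column_stack([
                rng.uniform(size=n) * lx,
                center[1] + r * np.cos(phi),
                center[2] + r * np.sin(phi),
            ])

        def core(n):
            return _disk(n, 0.0, r_core)

        def shell(n):
            return _disk(n, r_core, r_core + 0.7)

    elif shape == "sphere":
        r_out = min(lx, ly, lz) / 3.5
        r_in = max(r_out - 2.0, r_out * 0.4)
        core_v = 4 / 3 * math.pi * (r_out**3 - r_in**3)
        shell_v = 4 / 3 * math.pi * ((r_out + 0.7) ** 3 - r_out**3
                                     + r_in**3 - max(r_in - 0.7, 0.0) ** 3)
        n_tail = int(rho * core_v)
        n_head = int(rho * shell_v)

        def _ball(n, r0, r1):
            r = (rng.uniform(r0**3, r1**3, size=n)) ** (1 / 3)
            v = rng.normal(size=(n, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            return center + r[:, None] * v

        def core(n):
            return _ball(n, r_in, r_out)

        def shell(n):
            half = n // 2
            outer = _ball(half, r_out, r_out + 0.7)
            inner = _ball(n - half, max(r_in - 0.7, 0.1), r_in)
            return np.vstack([outer, inner])

    else:
        raise ValueError(f"unknown shape {shape!r}; choose slab|cylinder|sphere")

    tails = fill(n_tail, core)
    heads = fill(n_head, shell)
    n_water = max(0, n_total - n_tail - n_head)
    water = rng.uniform(size=(n_water, 3)) * box
    pos = np.vstack([tails, heads, water])
    species = np.concatenate([
        np.full(n_tail, int(Species.TAIL1), dtype=np.int64),
        np.full(n_head, int(Species.HEAD1), dtype=np.int64),
        np.full(n_water, int(Species.WATER), dtype=np.int64),
    ])
    molid = np.concatenate([
        np.zeros(n_tail + n_head, dtype=np.int64),
        np.full(n_water, -1, dtype=np.int64),
    ])
    vel = np.zeros_like(pos)
    state = SystemState(pos, vel, species, molid, box, 0)
    state.wrap()
    return state
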