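"""Force-field definitions for the two-lipid DPD system.

Everything here is in reduced DPD units: lengths in the cutoff radius
``rc``, energies in ``kBT``, masses in the bead mass ``m``, and time in
``tau = rc*sqrt(m/kBT)``.  The system contains five bead species — water,
and head/tail beads of two lipid architectures: a single-tail lipid
(type 1) and a double-tail lipid (type 2).  Both carry three head beads;
the tail lengths ``nt1`` and ``nt2`` are the main phase-space variables.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Species",
    "N_SPECIES",
    "HYDROPHILIC",
    "HYDROPHOBIC",
    "DPDParams",
    "InteractionTable",
    "interaction_table",
    "BondTerm",
    "AngleTerm",
    "LipidTopology",
    "build_lipid_type1",
    "build_lipid_type2",
    "UnitSystem",
    "physical_time",
    "RunConfig",
]

# Bonded-interaction constants (reduced units).
BOND_KS = 120.0          # harmonic spring constant
BOND_RS = 0.7            # equilibrium bond length, in rc
ANGLE_K_BACKBONE = 6.0   # stiffness of straight backbone triples
ANGLE_T0_BACKBONE = math.pi
ANGLE_K_JUNCTION_HH_T = 3.0    # (head, head, first-tail) triple of lipid 2
ANGLE_K_JUNCTION_H_TT = 4.5    # (head, first-tail, second-tail) triple of lipid 2
ANGLE_T0_JUNCTION = 2.0 * math.pi / 3.0

A_LIKE = 25.0    # repulsion within a compatibility class
A_UNLIKE = 100.0 # repulsion across classes


class Species(enum.IntEnum):
    """The five bead species."""

    WATER = 0
    HEAD1 = 1
    TAIL1 = 2
    HEAD2 = 3
    TAIL2 = 4


N_SPECIES = 5

#: Hydrophilic compatibility class: water and both head species.
HYDROPHILIC = frozenset({Species.WATER, Species.HEAD1, Species.HEAD2})
#: Hydrophobic compatibility class: both tail species.
HYDROPHOBIC = frozenset({Species.TAIL1, Species.TAIL2})


@dataclass(frozen=True)
class DPDParams:
    """Core DPD parameters.

    The noise amplitude is tied to the friction by the
    fluctuation–dissipation relation ``sigma**2 = 2*gamma*kBT``; it is
    derived, never set independently.

    Parameters
    ----------
    rc : float
        Pair-interaction cutoff; the length unit (so 1.0 by definition).
    gamma : float
        Dissipative (friction) coefficient of the pair thermostat.
    dt : float
        Integration timestep, in tau.
    lam : float
        Velocity-prediction mixing parameter of the modified
        velocity-Verlet scheme; 0.5 recovers standard velocity-Verlet.
    kBT : float
        Thermostat target energy (the energy unit).
    m : float
        Bead mass (the mass unit).
    """

    rc: float = 1.0
    gamma: float = 4.5
    dt: float = 0.01
    lam: float = 0.5
    kBT: float = 1.0
    m: float = 1.0

    def __post_init__(self) -> None:
        if self.rc <= 0:
            raise ValueError(f"cutoff rc must be positive, got {self.rc}")
        if self.dt <= 0:
            raise ValueError(f"timestep dt must be positive, got {self.dt}")
        if not (0.0 < self.lam <= 1.0):
            raise ValueError(f"lambda must lie in (0, 1], got {self.lam}")
        if self.gamma < 0 or self.kBT < 0:
            raise ValueError("gamma and kBT must be non-negative")
        if self.m <= 0:
            raise ValueError("bead mass must be positive")

    @property
    def sigma(self) -> float:
        """Noise amplitude from fluctuation–dissipation: sqrt(2*gamma*kBT)."""
        return math.sqrt(2.0 * self.gamma * self.kBT)


@dataclass(frozen=True)
class InteractionTable:
    """Symmetric matrix of conservative repulsion amplitudes a[s, t].

    Units: kBT/rc.  Indexed by :class:`Species` values.
    """

    a: np.ndarray
    mode: str = "custom"

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=np.float64)
        if a.shape != (N_SPECIES, N_SPECIES):
            raise ValueError(f"interaction matrix must be {N_SPECIES}x{N_SPECIES}")
        if not np.allclose(a, a.T):
            raise ValueError("interaction matrix must be symmetric")
        if not np.all(a > 0):
            raise ValueError("all repulsion amplitudes must be positive")
        object.__setattr__(self, "a", a)

    def __getitem__(self, key: tuple[int, int]) -> float:
        s, t = key
        return float(self.a[int(s), int(t)])


def interaction_table(mode: str = "amphiphilic") -> InteractionTable:
    """Build the 5x5 repulsion table.

    ``amphiphilic`` (default): species are grouped into a hydrophilic class
    {water, head1, head2} and a hydrophobic class {tail1, tail2}; a=25
    within a class and a=100 across classes.  This is the standard
    lipid-DPD convention and makes head beads effectively water-liking.

    ``literal``: a=25 on the species diagonal and a=100 between any two
    distinct species, i.e. the same-species/different-species reading.
    Retained for auditing; it makes heads repel water and does not
    self-assemble bilayers.
    """
    if mode == "literal":
        a = np.full((N_SPECIES, N_SPECIES), A_UNLIKE)
        np.fill_diagonal(a, A_LIKE)
    elif mode == "amphiphilic":
        a = np.empty((N_SPECIES, N_SPECIES))
        for s in Species:
            for t in Species:
                same_class = (s in HYDROPHILIC) == (t in HYDROPHILIC)
                a[s, t] = A_LIKE if same_class else A_UNLIKE
    else:
        raise ValueError(
            f"unknown interaction mode {mode!r}; choose 'amphiphilic' or 'literal'"
        )
    return InteractionTable(a=a, mode=mode)


@dataclass(frozen=True)
class BondTerm:
    """Harmonic bond i-j with F = ks*(1 - r/rs) rhat."""

    i: int
    j: int
    ks: float = BOND_KS
    rs: float = BOND_RS

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("bond endpoints must differ")
        if self.ks < 0:
            raise ValueError("bond spring constant must be non-negative")
        if self.rs <= 0:
            raise ValueError("equilibrium bond length must be positive")


@dataclass(frozen=True)
class AngleTerm:
    """Harmonic bending term U = ktheta*(theta - theta0)**2 on triple (i, j, k).

    ``j`` is the vertex bead; ``theta`` is the angle between the bond
    vectors j->i and j->k.
    """

    i: int
    j: int
    k: int
    ktheta: float
    theta0: float

    def __post_init__(self) -> None:
        if len({self.i, self.j, self.k}) != 3:
            raise ValueError("angle triple must have three distinct beads")
        if self.ktheta < 0:
            raise ValueError("bending constant must be non-negative")
        if not (0.0 < self.theta0 <= math.pi):
            raise ValueError("equilibrium angle must lie in (0, pi]")


class InvalidArchitectureError(ValueError):
    """Raised for lipid head/tail bead counts below the supported minimum."""


@dataclass(frozen=True)
class LipidTopology:
    """Bead sequence, bonds and angles of one lipid molecule.

    Bead indices are molecule-local (0-based).  The head block always
    occupies indices ``0..n_head-1``; tails follow.
    """

    species_sequence: tuple[Species, ...]
    bonds: tuple[BondTerm, ...]
    angles: tuple[AngleTerm, ...]
    n_head: int
    n_tail_per_tail: int
    n_tails: int
    lipid_type: int  # 1 or 2

    @property
    def n_beads(self) -> int:
        return len(self.species_sequence)

    def __post_init__(self) -> None:
        if self.n_beads != self.n_head + self.n_tails * self.n_tail_per_tail:
            raise ValueError("bead count inconsistent with head/tail layout")
        # bond graph must be a spanning tree: connected and acyclic
        if len(self.bonds) != self.n_beads - 1:
            raise ValueError("bond graph of a lipid must be a tree")
        adj: dict[int, list[int]] = {i: [] for i in range(self.n_beads)}
        for b in self.bonds:
            adj[b.i].append(b.j)
            adj[b.j].append(b.i)
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if len(seen) != self.n_beads:
            raise ValueError("bond graph of a lipid must be connected")


def _backbone_angles(indices: list[int]) -> list[AngleTerm]:
    """Straightening terms on every consecutive triple of a chain segment."""
    return [
        AngleTerm(indices[t], indices[t + 1], indices[t + 2],
                  ANGLE_K_BACKBONE, ANGLE_T0_BACKBONE)
        for t in range(len(indices) - 2)
    ]


def build_lipid_type1(
    nh: int = 3,
    nt: int = 10,
    *,
    junction_angles: bool = True,
) -> LipidTopology:
    """Linear single-tail lipid: ``nh`` head beads then ``nt`` tail beads.

    Consecutive beads are bonded (ks=120, rs=0.7rc).  Every consecutive
    triple of the backbone carries a straightening angle (ktheta=6,
    theta0=pi).  Triples that straddle the head-tail junction are included
    by default so the whole molecule is rod-like at equilibrium; pass
    ``junction_angles=False`` to restrict angles to pure head and pure
    tail triples.
    """
    if nh < 2:
        raise InvalidArchitectureError(f"type-1 lipid needs >= 2 head beads, got {nh}")
    if nt < 1:
        raise InvalidArchitectureError(f"type-1 lipid needs >= 1 tail bead, got {nt}")
    seq = (Species.HEAD1,) * nh + (Species.TAIL1,) * nt
    n = nh + nt
    bonds = tuple(BondTerm(i, i + 1) for i in range(n - 1))
    if junction_angles:
        angles = tuple(_backbone_angles(list(range(n))))
    else:
        angles = tuple(
            _backbone_angles(list(range(nh))) + _backbone_angles(list(range(nh, n)))
        )
    return LipidTopology(seq, bonds, angles, nh, nt, 1, 1)


def build_lipid_type2(nh: int = 3, nt_per_tail: int = 10) -> LipidTopology:
    """Branched double-tail lipid.

    ``nh`` head beads form a chain; two tails of ``nt_per_tail`` beads each
    are bonded to the last head bead.  Angle terms:

    - (ktheta=6, theta0=pi) on pure-head and pure-tail consecutive triples;
    - (ktheta=3, theta0=2pi/3) on (head[-2], head[-1], first tail bead),
      one per tail;
    - (ktheta=4.5, theta0=2pi/3) on (head[-1], first tail bead, second
      tail bead), one per tail (absent when tails have a single bead).

    The two tails are independent: no angle couples tail 1 to tail 2.
    """
    if nh < 2:
        raise InvalidArchitectureError(f"type-2 lipid needs >= 2 head beads, got {nh}")
    if nt_per_tail < 1:
        raise InvalidArchitectureError(
            f"type-2 lipid needs >= 1 bead per tail, got {nt_per_tail}"
        )
    seq = (Species.HEAD2,) * nh + (Species.TAIL2,) * (2 * nt_per_tail)
    tail_a = list(range(nh, nh + nt_per_tail))
    tail_b = list(range(nh + nt_per_tail, nh + 2 * nt_per_tail))

    bonds = [BondTerm(i, i + 1) for i in range(nh - 1)]
    for tail in (tail_a, tail_b):
        bonds.append(BondTerm(nh - 1, tail[0]))
        bonds.extend(BondTerm(tail[t], tail[t + 1]) for t in range(len(tail) - 1))

    angles = _backbone_angles(list(range(nh)))
    for tail in (tail_a, tail_b):
        angles.extend(_backbone_angles(tail))
        if nh >= 2:
            angles.append(
                AngleTerm(nh - 2, nh - 1, tail[0],
                          ANGLE_K_JUNCTION_HH_T, ANGLE_T0_JUNCTION)
            )
        if len(tail) >= 2:
            angles.append(
                AngleTerm(nh - 1, tail[0], tail[1],
                          ANGLE_K_JUNCTION_H_TT, ANGLE_T0_JUNCTION)
            )
    return LipidTopology(seq, tuple(bonds), tuple(angles), nh, nt_per_tail, 2, 2)


@dataclass(frozen=True)
class UnitSystem:
    """Mapping between reduced and physical units.

    The physical cutoff follows from the bead volume and number density,
    ``rc = (rho*Vp)**(1/3)``; with the conventional Vp = 0.03 nm^3 and
    rho = 3 this gives rc ~ 0.45 nm, and the time unit maps to
    tau = 1.88 ns.
    """

    Vp_nm3: float = 0.03
    rho: float = 3.0
    tau_ns: float = 1.88

    @property
    def rc_nm(self) -> float:
        return (self.rho * self.Vp_nm3) ** (1.0 / 3.0)


def physical_time(n_steps: int, units: UnitSystem | None = None,
                  params: DPDParams | None = None) -> float:
    """Physical duration of ``n_steps`` timesteps, in nanoseconds."""
    if n_steps < 0:
        raise ValueError("step count must be non-negative")
    units = units or UnitSystem()
    params = params or DPDParams()
    return n_steps * params.dt * units.tau_ns


@dataclass
class RunConfig:
    """Full run configuration with the production study as defaults.

    The production setup: cubic box L=30rc at bead density rho=3, 600
    lipids of each type with 3 head beads and 10-bead tails, 200,000
    timesteps.  ``swap_interval`` W controls shear: 0 means no shear;
    W=6 drives the weak flow and W=1 the strong flow.
    """

    box_lengths: tuple[float, float, float] = (30.0, 30.0, 30.0)
    n_lipids_1: int = 600
    n_lipids_2: int = 600
    nh1: int = 3
    nh2: int = 3
    nt1: int = 10
    nt2: int = 10
    rho: float = 3.0
    total_steps: int = 200_000
    swap_interval: int = 0  # 0 = shear off
    n_slabs: int = 20
    interaction_mode: str = "amphiphilic"
    seed: int = 0
    traj_every: int = 1000
    energy_every: int = 100
    params: DPDParams = field(default_factory=DPDParams)

    def __post_init__(self) -> None:
        lx, ly, lz = self.box_lengths
        if min(lx, ly, lz) <= 2.0 * self.params.rc:
            raise ValueError("box lengths must exceed 2*rc")
        if self.total_steps < 0:
            raise ValueError("total_steps must be non-negative")
        if self.swap_interval < 0:
            raise ValueError("swap_interval must be >= 0 (0 disables shear)")
        if self.rho <= 0:
            raise ValueError("bead density must be positive")
        if self.n_total_beads < self.n_lipid_beads:
            raise ValueError(
                "box too small: lipid beads exceed rho*V "
                f"({self.n_lipid_beads} > {self.n_total_beads})"
            )

    @property
    def topology_1(self) -> LipidTopology:
        return build_lipid_type1(self.nh1, self.nt1)

    @property
    def topology_2(self) -> LipidTopology:
        return build_lipid_type2(self.nh2, self.nt2)

    @property
    def n_lipid_beads(self) -> int:
        return (self.n_lipids_1 * (self.nh1 + self.nt1)
                + self.n_lipids_2 * (self.nh2 + 2 * self.nt2))

    @property
    def n_total_beads(self) -> int:
        lx, ly, lz = self.box_lengths
        return int(round(self.rho * lx * ly * lz))

    @property
    def n_water_beads(self) -> int:
        return self.n_total_beads - self.n_lipid_beads

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    # -- TOML round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["box_lengths"] = list(self.box_lengths)
        d["params"] = {
            "rc": self.params.rc, "gamma": self.params.gamma,
            "dt": self.params.dt, "lam": self.params.lam,
            "kBT": self.params.kBT, "m": self.params.m,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        if "box_lengths" in d:
            d["box_lengths"] = tuple(float(x) for x in d["box_lengths"])
        if "params" in d:
            d["params"] = DPDParams(**d["params"])
        return cls(**d)

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def to_toml(self, path) -> None:
        def fmt(v):
            if isinstance(v, bool):
                return "true" if v else "false"
            if isinstance(v, str):
                return f'"{v}"'
            if isinstance(v, (list, tuple)):
                return "[" + ", ".join(fmt(x) for x in v) + "]"
            return repr(v)

        lines = []
        d = self.to_dict()
        params = d.pop("params")
        for k, v in d.items():
            lines.append(f"{k} = {fmt(v)}")
        lines.append("")
        lines.append("[params]")
        for k, v in params.items():
            lines.append(f"{k} = {fmt(v)}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
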