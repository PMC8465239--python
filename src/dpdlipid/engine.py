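"""DPD integration engine.

Forces are the soft conservative pair repulsion, the pairwise
dissipative/random thermostat satisfying fluctuation-dissipation, and the
harmonic bond and bending terms of the lipid molecules.  Integration uses
the modified velocity-Verlet scheme: positions advance with the cached
force, a predicted velocity v~ = v + lambda*dt*f enters the dissipative
force at the new positions, and the final velocity uses the trapezoidal
force average.  One force evaluation per step; the evaluation at t+dt is
reused as f(t) of the next step.

Determinism: the random pair force is keyed on (seed, step, i<j), so a run
is bitwise reproducible for a given (initial state, seed) regardless of
neighbor-list iteration order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .builder import SystemState, SystemTopology
from .model import DPDParams, InteractionTable, interaction_table

__all__ = ["Simulation", "Trajectory", "IntegrationBlowupError",
           "kinetic_temperature", "total_energy", "weight"]


def weight(r, rc: float = 1.0):
    """DPD weight function w(r) = 1 - r/rc for r < rc, else 0.

    Accepts scalars or arrays; negative distances are rejected.
    """
    r = np.asarray(r, dtype=np.float64)
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    out = np.where(r < rc, 1.0 - r / rc, 0.0)
    return float(out) if out.ndim == 0 else out


class IntegrationBlowupError(RuntimeError):
    """Raised when coordinates become non-finite during integration."""


def kinetic_temperature(state: SystemState, m: float = 1.0) -> float:
    """Instantaneous kinetic temperature <m v^2>/3 per bead."""
    v2 = np.einsum("ij,ij->", state.velocities, state.velocities)
    return m * v2 / (3.0 * state.n_beads)


@dataclass
class Trajectory:
    """Frames, energy series and shear bookkeeping emitted by a run."""

    frames: list = field(default_factory=list)
    frame_steps: list = field(default_factory=list)
    energy_steps: list = field(default_factory=list)
    potential: list = field(default_factory=list)
    kinetic: list = field(default_factory=list)
    swap_steps: list = field(default_factory=list)
    swap_px: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)

    def energy_table(self):
        """Energy series as a pandas DataFrame (step, potential, kinetic, total)."""
        import pandas as pd

        ep = np.asarray(self.potential)
        ek = np.asarray(self.kinetic)
        return pd.DataFrame({
            "step": np.asarray(self.energy_steps, dtype=np.int64),
            "potential": ep,
            "kinetic": ek,
            "total": ep + ek,
        })


class Simulation:
    """A DPD system ready to integrate.

    Parameters
    ----------
    state : SystemState
        Initial configuration; advanced in place by :meth:`run`.
    topology : SystemTopology, optional
        Bonded interactions; omit for a pure-water box.
    table : InteractionTable, optional
        Conservative repulsion matrix (default: amphiphilic class matrix).
    params : DPDParams, optional
    seed : int
        Seed of the counter-based random-force stream.
    shear : dpdlipid.shear.ShearProtocol, optional
        When set, its momentum swap runs every ``swap_interval`` steps.
    """

    def __init__(self, state: SystemState, topology: SystemTopology | None = None,
                 table: InteractionTable | None = None,
                 params: DPDParams | None = None, seed: int = 0,
                 shear=None) -> None:
        self.state = state
        self.topology = topology if topology is not None else SystemTopology.empty()
        self.table = table if table is not None else interaction_table()
        self.params = params if params is not None else DPDParams()
        self.seed = int(seed)
        self.shear = shear
        self._forces: np.ndarray | None = None
        self._epot = 0.0

    # -- force evaluation ---------------------------------------------------

    def compute_forces(self, positions: np.ndarray | None = None,
                       velocities: np.ndarray | None = None,
                       step: int | None = None,
                       thermostat: bool = True):
        """Total forces at given coordinates.

        Returns ``(forces, potential_energy, conservative_virial_diag)``.
        With ``thermostat=False`` only conservative + bonded terms enter
        (used for energy-conservation checks and the pressure module).
        """
        p = self.params
        pos = self.state.positions if positions is None else positions
        vel = self.state.velocities if velocities is None else velocities
        step = self.state.step_index if step is None else step
        box = self.state.box
        forces = np.zeros_like(pos)
        virial = np.zeros(3)
        gamma = p.gamma if thermostat else 0.0
        sigma = p.sigma if thermostat else 0.0
        pi, pj = _kernels.find_pairs(pos, box, p.rc)
        base = np.uint64(_kernels.noise_base(self.seed, step))
        epot = _kernels.pair_forces(
            pos, vel, self.state.species, pi, pj, box, self.table.a, p.rc,
            gamma, sigma, 1.0 / math.sqrt(p.dt), base, forces, virial,
        )
        topo = self.topology
        if topo.bond_ij.shape[0]:
            epot += _kernels.bond_forces(pos, topo.bond_ij, topo.bond_ks,
                                         topo.bond_rs, box, forces, virial)
        if topo.angle_ijk.shape[0]:
            epot += _kernels.angle_forces(pos, topo.angle_ijk, topo.angle_k,
                                          topo.angle_t0, box, forces, virial)
        return forces, epot, virial

    # -- observables --------------------------------------------------------

    def total_energy(self) -> tuple[float, float]:
        """(potential, kinetic) energy of the current state.

        Potential is the conservative content only: soft pair repulsion,
        bond and angle terms (the antiderivatives of the conservative
        forces); the thermostat forces have no potential.
        """
        _, epot, _ = self.compute_forces(thermostat=False)
        s = self.state
        ekin = 0.5 * self.params.m * np.einsum(
            "ij,ij->", s.velocities, s.velocities)
        return epot, ekin

    def pressure_tensor_diag(self) -> np.ndarray:
        """Global virial pressure components (pxx, pyy, pzz)."""
        _, _, virial = self.compute_forces(thermostat=False)
        s = self.state
        vol = float(np.prod(s.box))
        kin = self.params.m * np.einsum("ij,ij->j", s.velocities, s.velocities)
        return (kin + virial) / vol

    def temperature(self) -> float:
        return kinetic_temperature(self.state, self.params.m)

    # -- integration --------------------------------------------------------

    def step(self) -> None:
        """Advance one timestep (modified velocity-Verlet)."""
        p = self.params
        s = self.state
        dt = p.dt
        inv_m = 1.0 / p.m
        if self._forces is None:
            self._forces, self._epot, _ = self.compute_forces()
        f = self._forces
        s.positions += dt * s.velocities + (0.5 * dt * dt * inv_m) * f
        s.wrap()
        v_pred = s.velocities + (p.lam * dt * inv_m) * f
        f_new, epot, _ = self.compute_forces(
            velocities=v_pred, step=s.step_index + 1)
        s.velocities += (0.5 * dt * inv_m) * (f + f_new)
        self._forces = f_new
        self._epot = epot
        s.step_index += 1

    def run(self, n_steps: int, traj_every: int = 0, energy_every: int = 0,
            check_every: int = 100, record_initial: bool = True) -> Trajectory:
        """Advance ``n_steps`` steps, recording frames and energies.

        ``traj_every``/``energy_every`` of 0 disables the respective
        cadence (the final frame is always recorded when ``traj_every``
        is nonzero).  Momentum swaps interleave every ``swap_interval``
        steps when a shear protocol is attached.
        """
        traj = Trajectory()

        def record_frame():
            traj.frames.append(self.state.copy())
            traj.frame_steps.append(self.state.step_index)

        def record_energy():
            epot, ekin = self._epot, 0.5 * self.params.m * np.einsum(
                "ij,ij->", self.state.velocities, self.state.velocities)
            traj.energy_steps.append(self.state.step_index)
            traj.potential.append(epot)
            traj.kinetic.append(ekin)

        if self._forces is None and n_steps > 0:
            self._forces, self._epot, _ = self.compute_forces()
        if record_initial and traj_every:
            record_frame()
        if record_initial and energy_every and n_steps > 0:
            record_energy()

        for k in range(n_steps):
            if self.shear is not None and self.shear.active:
                if self.state.step_index % self.shear.swap_interval == 0:
                    dpx = self.shear.momentum_swap(self.state)
                    traj.swap_steps.append(self.state.step_index)
                    traj.swap_px.append(dpx)
            self.step()
            done = k == n_steps - 1
            if energy_every and (self.state.step_index % energy_every == 0
                                 or done):
                record_energy()
            if traj_every and (self.state.step_index % traj_every == 0 or done):
                if not (traj.frame_steps
                        and traj.frame_steps[-1] == self.state.step_index):
                    record_frame()
            if (check_every and self.state.step_index % check_every == 0) or done:
                if not np.all(np.isfinite(self.state.positions)):
                    raise IntegrationBlowupError(
                        f"non-finite coordinates at step {self.state.step_index}"
                    )
        return traj


def total_energy(state: SystemState, topology: SystemTopology | None = None,
                 table: InteractionTable | None = None,
                 params: DPDParams | None = None) -> tuple[float, float]:
    """Functional form of :meth:`Simulation.total_energy`."""
    return Simulation(state, topology, table, params).total_energy()
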