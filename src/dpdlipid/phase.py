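"""Morphology classification and phase-diagram sweeps.

A configuration is labelled by the periodic-percolation topology of its
largest hydrophobic (tail-bead) cluster, beads being linked when closer
than the interaction range rc:

- cluster spans >= 2 box axes  -> MEMBRANE (a lamella wraps two axes)
- cluster spans exactly 1 axis -> TUBE
- cluster spans no axis        -> VESICLE (closed aggregate; the evidence
  records whether it encloses an interior cavity, distinguishing a true
  vesicle from a filled micelle)

The classifier is deterministic and invariant under periodic translation
and axis permutation of the state.  :func:`phase_sweep` drives reduced-
scale simulations over a (NT1, NT2) grid at fixed shear and records the
modal label per cell.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from . import _kernels
from .builder import SystemState, random_initial_configuration
from .model import RunConfig, Species, interaction_table

__all__ = ["PhaseLabel", "Morphology", "PhaseDiagram",
           "classify_structure", "phase_sweep"]

logger = logging.getLogger(__name__)


class Morphology(enum.Enum):
    MEMBRANE = "membrane"
    TUBE = "tube"
    VESICLE = "vesicle"
    OTHER = "other"


@dataclass(frozen=True)
class PhaseLabel:
    """Assigned morphology plus the evidence that produced it."""

    label: Morphology
    spanning_axes: tuple[int, ...]
    n_clusters: int
    largest_cluster_size: int
    has_enclosed_interior: bool
    encloses_water: bool


def _percolation_axes(pos: np.ndarray, box: np.ndarray,
                      pi: np.ndarray, pj: np.ndarray,
                      members: np.ndarray) -> tuple[int, ...]:
    """Axes along which the bead set winds around the periodic box.

    BFS assigns each bead an unwrapped image; a non-tree edge whose
    minimum-image displacement disagrees with the assigned images by a
    whole box vector exposes a winding (percolating) direction.
    """
    n = pos.shape[0]
    in_set = np.zeros(n, dtype=bool)
    in_set[members] = True
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in zip(pi, pj):
        if in_set[a] and in_set[b]:
            adj[a].append(b)
            adj[b].append(a)
    unwrapped = np.zeros((n, 3))
    visited = np.zeros(n, dtype=bool)
    root = int(members[0])
    visited[root] = True
    unwrapped[root] = pos[root]
    queue = [root]
    winding = np.zeros(3, dtype=bool)
    while queue:
        u = queue.pop()
        for v in adj[u]:
            d = pos[v] - pos[u]
            d -= box * np.round(d / box)
            cand = unwrapped[u] + d
            if not visited[v]:
                visited[v] = True
                unwrapped[v] = cand
                queue.append(v)
            else:
                shift = np.round((cand - unwrapped[v]) / box)
                winding |= shift != 0
    return tuple(int(a) for a in np.flatnonzero(winding))


def _enclosed_interior(state: SystemState, voxel: float = 0.75):
    """Detect a cavity sealed off from the bulk by lipid beads.

    Voxelizes the box, marks voxels containing lipid beads as occupied,
    and counts periodic connected components of the empty region: more
    than one means the aggregate walls off an interior.  Returns
    (has_interior, interior_contains_water).
    """
    box = state.box
    dims = np.maximum((box / voxel).astype(int), 3)
    lipid = state.species != int(Species.WATER)
    idx = np.minimum((state.positions[lipid] / box * dims).astype(int),
                     dims - 1)
    occ = np.zeros(dims, dtype=bool)
    occ[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    labels, n = ndimage.label(~occ)
    if n == 0:
        return False, False
    # merge labels across the three periodic faces
    parent = np.arange(n + 1)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for ax in range(3):
        lo = np.take(labels, 0, axis=ax).ravel()
        hi = np.take(labels, dims[ax] - 1, axis=ax).ravel()
        for a, b in zip(lo, hi):
            if a and b:
                union(a, b)
    roots = {find(l) for l in range(1, n + 1)}
    if len(roots) <= 1:
        return False, False
    # the bulk component is the largest; any other empty component is interior
    sizes = {r: 0 for r in roots}
    flat = labels.ravel()
    for l, c in zip(*np.unique(flat[flat > 0], return_counts=True)):
        sizes[find(l)] += int(c)
    bulk = max(sizes, key=sizes.get)
    interior_mask = np.zeros(dims, dtype=bool)
    for l in range(1, n + 1):
        r = find(l)
        if r != bulk:
            interior_mask |= labels == l
    if not interior_mask.any():
        return False, False
    water_idx = np.minimum(
        (state.positions[~lipid] / box * dims).astype(int), dims - 1)
    contains_water = bool(
        water_idx.size
        and interior_mask[water_idx[:, 0], water_idx[:, 1],
                          water_idx[:, 2]].any()
    )
    return True, contains_water


def classify_structure(state: SystemState, rc: float = 1.0) -> PhaseLabel:
    """Assign MEMBRANE / TUBE / VESICLE / OTHER to a configuration."""
    tails = np.flatnonzero(
        (state.species == int(Species.TAIL1))
        | (state.species == int(Species.TAIL2))
    )
    if tails.size == 0:
        raise ValueError("no tail beads: nothing to classify")
    pos = state.positions
    box = state.box
    pi, pj = _kernels.find_pairs(pos[tails], box, rc)
    graph = coo_matrix(
        (np.ones(pi.size), (pi, pj)), shape=(tails.size, tails.size)
    )
    n_comp, comp = connected_components(graph, directed=False)
    sizes = np.bincount(comp)
    largest = int(sizes.argmax())
    members_local = np.flatnonzero(comp == largest)
    if members_local.size < 4:
        return PhaseLabel(Morphology.OTHER, (), n_comp,
                          int(members_local.size), False, False)
    axes = _percolation_axes(pos[tails], box, pi, pj, members_local)
    if len(axes) >= 2:
        label = Morphology.MEMBRANE
        interior = water_in = False
    elif len(axes) == 1:
        label = Morphology.TUBE
        interior = water_in = False
    else:
        interior, water_in = _enclosed_interior(state)
        label = Morphology.VESICLE
    return PhaseLabel(label, axes, n_comp, int(sizes[largest]),
                      interior, water_in)


@dataclass
class PhaseDiagram:
    """Grid of labels over tail lengths (NT1 x NT2) at fixed shear."""

    nt1_values: tuple[int, ...]
    nt2_values: tuple[int, ...]
    swap_interval: int
    cells: dict = field(default_factory=dict)  # (nt1, nt2) -> cell record

    def modal_label(self, nt1: int, nt2: int) -> str | None:
        cell = self.cells.get((nt1, nt2))
        if not cell or not cell["labels"]:
            return None
        labels = cell["labels"]
        return max(set(labels), key=labels.count)

    def to_frame(self):
        import pandas as pd

        rows = []
        for (nt1, nt2), cell in sorted(self.cells.items()):
            rows.append({
                "nt1": nt1, "nt2": nt2,
                "label": self.modal_label(nt1, nt2),
                "n_seeds": len(cell["labels"]),
                "agreement": (cell["labels"].count(self.modal_label(nt1, nt2))
                              / len(cell["labels"]) if cell["labels"] else 0.0),
                "failures": cell["failures"],
                "min_potential": (min(cell["potentials"])
                                  if cell["potentials"] else np.nan),
            })
        return pd.DataFrame(rows)


def phase_sweep(
    base_config: RunConfig,
    nt1_values,
    nt2_values,
    seeds=(0,),
    steps: int | None = None,
    progress: bool = False,
) -> PhaseDiagram:
    """Run reduced-scale simulations over the tail-length grid and classify.

    Each cell runs ``len(seeds)`` independent random starts of
    ``base_config`` with the cell's (nt1, nt2); the final frame is
    classified and its potential energy recorded, so the minimum-energy
    seed is identifiable.  Per-cell failures are recorded and the sweep
    continues.
    """
    from .engine import Simulation
    from .shear import ShearProtocol

    steps = base_config.total_steps if steps is None else steps
    diagram = PhaseDiagram(tuple(nt1_values), tuple(nt2_values),
                           base_config.swap_interval)
    table = interaction_table(base_config.interaction_mode)
    for nt1 in nt1_values:
        for nt2 in nt2_values:
            cell = {"labels": [], "potentials": [], "failures": 0,
                    "evidence": []}
            diagram.cells[(nt1, nt2)] = cell
            for seed in seeds:
                try:
                    config = base_config.replace(nt1=int(nt1), nt2=int(nt2),
                                                 seed=int(seed))
                    state, topo = random_initial_configuration(config)
                    shear = (ShearProtocol(config.swap_interval,
                                           config.n_slabs)
                             if config.swap_interval else None)
                    sim = Simulation(state, topo, table, config.params,
                                     seed=int(seed), shear=shear)
                    sim.run(steps)
                    epot, _ = sim.total_energy()
                    result = classify_structure(state, config.params.rc)
                    cell["labels"].append(result.label.value)
                    cell["potentials"].append(epot)
                    cell["evidence"].append(result)
                except Exception:
                    logger.exception("sweep cell (%d, %d) seed %d failed",
                                     nt1, nt2, seed)
                    cell["failures"] += 1
            if progress:
                logger.info("cell (%d, %d): %s", nt1, nt2,
                            diagram.modal_label(nt1, nt2))
    return diagram
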