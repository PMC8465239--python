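"""Observables: density profiles, head order parameter, gyration tensor,
shape factor, and Irving-Kirkwood pressure/tension profiles.

Chains are unwrapped across the periodic boundary by a minimum-image walk
along the bond tree before any shape analysis; profiles operate on wrapped
coordinates.  Unless noted otherwise an operation accepts either a single
:class:`~dpdlipid.builder.SystemState` or an iterable of frames and
averages over them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .builder import SystemState, SystemTopology
from .model import DPDParams, InteractionTable, Species, interaction_table

__all__ = [
    "ProfileResult", "GyrationResult", "PressureProfile",
    "density_profile", "unwrap_chain", "chain_head_vectors",
    "p2_order", "order_parameter", "order_parameter_profile",
    "gyration_tensor", "shape_factor", "rg_components_series",
    "membrane_gyration_components", "shape_factor_series",
    "pressure_profile", "tension_profile", "integrated_tension",
]

_AXIS = {"x": 0, "y": 1, "z": 2}


def _frames(obj) -> list[SystemState]:
    if isinstance(obj, SystemState):
        return [obj]
    out = list(obj)
    if not out:
        raise ValueError("empty frame window")
    return out


@dataclass
class ProfileResult:
    """A binned quantity along one box axis.

    ``values`` maps a label (species name or quantity) to a per-bin array.
    For densities the label's array integrates (value * bin volume) to the
    bead count of that label.
    """

    axis: str
    bin_edges: np.ndarray
    values: dict[str, np.ndarray]
    n_frames: int = 1
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self):
        import pandas as pd

        d = {self.axis: self.bin_centers}
        d.update(self.values)
        return pd.DataFrame(d)


def density_profile(window, species, axis: str = "z",
                    n_bins: int = 60) -> ProfileResult:
    """Frame-averaged number density (beads/rc^3) of selected species.

    ``species`` is a single :class:`Species`, an iterable of them, or
    ``None`` for one curve per species present.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    frames = _frames(window)
    ax = _AXIS[axis]
    box = frames[0].box
    length = box[ax]
    edges = np.linspace(0.0, length, n_bins + 1)
    bin_vol = np.prod(box) / n_bins / 1.0  # slab volume per bin

    if species is None:
        sel = sorted({int(s) for fr in frames for s in np.unique(fr.species)})
    elif isinstance(species, (int, Species)):
        sel = [int(species)]
    else:
        sel = [int(s) for s in species]
    if not sel:
        raise ValueError("empty species selection")

    values = {}
    for sp in sel:
        acc = np.zeros(n_bins)
        for fr in frames:
            mask = fr.species == sp
            coords = fr.positions[mask, ax] % length
            hist, _ = np.histogram(coords, bins=edges)
            acc += hist
        values[Species(sp).name] = acc / (len(frames) * bin_vol)
    return ProfileResult(axis, edges, values, len(frames))


# ---------------------------------------------------------------------------
# Chain geometry
# ---------------------------------------------------------------------------

def unwrap_chain(state: SystemState, topology: SystemTopology,
                 chain: int) -> np.ndarray:
    """Chain coordinates made whole by a minimum-image walk from bead 0.

    Bonds of the molecule template are listed parent-first, so a single
    pass assigns every bead an image consistent with its bonded neighbor.
    """
    start = topology.chain_start[chain]
    n = topology.chain_nbeads[chain]
    tmpl = topology.templates[int(topology.chain_type[chain])]
    box = state.box
    wrapped = state.positions[start:start + n]
    out = np.empty((n, 3))
    out[0] = wrapped[0]
    placed = np.zeros(n, dtype=bool)
    placed[0] = True
    for b in tmpl.bonds:
        i, j = b.i, b.j
        if placed[i] and not placed[j]:
            src, dst = i, j
        elif placed[j] and not placed[i]:
            src, dst = j, i
        else:
            continue
        d = wrapped[dst] - wrapped[src]
        d -= box * np.round(d / box)
        out[dst] = out[src] + d
        placed[dst] = True
    return out


def chain_head_vectors(state: SystemState, topology: SystemTopology,
                       lipid_type: int | None = None):
    """First-to-last head-bead vector and head centroid of each chain.

    Returns (vectors (n,3), centroids (n,3), chain indices).  Chains with
    fewer than 2 head beads are excluded.
    """
    vecs, cents, idx = [], [], []
    for c in range(topology.n_chains):
        if lipid_type is not None and topology.chain_type[c] != lipid_type:
            continue
        nh = int(topology.chain_nhead[c])
        if nh < 2:
            continue
        xyz = unwrap_chain(state, topology, c)
        vecs.append(xyz[nh - 1] - xyz[0])
        cents.append(xyz[:nh].mean(axis=0))
        idx.append(c)
    if not vecs:
        raise ValueError("no chains with a >=2-bead head block")
    return np.asarray(vecs), np.asarray(cents), np.asarray(idx)


def p2_order(vectors: np.ndarray, axis: str = "z"):
    """Second Legendre polynomial <(3 cos^2 theta - 1)/2> of given vectors.

    Returns (per-vector P2 array, number of zero-length vectors excluded).
    1 = parallel to the axis, -0.5 = perpendicular, 0 = isotropic.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=np.float64))
    norms = np.linalg.norm(vectors, axis=1)
    ok = norms > 1.0e-12
    cos = vectors[ok, _AXIS[axis]] / norms[ok]
    return 1.5 * cos**2 - 0.5, int((~ok).sum())


def order_parameter(window, topology: SystemTopology,
                    lipid_type: int | None = None, axis: str = "z") -> float:
    """Scalar head order parameter averaged over chains and frames."""
    vals = []
    for fr in _frames(window):
        vecs, _, _ = chain_head_vectors(fr, topology, lipid_type)
        p2, _ = p2_order(vecs, axis)
        vals.append(p2)
    return float(np.concatenate(vals).mean())


def order_parameter_profile(window, topology: SystemTopology,
                            n_bins: int = 30, axis: str = "z",
                            lipid_type: int | None = None) -> ProfileResult:
    """Head order parameter binned by the head-block centroid position."""
    frames = _frames(window)
    ax = _AXIS[axis]
    length = frames[0].box[ax]
    edges = np.linspace(0.0, length, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    excluded = 0
    for fr in frames:
        vecs, cents, _ = chain_head_vectors(fr, topology, lipid_type)
        p2, nz = p2_order(vecs, axis)
        excluded += nz
        norms = np.linalg.norm(vecs, axis=1)
        zc = cents[norms > 1.0e-12, ax] % length
        which = np.minimum((zc / length * n_bins).astype(np.int64), n_bins - 1)
        sums += np.bincount(which, weights=p2, minlength=n_bins)
        counts += np.bincount(which, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    label = "P2" if lipid_type is None else f"P2_type{lipid_type}"
    return ProfileResult(axis, edges, {label: mean}, len(frames),
                         counts={label: counts})


# ---------------------------------------------------------------------------
# Gyration tensor and shape factor
# ---------------------------------------------------------------------------

@dataclass
class GyrationResult:
    """Gyration tensor of one chain, its eigenvalues and derived shape."""

    tensor: np.ndarray          # 3x3, symmetric PSD (units rc^2)
    eigenvalues: np.ndarray     # sorted descending: L1^2 >= L2^2 >= L3^2

    @property
    def components(self) -> np.ndarray:
        """(Rgxx, Rgyy, Rgzz) as square roots of the diagonal entries."""
        return np.sqrt(np.diag(self.tensor))

    @property
    def rg(self) -> float:
        return float(np.sqrt(self.tensor.trace()))


def gyration_tensor(chain_positions: np.ndarray) -> GyrationResult:
    """Second-moment tensor of bead positions about the chain centroid.

    The chain must be unwrapped first (see :func:`unwrap_chain`).
    """
    xyz = np.asarray(chain_positions, dtype=np.float64)
    if xyz.ndim != 2 or xyz.shape[0] < 2:
        raise ValueError("gyration tensor needs at least 2 beads")
    d = xyz - xyz.mean(axis=0)
    t = d.T @ d / xyz.shape[0]
    eig = np.sort(np.linalg.eigvalsh(t))[::-1]
    return GyrationResult(t, eig)


def shape_factor(g) -> float:
    """Shape factor delta = 1 - 3 (L1L2 + L2L3 + L1L3) / (L1+L2+L3)^2.

    (Li denote squared eigenvalues of the gyration tensor.)  0 for
    spherically symmetric mass distributions, 1 for collinear ones.
    Accepts a :class:`GyrationResult` or a length-3 eigenvalue array.
    """
    lam = g.eigenvalues if isinstance(g, GyrationResult) else np.asarray(g)
    l1, l2, l3 = float(lam[0]), float(lam[1]), float(lam[2])
    s = l1 + l2 + l3
    if s <= 0.0:
        raise ValueError("shape factor undefined for a point distribution")
    return 1.0 - 3.0 * (l1 * l2 + l2 * l3 + l1 * l3) / (s * s)


def _per_type_chains(topology: SystemTopology, lipid_type: int) -> np.ndarray:
    sel = np.flatnonzero(topology.chain_type == lipid_type)
    if sel.size == 0:
        raise ValueError(f"no chains of lipid type {lipid_type}")
    return sel


def rg_components_series(window, topology: SystemTopology, lipid_type: int):
    """Per-frame averages of (Rgxx, Rgyy, Rgzz) over chains of one type.

    Returns a pandas DataFrame with columns step, Rgxx, Rgyy, Rgzz.
    """
    import pandas as pd

    sel = _per_type_chains(topology, lipid_type)
    rows = []
    for fr in _frames(window):
        comps = np.array([
            gyration_tensor(unwrap_chain(fr, topology, c)).components
            for c in sel
        ])
        rows.append((fr.step_index, *comps.mean(axis=0)))
    return pd.DataFrame(rows, columns=["step", "Rgxx", "Rgyy", "Rgzz"])


def membrane_gyration_components(window, topology: SystemTopology,
                                 lipid_type: int):
    """Aggregate gyration components over the chain centers of mass.

    The second-moment tensor is taken over the centers of mass of all
    chains of one lipid type (normalized by the number of chains), per
    frame.  For a box-spanning membrane this measures the aggregate's
    extent: large, near-equal in-plane components and a small normal
    component.  Complements :func:`rg_components_series`, which averages
    per-molecule tensors and therefore tracks single-chain conformation
    instead.  Returns a DataFrame with columns step, Rgxx, Rgyy, Rgzz.
    """
    import pandas as pd

    sel = _per_type_chains(topology, lipid_type)
    rows = []
    for fr in _frames(window):
        coms = np.array([unwrap_chain(fr, topology, c).mean(axis=0) % fr.box
                         for c in sel])
        if coms.shape[0] < 2:
            raise ValueError("aggregate gyration needs at least 2 chains")
        d = coms - coms.mean(axis=0)
        rows.append((fr.step_index, *np.sqrt((d * d).mean(axis=0))))
    return pd.DataFrame(rows, columns=["step", "Rgxx", "Rgyy", "Rgzz"])


def shape_factor_series(window, topology: SystemTopology, lipid_type: int):
    """Per-frame mean shape factor over chains of one type (DataFrame)."""
    import pandas as pd

    sel = _per_type_chains(topology, lipid_type)
    rows = []
    for fr in _frames(window):
        deltas = [
            shape_factor(gyration_tensor(unwrap_chain(fr, topology, c)))
            for c in sel
        ]
        rows.append((fr.step_index, float(np.mean(deltas))))
    return pd.DataFrame(rows, columns=["step", "delta"])


# ---------------------------------------------------------------------------
# Pressure and tension profiles
# ---------------------------------------------------------------------------

@dataclass
class PressureProfile:
    """Slab-resolved diagonal pressure components along z.

    The kinetic term is assigned to the bead's slab; the configurational
    (pair-virial) term is spread along the minimum-image i-j segment
    (Irving-Kirkwood contour), so slab averages reproduce the global
    virial pressure exactly.  Virial content: conservative pair + bond +
    angle forces (the thermostat contributions are excluded).
    """

    bin_edges: np.ndarray
    pxx: np.ndarray
    pyy: np.ndarray
    pzz: np.ndarray
    n_frames: int
    box: np.ndarray

    @property
    def n_slabs(self) -> int:
        return self.pxx.shape[0]

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def global_components(self) -> np.ndarray:
        """Slab-volume-weighted averages (pxx, pyy, pzz) over the box."""
        return np.array([self.pxx.mean(), self.pyy.mean(), self.pzz.mean()])


def pressure_profile(window, n_slabs: int = 20,
                     table: InteractionTable | None = None,
                     topology: SystemTopology | None = None,
                     params: DPDParams | None = None) -> PressureProfile:
    """Irving-Kirkwood pressure components per z-slab, frame-averaged."""
    if n_slabs < 2:
        raise ValueError("need at least 2 slabs")
    frames = _frames(window)
    table = table if table is not None else interaction_table()
    params = params if params is not None else DPDParams()
    topo = topology if topology is not None else SystemTopology.empty()
    box = frames[0].box
    lz = box[2]
    h = lz / n_slabs
    slab_vol = box[0] * box[1] * h
    acc = np.zeros((n_slabs, 3))
    for fr in frames:
        vir = np.zeros((n_slabs, 3))
        pi, pj = _kernels.find_pairs(fr.positions, box, params.rc)
        _kernels.slab_pair_virial(fr.positions, pi, pj, fr.species,
                                  table.a, box, params.rc, n_slabs, vir)
        if topo.bond_ij.shape[0]:
            _kernels.slab_bond_virial(fr.positions, topo.bond_ij, topo.bond_ks,
                                      topo.bond_rs, box, n_slabs, vir)
        if topo.angle_ijk.shape[0]:
            _kernels.slab_angle_virial(fr.positions, topo.angle_ijk,
                                       topo.angle_k, topo.angle_t0, box,
                                       n_slabs, vir)
        slab = np.minimum((fr.positions[:, 2] % lz) / h,
                          n_slabs - 1).astype(np.int64)
        for a in range(3):
            kin = np.bincount(slab, weights=params.m * fr.velocities[:, a] ** 2,
                              minlength=n_slabs)
            acc[:, a] += (kin + vir[:, a]) / slab_vol
    acc /= len(frames)
    edges = np.linspace(0.0, lz, n_slabs + 1)
    return PressureProfile(edges, acc[:, 0], acc[:, 1], acc[:, 2],
                           len(frames), box.copy())


def tension_profile(pressure: PressureProfile) -> ProfileResult:
    """Interfacial tension sigma(z) = pzz - (pxx + pyy)/2 per slab.

    Vanishes slab-by-slab in isotropic bulk; see
    :func:`integrated_tension` for the z-integral (total tension).
    """
    sigma = pressure.pzz - 0.5 * (pressure.pxx + pressure.pyy)
    return ProfileResult("z", pressure.bin_edges, {"sigma_z": sigma},
                         pressure.n_frames)


def integrated_tension(pressure: PressureProfile) -> float:
    """Total interfacial tension: integral of sigma(z) dz over the box."""
    sigma = pressure.pzz - 0.5 * (pressure.pxx + pressure.pyy)
    h = pressure.box[2] / pressure.n_slabs
    return float(sigma.sum() * h)
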