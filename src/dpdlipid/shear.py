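"""Reverse non-equilibrium shear via extreme-momentum swaps.

The box is divided into ``n_slabs`` slabs along z.  Every ``swap_interval``
(W) timesteps, the bead with the most negative x-momentum in the lower
driven slab (slab 0) and the bead with the most positive x-momentum in the
opposite driven slab (slab n_slabs/2) exchange x-velocities.  With equal
bead masses this conserves total momentum and kinetic energy exactly while
imposing a known momentum flux

    j_z(px) = sum(dpx) / (2 t Lx Ly)

(the factor 2 because the flux flows through both halves of the periodic
box).  The system responds with a steady two-branch linear vx(z) profile;
the shear rate is the mean |slope| of the branches and the viscosity
follows from j = -eta dvx/dz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .builder import SystemState

__all__ = ["ShearProtocol", "VelocityProfile", "momentum_flux",
           "velocity_profile", "InsufficientDataError"]

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Raised when a measurement window holds too little data."""


def momentum_flux(accumulated_px: float, t: float, lx: float, ly: float) -> float:
    """Imposed momentum flux from the accumulated swapped momentum.

    ``t`` is the total shearing time (in tau), ``lx``/``ly`` the box
    cross-section.
    """
    if t <= 0:
        raise ValueError("flux is undefined for non-positive accumulation time")
    return accumulated_px / (2.0 * t * lx * ly)


@dataclass
class ShearProtocol:
    """Mutable state of the momentum-swap driver.

    ``swap_interval`` W in steps (0 disables shear); driven slabs are slab
    0 and slab ``n_slabs // 2`` so the two linear branches wrap smoothly
    through the periodic boundary.
    """

    swap_interval: int = 0
    n_slabs: int = 20
    m: float = 1.0
    accumulated_px: float = 0.0
    n_swaps: int = 0
    skipped_swaps: int = 0
    slab_lo: int = 0
    slab_hi: int = field(init=False)

    def __post_init__(self) -> None:
        if self.n_slabs < 2:
            raise ValueError("need at least 2 slabs")
        self.slab_hi = self.n_slabs // 2
        if self.slab_lo == self.slab_hi:
            raise ValueError("driven slabs must differ")

    @property
    def active(self) -> bool:
        return self.swap_interval > 0

    def momentum_swap(self, state: SystemState) -> float:
        """Exchange x-velocities of the two extreme beads; returns dpx.

        Total momentum and kinetic energy are invariant (equal masses).
        Empty driven slabs skip the event with a logged warning.
        """
        lz = state.box[2]
        h = lz / self.n_slabs
        slab = np.minimum((state.positions[:, 2] % lz) / h,
                          self.n_slabs - 1).astype(np.int64)
        in_lo = np.flatnonzero(slab == self.slab_lo)
        in_hi = np.flatnonzero(slab == self.slab_hi)
        if in_lo.size == 0 or in_hi.size == 0:
            logger.warning("momentum swap skipped: empty driven slab at step %d",
                           state.step_index)
            self.skipped_swaps += 1
            return 0.0
        vx = state.velocities[:, 0]
        i = in_lo[np.argmin(vx[in_lo])]   # most negative px in lower slab
        j = in_hi[np.argmax(vx[in_hi])]   # most positive px in upper slab
        dpx = self.m * (vx[j] - vx[i])
        vx[i], vx[j] = vx[j], vx[i]
        self.accumulated_px += dpx
        self.n_swaps += 1
        return float(dpx)

    def flux(self, t: float, lx: float, ly: float) -> float:
        return momentum_flux(self.accumulated_px, t, lx, ly)


@dataclass
class VelocityProfile:
    """Slab-averaged vx(z) with fitted branch slopes and viscosity."""

    bin_centers: np.ndarray
    vx: np.ndarray
    counts: np.ndarray
    slope_lo: float
    slope_hi: float
    slope_lo_stderr: float
    slope_hi_stderr: float
    shear_rate: float
    flux: float | None = None
    viscosity: float | None = None

    @property
    def n_bins(self) -> int:
        return self.bin_centers.shape[0]


def _branch_fit(z: np.ndarray, v: np.ndarray):
    if z.size < 3:
        raise InsufficientDataError("branch has fewer than 3 slabs to fit")
    res = stats.linregress(z, v)
    return float(res.slope), float(res.stderr if np.isfinite(res.stderr) else 0.0)


def velocity_profile(frames, shear: ShearProtocol,
                     accumulation_time: float | None = None) -> VelocityProfile:
    """Time-averaged vx(z) over frames, branch slopes, and viscosity.

    The two branches run between the driven slabs (which are excluded from
    the fits); the reported shear rate is the mean absolute slope.  When
    ``accumulation_time`` (tau) is given and the protocol has accumulated
    momentum, the imposed flux and the viscosity eta = |j| / shear_rate
    are filled in.
    """
    frames = list(frames)
    if not frames:
        raise InsufficientDataError("no frames in measurement window")
    n = shear.n_slabs
    box = frames[0].box
    lz = box[2]
    h = lz / n
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=np.int64)
    for fr in frames:
        slab = np.minimum((fr.positions[:, 2] % lz) / h, n - 1).astype(np.int64)
        sums += np.bincount(slab, weights=fr.velocities[:, 0], minlength=n)
        counts += np.bincount(slab, minlength=n)
    with np.errstate(invalid="ignore"):
        vx = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    centers = (np.arange(n) + 0.5) * h

    lo, hi = shear.slab_lo, shear.slab_hi
    branch1 = np.arange(lo + 1, hi)                  # rising/falling branch 1
    branch2 = np.concatenate([np.arange(hi + 1, n)]) # branch 2 wraps to slab 0
    s1, e1 = _branch_fit(centers[branch1], vx[branch1])
    s2, e2 = _branch_fit(centers[branch2], vx[branch2])
    shear_rate = 0.5 * (abs(s1) + abs(s2))

    flux = visc = None
    if accumulation_time is not None and shear.n_swaps > 0:
        flux = shear.flux(accumulation_time, box[0], box[1])
        if shear_rate > 0:
            visc = abs(flux) / shear_rate
    return VelocityProfile(centers, vx, counts, s1, s2, e1, e2,
                           shear_rate, flux, visc)
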