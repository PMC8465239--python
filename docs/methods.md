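# Methods

## Model

The system is a two-species amphiphile mixture in explicit coarse-grained
water under dissipative particle dynamics (DPD). Five bead species exist:
water, head and tail beads of a single-tail lipid (type 1), and head and
tail beads of a double-tail lipid (type 2). All beads have equal mass m
and interact below a single cutoff r_c; reduced units set
r_c = m = k_BT = 1 and the time unit is τ = r_c √(m/k_BT).

Pair forces are the standard DPD triplet. The conservative force is the
soft linear repulsion a_ij (1 − r/r_c) r̂; the dissipative and random
forces form a momentum-conserving pairwise thermostat with
σ² = 2 γ k_BT (γ = 4.5, hence σ = 3 at k_BT = 1). The random variates
ζ_ij are uniform with unit variance (width √12); a uniform distribution
is statistically equivalent to a Gaussian for DPD at these time steps
and cheaper to generate. The random force carries the Δt^(−1/2) factor
explicitly.

Bonded terms: consecutive beads are joined by F = k_s (1 − r/r_s) r̂
with k_s = 120, r_s = 0.7 r_c (potential k_s/(2 r_s) (r − r_s)², the
exact antiderivative). Bending terms U = k_θ (θ − θ0)² act on triples:
(k_θ = 6, θ0 = π) on all pure-head and pure-tail backbone triples of
both lipids, and on the head–tail junction triples of the single-tail
lipid so that molecule is a straight rod at its energy minimum (this
junction choice is configurable off; it fixes the initial shape factor
at exactly 1). The double-tail lipid adds, per tail, a
(k_θ = 3, θ0 = 2π/3) term on (head[-2], head[-1], first tail bead) and a
(k_θ = 4.5, θ0 = 2π/3) term on (head[-1], first tail bead, second tail
bead); the two tails are mutually uncoupled.

Interaction matrix: the production matrix groups species into a
hydrophilic class {water, both head species} and a hydrophobic class
{both tail species}, with a = 25 inside a class and a = 100 across.
This is the standard lipid-DPD convention and is what makes heads
water-liking and drives self-assembly. A "literal" matrix (25 on the
species diagonal, 100 between any two distinct species) is retained for
auditing; note it makes head–water repulsive and does not produce
bilayers, which is why it is not the default.

## Integration

Modified velocity-Verlet: positions advance with the cached force;
a predicted velocity ṽ = v + λ Δt f (λ = 0.5) enters the dissipative
force evaluated at the new positions; the final velocity uses the
trapezoidal force average. One force evaluation per step (the evaluation
at t + Δt is reused as f(t) of the next step). Δt = 0.01 τ.

Randomness is counter-based: each pair's ζ_ij is a splitmix64 hash of
(seed, step, min(i,j), max(i,j)), so ζ_ij = ζ_ji by construction and a
run is bitwise reproducible for a given seed regardless of neighbor-list
iteration order. Neighbor search is a linked-cell decomposition with
cell edge ≥ r_c (capped so the grid never exceeds ~one bead per cell);
boxes thinner than three cells per axis fall back to an O(N²) loop with
identical pair semantics. Coincident beads (r → 0) receive a
deterministic x-axis fallback direction.

With γ = σ = 0 the integrator is plain velocity-Verlet and conserves
energy (bounded O(Δt²) oscillation on bonded molecules; ~2×10⁻⁴ per bead
per 1000 steps residual drift in bulk soft-repulsion fluid, from the
discontinuous second derivative of the pair potential at the cutoff).

## Shear protocol

Reverse non-equilibrium shear: the box is sliced into n_slabs = 20 slabs
along z; slab 0 and slab n_slabs/2 are driven. Every W steps the bead
with the most negative p_x in slab 0 swaps x-velocities with the bead
with the most positive p_x in the mid slab — an unphysical momentum
transfer that conserves total momentum and kinetic energy exactly and
imposes flux j_z = Σ Δp_x / (2 t L_x L_y). Driving opposite slabs (not
z = 0 and z = L_z, which coincide under periodicity) yields the
two-branch linear v_x(z) profile; the shear rate is the mean |slope| of
the two branches fitted by least squares with the driven slabs excluded,
and η = |j_z| / (shear rate). One pair is exchanged per event. W = 6 and
W = 1 are the weak/strong presets; at full production scale these
correspond to shear rates of about 0.073 and 0.168 τ⁻¹.

## Observables

- **Density profiles**: per-species bead counts in slabs along an axis,
  normalized to beads/r_c³; they integrate back to the species count.
- **Order parameter**: P2 = ⟨(3 cos²θ − 1)/2⟩ of the first-to-last
  head-bead vector of each chain against +z, averaged over chains and
  frames, optionally binned by the head-block centroid. Only heads are
  used (they are the stiff part of the molecule). The value is signed:
  +1 parallel, −0.5 perpendicular, 0 isotropic; no absolute-value
  convention is applied to the perpendicular limit.
- **Gyration tensor**: per chain, the second moment of bead positions
  about the chain centroid after unwrapping the molecule across the
  periodic boundary by a minimum-image walk along its bond tree.
  Components Rg_xx etc. are reported as square roots of the diagonal
  entries (length units). Two series exist deliberately:
  `rg_components_series` averages per-molecule tensors (single-chain
  conformation), while `membrane_gyration_components` takes the tensor
  over the chain centers of mass of one lipid type, normalized by the
  number of chains (aggregate extent). For a box-spanning membrane the
  aggregate reading gives large, near-equal in-plane components and a
  small normal one; the per-chain reading gives the opposite ordering
  whenever chains stand along the membrane normal. Both are exposed
  because the two normalizations answer different questions, and
  conflating them inverts the expected inequalities.
- **Shape factor**: δ = 1 − 3(L1L2 + L2L3 + L1L3)/(L1 + L2 + L3)² with
  Li the squared gyration eigenvalues; 0 = sphere, 1 = rod, 0.25 = flat
  disc. Computed per chain and averaged per lipid type.
- **Pressure/tension profiles**: Irving–Kirkwood. The kinetic term
  m v_α² is assigned to the bead's slab; each pair-virial contribution
  F_α d_α is spread over the slabs crossed by the minimum-image i–j
  segment in proportion to the segment length per slab, so slab averages
  reproduce the global virial exactly (the suite checks 10⁻⁶ relative).
  Angle forces are decomposed into (i, vertex) and (k, vertex) pair
  contributions, which preserves the total virial. The recorded virial
  contains conservative pair + bond + angle forces only; the
  thermostat's dissipative/random contributions are excluded (their
  average is part of the ideal term and they add large noise).
  Tension: σ(z) = p_zz − (p_xx + p_yy)/2, plus its z-integral.

## Structure classification

Tail beads closer than r_c are linked; the largest connected cluster is
tested for winding around each periodic axis (breadth-first image
assignment; a non-tree edge whose image disagrees by a whole box vector
exposes a winding axis). Spanning ≥ 2 axes → membrane; exactly 1 → tube;
0 → vesicle. For vesicles a voxel flood fill (0.75 r_c voxels, periodic
connectivity) reports whether the aggregate walls off an interior cavity
and whether that cavity holds water — evidence distinguishing a true
vesicle from a filled micelle, though both are labelled VESICLE (at
small scale the smallest closed aggregates are micelle-like). The
classifier is deterministic and invariant under periodic translation and
axis permutation.

The phase-sweep driver runs several random starts per (NT1, NT2) cell,
classifies each final state, records per-seed final potential energies
(so the minimum-energy start is identifiable) and reports the modal
label with the agreement fraction; per-cell failures are recorded and
the sweep continues.

## Synthetic initial states

- `random_initial_configuration`: every lipid at its exact ideal
  internal geometry (bonds at r_s, angles at θ0; the double-tail lipid's
  tails splayed symmetrically at 120°), random rigid-body pose, water
  filled to ρ = 3, Maxwell–Boltzmann velocities at k_BT with net momentum
  removed. Overlaps are not rejected — DPD potentials are finite at
  r = 0 and overlapping starts relax within a few steps.
- `preassembled_bilayer`: two apposed leaflets normal to z (double-tail
  above, single-tail below), tails toward the midplane, water only
  outside the membrane slab. Used for fast-equilibration studies; the
  as-built head order parameter is 1 by construction.
- `synthetic_geometry`: static slab / cylinder / sphere bead clouds for
  exercising the classifier.

What the generators do **not** emulate: chemistry-specific bead
mappings, leaflet-number asymmetry beyond the two-species split,
electrostatics, and the multi-start minimum-energy selection of
production phase diagrams (the sweep's seed ensemble stands in for it).
Passing tests on these states therefore demonstrates correctness of the
mechanics and observables, not agreement with any particular
experimental membrane.

## Problem sizes and numerical choices

The default test suite runs scaled-down systems chosen to exercise every
code path at meaningful statistics: 648–3,000-bead water boxes for
thermostat/conservation checks (temperature within 2% of k_BT over
5,000 steps), a 5,184-bead preassembled membrane (12 r_c box, 150 + 150
lipids with 4-bead tails) relaxed for 10⁴ steps for the structural
checks, and a 6 × 6 × 12 water box for the shear-response suite
(monotonic flux and shear rate across W ∈ {12, 6, 3, 1}; viscosity
consistent across W within 15%, η ≈ 1.1 in reduced units). Production
parameters (30 r_c box, 600 + 600 lipids with 10-bead tails, 2×10⁵
steps) are the package defaults and are reachable through
`scripts/long_run.py`.

Other numerical choices: angle-force gradients are exact except within
10⁻⁸ of sin θ = 0, where the sine is clamped; bond directions for
coincident beads fall back deterministically to the x-axis; profile
measurements treat the last 25% of frames as the steady-state window by
default; the shear-rate report is the mean of the two branch |slopes|.
Build-time molecular geometry is exact in cos θ to ~10⁻¹⁵ (the angle
itself is only conditioned to ~10⁻⁸ at θ = π through arccos).

## Known limitations

- No electrostatics, no rigid constraints, no chemistry-specific bead
  mapping; single-node, single-thread execution.
- The momentum-swap thermostat pair (swap + DPD thermostat) weakly
  perturbs the temperature near the driven slabs at very small W; the
  suite's tolerance windows account for this.
- The classifier's vesicle/micelle distinction is evidence-only; very
  sparse aggregates (< 4 beads) are labelled OTHER.
- At test scale the double-tail lipid's tails are short (4 beads); the
  per-chain anisotropy and order-parameter magnitudes differ
  quantitatively from the 10-bead production system, though their
  orderings (single-tail more ordered, rod-like δ ≈ 0.9) already agree.
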