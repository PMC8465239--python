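"""Shared fixtures: relaxed water boxes and a scaled-down membrane run.

The expensive fixtures are session-scoped so the whole suite pays for
each simulation once.
"""

from __future__ import annotations

import numpy as np
import pytest

import dpdlipid as d


@pytest.fixture(scope="session")
def water_cfg():
    return d.RunConfig(box_lengths=(6.0, 6.0, 6.0), n_lipids_1=0,
                       n_lipids_2=0, total_steps=0)


@pytest.fixture(scope="session")
def relaxed_water(water_cfg):
    """648-bead water box equilibrated with the thermostat."""
    state, topo = d.random_initial_configuration(water_cfg, seed=7)
    sim = d.Simulation(state, topo, seed=7)
    sim.run(500)
    return state, topo


@pytest.fixture(scope="session")
def water_window(relaxed_water):
    """Equilibrium water frames (no shear) for profile statistics."""
    state, topo = relaxed_water
    st = state.copy()
    sim = d.Simulation(st, topo, seed=17)
    traj = sim.run(1500, traj_every=50, record_initial=False)
    return traj.frames, topo


@pytest.fixture(scope="session")
def bilayer_run():
    """Scaled-down preassembled membrane relaxed for 10^4 steps.

    L=12rc, 150 single-tail + 150 double-tail lipids with 4-bead tails,
    amphiphilic interactions, no shear.  Returns (final_state, topology,
    frames, config).
    """
    cfg = d.RunConfig(box_lengths=(12.0, 12.0, 12.0), n_lipids_1=150,
                      n_lipids_2=150, nt1=4, nt2=4, total_steps=0)
    state, topo = d.preassembled_bilayer(cfg, seed=11)
    sim = d.Simulation(state, topo, seed=11)
    traj = sim.run(10_000, traj_every=500)
    return state, topo, traj.frames, cfg


@pytest.fixture(scope="session")
def sheared_water():
    """Momentum-swap runs on one water box for W in {12, 6, 3, 1}.

    Returns dict W -> (ShearProtocol, frames in the steady-state window,
    total run time in tau).
    """
    cfg = d.RunConfig(box_lengths=(6.0, 6.0, 12.0), n_lipids_1=0,
                      n_lipids_2=0, total_steps=0)
    st0, topo = d.random_initial_configuration(cfg, seed=21)
    simr = d.Simulation(st0, topo, seed=21)
    simr.run(500)
    out = {}
    for w in (12, 6, 3, 1):
        st = st0.copy()
        st.step_index = 0
        sh = d.ShearProtocol(w, 12)
        sim = d.Simulation(st, topo, seed=100 + w, shear=sh)
        traj = sim.run(3000, traj_every=50)
        frames = [f for f in traj.frames if f.step_index > 1500]
        out[w] = (sh, frames, 3000 * sim.params.dt)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
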