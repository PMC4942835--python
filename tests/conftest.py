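"""Shared fixtures.

The expensive Langevin ensembles are session-scoped and shared between the
unit tests and the acceptance tests so the whole suite fits the time budget.
All scales here are deliberately reduced relative to the acceptance script
(which runs the full-size ensembles); the acceptance criteria keep their
stated tolerances.
"""

from __future__ import annotations

import numpy as np
import pytest

from sbsfold.inference import (
    AnnealSchedule,
    BindingProfile,
    anneal_binding_profile,
    calibrate_kappa,
)
from sbsfold.model import INERT
from sbsfold.synthetic import (
    make_block_fixture,
    phase_ensemble,
    sample_gaussian_chain,
    sample_saw_pivot,
)

# geometry shared by all inference/variant tests (N = 200, 2 colors,
# 12-bead inert spacer between the two same-color blocks)
FIXTURE_BLOCKS = [(60, 0), (12, INERT), (58, 0), (70, 1)]
SPACER = (60, 72)
FIXTURE_KW = dict(e_int=3.3, binders_per_color=90, box_edge=18.0,
                  n_traj=10, n_steps=100_000, sample_interval=2000,
                  equilibration_fraction=0.45)

SMALL_BLOCKS = [(30, 0), (12, INERT), (28, 0), (30, 1)]
SMALL_KW = dict(e_int=3.3, binders_per_color=45, box_edge=14.0,
                n_traj=8, n_steps=80_000, sample_interval=2000,
                equilibration_fraction=0.45)


@pytest.fixture(scope="session")
def saw_ensemble():
    """Pivot-SAW ensemble, N=256 (coil reference)."""
    return sample_saw_pivot(256, 1500, seed=101)


@pytest.fixture(scope="session")
def gaussian_ensemble():
    """Ideal-chain ensemble, N=256, bond 2 sigma (theta reference)."""
    return sample_gaussian_chain(256, 2.0, 4000, seed=102)


@pytest.fixture(scope="session")
def ordered_globule():
    """Equilibrium ordered-globule ensemble (N=250, compact-initialized)."""
    frames, trajs = phase_ensemble("globule_ordered", n_traj=3,
                                   n_steps=100_000, sample_interval=4000,
                                   seed=7)
    return {"frames": frames, "trajs": trajs}


@pytest.fixture(scope="session")
def disordered_globule():
    """Disordered-lump ensemble (N=250, SAW-start collapse at E=2.6)."""
    frames, trajs = phase_ensemble("globule_disordered", n_traj=3,
                                   n_steps=200_000, sample_interval=4000,
                                   equilibration_fraction=0.5, seed=8)
    return {"frames": frames, "trajs": trajs}


@pytest.fixture(scope="session")
def coil_md():
    """Open-state MD run (E_int = 0) of the same chain."""
    frames, trajs = phase_ensemble("coil", n_traj=2, n_steps=80_000,
                                   sample_interval=4000, seed=9)
    return {"frames": frames, "trajs": trajs}


@pytest.fixture(scope="session")
def block_fixture():
    """Ground-truth 2-color fixture: MD target + truth profile (keeps the
    trajectories for distance-distribution tests)."""
    return make_block_fixture(FIXTURE_BLOCKS, seed=21, keep_trajectories=True,
                              **FIXTURE_KW)


@pytest.fixture(scope="session")
def small_fixture_pair():
    """Two independent realizations of a small (N=100) fixture, used as the
    replicate-noise baseline for variant-prediction tests."""
    a = make_block_fixture(SMALL_BLOCKS, seed=31, **SMALL_KW)
    b = make_block_fixture(SMALL_BLOCKS, seed=32, **SMALL_KW)
    return a, b


@pytest.fixture(scope="session")
def truth_profile(block_fixture):
    return BindingProfile(multiplicities=block_fixture.chain.colors)


@pytest.fixture(scope="session")
def fixture_kappa(block_fixture, truth_profile):
    return calibrate_kappa(block_fixture.target, truth_profile)


@pytest.fixture(scope="session")
def anneal_result(block_fixture, fixture_kappa):
    """Best-of-2-seeds annealing recovery on the MD fixture target."""
    best = None
    for seed in range(2):
        res = anneal_binding_profile(
            block_fixture.target, n_colors=2, kappa=fixture_kappa, lam=0.01,
            schedule=AnnealSchedule(sweeps_per_level=50, seed=seed))
        if best is None or res.best_cost < best.best_cost:
            best = res
    return best


@pytest.fixture(scope="session")
def simulated_library(saw_ensemble, gaussian_ensemble, ordered_globule,
                      disordered_globule):
    """Pure-state curve library assembled from the oracle ensembles and the
    SBS phase-point runs (desk-scale MD limits the shared span)."""
    from sbsfold.mixture import build_pure_state_library
    from sbsfold.observables import contact_probability_vs_separation

    coil = contact_probability_vs_separation(saw_ensemble, threshold=2.0)
    theta = contact_probability_vs_separation(gaussian_ensemble, threshold=2.0)
    dis = contact_probability_vs_separation(
        disordered_globule["frames"], threshold=2.0, box_edge=20.0)
    order = contact_probability_vs_separation(
        ordered_globule["frames"], threshold=2.0, box_edge=20.0)
    return build_pure_state_library(coil, theta, dis, order, check=True,
                                    provenance={"scale": "desk"},
                                    min_decades=2.0)


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same fresh stream regardless of
    # execution order
    return np.random.default_rng(0)
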