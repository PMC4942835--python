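import numpy as np
import pytest

from sbsfold.dynamics import (
    LangevinParams,
    attraction_depth_scale,
    langevin_step,
    pair_energy,
    potential_energy,
    run_trajectory,
    total_forces,
)
from sbsfold.errors import OverstretchError
from sbsfold.model import (
    BeadChain,
    BinderSet,
    ForceField,
    SimulationBox,
    System,
    assemble_system,
    build_homopolymer,
)

WCA_CUT = 2 ** (1 / 6)


def small_system(n_beads=12, m_binders=8, e_int=2.0, edge=12.0, seed=0):
    chain = build_homopolymer(n_beads)
    box = SimulationBox(edge=edge)
    ff = ForceField(e_int=(e_int,))
    return assemble_system(chain, ff, box, binder_counts=[m_binders], seed=seed)


class TestPairEnergy:
    def test_wca_zero_at_cutoff(self):
        ff = ForceField()
        assert pair_energy(WCA_CUT, "wca", ff) == pytest.approx(0.0)

    def test_wca_at_sigma(self):
        ff = ForceField(eps_rep=1.0)
        assert pair_energy(1.0, "wca", ff) == pytest.approx(1.0)

    def test_fene_overstretch(self):
        ff = ForceField()
        with pytest.raises(OverstretchError):
            pair_energy(ff.fene_r0, "fene", ff)

    def test_attract_well_depth_is_e_int(self):
        ff = ForceField(e_int=(4.1,))
        rmin = WCA_CUT
        assert pair_energy(rmin, "attract", ff, 0) == pytest.approx(-4.1, rel=1e-9)

    def test_attract_zero_beyond_cutoff(self):
        ff = ForceField(e_int=(4.1,))
        assert pair_energy(1.5, "attract", ff, 0) == 0.0

    def test_depth_scale_closed_form(self):
        rc = 1.5
        src6 = rc**-6
        assert attraction_depth_scale(rc) == pytest.approx(
            1.0 / (1.0 + 4.0 * (src6**2 - src6)))


class TestForces:
    def test_finite_difference_oracle(self):
        """Analytic forces match central finite differences of the energy."""
        sys_ = small_system(e_int=2.5, seed=3)
        f = total_forces(sys_)
        pos = np.vstack([sys_.chain.positions, sys_.binders.positions])
        h = 1e-6
        rng = np.random.default_rng(1)
        for _ in range(12):
            i = rng.integers(pos.shape[0])
            d = rng.integers(3)
            pp = pos.copy()
            pp[i, d] += h
            pm = pos.copy()
            pm[i, d] -= h
            fd = -(potential_energy(sys_, pp) - potential_energy(sys_, pm)) / (2 * h)
            scale = max(1.0, abs(f[i, d]))
            assert abs(fd - f[i, d]) / scale < 1e-5

    def test_newton_third_law(self):
        sys_ = small_system(e_int=3.0, seed=4)
        f = total_forces(sys_)
        assert np.abs(f.sum(axis=0)).max() < 1e-9

    def test_two_beads_at_wca_cutoff_no_force(self):
        chain = BeadChain(colors=np.zeros((2, 1), dtype=int))
        chain.positions = np.array([[5.0, 5.0, 5.0], [5.0 + 1.3, 5.0, 5.0]])
        binders = BinderSet(colors=np.empty(0, dtype=int))
        binders.positions = np.empty((0, 3))
        sys_ = System(chain=chain, binders=binders,
                      box=SimulationBox(edge=20.0), ff=ForceField())
        f = total_forces(sys_)
        # only the FENE bond acts at r=1.3 (beyond the WCA cutoff)
        r = 1.3
        fene = ForceField()
        expected = fene.fene_k * r / (1 - (r / fene.fene_r0) ** 2)
        assert f[0, 0] == pytest.approx(expected, rel=1e-9)


class TestLangevin:
    def test_free_flight(self):
        """gamma=0, no noise, no interactions -> r(t+dt) = r(t) + v dt."""
        chain = BeadChain(colors=np.zeros((2, 1), dtype=int))
        chain.positions = np.array([[2.0, 2.0, 2.0], [3.0, 2.0, 2.0]])
        binders = BinderSet(colors=np.empty(0, dtype=int))
        binders.positions = np.empty((0, 3))
        sys_ = System(chain=chain, binders=binders,
                      box=SimulationBox(edge=50.0), ff=ForceField())
        v0 = np.array([[0.05, 0.0, 0.0], [0.05, 0.0, 0.0]])
        x0 = chain.positions.copy()
        params = LangevinParams(dt=0.01, gamma=0.0)
        v = langevin_step(sys_, v0, params)
        # internal forces cancel: the center of mass is in free flight
        com0 = x0.mean(axis=0)
        com1 = chain.positions.mean(axis=0)
        assert np.allclose(com1, com0 + 0.01 * v0[0], atol=1e-12)
        assert np.allclose(v.mean(axis=0), v0[0], atol=1e-12)

    def test_energy_conservation_dimer(self):
        """gamma=0: FENE+WCA dimer conserves energy to 1e-4 relative."""
        chain = BeadChain(colors=np.zeros((2, 1), dtype=int))
        chain.positions = np.array([[5.0, 5.0, 5.0], [6.05, 5.0, 5.0]])
        binders = BinderSet(colors=np.empty(0, dtype=int))
        binders.positions = np.empty((0, 3))
        sys_ = System(chain=chain, binders=binders,
                      box=SimulationBox(edge=20.0), ff=ForceField())
        vel = np.array([[0.3, 0.0, 0.0], [-0.3, 0.0, 0.0]])
        params = LangevinParams(dt=0.001, gamma=0.0)
        e0 = potential_energy(sys_) + 0.5 * (vel**2).sum()
        for _ in range(10_000):
            vel = langevin_step(sys_, vel, params)
        e1 = potential_energy(sys_) + 0.5 * (vel**2).sum()
        assert abs(e1 - e0) / abs(e0) < 1e-4

    def test_equipartition(self):
        """Mean kinetic energy per dof = kT/2 within 3 s.e."""
        sys_ = small_system(n_beads=16, m_binders=16, e_int=1.0, seed=5)
        traj = run_trajectory(sys_, 40_000, 400, seed=6)
        ke = traj.kinetic_per_dof[20:]
        se = ke.std(ddof=1) / np.sqrt(len(ke))
        assert abs(ke.mean() - 0.5) < 3 * max(se, 0.01)


class TestRunTrajectory:
    def test_zero_steps_initial_snapshot(self):
        sys_ = small_system()
        traj = run_trajectory(sys_, 0, 100, seed=1)
        assert traj.n_snapshots == 1
        assert traj.times[0] == 0.0

    def test_seed_reproducibility(self):
        a = run_trajectory(small_system(seed=2), 5000, 500, seed=11)
        b = run_trajectory(small_system(seed=2), 5000, 500, seed=11)
        assert np.array_equal(a.beads, b.beads)
        assert np.array_equal(a.binders, b.binders)

    def test_different_seed_differs(self):
        a = run_trajectory(small_system(seed=2), 2000, 500, seed=11)
        b = run_trajectory(small_system(seed=2), 2000, 500, seed=12)
        assert not np.array_equal(a.beads, b.beads)

    def test_times_strictly_increasing(self):
        traj = run_trajectory(small_system(seed=2), 4000, 500, seed=1)
        assert (np.diff(traj.times) > 0).all()

    def test_bonds_bounded_in_snapshots(self):
        traj = run_trajectory(small_system(seed=2, e_int=3.0), 20_000, 1000, seed=3)
        bonds = np.linalg.norm(np.diff(traj.beads, axis=1), axis=2)
        assert bonds.max() < 1.5

    def test_folding_rg_decreases(self, ordered_globule, coil_md):
        """Above the theta point the chain folds: equilibrium globule Rg is
        far below the open-state Rg (and a SAW-start run decreases in time)."""
        from sbsfold.observables import gyration_radius_series

        rg_coil = np.mean([gyration_radius_series(t)[5:].mean()
                           for t in coil_md["trajs"]])
        rg_glob = np.mean([gyration_radius_series(t)[-5:].mean()
                           for t in ordered_globule["trajs"]])
        assert rg_glob < 0.5 * rg_coil

    def test_collapse_from_saw_start(self, block_fixture):
        from sbsfold.observables import gyration_radius_series

        rg = gyration_radius_series(block_fixture.trajectories[0])
        assert rg[-5:].mean() < 0.85 * rg[0]
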