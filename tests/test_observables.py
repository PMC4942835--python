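import numpy as np
import pytest

from sbsfold.errors import (
    DomainError,
    EmptyInputError,
    FitDomainError,
    NotConvergedError,
    WavevectorError,
)
from sbsfold.observables import (
    ContactMatrix,
    PsCurve,
    boundary_pair_distance_test,
    classify_state,
    contact_map,
    contact_probability_vs_separation,
    fit_power_law_exponent,
    gyration_radius,
    has_sharp_peak,
    many_body_contact_frequency,
    mean_square_distance_vs_separation,
    pre_plateau_window,
    structure_factor,
    triplet_contact_probability,
)
from sbsfold.synthetic import (
    brute_force_component_counts,
    brute_force_contact_probability,
    brute_force_triplet_grid,
    saw_many_body_baseline,
    saw_rg_reference,
)


class TestGyrationRadius:
    def test_single_bead(self):
        assert gyration_radius(np.zeros((1, 3))) == 0.0

    def test_two_beads(self):
        pos = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        assert gyration_radius(pos) == pytest.approx(1.5)

    def test_rod_of_three(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        assert gyration_radius(pos) == pytest.approx(np.sqrt(2.0 / 3.0))


class TestContactMap:
    def test_all_close(self):
        frame = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.5, 0.8, 0]])
        cm = contact_map(frame, threshold=2.0)
        off = cm.values[np.triu_indices(3, 1)]
        assert (off == 1.0).all()

    def test_all_far(self):
        frame = np.array([[0.0, 0, 0], [5.0, 0, 0], [10.0, 0, 0]])
        cm = contact_map(frame, threshold=2.0)
        assert cm.values[0, 1] == 0.0 and cm.values[0, 2] == 0.0

    def test_diagonal_is_row_max(self):
        rng = np.random.default_rng(0)
        frames = rng.uniform(0, 6, size=(10, 12, 3))
        cm = contact_map(frames, threshold=2.0)
        assert (np.diag(cm.values) >= cm.values.max(axis=1) - 1e-12).all()

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        frames = rng.uniform(0, 6, size=(8, 15, 3))
        cm = contact_map(frames, threshold=2.5)
        assert np.array_equal(cm.values, cm.values.T)

    def test_empty_error(self):
        with pytest.raises(EmptyInputError):
            contact_map(np.empty((0, 5, 3)))

    def test_chessboard_block_pattern(self, block_fixture):
        """Ordered block-copolymer: same-color inter-block contacts exceed
        cross-color contacts."""
        v = block_fixture.target.values
        red_red = v[0:60, 72:130].mean()
        red_green = v[72:130, 130:200].mean()
        assert red_red > 2 * red_green


class TestPsCurveConsistency:
    def test_matches_contact_map(self, rng):
        frames = rng.uniform(0, 8, size=(5, 20, 3))
        cm = contact_map(frames, threshold=2.0)
        a = contact_probability_vs_separation(cm)
        b = contact_probability_vs_separation(frames, threshold=2.0)
        assert np.allclose(a.p, b.p)

    def test_brute_force_oracle(self, rng):
        for trial in range(5):
            frames = rng.uniform(0, 5, size=(6, 14, 3))
            ours = contact_probability_vs_separation(frames, threshold=1.8)
            oracle = brute_force_contact_probability(frames, threshold=1.8)
            assert np.allclose(ours.p, oracle)


class TestPowerLawFit:
    def test_exact_power_law(self):
        s = np.arange(1, 200, dtype=float)
        curve = PsCurve(s=s, p=s**-2.0)
        fit = fit_power_law_exponent(curve, (5, 100))
        assert fit.alpha == pytest.approx(2.0, abs=1e-6)

    def test_constant_curve(self):
        s = np.arange(1, 100, dtype=float)
        curve = PsCurve(s=s, p=np.full_like(s, 0.3))
        assert fit_power_law_exponent(curve, (5, 80)).alpha == pytest.approx(0.0, abs=1e-9)

    def test_noisy_recovery(self, rng):
        s = np.geomspace(1, 300, 50)
        s = np.unique(np.round(s))
        p = 0.5 * s**-1.5 * rng.lognormal(0, 0.05, size=len(s))
        fit = fit_power_law_exponent(PsCurve(s=s, p=p), (2, 300))
        assert fit.alpha == pytest.approx(1.5, abs=0.1)

    def test_nonpositive_error(self):
        s = np.arange(1, 50, dtype=float)
        p = np.zeros_like(s)
        with pytest.raises(FitDomainError):
            fit_power_law_exponent(PsCurve(s=s, p=p), (5, 40))

    def test_too_few_points(self):
        curve = PsCurve(s=np.array([1.0, 2, 3]), p=np.array([1.0, 0.5, 0.3]))
        with pytest.raises(FitDomainError):
            fit_power_law_exponent(curve, (1, 3))

    def test_threshold_insensitivity_saw(self, saw_ensemble):
        """Coil exponent moves < 0.1 when the contact threshold changes."""
        fits = []
        for thr in (1.8, 2.0, 2.2):
            cur = contact_probability_vs_separation(saw_ensemble, threshold=thr)
            fits.append(fit_power_law_exponent(cur.positive(), (10, 64)).alpha)
        assert max(fits) - min(fits) < 0.15


class TestMeanSquareDistance:
    def test_rod(self):
        n = 10
        frame = np.zeros((1, n, 3))
        frame[0, :, 0] = 2.0 * np.arange(n)
        s, r2 = mean_square_distance_vs_separation(frame)
        assert np.allclose(r2, 4.0 * s**2)

    def test_gaussian_chain_closed_form(self, gaussian_ensemble):
        s, r2 = mean_square_distance_vs_separation(gaussian_ensemble[:1000])
        sel = s < 100
        ratio = r2[sel] / (4.0 * s[sel])  # b^2 = 4
        assert np.abs(ratio - 1.0).max() < 0.1

    def test_saw_scaling(self, saw_ensemble):
        s, r2 = mean_square_distance_vs_separation(saw_ensemble[:500])
        sel = (s >= 10) & (s <= 64)
        slope = np.polyfit(np.log10(s[sel]), np.log10(r2[sel]), 1)[0]
        assert 1.1 <= slope <= 1.25


class TestStructureFactor:
    def test_single_particle_flat(self):
        from sbsfold.observables import structure_factor_direct

        pos = np.array([[3.0, 3.0, 3.0]])
        kv = np.array([[0.5, 0, 0], [1.3, 0.2, 0], [0, 0, 4.0]])
        assert np.allclose(structure_factor_direct(pos, kv), 1.0, atol=1e-12)

    def test_two_particles_cosine(self):
        from sbsfold.observables import structure_factor_direct

        d = 2.5
        pos = np.array([[0.0, 0, 0], [d, 0, 0]])
        ks = np.linspace(0.3, 5.0, 9)
        kv = np.stack([ks, np.zeros_like(ks), np.zeros_like(ks)], axis=1)
        expected = 1.0 + np.cos(ks * d)
        assert np.allclose(structure_factor_direct(pos, kv), expected, atol=1e-12)

    def test_ideal_gas_flat(self, rng):
        pos = rng.uniform(0, 12.0, size=(10, 400, 3))
        sk = structure_factor(pos, box_edge=12.0)
        sel = sk.k > 1.0
        assert abs(np.mean(sk.sk[sel]) - 1.0) < 0.15

    def test_incommensurate_error(self):
        pos = np.zeros((1, 3, 3))
        with pytest.raises(WavevectorError):
            structure_factor(pos, box_edge=10.0, k_grid=np.array([0.123]))

    def test_no_binders(self):
        with pytest.raises(EmptyInputError):
            structure_factor(np.zeros((1, 0, 3)), box_edge=10.0)


class TestManyBody:
    def test_triangle_single_component(self):
        frame = np.array([[[0.0, 0, 0], [1.0, 0, 0], [0.5, 0.8, 0]]])
        out = many_body_contact_frequency(frame, threshold=1.5, n_max=5, s_min=1)
        assert out["mean_counts"][1] == 1.0  # one component of size 3
        assert out["mean_counts"][0] == 0.0  # none of size 2

    def test_isolated_beads(self):
        frame = np.array([[[0.0, 0, 0], [10.0, 0, 0], [20.0, 0, 0]]])
        out = many_body_contact_frequency(frame, threshold=1.5, n_max=4, s_min=1)
        assert (out["mean_counts"] == 0).all()

    def test_brute_force_oracle(self, rng):
        for _ in range(3):
            frames = rng.uniform(0, 4.5, size=(4, 16, 3))
            ours = many_body_contact_frequency(frames, threshold=1.5, n_max=6,
                                               s_min=2)
            oracle = brute_force_component_counts(frames, threshold=1.5,
                                                  n_max=6, s_min=2)
            assert np.allclose(ours["mean_counts"], oracle)

    def test_globule_vs_saw_ratio_increasing(self, ordered_globule):
        """Many-body contacts are exponentially enriched in the globule:
        the (globule / SAW) frequency ratio increases with n."""
        frames = ordered_globule["frames"]
        baseline = saw_many_body_baseline(frames.shape[1], threshold=1.3,
                                          n_max=8, n_samples=3000, seed=3)
        out = many_body_contact_frequency(
            frames, threshold=1.3, n_max=8, s_min=2, box_edge=20.0,
            baseline=baseline)
        ratio = out["ratio"]  # n = 2..8
        r = ratio[1:]  # n = 3..8
        assert (np.diff(np.log(r)) > 0).all(), f"ratios not increasing: {r}"


class TestTripletContacts:
    def test_three_beads_all_contact(self):
        frame = np.array([[[0.0, 0, 0], [1.0, 0, 0], [0.5, 0.8, 0]]])
        grid = triplet_contact_probability(frame, threshold=1.5, max_s=1)
        assert grid[1, 1] == 1.0

    def test_never_in_contact(self):
        frame = np.array([[[0.0, 0, 0], [5.0, 0, 0], [10.0, 0, 0], [15.0, 0, 0]]])
        grid = triplet_contact_probability(frame, threshold=1.5, max_s=1)
        assert np.nansum(grid) == 0.0

    def test_brute_force_oracle(self, rng):
        frames = rng.uniform(0, 4, size=(20, 10, 3))
        ours = triplet_contact_probability(frames, threshold=1.6, max_s=4)
        oracle = brute_force_triplet_grid(frames, threshold=1.6, max_s=4)
        assert np.allclose(ours[1:, 1:], oracle[1:, 1:], equal_nan=True)

    def test_marginal_bounded_by_pairwise(self, rng):
        """A triplet contact implies each pairwise contact."""
        frames = rng.uniform(0, 4.0, size=(30, 12, 3))
        grid = triplet_contact_probability(frames, threshold=2.0, max_s=5)
        curve = contact_probability_vs_separation(frames, threshold=2.0)
        for s1 in range(1, 6):
            for s2 in range(1, 6):
                if np.isnan(grid[s1, s2]):
                    continue
                assert grid[s1, s2] <= curve.p[s1 - 1] + 1e-9
                assert grid[s1, s2] <= curve.p[s2 - 1] + 1e-9

    def test_domain_error(self):
        frame = np.zeros((1, 4, 3))
        with pytest.raises(DomainError):
            triplet_contact_probability(frame, max_s=3)


class TestClassifyState:
    def test_no_attraction_is_coil(self):
        cls = classify_state(0.0, 54.0, {
            "rg_mean": 11.0, "n_beads": 250, "saw_rg_mean": 11.0,
            "saw_rg_sd": 0.2})
        assert cls.state == "coil"

    def test_gaussian_ensemble_theta_flag(self, gaussian_ensemble):
        # ideal-chain Rg at bond 2: 2 * sqrt(N/6)
        rgs = [gyration_radius(f) for f in gaussian_ensemble[:200]]
        cls = classify_state(2.0, 50.0, {
            "rg_mean": float(np.mean(rgs)), "n_beads": 256,
            "saw_rg_mean": 11.1, "saw_rg_sd": 0.2, "bond_length": 2.0})
        assert cls.theta_proximal

    def test_saw_ensembles_classified_coil(self, saw_ensemble):
        """>= 95% of seeded subsamples of the SAW ensemble classify as coil."""
        ref_mean, ref_sd = saw_rg_reference(256, seed=5, n_samples=200)
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(20):
            pick = rng.integers(0, len(saw_ensemble), size=50)
            rg = np.mean([gyration_radius(saw_ensemble[i]) for i in pick])
            cls = classify_state(1.0, 10.0, {
                "rg_mean": rg, "n_beads": 256,
                "saw_rg_mean": ref_mean, "saw_rg_sd": ref_sd / np.sqrt(50)})
            hits += cls.state == "coil"
        assert hits >= 19

    def test_ordered_globule(self, ordered_globule):
        from sbsfold.observables import gyration_radius_series

        traj = ordered_globule["trajs"][0]
        rgs = gyration_radius_series(traj)[5:]
        sk = structure_factor(traj.binders[5:], box_edge=20.0)
        cls = classify_state(4.1, 38.0, {
            "rg_mean": float(rgs.mean()), "rg_series": rgs, "n_beads": 250,
            "saw_rg_mean": 11.0, "saw_rg_sd": 0.3, "sk": sk})
        assert cls.state == "globule_ordered"

    def test_disordered_globule(self, disordered_globule):
        """Across converged trajectories of the binder-lump state, the
        classifier returns the disordered globule and never the ordered one."""
        from sbsfold.observables import gyration_radius_series

        votes = []
        for traj in disordered_globule["trajs"]:
            rgs = gyration_radius_series(traj)
            half = len(rgs) // 2
            sk = structure_factor(traj.binders[half:], box_edge=20.0)
            try:
                cls = classify_state(2.6, 38.0, {
                    "rg_mean": float(rgs[half:].mean()),
                    "rg_series": rgs[half:], "n_beads": 250,
                    "saw_rg_mean": 11.0, "saw_rg_sd": 0.3, "sk": sk})
            except NotConvergedError:
                continue
            votes.append(cls.state)
        assert "globule_disordered" in votes
        assert "globule_ordered" not in votes

    def test_not_converged(self):
        series = np.linspace(11, 6, 40)  # still collapsing
        with pytest.raises(NotConvergedError):
            classify_state(3.0, 50.0, {
                "rg_mean": 8.0, "rg_series": series, "n_beads": 250,
                "saw_rg_mean": 11.0})


class TestPrePlateauWindow:
    def test_synthetic_plateau(self):
        s = np.arange(1, 250, dtype=float)
        p = np.where(s < 50, 0.5 * s**-1.0, 0.5 * 50**-1.0)
        lo, hi = pre_plateau_window(PsCurve(s=s, p=p))
        assert 25 <= hi <= 90
        fit = fit_power_law_exponent(PsCurve(s=s, p=p), (lo, hi))
        assert fit.alpha == pytest.approx(1.0, abs=0.25)


class TestBoundaryPairs:
    def test_same_pair_zero_effect(self, rng):
        frames = rng.uniform(0, 10, size=(20, 40, 3))
        res = boundary_pair_distance_test(frames, boundary=20, separation=4)
        # symmetric pair is (16, 24), asymmetric (18, 26): different pairs,
        # but comparing a pair against itself must give zero effect
        from sbsfold.observables import BoundaryPairResult
        same = BoundaryPairResult(res.distances_symmetric,
                                  res.distances_symmetric, 0.0, np.nan, 1.0)
        assert same.median_difference == 0.0

    def test_open_phase_no_difference(self, saw_ensemble):
        res = boundary_pair_distance_test(saw_ensemble[:800], boundary=128,
                                          separation=16)
        # same contour separation in a homogeneous coil: no boundary effect
        assert res.p_value > 0.01 or abs(res.median_difference) < 0.05 * np.median(
            res.distances_symmetric)

    def test_separation_too_large(self, rng):
        frames = rng.uniform(0, 5, size=(3, 30, 3))
        with pytest.raises(DomainError):
            boundary_pair_distance_test(frames, boundary=15, separation=20)

    def test_symmetry_breaking_in_closed_phase(self, block_fixture):
        """In the collapsed block copolymer the boundary-straddling symmetric
        pair sits farther apart than the asymmetric pair."""
        frames = np.concatenate(
            [t.beads[t.n_snapshots // 2:] for t in block_fixture.trajectories],
            axis=0)
        res = boundary_pair_distance_test(frames, boundary=130, separation=20)
        assert res.median_difference > 0
        assert res.p_value < 0.05
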