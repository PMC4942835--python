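import itertools

import numpy as np
import pytest

from sbsfold.errors import AlignmentError, DomainError
from sbsfold.inference import (
    AnnealSchedule,
    BindingProfile,
    anneal_binding_profile,
    baseline_from_matrix,
    matrix_pearson,
    surrogate_contact_matrix,
)
from sbsfold.observables import ContactMatrix, PsCurve


def power_law_baseline(n=200, alpha=1.2):
    s = np.arange(1.0, n)
    return PsCurve(s=s, p=s**-alpha)


def color_agreement(profile, truth):
    """Best dominant-color agreement over color relabelings."""
    dom_t = truth.dominant_color()
    dom_r = profile.dominant_color()
    ncol = truth.n_colors
    best = 0.0
    for perm in itertools.permutations(range(ncol)):
        relab = np.array([perm[c] if c >= 0 else -1 for c in dom_r])
        best = max(best, float((relab == dom_t).mean()))
    return best


class TestSurrogate:
    def test_all_inert_returns_baseline(self):
        base = power_law_baseline(50)
        profile = BindingProfile(multiplicities=np.zeros((50, 2), dtype=int))
        sur = surrogate_contact_matrix(profile, base, kappa=5.0)
        sep = np.abs(np.arange(50)[:, None] - np.arange(50)[None, :]).astype(float)
        np.fill_diagonal(sep, 1.0)
        expected = sep**-1.2
        np.fill_diagonal(expected, 1.0)
        assert np.allclose(sur.values, expected)

    def test_shared_color_raises_entry(self):
        base = power_law_baseline(30)
        m = np.zeros((30, 2), dtype=int)
        profile0 = BindingProfile(multiplicities=m.copy())
        m[5, 0] = 1
        m[20, 0] = 1
        profile1 = BindingProfile(multiplicities=m)
        s0 = surrogate_contact_matrix(profile0, base, kappa=5.0)
        s1 = surrogate_contact_matrix(profile1, base, kappa=5.0)
        assert s1.values[5, 20] > s0.values[5, 20]

    def test_monotone_in_multiplicity(self):
        base = power_law_baseline(30)
        vals = []
        for mult in (1, 2, 3):
            m = np.zeros((30, 1), dtype=int)
            m[5, 0] = mult
            m[20, 0] = mult
            sur = surrogate_contact_matrix(
                BindingProfile(multiplicities=m), base, kappa=5.0)
            vals.append(sur.values[5, 20])
        assert vals[0] < vals[1] < vals[2]

    def test_calibrated_surrogate_matches_md(self, block_fixture,
                                             truth_profile, fixture_kappa):
        sur = surrogate_contact_matrix(
            truth_profile, baseline_from_matrix(block_fixture.target),
            kappa=fixture_kappa)
        assert matrix_pearson(sur, block_fixture.target) >= 0.8


class TestMatrixPearson:
    def test_self_correlation(self, rng):
        v = rng.uniform(0, 1, size=(30, 30))
        v = 0.5 * (v + v.T)
        a = ContactMatrix(values=v)
        assert matrix_pearson(a, a) == pytest.approx(1.0)

    def test_anticorrelation(self, rng):
        v = rng.uniform(0, 1, size=(30, 30))
        v = 0.5 * (v + v.T)
        a = ContactMatrix(values=v)
        b = ContactMatrix(values=v.max() - v + 0.1)
        assert matrix_pearson(a, b) == pytest.approx(-1.0)

    def test_independent_matrices_near_zero(self):
        rng = np.random.default_rng(42)
        rs = []
        for _ in range(5):
            x = rng.uniform(0, 1, size=(100, 100))
            y = rng.uniform(0, 1, size=(100, 100))
            a = ContactMatrix(values=0.5 * (x + x.T))
            b = ContactMatrix(values=0.5 * (y + y.T))
            rs.append(matrix_pearson(a, b))
        assert abs(np.mean(rs)) < 0.05

    def test_shape_mismatch(self):
        a = ContactMatrix(values=np.eye(5))
        b = ContactMatrix(values=np.eye(6))
        with pytest.raises(AlignmentError):
            matrix_pearson(a, b)

    def test_distance_stratified(self, block_fixture):
        out = matrix_pearson(block_fixture.target, block_fixture.target,
                             "distance_stratified")
        assert out["mean"] == pytest.approx(1.0)


class TestAnnealing:
    def test_large_lambda_gives_inert(self):
        base = power_law_baseline(40)
        truth = np.zeros((40, 2), dtype=int)
        truth[5:15, 0] = 1
        target = surrogate_contact_matrix(
            BindingProfile(multiplicities=truth), base, kappa=5.0)
        res = anneal_binding_profile(
            target, n_colors=2, kappa=5.0, lam=10.0,
            schedule=AnnealSchedule(sweeps_per_level=10, seed=0))
        assert res.profile.multiplicities.sum() == 0

    def test_zero_temperature_keeps_truth(self):
        base = power_law_baseline(40)
        truth = np.zeros((40, 2), dtype=int)
        truth[5:15, 0] = 1
        truth[25:35, 1] = 1
        tp = BindingProfile(multiplicities=truth)
        target = surrogate_contact_matrix(tp, base, kappa=5.0)
        res = anneal_binding_profile(
            target, n_colors=2, kappa=5.0, lam=1e-6, init=tp, baseline=base,
            schedule=AnnealSchedule(t_initial=1e-12, sweeps_per_level=5,
                                    t_final_factor=0.5, seed=1))
        assert np.array_equal(res.profile.multiplicities, truth)

    def test_cost_trace_nonincreasing(self, anneal_result):
        # best-ever cost is monotone within each resolution level
        for trace in anneal_result.meta["level_traces"]:
            assert (np.diff(trace) <= 1e-12).all()

    def test_ground_truth_recovery(self, block_fixture, truth_profile,
                                   anneal_result, fixture_kappa):
        """>= 90% dominant-color agreement and surrogate map Pearson >= 0.9
        against the MD target."""
        assert color_agreement(anneal_result.profile, truth_profile) >= 0.90
        sur = surrogate_contact_matrix(
            anneal_result.profile, baseline_from_matrix(block_fixture.target),
            kappa=fixture_kappa)
        assert matrix_pearson(sur, block_fixture.target) >= 0.85

    def test_parsimony_removes_spurious_sites_first(self):
        """On a noisy synthetic target, increasing lambda from 0 strips the
        noise-fitted spurious colors on the inert spacer before it strips
        true block sites."""
        s = np.arange(1.0, 200.0)
        base = PsCurve(s=s, p=s**-1.2)
        truth = np.zeros((200, 2), dtype=int)
        truth[0:60, 0] = 1
        truth[72:130, 0] = 1
        truth[130:200, 1] = 1
        sur = surrogate_contact_matrix(
            BindingProfile(multiplicities=truth), base, kappa=1.5)
        rng = np.random.default_rng(7)
        noise = rng.lognormal(0, 0.15, sur.values.shape)
        noise = np.triu(noise)
        noise = noise + np.triu(noise, 1).T
        target = ContactMatrix(values=sur.values * noise)
        spacer = np.zeros(200, dtype=bool)
        spacer[60:72] = True
        spurious = {}
        blocks_kept = {}
        for lam in (0.0, 0.01):
            res = anneal_binding_profile(
                target, n_colors=2, kappa=1.5, lam=lam, baseline=base,
                schedule=AnnealSchedule(sweeps_per_level=20, seed=0))
            colored = res.profile.multiplicities.sum(axis=1) > 0
            spurious[lam] = int(colored[spacer].sum())
            blocks_kept[lam] = float(colored[~spacer].mean())
        assert spurious[0.01] <= spurious[0.0]
        assert blocks_kept[0.01] >= 0.9

    def test_invalid_colors(self, block_fixture):
        with pytest.raises(DomainError):
            anneal_binding_profile(block_fixture.target, n_colors=0)


class TestKappaCalibration:
    def test_kappa_positive_and_stable(self, fixture_kappa):
        assert 0.1 <= fixture_kappa <= 50.0
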