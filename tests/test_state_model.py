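from itertools import product

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from eegdyn.network_metrics import ObservationSeries
from eegdyn.state_model import (
    GaussianHMM,
    HMMParams,
    StatePath,
    best_of_restarts,
    canonical_state_order,
    dwell_times,
    fit_em,
    init_model,
    loglik,
    permute_states,
    state_sweep,
    viterbi,
    zscore_observations,
)
from eegdyn.synthetic import make_state_sequence


def make_series(values, condition=None):
    T = len(values)
    cond = condition if condition is not None else np.array(["EO"] * T)
    return ObservationSeries(
        np.asarray(values, float), np.arange(T, dtype=float), cond, "power",
        ("delta", "theta", "alpha", "beta")[: np.asarray(values).shape[1]],
    )


def simulate(params: HMMParams, T: int, seed: int):
    rng = np.random.default_rng(seed)
    path = make_state_sequence(params.transition, params.initial, T, seed)
    x = np.empty((T, params.n_dims))
    for t, s in enumerate(path):
        x[t] = rng.multivariate_normal(params.means[s], params.covariances[s])
    return x, path


def random_params(n: int, d: int, seed: int, sep: float = 3.0) -> HMMParams:
    rng = np.random.default_rng(seed)
    means = rng.standard_normal((n, d)) * sep
    covs = np.stack([np.eye(d) * rng.uniform(0.5, 1.5) for _ in range(n)])
    initial = rng.dirichlet(np.ones(n))
    transition = rng.dirichlet(np.ones(n) * 3, size=n)
    return HMMParams(initial, means, covs, transition)


class TestZscoreObservations:
    def test_column_standardised(self):
        s = make_series(np.column_stack([[2.0, 4.0, 6.0], [1.0, 1.5, 2.0]]))
        z = zscore_observations(s)
        np.testing.assert_allclose(z.values[:, 0], [-1.0, 0.0, 1.0])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        s = make_series(rng.standard_normal((50, 4)))
        once = zscore_observations(s)
        twice = zscore_observations(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_constant_dimension_rejected(self):
        vals = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(ValueError, match="theta"):
            zscore_observations(make_series(vals))


class TestInitModel:
    def test_deterministic_given_seed(self):
        data = np.random.default_rng(0).standard_normal((40, 4))
        a = init_model(3, data, seed=5)
        b = init_model(3, data, seed=5)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.transition, b.transition)

    def test_invariants(self):
        data = np.random.default_rng(1).standard_normal((40, 4))
        m = init_model(4, data, seed=0)
        assert m.initial.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(m.transition.sum(axis=1), 1.0, atol=1e-9)
        for c in m.covariances:
            assert np.linalg.eigvalsh(c).min() > 0

    def test_distinct_seeds_give_distinct_means(self):
        data = np.random.default_rng(2).standard_normal((100, 4))
        means = {init_model(3, data, seed=s).means.tobytes() for s in range(10)}
        assert len(means) == 10

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            init_model(5, np.zeros((4, 2)), seed=0)


class TestFitEM:
    def test_single_state_fixed_point(self):
        """With one state EM lands on the sample mean and covariance."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal((500, 3)) @ np.diag([1.0, 2.0, 0.5]) + [1, -1, 0]
        p0 = HMMParams(
            np.array([1.0]),
            np.zeros((1, 3)),
            np.eye(3)[None],
            np.array([[1.0]]),
        )
        fitted, trace = fit_em(p0, [x], tol=1e-12, max_iter=5)
        np.testing.assert_allclose(fitted.means[0], x.mean(axis=0), atol=1e-6)
        expected_cov = np.cov(x.T, bias=True)
        np.testing.assert_allclose(
            fitted.covariances[0], expected_cov, atol=2e-5
        )

    def test_trace_monotone_nondecreasing(self):
        truth = random_params(2, 2, seed=4, sep=2.0)
        x, _ = simulate(truth, 300, seed=4)
        p0 = init_model(2, x, seed=1)
        _, trace = fit_em(p0, [x], tol=1e-4, max_iter=60)
        assert np.all(np.diff(trace) >= -1e-6)

    def test_simplex_preserved_after_fit(self):
        truth = random_params(3, 2, seed=5)
        x, _ = simulate(truth, 200, seed=5)
        fitted, _ = fit_em(init_model(3, x, seed=0), [x], max_iter=30)
        assert fitted.initial.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(fitted.transition.sum(axis=1), 1.0, atol=1e-9)

    def test_well_separated_two_state_recovery(self):
        means = np.array([[-5.0, 0.0], [5.0, 0.0]])  # 10 SD apart
        truth = HMMParams(
            np.array([0.5, 0.5]),
            means,
            np.stack([np.eye(2), np.eye(2)]),
            np.array([[0.9, 0.1], [0.1, 0.9]]),
        )
        x, _ = simulate(truth, 3000, seed=11)
        fitted, _, _ = best_of_restarts(2, [x], restarts=5, seed=3, max_iter=200)
        order = np.argsort(fitted.means[:, 0])
        np.testing.assert_allclose(
            fitted.means[order], means, atol=0.1
        )

    def test_matches_hmmlearn_loglik(self):
        hmm = pytest.importorskip("hmmlearn.hmm")
        params = random_params(3, 2, seed=6)
        x, _ = simulate(params, 150, seed=6)
        ref = hmm.GaussianHMM(n_components=3, covariance_type="full", init_params="")
        ref.startprob_ = params.initial
        ref.transmat_ = params.transition
        ref.means_ = params.means
        ref.covars_ = params.covariances
        assert loglik(params, [x]) == pytest.approx(ref.score(x), abs=1e-6)


class TestBestOfRestarts:
    def test_single_restart_equals_direct_fit(self):
        params = random_params(2, 2, seed=7)
        x, _ = simulate(params, 200, seed=7)
        direct_seed = int(np.random.SeedSequence(9).generate_state(1)[0])
        direct, trace = fit_em(init_model(2, x, seed=direct_seed), [x])
        best, ll, _ = best_of_restarts(2, [x], restarts=1, seed=9)
        np.testing.assert_allclose(best.means, direct.means, atol=1e-12)
        assert ll == pytest.approx(trace[-1])

    def test_best_dominates_all_restarts(self):
        params = random_params(3, 2, seed=8)
        x, _ = simulate(params, 200, seed=8)
        _, ll, lls = best_of_restarts(3, [x], restarts=4, seed=2)
        assert ll == pytest.approx(max(lls))
        assert all(ll >= v - 1e-9 for v in lls)

    def test_well_separated_states_mostly_converge_to_best(self):
        """With strong separation most restarts land within 1% of the best."""
        truth = HMMParams(
            np.full(4, 0.25),
            8.0 * np.eye(4),  # pairwise mean distance 8*sqrt(2) SD
            np.stack([np.eye(4)] * 4),
            np.full((4, 4), 0.1) + 0.6 * np.eye(4),
        )
        xs = [simulate(truth, 300, seed=s)[0] for s in range(4)]
        _, ll, lls = best_of_restarts(4, xs, restarts=10, seed=3)
        near = sum(abs(v - ll) <= 0.01 * abs(ll) for v in lls)
        assert near >= 8


class TestViterbi:
    def test_hand_case_two_states(self):
        params = HMMParams(
            np.array([0.5, 0.5]),
            np.array([[-5.0], [5.0]]),
            np.stack([np.eye(1), np.eye(1)]),
            np.full((2, 2), 0.5),
        )
        path = viterbi(params, np.array([[-5.1], [5.2], [4.9]]))
        assert path.states.tolist() == [0, 1, 1]

    def brute_force(self, params: HMMParams, x: np.ndarray):
        n, T = params.n_states, len(x)
        logb = np.column_stack(
            [
                multivariate_normal.logpdf(
                    x, params.means[s], params.covariances[s]
                )
                for s in range(n)
            ]
        )
        best_lp, best_path = -np.inf, None
        for path in product(range(n), repeat=T):
            lp = np.log(params.initial[path[0]]) + logb[0, path[0]]
            for t in range(1, T):
                lp += np.log(params.transition[path[t - 1], path[t]])
                lp += logb[t, path[t]]
            if lp > best_lp + 1e-12:
                best_lp, best_path = lp, path
        return best_lp, best_path

    @pytest.mark.parametrize("n,T,seed", [(2, 6, 0), (3, 5, 1), (3, 8, 2), (2, 8, 3)])
    def test_matches_exhaustive_enumeration(self, n, T, seed):
        params = random_params(n, 2, seed=seed, sep=1.5)
        x, _ = simulate(params, T, seed=seed + 100)
        path = viterbi(params, x)
        best_lp, best_path = self.brute_force(params, x)
        assert path.loglik == pytest.approx(best_lp, abs=1e-9)
        assert path.states.tolist() == list(best_path)

    def test_matches_hmmlearn_decoding(self):
        hmm = pytest.importorskip("hmmlearn.hmm")
        params = random_params(3, 2, seed=12)
        x, _ = simulate(params, 120, seed=12)
        ref = hmm.GaussianHMM(n_components=3, covariance_type="full", init_params="")
        ref.startprob_ = params.initial
        ref.transmat_ = params.transition
        ref.means_ = params.means
        ref.covars_ = params.covariances
        lp_ref, path_ref = ref.decode(x, algorithm="viterbi")
        ours = viterbi(params, x)
        assert ours.loglik == pytest.approx(lp_ref, abs=1e-6)
        np.testing.assert_array_equal(ours.states, path_ref)

    def test_single_state_constant_path(self):
        params = HMMParams(
            np.array([1.0]), np.zeros((1, 2)), np.eye(2)[None], np.array([[1.0]])
        )
        path = viterbi(params, np.random.default_rng(0).standard_normal((10, 2)))
        assert np.all(path.states == 0)

    def test_dominates_posterior_marginal_path(self):
        """The joint Viterbi path is at least as probable as the pointwise
        posterior-mode path."""
        from eegdyn.state_model import _forward_backward, _log_emission

        for seed in range(3):
            params = random_params(2, 2, seed=seed, sep=0.8)
            x, _ = simulate(params, 30, seed=seed)
            vit = viterbi(params, x)
            _, gamma, _, _ = _forward_backward(x, params)
            marg = gamma.argmax(axis=1)

            def path_lp(states):
                logb = _log_emission(x, params)
                lp = np.log(params.initial[states[0]]) + logb[0, states[0]]
                for t in range(1, len(states)):
                    lp += np.log(params.transition[states[t - 1], states[t]])
                    lp += logb[t, states[t]]
                return lp

            assert path_lp(vit.states) >= path_lp(marg) - 1e-9


class TestDwellTimes:
    def test_even_split(self):
        prof = dwell_times(np.array([0, 0, 1, 1]), n=2)
        np.testing.assert_allclose(prof.overall, [0.5, 0.5])

    def test_absent_state_gets_zero(self):
        prof = dwell_times(np.array([0, 0, 0]), n=3)
        np.testing.assert_allclose(prof.overall, [1.0, 0.0, 0.0])

    def test_by_condition_counting(self):
        path = np.array([0, 0, 1, 1, 1, 0])
        cond = np.array(["EO", "EO", "EO", "EC", "EC", "EC"])
        prof = dwell_times(path, n=2, condition=cond)
        np.testing.assert_allclose(prof.by_condition["EO"], [2 / 3, 1 / 3])
        np.testing.assert_allclose(prof.by_condition["EC"], [1 / 3, 2 / 3])
        assert prof.overall.sum() == pytest.approx(1.0)

    def test_empty_path_rejected(self):
        with pytest.raises(ValueError):
            dwell_times(np.array([], dtype=int), n=2)


class TestCanonicalOrdering:
    def test_orders_by_descending_dwell(self):
        dwell = np.array([[0.1, 0.6, 0.3], [0.2, 0.5, 0.3]])
        perm = canonical_state_order(dwell)
        assert perm.tolist() == [1, 2, 0]

    def test_permute_roundtrip(self):
        params = random_params(3, 2, seed=13)
        perm = np.array([2, 0, 1])
        back = np.empty(3, int)
        back[perm] = np.arange(3)
        again = permute_states(permute_states(params, perm), back)
        np.testing.assert_allclose(again.means, params.means)
        np.testing.assert_allclose(again.transition, params.transition)


@pytest.fixture(scope="module")
def sweep_data():
    truth = random_params(3, 2, seed=14, sep=4.0)
    return [simulate(truth, 200, seed=s)[0] for s in range(3)]


class TestStateSweep:
    def test_loglik_nondecreasing_in_n(self, sweep_data):
        res = state_sweep(sweep_data, n_values=(2, 3, 4), restarts=3, seed=0)
        lls = [res[n]["loglik"] for n in (2, 3, 4)]
        assert lls[0] <= lls[1] + 1e-6 and lls[1] <= lls[2] + 1e-6

    def test_shapes_and_canonical_order(self, sweep_data):
        res = state_sweep(sweep_data, n_values=(2, 3), restarts=2, seed=1)
        for n in (2, 3):
            dwell = res[n]["dwell"]
            assert dwell.shape == (3, n)
            mean = dwell.mean(axis=0)
            assert np.all(np.diff(mean) <= 1e-12)  # descending dwell order

    def test_single_value_matches_direct_path(self, sweep_data):
        res = state_sweep(sweep_data, n_values=(3,), restarts=2, seed=2)
        assert set(res) == {3}
        assert res[3]["params"].n_states == 3


class TestEstimatorAPI:
    def test_sklearn_params_roundtrip(self):
        est = GaussianHMM(n_states=3, random_state=1)
        params = est.get_params()
        est2 = GaussianHMM(**params)
        assert est2.get_params() == params

    def test_fit_predict_score(self):
        truth = random_params(2, 2, seed=15, sep=5.0)
        xs = [simulate(truth, 150, seed=s)[0] for s in range(3)]
        X = np.vstack(xs)
        est = GaussianHMM(n_states=2, n_restarts=2, random_state=0)
        est.fit(X, lengths=[150] * 3)
        assert est.means_.shape == (2, 2)
        assert est.transmat_.shape == (2, 2)
        labels = est.predict(X, lengths=[150] * 3)
        assert labels.shape == (450,)
        assert set(labels) <= {0, 1}
        assert est.score(X, lengths=[150] * 3) == pytest.approx(est.loglik_, rel=1e-6)

    def test_sklearn_clone(self):
        sklearn = pytest.importorskip("sklearn")
        from sklearn.base import clone

        est = GaussianHMM(n_states=3, tol=0.01)
        c = clone(est)
        assert c.get_params() == est.get_params()
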