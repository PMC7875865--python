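import json

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from gazehmm import (
    DegenerateModelError,
    GaussianHMM,
    InfeasibleError,
    baum_welch,
    bic,
    initialize_params,
    log_likelihood,
    n_free_parameters,
    posterior_state_probs,
    viterbi_logprob,
    viterbi_path,
)
from gazehmm.hmm import FitResult
from conftest import (
    enumerate_paths_argmax,
    enumerate_paths_loglik,
    enumerate_posteriors,
    random_model,
    simulate_from,
)


class TestLogLikelihood:
    def test_single_state_closed_form(self, rng):
        m = GaussianHMM(pi=[1.0], A=[[1.0]], means=[[50.0, 60.0]], covars=[[100.0, 225.0]])
        xy = rng.uniform(0, 120, (40, 2))
        expected = multivariate_normal(mean=[50, 60], cov=np.diag([100, 225])).logpdf(xy).sum()
        assert log_likelihood(m, [xy]) == pytest.approx(expected, rel=1e-12)

    def test_matches_path_enumeration(self, rng):
        for _ in range(25):
            n, t = int(rng.integers(1, 4)), int(rng.integers(2, 7))
            m = random_model(rng, n)
            xy = rng.uniform(0, 500, (t, 2))
            assert log_likelihood(m, [xy]) == pytest.approx(
                enumerate_paths_loglik(m, xy), rel=1e-9
            )

    def test_state_relabelling_invariance(self, rng):
        m = random_model(rng, 3)
        xy = rng.uniform(0, 500, (30, 2))
        perm = np.array([2, 0, 1])
        mp = GaussianHMM(
            pi=m.pi[perm], A=m.A[np.ix_(perm, perm)],
            means=m.means[perm], covars=m.covars[perm],
        )
        assert log_likelihood(mp, [xy]) == pytest.approx(log_likelihood(m, [xy]), rel=1e-9)

    def test_order_of_sequences_irrelevant_and_additive(self, rng):
        m = random_model(rng, 2)
        a, b = rng.uniform(0, 500, (10, 2)), rng.uniform(0, 500, (15, 2))
        assert log_likelihood(m, [a, b]) == pytest.approx(log_likelihood(m, [b, a]))
        assert log_likelihood(m, [a, b]) == pytest.approx(
            log_likelihood(m, [a]) + log_likelihood(m, [b])
        )

    def test_long_sequence_no_underflow(self, rng):
        m = random_model(rng, 3)
        xy = rng.uniform(0, 500, (10_000, 2))
        assert np.isfinite(log_likelihood(m, [xy]))


class TestPosteriors:
    def test_rows_sum_to_one(self, rng):
        m = random_model(rng, 3)
        g = posterior_state_probs(m, rng.uniform(0, 500, (60, 2)))
        assert g.shape == (60, 3)
        np.testing.assert_allclose(g.sum(axis=1), 1.0, atol=1e-9)

    def test_single_state_posterior_is_one(self, rng):
        m = GaussianHMM(pi=[1.0], A=[[1.0]], means=[[0.0, 0.0]], covars=[[25.0, 25.0]])
        g = posterior_state_probs(m, rng.uniform(0, 10, (5, 2)))
        np.testing.assert_array_equal(g, np.ones((5, 1)))

    def test_separated_states_confident_posteriors(self, rng):
        m = GaussianHMM(
            pi=[0.5, 0.5], A=[[0.5, 0.5], [0.5, 0.5]],
            means=[[0.0, 0.0], [500.0, 0.0]], covars=[[100.0, 100.0], [100.0, 100.0]],
        )
        xy = rng.normal(0, 10, (30, 2))
        g = posterior_state_probs(m, xy)
        assert (g[:, 0] > 0.999).all()

    def test_matches_enumeration(self, rng):
        m = random_model(rng, 2)
        xy = rng.uniform(0, 500, (3, 2))
        np.testing.assert_allclose(
            posterior_state_probs(m, xy), enumerate_posteriors(m, xy), atol=1e-9
        )


class TestViterbi:
    def test_matches_brute_force(self, rng):
        for _ in range(15):
            n, t = int(rng.integers(2, 4)), int(rng.integers(2, 6))
            m = random_model(rng, n)
            xy = rng.uniform(0, 500, (t, 2))
            expected, lp = enumerate_paths_argmax(m, xy)
            np.testing.assert_array_equal(viterbi_path(m, xy), expected)
            assert viterbi_logprob(m, xy) == pytest.approx(lp, rel=1e-9)

    def test_path_logprob_below_total_loglik(self, rng):
        m = random_model(rng, 3)
        xy = rng.uniform(0, 500, (40, 2))
        assert viterbi_logprob(m, xy) <= log_likelihood(m, [xy]) + 1e-9

    def test_single_state_constant_path(self, rng):
        m = GaussianHMM(pi=[1.0], A=[[1.0]], means=[[0.0, 0.0]], covars=[[25.0, 25.0]])
        assert (viterbi_path(m, rng.uniform(0, 10, (8, 2))) == 0).all()

    def test_deterministic_cycle_forced_path(self, rng):
        # permutation transition matrix and a point-mass start: the only path
        # with nonzero probability is 0,1,2,0,1,2,... whatever the data say
        m = GaussianHMM(
            pi=[1.0, 0.0, 0.0],
            A=[[0, 1, 0], [0, 0, 1], [1, 0, 0]],
            means=[[0, 0], [100, 0], [0, 100]],
            covars=np.full((3, 2), 50.0),
        )
        path = viterbi_path(m, rng.uniform(0, 100, (9, 2)))
        np.testing.assert_array_equal(path, np.tile([0, 1, 2], 3))


class TestInitialisation:
    def test_deterministic_given_seed(self, rng):
        xy = rng.uniform(0, 500, (100, 2))
        for strategy in ("kmeans", "random"):
            a = initialize_params([xy], 4, seed=7, strategy=strategy)
            b = initialize_params([xy], 4, seed=7, strategy=strategy)
            np.testing.assert_array_equal(a.means, b.means)
            np.testing.assert_array_equal(a.covars, b.covars)

    def test_kmeans_finds_separated_clusters(self, rng):
        centers = np.array([[0, 0], [300, 0], [150, 300]], dtype=float)
        xy = np.concatenate([rng.normal(c, 15, (50, 2)) for c in centers])
        m = initialize_params([xy], 3, seed=0, strategy="kmeans")
        dists = np.linalg.norm(m.means[:, None] - centers[None], axis=2)
        assert sorted(np.argmin(dists, axis=1).tolist()) == [0, 1, 2]
        assert dists.min(axis=1).max() < 45  # within 3 x cluster SD

    def test_output_valid_and_infeasible_raises(self, rng):
        xy = rng.uniform(0, 100, (10, 2))
        m = initialize_params([xy], 3, seed=0, strategy="random")
        np.testing.assert_allclose(m.A.sum(axis=1), 1.0, atol=1e-9)
        assert m.pi.sum() == pytest.approx(1.0)
        with pytest.raises(InfeasibleError):
            initialize_params([xy], 11, seed=0)


class TestBaumWelch:
    def test_single_state_recovers_sample_moments(self, rng):
        xy = rng.normal([200, 300], [20, 35], (400, 2))
        fit = baum_welch([xy], 1, seed=0)
        np.testing.assert_allclose(fit.model.means[0], xy.mean(axis=0), atol=1e-6)
        np.testing.assert_allclose(fit.model.covars[0], xy.var(axis=0, ddof=0), rtol=1e-6)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_parameter_recovery_separated_states(self, separated_3state, seed):
        seqs = simulate_from(separated_3state, 30, 100, seed=seed)
        fit = baum_welch(seqs, 3, seed=seed)
        # optimal state matching by nearest recovered mean
        perm = [
            int(np.argmin(np.linalg.norm(fit.model.means - t, axis=1)))
            for t in separated_3state.means
        ]
        assert sorted(perm) == [0, 1, 2]
        err = np.linalg.norm(fit.model.means[perm] - separated_3state.means, axis=1)
        assert err.max() < 5.0
        A_hat = fit.model.A[np.ix_(perm, perm)]
        assert np.abs(A_hat - separated_3state.A).max() < 0.05

    def test_monotone_loglik_from_perturbed_truth(self, separated_3state, rng):
        seqs = simulate_from(separated_3state, 5, 80, seed=3)
        perturbed = GaussianHMM(
            pi=separated_3state.pi,
            A=separated_3state.A,
            means=separated_3state.means + rng.normal(0, 5, (3, 2)),
            covars=separated_3state.covars * 1.3,
        )
        fit = baum_welch(seqs, 3, init=perturbed, max_iter=50)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-8)

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(InfeasibleError):
            baum_welch([rng.uniform(0, 10, (9, 2))], 2, seed=0)

    def test_crosscheck_against_reference_hmm_library(self, separated_3state):
        """Likelihood and EM optimum agree with an independent reference
        implementation (hmmlearn) on one fixed dataset."""
        from hmmlearn.hmm import GaussianHMM as RefHMM

        seqs = simulate_from(separated_3state, 10, 80, seed=11)
        X = np.concatenate([s.xy for s in seqs])
        lengths = [len(s) for s in seqs]
        ours = baum_welch(seqs, 3, seed=0)
        # the likelihood function itself: same parameters, same value
        scorer = RefHMM(n_components=3, covariance_type="diag", init_params="", params="")
        scorer.startprob_ = ours.model.pi
        scorer.transmat_ = ours.model.A
        scorer.means_ = ours.model.means
        scorer.covars_ = ours.model.covars
        assert scorer.score(X, lengths) == pytest.approx(ours.log_likelihood, rel=1e-10)
        # the fitted optimum: best of a few reference restarts matches within 0.1%
        ref_ll = max(
            RefHMM(n_components=3, covariance_type="diag", n_iter=500,
                   tol=1e-6, random_state=rs).fit(X, lengths).score(X, lengths)
            for rs in range(5)
        )
        assert ours.log_likelihood == pytest.approx(ref_ll, rel=1e-3)

    def test_full_covariance_supported(self, rng):
        cov = np.array([[[400.0, 120.0], [120.0, 300.0]]])
        xy = rng.multivariate_normal([100, 100], cov[0], size=500)
        fit = baum_welch([xy], 1, seed=0, covariance_kind="full")
        np.testing.assert_allclose(fit.model.covars[0], np.cov(xy.T, ddof=0), rtol=0.05)


class TestComplexityAndBIC:
    @pytest.mark.parametrize(
        "n,kind,expected",
        [(1, "diag", 4), (2, "diag", 11), (7, "full", 83), (14, "diag", 251)],
    )
    def test_free_parameter_count(self, n, kind, expected):
        assert n_free_parameters(n, kind) == expected

    def test_bic_formula(self):
        m = GaussianHMM(pi=[0.5, 0.5], A=[[0.9, 0.1], [0.1, 0.9]],
                        means=[[0, 0], [10, 10]], covars=[[4.0, 4.0], [4.0, 4.0]])
        fit = FitResult(model=m, log_likelihood=-500.0, loglik_trace=[-500.0],
                        n_iterations=1, converged=True, seed=0, n_observations=100)
        assert bic(fit) == pytest.approx(1000 + 11 * np.log(100))

    def test_bic_single_point_edge_case(self):
        m = GaussianHMM(pi=[1.0], A=[[1.0]], means=[[0, 0]], covars=[[1.0, 1.0]])
        fit = FitResult(model=m, log_likelihood=0.0, loglik_trace=[0.0],
                        n_iterations=1, converged=True, seed=0, n_observations=1)
        assert bic(fit) == 0.0

    def test_bic_increases_with_n(self):
        m = GaussianHMM(pi=[1.0], A=[[1.0]], means=[[0, 0]], covars=[[1.0, 1.0]])
        vals = [
            bic(FitResult(model=m, log_likelihood=-50.0, loglik_trace=[-50.0],
                          n_iterations=1, converged=True, seed=0, n_observations=n))
            for n in (10, 100, 1000)
        ]
        assert vals[0] < vals[1] < vals[2]


class TestSerialization:
    def test_json_round_trip_bit_exact(self, rng):
        m = random_model(rng, 4)
        back = GaussianHMM.from_json(m.to_json())
        np.testing.assert_array_equal(back.pi, m.pi)
        np.testing.assert_array_equal(back.A, m.A)
        np.testing.assert_array_equal(back.means, m.means)
        np.testing.assert_array_equal(back.covars, m.covars)

    def test_json_fields(self, rng):
        d = json.loads(random_model(rng, 2).to_json())
        assert set(d) == {"n_states", "pi", "A", "means", "variances", "covariance_kind"}


class TestDegeneracy:
    def test_unreachable_emitting_state_raises(self):
        # all probability mass is trapped in state 0, whose emission density
        # underflows to zero at the second observation: the forward mass dies
        m = GaussianHMM(
            pi=[1.0, 0.0], A=[[1.0, 0.0], [0.0, 1.0]],
            means=[[0.0, 0.0], [1e6, 1e6]], covars=[[1.0, 1.0], [1.0, 1.0]],
        )
        xy = np.array([[0.0, 0.0], [1e6, 1e6]])
        with pytest.raises(DegenerateModelError):
            log_likelihood(m, [xy])
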