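"""The cumulative-logit kernel, induced-Dirichlet prior, and joint density."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, stats
from scipy.special import expit

from latentconn.ordinal_model import (ConstraintError, ModelData, Parameters,
                                      PriorConfig, category_logprobs,
                                      corr_cholesky, induced_dirichlet_logpdf,
                                      log_posterior, loglik_row,
                                      marginal_loglik_by_participant,
                                      observed_logprob)
from oracles import log_posterior_brute


class TestCategoryLogprobs:
    def test_matches_direct_logistic_cdf_evaluation(self):
        p = np.exp(category_logprobs(0.0, np.array([-1.0, 0.0, 1.0])))
        F = expit
        expected = [F(-1), F(0) - F(-1), F(1) - F(0), 1 - F(1)]
        np.testing.assert_allclose(p, expected, rtol=1e-12)
        np.testing.assert_allclose(p, [0.26894, 0.23106, 0.23106, 0.26894], atol=1e-5)

    def test_saturates_to_first_category_for_very_negative_eta(self):
        p = np.exp(category_logprobs(-1e6, np.array([-1.0, 0.0, 1.0])))
        assert p[0] == pytest.approx(1.0)

    def test_symmetric_cuts_give_symmetric_probabilities(self):
        p = np.exp(category_logprobs(0.4, np.array([-2.0, 0.0, 2.0]) + 0.4))
        np.testing.assert_allclose(p, p[::-1], rtol=1e-12)

    def test_rejects_non_ascending_cuts(self):
        with pytest.raises(ConstraintError):
            category_logprobs(0.0, np.array([1.0, 0.0]))

    @given(st.integers(3, 7), st.floats(-30, 30), st.integers(0, 10_000))
    def test_probabilities_sum_to_one(self, k, eta, seed):
        cut = np.sort(np.random.default_rng(seed).normal(size=k - 1) * 3)
        cut += np.arange(k - 1) * 1e-6  # enforce strict ascent under ties
        total = np.exp(category_logprobs(eta, cut)).sum()
        assert total == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(-5, 5), st.floats(-8, 8))
    def test_translation_invariance_of_cuts_and_eta(self, shift, eta):
        cut = np.array([-1.5, -0.2, 0.9, 2.0])
        base = category_logprobs(eta, cut)
        moved = category_logprobs(eta + shift, cut + shift)
        np.testing.assert_allclose(base, moved, atol=1e-10)


class TestInducedDirichlet:
    def test_single_cut_reduces_to_logistic_density(self):
        for c in (-1.3, 0.0, 0.8):
            got = induced_dirichlet_logpdf(np.array([c]), [1.0, 1.0], anchor=0.0)
            assert got == pytest.approx(stats.logistic.logpdf(c), abs=1e-12)

    def test_density_integrates_to_one_over_ordered_cuts(self):
        val, err = integrate.dblquad(
            lambda c2, c1: np.exp(
                induced_dirichlet_logpdf(np.array([c1, c2]), [1.0, 1.0, 1.0])),
            -15, 15, lambda c1: c1 + 1e-9, lambda c1: 15, epsabs=1e-6)
        assert val == pytest.approx(1.0, abs=1e-3)

    def test_symmetric_alpha_pools_toward_equal_category_probabilities(self):
        # the density transported back to probability space (Jacobian removed)
        # is the plain Dirichlet: over symmetric two-cut configurations (-c, c)
        # it peaks where the implied category probabilities are equal,
        # i.e. F(c) = 2/3 -> c = log 2 (grid-search oracle)
        alpha = [2.0, 2.0, 2.0]
        grid = np.linspace(0.05, 4.0, 400)
        dens = []
        for c in grid:
            jac = stats.logistic.logpdf(-c) + stats.logistic.logpdf(c)
            dens.append(induced_dirichlet_logpdf(np.array([-c, c]), alpha) - jac)
        best = grid[int(np.argmax(dens))]
        assert best == pytest.approx(np.log(2.0), abs=0.02)

    def test_non_ascending_cut_flagged(self):
        with pytest.raises(ConstraintError):
            induced_dirichlet_logpdf(np.array([1.0, 0.0]), [1, 1, 1])
        assert induced_dirichlet_logpdf(np.array([1.0, 0.0]), [1, 1, 1],
                                        strict=False) == -np.inf


def _toy_params(n_participants=3, with_concert=False):
    return Parameters(
        beta={"artist": np.array([0.5, -0.3]), "audience": np.array([0.2])},
        cut={"explicit5": np.array([-1.4, -0.4, 0.4, 1.4]),
             "ios7": np.array([-1.8, -0.9, -0.3, 0.3, 0.9, 1.8])},
        u=np.array([[0.3, -0.2], [0.0, 0.1], [-0.5, 0.4]])[:n_participants],
        sigma_u=np.array([0.8, 1.1]),
        L=corr_cholesky(0.35),
        w=np.array([0.2, -0.1]) if with_concert else None,
        sigma_w=0.6 if with_concert else None,
    )


def _toy_data(with_concert=False):
    X = {"artist": np.array([[1.0, 0.5], [0.0, -1.0], [2.0, 0.3], [1.0, 1.0], [-1.0, 0.0]]),
         "audience": np.array([[0.5], [1.5], [-0.5], [0.0], [1.0]])}
    y = {"artist": {"explicit5": np.array([1, 3, 5, 0, 2]),
                    "ios7": np.array([2, 7, 6, 1, 0])},
         "audience": {"explicit5": np.array([4, 2, 0, 3, 1]),
                      "ios7": np.array([5, 3, 2, 0, 6])}}
    return ModelData(X=X, y=y, participant_idx=np.array([0, 1, 2, 0, 1]),
                     concert_idx=np.array([0, 0, 1, 1, 0]) if with_concert else None)


class TestLoglik:
    def test_missing_response_contributes_exactly_zero(self):
        terms = loglik_row({"artist": {"explicit5": None}, "audience": {"ios7": 4}},
                           0.5, -0.2,
                           {"explicit5": np.array([-1, 0, 1.0]),
                            "ios7": np.arange(-2.5, 3, 1.0)},
                           np.array([0.1, -0.1]))
        assert terms[("artist", "explicit5")] == 0.0
        assert terms[("audience", "ios7")] < 0

    def test_certain_category_has_near_zero_term(self):
        terms = loglik_row({"artist": {"explicit5": 1}}, -40.0, 0.0,
                           {"explicit5": np.array([-1, 0, 1.0])}, np.zeros(2))
        assert terms[("artist", "explicit5")] == pytest.approx(0.0, abs=1e-12)

    def test_total_equals_hand_summed_category_logprobs(self):
        params, data = _toy_params(), _toy_data()
        total = 0.0
        for i, o in enumerate(("artist", "audience")):
            eta = data.X[o] @ params.beta[o]
            for m, yvec in data.y[o].items():
                for r, yy in enumerate(yvec):
                    if yy < 1:
                        continue
                    shifted = params.cut[m] + params.u[data.participant_idx[r], i]
                    total += category_logprobs(eta[r], shifted)[yy - 1]
        vec = 0.0
        for i, o in enumerate(("artist", "audience")):
            eta = data.X[o] @ params.beta[o]
            for m, yvec in data.y[o].items():
                vec += observed_logprob(yvec, eta, params.cut[m],
                                        params.u[data.participant_idx, i]).sum()
        assert vec == pytest.approx(total, abs=1e-10)


class TestLogPosterior:
    @pytest.mark.parametrize("with_concert", [False, True])
    def test_matches_from_scratch_oracle(self, with_concert):
        params = _toy_params(with_concert=with_concert)
        data = _toy_data(with_concert=with_concert)
        priors = PriorConfig()
        got = log_posterior(params, data, priors=priors)
        want = log_posterior_brute(params, data, priors)
        assert got == pytest.approx(want, abs=1e-10)

    def test_empty_data_equals_pure_prior(self):
        params = _toy_params()
        priors = PriorConfig()
        prior_only = log_posterior(params, None, priors=priors)
        data = _toy_data()
        empty = ModelData(X={o: X[:0] for o, X in data.X.items()},
                          y={o: {m: y[:0] for m, y in ys.items()}
                             for o, ys in data.y.items()},
                          participant_idx=np.array([], dtype=int))
        assert log_posterior(params, empty, priors=priors) == pytest.approx(prior_only)

    def test_duplicating_one_observation_adds_its_loglik(self):
        params, data = _toy_params(), _toy_data()
        base = log_posterior(params, data)
        dup = ModelData(
            X={o: np.vstack([X, X[:1]]) for o, X in data.X.items()},
            y={o: {m: np.concatenate([y, [0]]) if o != "artist" or m != "explicit5"
                   else np.concatenate([y, y[:1]])
                   for m, y in ys.items()} for o, ys in data.y.items()},
            participant_idx=np.concatenate([data.participant_idx, [0]]))
        eta = data.X["artist"][0] @ params.beta["artist"]
        extra = category_logprobs(eta, params.cut["explicit5"] + params.u[0, 0])[0]
        assert log_posterior(params, dup) == pytest.approx(base + extra, abs=1e-10)

    def test_constraint_violations_give_minus_inf(self):
        params = _toy_params()
        params.sigma_u = np.array([-1.0, 1.0])
        assert log_posterior(params, _toy_data()) == -np.inf

    def test_finite_on_interior(self):
        assert np.isfinite(log_posterior(_toy_params(), _toy_data()))


class TestMarginalLoglik:
    def test_zero_variance_effect_reduces_to_plug_in(self):
        params, data = _toy_params(), _toy_data()
        params.u = np.zeros_like(params.u)
        params.sigma_u = np.array([1e-8, 1e-8])
        marg = marginal_loglik_by_participant(params, data, n_nodes=7)
        plug = np.zeros(3)
        for i, o in enumerate(("artist", "audience")):
            eta = data.X[o] @ params.beta[o]
            for m, yvec in data.y[o].items():
                ll = observed_logprob(yvec, eta, params.cut[m], 0.0)
                plug += np.bincount(data.participant_idx, weights=ll, minlength=3)
        np.testing.assert_allclose(marg, plug, atol=1e-6)

    def test_sums_match_direct_quadrature_on_one_participant(self):
        params, data = _toy_params(), _toy_data()
        marg = marginal_loglik_by_participant(params, data, n_nodes=31)
        # brute 2-D quadrature over the participant-0 likelihood
        from scipy.stats import multivariate_normal
        s1, s2 = params.sigma_u
        rho = 0.35
        cov = [[s1**2, rho * s1 * s2], [rho * s1 * s2, s2**2]]
        rows = np.flatnonzero(data.participant_idx == 0)

        def integrand(u1, u2):
            total = 0.0
            for i, o in enumerate(("artist", "audience")):
                eta = data.X[o] @ params.beta[o]
                for m, yvec in data.y[o].items():
                    for r in rows:
                        if yvec[r] >= 1:
                            total += category_logprobs(
                                eta[r], params.cut[m] + (u1, u2)[i])[yvec[r] - 1]
            return np.exp(total) * multivariate_normal.pdf([u1, u2], [0, 0], cov)

        val, _ = integrate.dblquad(integrand, -6, 6, -6, 6, epsabs=1e-10)
        assert marg[0] == pytest.approx(np.log(val), abs=1e-4)
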