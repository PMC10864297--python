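import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from roambait import (
    PosteriorApprox,
    build_fractional_prior,
    estimate_complexity,
    estimate_fit,
    evaluate_hypotheses,
    evidence_table,
    parse_hypothesis,
    posterior_model_probabilities,
    sensitivity_over_fractions,
)
from roambait.evidence import EvidenceResult, evidence

DRAWS = 50_000


def _post(mean, cov, n_eff=100.0, names=None):
    mean = np.atleast_1d(np.asarray(mean, float))
    names = names or tuple(f"g{i+1}" for i in range(mean.size))
    return PosteriorApprox(mean, cov, n_eff, names=tuple(names))


class TestFractionalPrior:
    def test_b_and_cov_scaling(self):
        post = _post([0, 0], np.eye(2), n_eff=100)
        cs = parse_hypothesis("g1>0 & g2>0", post.names)
        prior = build_fractional_prior(post, cs, fraction=2)
        assert prior.b == pytest.approx(0.02)  # J=2 / n_eff=100
        assert np.allclose(prior.cov, 25 * np.eye(2))
        assert np.allclose(prior.mean, 0)

    def test_b_equals_one_returns_posterior_cov(self):
        post = _post([1.0], [[2.0]], n_eff=1)
        cs = parse_hypothesis("g1>0", post.names)
        prior = build_fractional_prior(post, cs, fraction=1)
        assert np.allclose(prior.cov, post.sigma)

    def test_fraction_scales_cov_linearly(self):
        post = _post([0, 0], np.eye(2), n_eff=50)
        cs = parse_hypothesis("g1>g2", post.names)
        p1 = build_fractional_prior(post, cs, fraction=1)
        p3 = build_fractional_prior(post, cs, fraction=3)
        assert np.allclose(p3.cov, p1.cov / 3)

    def test_shared_J_override(self):
        post = _post([0, 0], np.eye(2), n_eff=100)
        cs = parse_hypothesis("g1>0", post.names)
        prior = build_fractional_prior(post, cs, fraction=1, J=2)
        assert prior.b == pytest.approx(0.02)

    def test_nonzero_boundary_rejected(self):
        post = _post([0.0], [[1.0]])
        cs = parse_hypothesis("g1>1.5", post.names)
        with pytest.raises(ValueError, match="boundary"):
            build_fractional_prior(post, cs, fraction=2)


class TestFit:
    def test_orthant_fit_matches_cdf_product(self):
        post = _post([1, 1], np.eye(2))
        cs = parse_hypothesis("g1>0 & g2>0", post.names)
        fit, se = estimate_fit(post, cs, draws=100_000, seed=1)
        assert fit == pytest.approx(stats.norm.cdf(1) ** 2, abs=3 * se)
        assert 0 < se < 0.01

    def test_symmetric_half_space(self):
        post = _post([0.0], [[1.0]])
        cs = parse_hypothesis("g1>0", post.names)
        fit, se = estimate_fit(post, cs, draws=DRAWS, seed=2)
        assert fit == pytest.approx(0.5, abs=3 * se)

    def test_equality_density_is_normal_pdf(self):
        post = _post([0.0], [[1.0]])
        cs = parse_hypothesis("g1=0", post.names)
        fit, se = estimate_fit(post, cs, draws=DRAWS, seed=3)
        assert se == 0.0  # closed form
        assert fit == pytest.approx(1 / np.sqrt(2 * np.pi), rel=1e-12)

    def test_conditional_inequality_given_equality(self):
        # correlated pair: under g1 = 0 the conditional of g2 is
        # N(mu2 + rho*(0 - mu1), 1 - rho^2)
        rho = 0.6
        post = _post([1.0, 1.0], [[1, rho], [rho, 1]])
        cs = parse_hypothesis("g1=0 & g2>0", post.names)
        fit, se = estimate_fit(post, cs, draws=200_000, seed=4)
        cond_mean = 1.0 + rho * (0.0 - 1.0)
        cond_sd = np.sqrt(1 - rho**2)
        expected = stats.norm.pdf(0.0, 1.0, 1.0) * stats.norm.sf(0.0, cond_mean, cond_sd)
        assert fit == pytest.approx(expected, abs=3 * se * stats.norm.pdf(0.0, 1.0, 1.0) + 1e-4)

    def test_too_few_draws_rejected(self):
        post = _post([0.0], [[1.0]])
        cs = parse_hypothesis("g1>0", post.names)
        with pytest.raises(ValueError, match="draws"):
            estimate_fit(post, cs, draws=100, seed=0)


class TestComplexity:
    def test_two_independent_inequalities_quarter(self):
        post = _post([3, -2], np.diag([1.0, 2.0]), n_eff=64)
        cs = parse_hypothesis("g1>0 & g2>0", post.names)
        prior = build_fractional_prior(post, cs, fraction=2)
        c, se = estimate_complexity(prior, cs, draws=DRAWS, seed=5)
        assert c == pytest.approx(0.25, abs=3 * se)

    @pytest.mark.parametrize("k", [3, 4, 5])
    def test_full_ordering_one_over_k_factorial(self, k):
        names = tuple(f"m{i}" for i in range(k))
        post = _post(np.zeros(k), np.eye(k), names=names)
        cs = parse_hypothesis(">".join(names), names)
        prior = build_fractional_prior(post, cs, fraction=1)
        c, se = estimate_complexity(prior, cs, draws=200_000, seed=6)
        expected = 1 / math.factorial(k)
        assert c == pytest.approx(expected, abs=4 * se)

    def test_equality_complexity_is_prior_density(self):
        post = _post([0.7], [[0.5]], n_eff=40)
        cs = parse_hypothesis("g1=0", post.names)
        prior = build_fractional_prior(post, cs, fraction=2)
        c, _ = estimate_complexity(prior, cs, draws=DRAWS, seed=7)
        v = prior.cov[0, 0]
        assert c == pytest.approx(1 / np.sqrt(2 * np.pi * v), rel=1e-12)

    def test_pure_inequality_complexity_invariant_to_fraction_and_neff(self):
        # orthant probabilities of a zero-mean normal are scale free
        names = ("g1", "g2")
        cs = parse_hypothesis("g1>0 & g2>g1", names)
        vals = []
        for f, n_eff in [(1, 50), (2, 50), (3, 500)]:
            post = _post([1, 2], [[1.0, 0.3], [0.3, 2.0]], n_eff=n_eff, names=names)
            prior = build_fractional_prior(post, cs, fraction=f)
            c, se = estimate_complexity(prior, cs, draws=DRAWS, seed=8)
            vals.append((c, se))
        for (c, se), (c2, se2) in zip(vals, vals[1:]):
            assert c == pytest.approx(c2, abs=3 * np.hypot(se, se2))


class TestBayesFactors:
    def test_bf_arithmetic(self):
        bf_iu, bf_ic = evidence(0.5, 0.25)
        assert bf_iu == pytest.approx(2.0)
        assert bf_ic == pytest.approx(3.0)

    def test_indifference(self):
        _, bf_ic = evidence(0.4, 0.4)
        assert bf_ic == pytest.approx(1.0)

    def test_equality_only_uses_bf_iu(self):
        bf_iu, bf_ic = evidence(0.4, 0.1, equality_only=True)
        assert bf_iu == bf_ic == pytest.approx(4.0)

    def test_certain_fit_gives_infinite_bf_ic_not_crash(self):
        _, bf_ic = evidence(1.0, 0.25)
        assert np.isinf(bf_ic)

    def test_bf_ic_of_complementary_inequalities_multiply_to_one(self):
        # exact identity: complement swaps fit -> 1-fit, complexity -> 1-c
        p, c = 0.7, 0.25
        _, bf_h = evidence(p, c)
        _, bf_comp = evidence(1 - p, 1 - c)
        assert bf_h * bf_comp == pytest.approx(1.0, rel=1e-12)
        # and within Monte-Carlo error when both sides are estimated
        post = _post([0.8], [[1.0]])
        h = evaluate_hypotheses(post, {"H1": "g1>0", "H2": "g1<0"},
                                draws=DRAWS, seed=9, include_failsafe=False)
        assert h[0].bf_ic * h[1].bf_ic == pytest.approx(1.0, rel=0.1)


class TestPosteriorModelProbabilities:
    @staticmethod
    def _mk(bf):
        return EvidenceResult(name="H", fit=np.nan, complexity=np.nan,
                              bf_iu=bf, bf_ic=np.nan)

    def test_normalization(self):
        post = posterior_model_probabilities([self._mk(4.0), self._mk(1.0)])
        assert np.allclose(post, [0.8, 0.2])

    def test_failsafe_unconstrained_mode(self):
        res = [self._mk(2.0), self._mk(2.0)]
        post = posterior_model_probabilities(res, include_failsafe=True,
                                             failsafe_mode="unconstrained")
        assert np.allclose(post, [0.4, 0.4, 0.2])

    def test_single_hypothesis_with_complement(self):
        post = _post([1.3], [[1.0]], n_eff=50)
        res = evaluate_hypotheses(post, {"H1": "g1>0"}, draws=DRAWS, seed=10)
        tab = evidence_table(res)
        fit_h = res[0].fit
        com_h = res[0].complexity
        expect_h = (fit_h / com_h) / (fit_h / com_h + (1 - fit_h) / (1 - com_h))
        assert tab["PostP"].sum() == pytest.approx(1.0, abs=1e-9)
        assert tab.loc[0, "PostP"] == pytest.approx(expect_h, abs=1e-9)

    def test_non_exclusive_set_raises(self):
        over = [
            EvidenceResult("a", 0.9, 0.9, 1.0, np.nan, fit_prob=0.9, complexity_prob=0.9,
                           constraints=parse_hypothesis("g1>0", ("g1",))),
            EvidenceResult("b", 0.9, 0.9, 1.0, np.nan, fit_prob=0.9, complexity_prob=0.9,
                           constraints=parse_hypothesis("g1>1", ("g1",))),
        ]
        with pytest.raises(ValueError, match="exclusive"):
            posterior_model_probabilities(over, include_failsafe=True)

    @settings(max_examples=40, deadline=None)
    @given(
        bfs=st.lists(st.floats(0.01, 100.0), min_size=2, max_size=6),
        scale=st.floats(0.01, 100.0),
    )
    def test_postp_sums_to_one_and_is_scale_invariant(self, bfs, scale):
        a = posterior_model_probabilities([self._mk(b) for b in bfs])
        b = posterior_model_probabilities([self._mk(b * scale) for b in bfs])
        assert a.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(a, b, atol=1e-9)


class TestSensitivity:
    def test_inequality_bf_stable_over_fractions(self):
        post = _post([0.9, 0.2], np.eye(2), n_eff=80)
        tab = sensitivity_over_fractions(post, {"H1": "g1>g2"}, draws=DRAWS,
                                         seed=11, include_failsafe=False)
        h1 = tab[tab.hypothesis == "H1"]
        se = h1.mc_se.max()
        assert h1.BF_iu.max() - h1.BF_iu.min() < 6 * se / h1.complexity.min()

    def test_equality_bf_scales_as_sqrt_fraction(self):
        # prior density at 0 grows with sqrt(f*b), so BF(f=1)/BF(f=2) = sqrt(2)
        post = _post([0.4], [[1.0]], n_eff=100)
        tab = sensitivity_over_fractions(post, {"H0": "g1=0"}, fractions=(1, 2),
                                         draws=DRAWS, seed=12, include_failsafe=False)
        ratio = tab.BF_iu.iloc[0] / tab.BF_iu.iloc[1]
        assert ratio == pytest.approx(np.sqrt(2), rel=1e-9)

    def test_single_fraction_single_row_per_hypothesis(self):
        post = _post([0.0], [[1.0]])
        tab = sensitivity_over_fractions(post, {"H1": "g1>0"}, fractions=(2.0,),
                                         draws=DRAWS, seed=13, include_failsafe=False)
        assert len(tab) == 1
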