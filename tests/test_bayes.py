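"""Dirichlet-multinomial evidence, order posterior and predictives."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from obsinfer.bayes import (
    ObserverSpec,
    asymptotic_map_order,
    log_evidence_order,
    log_prior_order,
    order_posterior,
    predictive_argmax,
    predictive_average,
)
from obsinfer.stimuli import (
    EntropyCurve,
    SymbolSequence,
    count_contexts,
    generate_stimulus,
    sample_markov_model,
)


def quad_evidence(counts, R, alpha, beta):
    """Independent oracle: per-context numerical integration over theta.

    For a binary alphabet the order-R evidence factorizes over contexts:
    prod_c  [ integral theta^(b n(c1)+a-1) (1-theta)^(b n(c0)+a-1) dtheta
              / B(a, a) ].
    """
    from scipy.special import betaln

    total = 0.0
    for c in range(2 ** R):
        n1 = counts.n_sym(R, c, 1)
        n0 = counts.n_sym(R, c, 0)
        if n0 + n1 == 0:
            continue
        val, _ = quad(
            lambda th: th ** (beta * n1 + alpha - 1)
            * (1 - th) ** (beta * n0 + alpha - 1),
            0.0,
            1.0,
        )
        total += math.log(val) - betaln(alpha, alpha)
    return total


def quad_posterior_mean(n1, n0, alpha, beta):
    """Oracle posterior mean of theta_1 under beta-discounted counts."""
    num, _ = quad(
        lambda th: th * th ** (beta * n1 + alpha - 1) * (1 - th) ** (beta * n0 + alpha - 1),
        0, 1,
    )
    den, _ = quad(
        lambda th: th ** (beta * n1 + alpha - 1) * (1 - th) ** (beta * n0 + alpha - 1),
        0, 1,
    )
    return num / den


class TestLogPrior:
    @pytest.mark.parametrize(
        "R,gamma,A,expected",
        [(0, 2.0, 2, -2.0), (2, 2.0, 2, -8.0), (5, 0.0, 2, 0.0), (1, 1.0, 3, -6.0)],
    )
    def test_formula(self, R, gamma, A, expected):
        assert log_prior_order(R, gamma, A) == pytest.approx(expected, abs=1e-15)

    def test_domain(self):
        with pytest.raises(ValueError):
            log_prior_order(-1, 1.0, 2)
        with pytest.raises(ValueError):
            log_prior_order(0, -0.5, 2)


class TestLogEvidence:
    def test_empty_sequence_zero(self):
        counts = count_contexts(SymbolSequence([]), 2)
        for R in range(3):
            assert log_evidence_order(counts, R, alpha=1.7, beta=0.8) == 0.0

    def test_beta_zero_ignores_data(self):
        counts = count_contexts(SymbolSequence.from_string("011010"), 2)
        for R in range(3):
            assert log_evidence_order(counts, R, alpha=2.0, beta=0.0) == pytest.approx(
                0.0, abs=1e-12
            )

    def test_beta_integral_closed_form(self):
        """'0011' at order 0, uniform prior: evidence = 1/30 (Beta(3,3))."""
        counts = count_contexts(SymbolSequence.from_string("0011"), 0)
        assert log_evidence_order(counts, 0, alpha=1.0, beta=1.0) == pytest.approx(
            math.log(1 / 30), abs=1e-12
        )

    def test_alpha_domain(self):
        counts = count_contexts(SymbolSequence.from_string("01"), 0)
        with pytest.raises(ValueError):
            log_evidence_order(counts, 0, alpha=0.0, beta=1.0)

    @pytest.mark.parametrize("alpha,beta", [(1.0, 1.0), (2.0, 1.0), (1.5, 0.6)])
    @pytest.mark.parametrize("R", [0, 1])
    def test_quadrature_oracle_all_sequences(self, R, alpha, beta):
        """Evidence equals its defining integral for every sequence, t <= 5."""
        for t in range(1, 6):
            for code in range(2 ** t):
                bits = [(code >> i) & 1 for i in range(t)]
                counts = count_contexts(SymbolSequence(bits), R)
                got = log_evidence_order(counts, R, alpha, beta)
                want = quad_evidence(counts, R, alpha, beta)
                assert got == pytest.approx(want, abs=1e-8)


class TestOrderPosterior:
    def spec(self, **kw):
        base = dict(strategy="ngram_average", alpha=1.0, beta=1.0, gamma=0.1)
        base.update(kw)
        return ObserverSpec(**base)

    def test_empty_sequence_posterior_is_prior(self):
        counts = count_contexts(SymbolSequence([]), 3)
        post = order_posterior(counts, self.spec(gamma=0.7), 3)
        assert post.map_order == 0
        expected = post.log_prior - post.log_prior[0]
        centered = post.log_posterior - post.log_posterior[0]
        assert np.allclose(centered, expected, atol=1e-12)

    def test_posterior_normalized(self):
        counts = count_contexts(SymbolSequence.from_string("0110100110"), 3)
        post = order_posterior(counts, self.spec(), 3)
        assert np.exp(post.log_posterior).sum() == pytest.approx(1.0, abs=1e-10)
        assert post.z_prior == pytest.approx(np.exp(post.log_prior).sum(), rel=1e-12)

    def test_alternating_sequence_selects_order_one(self):
        seq = SymbolSequence.from_string("01" * 100)
        post = order_posterior(count_contexts(seq, 4), self.spec(), 4)
        assert post.map_order == 1

    def test_fair_coin_selects_order_zero(self):
        m = sample_markov_model(0, seed=0)
        m.emission[:] = 0.5
        seq = generate_stimulus(m, 1000, seed=4)
        post = order_posterior(count_contexts(seq, 4), self.spec(gamma=1.0), 4)
        assert post.map_order == 0


class TestPredictiveArgmax:
    def test_substitution(self):
        counts = count_contexts(SymbolSequence.from_string("1101110"), 0)
        # order 0: n(1) = 5, n() = 7 on this string; use a direct case instead
        counts.n_context[0][0] = 5
        counts.n_context_symbol[0][0] = [2, 3]
        spec = ObserverSpec("ngram_argmax", alpha=2.0, beta=1.0, gamma=1.0)
        p = predictive_argmax(counts, spec, 0, [], 1)
        assert p == pytest.approx(4 / 7, abs=1e-15)

    def test_no_data_uniform(self):
        counts = count_contexts(SymbolSequence([]), 1)
        spec = ObserverSpec("ngram_argmax", alpha=2.0, beta=1.0, gamma=1.0)
        assert predictive_argmax(counts, spec, 0, [], 1) == pytest.approx(0.5)
        spec1 = ObserverSpec("ngram_argmax", alpha=1.0, beta=1.0, gamma=1.0)
        assert predictive_argmax(counts, spec1, 0, [], 0) == pytest.approx(0.5)

    def test_empirical_mle_at_alpha_one(self):
        counts = count_contexts(SymbolSequence.from_string("11111"), 0)
        spec = ObserverSpec("ngram_argmax", alpha=1.0, beta=1.0, gamma=1.0)
        assert predictive_argmax(counts, spec, 0, [], 1) == pytest.approx(1.0)

    def test_normalization(self):
        counts = count_contexts(SymbolSequence.from_string("0110100110"), 2)
        spec = ObserverSpec("ngram_argmax", alpha=1.5, beta=0.7, gamma=0.3)
        for R, ctx in [(0, []), (1, [1]), (2, [1, 0])]:
            total = sum(predictive_argmax(counts, spec, R, ctx, s) for s in (0, 1))
            assert total == pytest.approx(1.0, abs=1e-10)


class TestPredictiveAverage:
    def test_hand_trace(self):
        """History '11', r_max 1, gamma = ln 2: mixture gives 13/18."""
        h = SymbolSequence.from_string("11")
        counts = count_contexts(h, 1)
        spec = ObserverSpec("ngram_average", alpha=1.0, beta=1.0, gamma=math.log(2))
        assert predictive_average(counts, spec, 1, h, 1) == pytest.approx(
            13 / 18, abs=1e-12
        )

    def test_no_data_uniform(self):
        h = SymbolSequence([])
        counts = count_contexts(h, 2)
        spec = ObserverSpec("ngram_average", alpha=0.8, beta=1.0, gamma=0.4)
        assert predictive_average(counts, spec, 0, h, 1) == pytest.approx(0.5)
        # beta = 0 wipes all counts: every order term is alpha/(2 alpha)
        h2 = SymbolSequence.from_string("0110")
        counts2 = count_contexts(h2, 2)
        spec0 = ObserverSpec("ngram_average", alpha=0.8, beta=0.0, gamma=0.4)
        assert predictive_average(counts2, spec0, 2, h2, 1) == pytest.approx(0.5)

    def test_history_shorter_than_r_max_rejected(self):
        h = SymbolSequence.from_string("1")
        counts = count_contexts(h, 3)
        spec = ObserverSpec("ngram_average", alpha=1.0, beta=1.0, gamma=0.4)
        with pytest.raises(ValueError, match="history"):
            predictive_average(counts, spec, 3, h, 1)

    def test_large_gamma_collapses_to_order0(self):
        h = SymbolSequence.from_string("110101")
        counts = count_contexts(h, 3)
        spec = ObserverSpec("ngram_average", alpha=1.0, beta=1.0, gamma=50.0)
        want = (1 + counts.n_sym(0, 0, 1)) / (2 + counts.n(0, 0))
        assert predictive_average(counts, spec, 3, h, 1) == pytest.approx(
            want, abs=1e-12
        )

    def test_normalization(self):
        h = SymbolSequence.from_string("0110100")
        counts = count_contexts(h, 3)
        spec = ObserverSpec("ngram_average", alpha=1.3, beta=0.5, gamma=0.2)
        total = sum(predictive_average(counts, spec, 3, h, s) for s in (0, 1))
        assert total == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("alpha,beta", [(1.0, 1.0), (2.0, 0.5)])
    def test_per_order_terms_match_quadrature(self, alpha, beta):
        """Each order term is the posterior-mean estimate (integral oracle)."""
        for code in range(2 ** 5):
            bits = [(code >> i) & 1 for i in range(5)]
            h = SymbolSequence(bits)
            counts = count_contexts(h, 1)
            for R in (0, 1):
                spec = ObserverSpec(
                    "ngram_average", alpha=alpha, beta=beta, gamma=50.0 if R == 0 else 0.0
                )
                # gamma=50 isolates R=0; for R=1 compare the flat two-term
                # mixture against the mixture of quadrature means
                codes = [0, int("".join(map(str, bits[-1:])), 2)]
                if R == 0:
                    want = quad_posterior_mean(
                        counts.n_sym(0, 0, 1), counts.n_sym(0, 0, 0), alpha, beta
                    )
                    got = predictive_average(counts, spec, 1, h, 1)
                    assert got == pytest.approx(want, abs=1e-8)
                else:
                    c1 = codes[1]
                    want = 0.5 * quad_posterior_mean(
                        counts.n_sym(0, 0, 1), counts.n_sym(0, 0, 0), alpha, beta
                    ) + 0.5 * quad_posterior_mean(
                        counts.n_sym(1, c1, 1), counts.n_sym(1, c1, 0), alpha, beta
                    )
                    got = predictive_average(counts, spec, 1, h, 1)
                    assert got == pytest.approx(want, abs=1e-8)


class TestAsymptoticMapOrder:
    def test_no_data_prior_wins(self):
        curve = EntropyCurve({0: math.log(2), 1: 0.1, 2: 0.05})
        assert asymptotic_map_order(1.0, 1.0, 0, curve, 2) == 0

    def test_flat_entropy_no_gain(self):
        curve = EntropyCurve({R: 0.4 for R in range(4)})
        for t in (0, 100, 10_000):
            assert asymptotic_map_order(1.0, 1.0, t, curve, 3) == 0

    def test_crossing_point(self):
        """R* flips 0 -> 1 when t (h(0)-h(1)) exceeds the penalty increase.

        For alpha = 1 the log-Gamma term vanishes, so score(1) - score(0)
        = -gamma (|A|-1)(|A|-1) + t (h(0) - h(1)) crosses zero at
        t* = gamma / (h(0) - h(1)).
        """
        gamma = 5.0
        h0, h1 = math.log(2), 0.1
        curve = EntropyCurve({0: h0, 1: h1})
        t_cross = gamma / (h0 - h1)  # ~8.4
        assert asymptotic_map_order(1.0, gamma, int(t_cross) - 2, curve, 1) == 0
        assert asymptotic_map_order(1.0, gamma, int(t_cross) + 2, curve, 1) == 1

    def test_agrees_with_exact_posterior_on_order1_stimulus(self):
        from obsinfer.stimuli import count_contexts, entropy_curve

        model = sample_markov_model(1, seed=5, min_order_gap=0.1)
        curve = entropy_curve(model, 4)
        spec = ObserverSpec("ngram_average", alpha=1.0, beta=1.0, gamma=0.1)
        for t in (1000, 10_000):
            seq = generate_stimulus(model, t, seed=21)
            post = order_posterior(count_contexts(seq, 4), spec, 4)
            approx = asymptotic_map_order(1.0, 0.1, t, curve, 4)
            assert post.map_order == approx == 1


class TestObserverSpecValidation:
    def test_glm_requires_window(self):
        with pytest.raises(ValueError):
            ObserverSpec("glm")

    def test_ngram_requires_parameters(self):
        with pytest.raises(ValueError):
            ObserverSpec("ngram_average", alpha=1.0)

    def test_argmax_alpha_below_one_rejected(self):
        with pytest.raises(ValueError):
            ObserverSpec("ngram_argmax", alpha=0.5, beta=1.0, gamma=1.0)

    def test_beta_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            ObserverSpec("ngram_average", alpha=1.0, beta=1.5, gamma=1.0)
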