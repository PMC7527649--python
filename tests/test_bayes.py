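"""Posterior formulas, the beta derivative, inversion, and MLE recovery."""

from decimal import Decimal, getcontext

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from confbayes.bayes import (
    BetaWeightEstimator,
    NonIdentifiableError,
    OutOfModelRangeError,
    PosteriorQuery,
    bne_posterior,
    estimate_beta_mle,
    invert_beta,
    posterior_beta_derivative,
    weighted_posterior,
)
from confbayes.simulate import npi_to_nm


def decimal_weighted_posterior(p_c: str, n: int, m: int, beta: str) -> float:
    """Independent high-precision evaluation of the weighted-posterior formula.

    Works directly from the algebraic form (no log-space tricks), with
    60-digit Decimal arithmetic; exponentiation via exp(b * ln(x)).
    """
    getcontext().prec = 60
    p = Decimal(p_c)
    q = 1 - p
    b = Decimal(beta)

    def power(x: Decimal, e: Decimal) -> Decimal:
        return (e * x.ln()).exp()

    num = power(p, Decimal(m)) * power(q, b) * power(q, Decimal(n - 1))
    den = num + power(p, b) * power(p, Decimal(n - 1)) * power(q, Decimal(m))
    return float(num / den)


class TestBnePosterior:
    @pytest.mark.parametrize(
        "p_c, n, m, expected",
        [
            (0.5524, 1, 3, 0.604),  # all three peers against the subject
            (0.5524, 2, 2, 0.500),  # one peer with, two against
        ],
    )
    def test_reported_values(self, p_c, n, m, expected):
        assert round(bne_posterior(p_c, n, m), 3) == expected

    @pytest.mark.parametrize("n,m", [(1, 1), (2, 2), (5, 5)])
    @pytest.mark.parametrize("p_c", [0.1, 0.5, 0.9])
    def test_symmetric_counts_give_half(self, p_c, n, m):
        assert bne_posterior(p_c, n, m) == pytest.approx(0.5)

    def test_uninformative_observer_gives_half(self):
        assert bne_posterior(0.5, 1, 3) == pytest.approx(0.5)

    def test_stable_at_extreme_p_c(self):
        # log-space evaluation: no overflow/underflow to nan, tiny tail
        # probabilities stay strictly positive
        v = bne_posterior(1e-12, 1, 3)
        assert 0.0 < v < 1.0
        v = bne_posterior(1 - 1e-12, 1, 3)
        assert np.isfinite(v) and 0.0 < v <= 1.0

    @pytest.mark.parametrize("bad_pc", [0.0, 1.0, -0.2, 1.5])
    def test_rejects_pc_outside_open_interval(self, bad_pc):
        with pytest.raises(ValueError):
            bne_posterior(bad_pc, 1, 3)

    @pytest.mark.parametrize("n,m", [(0, 3), (1, 0), (1.5, 3), (-1, 2)])
    def test_rejects_bad_counts(self, n, m):
        with pytest.raises(ValueError):
            bne_posterior(0.6, n, m)


class TestWeightedPosterior:
    def test_reduces_to_bne_at_unit_beta(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p_c = rng.uniform(0.01, 0.99)
            n = int(rng.integers(1, 6))
            m = int(rng.integers(1, 6))
            assert weighted_posterior(p_c, n, m, 1.0) == bne_posterior(p_c, n, m)

    def test_against_high_precision_oracle(self):
        got = weighted_posterior(0.5524, 1, 3, 2.0)
        want = decimal_weighted_posterior("0.5524", 1, 3, "2")
        assert got == pytest.approx(want, rel=1e-12)
        # at beta = m - n + 1 the formula collapses to p_c exactly
        assert got == pytest.approx(0.5524, rel=1e-12)

    @pytest.mark.parametrize("beta", ["0.3", "0.7", "1.4", "3.25"])
    @pytest.mark.parametrize("n,m", [(1, 3), (2, 2), (3, 1)])
    def test_oracle_grid(self, beta, n, m):
        got = weighted_posterior(0.5524, n, m, float(beta))
        want = decimal_weighted_posterior("0.5524", n, m, beta)
        assert got == pytest.approx(want, rel=1e-12)

    @given(
        p_c=st.floats(0.501, 0.99),
        n=st.integers(1, 4),
        m=st.integers(1, 4),
        beta=st.floats(0.05, 5.0),
        dbeta=st.floats(0.01, 2.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_strictly_decreasing_in_beta_above_half(self, p_c, n, m, beta, dbeta):
        assert weighted_posterior(p_c, n, m, beta + dbeta) < weighted_posterior(
            p_c, n, m, beta
        )

    def test_large_beta_limit_vanishes(self):
        assert weighted_posterior(0.5524, 1, 3, 200.0) < 1e-15

    def test_rejects_nonpositive_beta(self):
        with pytest.raises(ValueError):
            weighted_posterior(0.6, 1, 3, 0.0)


class TestBetaDerivative:
    @given(
        p_c=st.floats(0.05, 0.95),
        n=st.integers(1, 4),
        m=st.integers(1, 4),
        beta=st.floats(0.1, 4.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_central_finite_difference(self, p_c, n, m, beta):
        # Richardson-extrapolated central difference: a large enough step
        # to avoid cancellation in saturated posteriors, with the O(h^2)
        # truncation term eliminated
        h = 1e-3 * max(1.0, beta)

        def central(step):
            return (
                weighted_posterior(p_c, n, m, beta + step)
                - weighted_posterior(p_c, n, m, beta - step)
            ) / (2 * step)

        fd = (4 * central(h / 2) - central(h)) / 3
        closed = posterior_beta_derivative(p_c, n, m, beta)
        assert closed == pytest.approx(fd, rel=1e-6, abs=1e-10)

    def test_negative_above_half_and_zero_at_half(self):
        assert posterior_beta_derivative(0.5524, 1, 3, 1.0) < 0
        assert posterior_beta_derivative(0.5, 1, 3, 1.0) == pytest.approx(0.0)


class TestInvertBeta:
    def test_recovers_unit_beta_at_bne_value(self):
        bne = bne_posterior(0.5524, 1, 3)
        assert invert_beta(bne, 0.5524, 1, 3) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("beta", [0.25, 0.5, 1.0, 2.0, 4.0])
    @pytest.mark.parametrize("n,m", [(1, 3), (2, 2)])
    def test_roundtrip_identity(self, beta, n, m):
        target = weighted_posterior(0.5524, n, m, beta)
        assert invert_beta(target, 0.5524, n, m) == pytest.approx(beta, abs=1e-6)

    def test_below_bne_observation_gives_beta_above_one(self):
        # sham-like: observed conformity below the equal-weight posterior
        assert invert_beta(0.562, 0.5524, 1, 3) > 1.0

    def test_observation_above_model_supremum_is_out_of_range(self):
        # the probability-matching policy caps conformity at the beta -> 0
        # limit p^3 / (p^3 + (1-p)^3) ~ 0.653 for p_c = 0.5524
        with pytest.raises(OutOfModelRangeError):
            invert_beta(0.711, 0.5524, 1, 3)

    def test_rejects_pc_at_or_below_half(self):
        with pytest.raises(ValueError, match="identifiab"):
            invert_beta(0.6, 0.5, 1, 3)


class TestBetaWeightEstimator:
    @staticmethod
    def simulate_trials(beta, p_c, n_trials, seed):
        rng = np.random.default_rng(seed)
        nm = [npi_to_nm(l) for l in rng.choice([-3, -1], size=n_trials)]
        X = np.array(nm, dtype=float)
        p = np.array([weighted_posterior(p_c, int(a), int(b), beta) for a, b in nm])
        y = (rng.random(n_trials) < p).astype(int)
        return X, y

    def test_recovery_at_generating_beta(self):
        X, y = self.simulate_trials(1.5, 0.5524, 1200, seed=42)
        est = BetaWeightEstimator(p_c=0.5524).fit(X, y)
        assert est.beta_ == pytest.approx(1.5, abs=0.3)
        assert est.se_ > 0
        assert not est.on_boundary_

    def test_consistency_bias_shrinks_with_n(self):
        errs = []
        for n_trials in (400, 4000, 40000):
            X, y = self.simulate_trials(1.0, 0.5524, n_trials, seed=5)
            est = BetaWeightEstimator(p_c=0.5524).fit(X, y)
            errs.append(abs(est.beta_ - 1.0))
        assert errs[-1] < errs[0]
        assert errs[-1] < 0.1

    def test_degenerate_outcomes_non_identifiable(self):
        X = np.array([[1, 3]] * 10, dtype=float)
        with pytest.raises(NonIdentifiableError):
            BetaWeightEstimator(p_c=0.5524).fit(X, np.ones(10))
        with pytest.raises(NonIdentifiableError):
            estimate_beta_mle([(1, 3, 1)], p_c=0.5524)

    def test_predict_proba_matches_posterior(self):
        X, y = self.simulate_trials(1.5, 0.5524, 400, seed=1)
        est = BetaWeightEstimator(p_c=0.5524).fit(X, y)
        proba = est.predict_proba(np.array([[1, 3], [2, 2]]))
        assert proba.shape == (2, 2)
        assert proba[0, 1] == pytest.approx(
            weighted_posterior(0.5524, 1, 3, est.beta_)
        )
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_sklearn_protocol(self):
        est = BetaWeightEstimator(p_c=0.6)
        assert est.get_params()["p_c"] == 0.6
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        X, y = self.simulate_trials(1.0, 0.6, 200, seed=2)
        assert cloned.set_params(p_c=0.5524).fit(X, y) is cloned


def test_posterior_query_validation():
    q = PosteriorQuery(p_c=0.5524, n=1, m=3)
    assert q.beta is None
    with pytest.raises(ValueError):
        PosteriorQuery(p_c=1.2, n=1, m=3)
    with pytest.raises(ValueError):
        PosteriorQuery(p_c=0.6, n=0, m=3)
    with pytest.raises(ValueError):
        PosteriorQuery(p_c=0.6, n=1, m=3, beta=-1.0)
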