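"""Bayesian observer models of informational social conformity.

The core quantity is the posterior probability that following the peer
majority is correct after a 2AFC perceptual judgment, given ``n`` group
members (including oneself) who chose one option and ``m`` who chose the
other, each treated as an unbiased observer with perceived correct rate
``p_c``:

    p(correct | n, m) = p_c^m (1-p_c)^n / [p_c^m (1-p_c)^n + (1-p_c)^m p_c^n]

This is the Bayesian Nash Equilibrium (BNE) benchmark: every signal gets
equal weight.  Real decision-makers may over- or under-weight their own
(private) signal relative to the peers' (social) signals; the weighted
model raises the private-signal likelihood terms to a power ``beta``:

    p_beta(correct | n, m) =
        p_c^m (1-p_c)^beta (1-p_c)^(n-1)
        / [p_c^m (1-p_c)^beta (1-p_c)^(n-1) + p_c^beta p_c^(n-1) (1-p_c)^m]

``beta = 1`` recovers the BNE; ``beta > 1`` overweights private
information (less conformity), ``beta < 1`` overweights social
information (more conformity).  For ``0.5 < p_c < 1`` the posterior is
strictly decreasing in ``beta``, which makes ``beta`` identifiable from
observed conformity rates.

All expressions are evaluated in log-space for numerical stability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PosteriorQuery",
    "bne_posterior",
    "weighted_posterior",
    "posterior_beta_derivative",
    "invert_beta",
    "BetaWeightEstimator",
    "estimate_beta_mle",
    "NonIdentifiableError",
    "OutOfModelRangeError",
]


class NonIdentifiableError(ValueError):
    """Raised when the data cannot pin down beta (e.g. all-conform outcomes)."""


class OutOfModelRangeError(ValueError):
    """Raised when an observed conformity rate lies outside the model's range."""


@dataclass(frozen=True)
class PosteriorQuery:
    """A single posterior evaluation point.

    Parameters
    ----------
    p_c : float
        Perceived (subjective) correct rate of a single observer, in (0, 1).
    n : int
        Number of group members who chose the same option as the decision
        maker, *including* the decision maker; >= 1.
    m : int
        Number of group members who chose the other option; >= 1.
    beta : float, optional
        Private-information weight, > 0.  ``None`` means the equal-weight
        BNE model.
    """

    p_c: float
    n: int
    m: int
    beta: Optional[float] = None

    def __post_init__(self) -> None:
        _validate_pc(self.p_c)
        _validate_counts(self.n, self.m)
        if self.beta is not None and not self.beta > 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")


def _validate_pc(p_c: float) -> None:
    p_c = float(p_c)
    if not (0.0 < p_c < 1.0):
        raise ValueError(f"p_c must lie in the open interval (0, 1), got {p_c}")


def _validate_counts(n: int, m: int) -> None:
    for name, value in (("n", n), ("m", m)):
        if int(value) != value or value < 1:
            raise ValueError(f"{name} must be a positive integer, got {value!r}")


def bne_posterior(p_c: float, n: int, m: int) -> float:
    """Equal-weight (BNE) posterior that following the majority is correct.

    Evaluated in log-space as a logistic function of the log-likelihood
    difference: ``p = expit((n - m) * [log(1-p_c) - log(p_c)])``.

    Examples
    --------
    >>> round(bne_posterior(0.5524, 1, 3), 3)
    0.604
    >>> bne_posterior(0.5524, 2, 2)
    0.5
    """
    _validate_pc(p_c)
    _validate_counts(n, m)
    return weighted_posterior(p_c, n, m, beta=1.0)


def weighted_posterior(p_c: float, n: int, m: int, beta: float) -> float:
    """Posterior with private-information weight ``beta``.

    Reduces exactly to :func:`bne_posterior` at ``beta = 1``.
    """
    _validate_pc(p_c)
    _validate_counts(n, m)
    beta = float(beta)
    if not beta > 0:
        raise ValueError(f"beta must be > 0, got {beta}")
    lp = np.log(p_c)
    lq = np.log1p(-p_c)
    # log numerator  = m*lp + (beta + n - 1)*lq
    # log other term = (beta + n - 1)*lp + m*lq
    # posterior = 1 / (1 + exp(log other - log numerator))
    delta = (beta + n - 1 - m) * (lp - lq)
    return float(expit(-delta))


def posterior_beta_derivative(p_c: float, n: int, m: int, beta: float) -> float:
    """Closed-form derivative of :func:`weighted_posterior` with respect to beta.

        d p_beta / d beta = [ln(1-p_c) - ln p_c]
            * (1-p_c)^(beta+m+n-1) * p_c^(beta+m+n-1)
            / [p_c^m (1-p_c)^(beta+n-1) + p_c^(beta+n-1) (1-p_c)^m]^2

    Strictly negative for 0.5 < p_c < 1, zero at p_c = 0.5.
    """
    _validate_pc(p_c)
    _validate_counts(n, m)
    beta = float(beta)
    if not beta > 0:
        raise ValueError(f"beta must be > 0, got {beta}")
    lp = np.log(p_c)
    lq = np.log1p(-p_c)
    log_num = (beta + m + n - 1) * (lq + lp)
    log_a = m * lp + (beta + n - 1) * lq
    log_b = (beta + n - 1) * lp + m * lq
    log_den = 2.0 * np.logaddexp(log_a, log_b)
    return float((lq - lp) * np.exp(log_num - log_den))


# beta is searched on a log grid; this bracket spans conformity rates far
# beyond anything a behavioral experiment produces.
_LOG_BETA_LO = -12.0
_LOG_BETA_HI = 12.0


def invert_beta(
    observed_conformity: float,
    p_c: float,
    n: int,
    m: int,
    *,
    tol: float = 1e-8,
) -> float:
    """Find the beta whose weighted posterior equals an observed conformity rate.

    Uniqueness follows from strict monotonicity of the posterior in beta
    when ``p_c > 0.5``.  Uses bracketed root-finding (Brent) on log(beta),
    to absolute tolerance ``tol`` in beta.

    Raises
    ------
    OutOfModelRangeError
        If ``observed_conformity`` lies outside the posterior's range over
        the search bracket.
    ValueError
        If ``p_c <= 0.5`` (the posterior is flat or increasing in beta, so
        beta is not identifiable from a conformity rate).
    """
    _validate_pc(p_c)
    if p_c <= 0.5:
        raise ValueError(
            f"invert_beta requires p_c > 0.5 (got {p_c}): at p_c <= 0.5 the "
            "posterior is non-decreasing in beta and beta is not identifiable"
        )
    _validate_counts(n, m)
    observed_conformity = float(observed_conformity)
    if not (0.0 < observed_conformity < 1.0):
        raise ValueError(
            f"observed_conformity must lie in (0, 1), got {observed_conformity}"
        )
    hi_val = weighted_posterior(p_c, n, m, np.exp(_LOG_BETA_LO))  # beta -> 0 limit
    lo_val = weighted_posterior(p_c, n, m, np.exp(_LOG_BETA_HI))  # beta -> inf limit
    if not (lo_val <= observed_conformity <= hi_val):
        raise OutOfModelRangeError(
            f"observed conformity {observed_conformity:.6f} is outside the "
            f"model range [{lo_val:.6f}, {hi_val:.6f}] at p_c={p_c}, n={n}, m={m}"
        )

    def f(log_beta: float) -> float:
        return weighted_posterior(p_c, n, m, np.exp(log_beta)) - observed_conformity

    # xtol on log(beta) translates to a relative tolerance on beta; tighten
    # enough that the absolute beta tolerance holds across the bracket.
    log_beta = brentq(f, _LOG_BETA_LO, _LOG_BETA_HI, xtol=min(tol, 1e-12), rtol=8.9e-16)
    return float(np.exp(log_beta))


def _loglik(log_beta: float, p_c: float, nm: np.ndarray, counts: np.ndarray) -> float:
    """Bernoulli log-likelihood of conform/non-conform counts per (n, m) cell."""
    beta = np.exp(log_beta)
    total = 0.0
    for (n, m), (k_conf, k_non) in zip(nm, counts):
        p = weighted_posterior(p_c, int(n), int(m), beta)
        p = min(max(p, 1e-300), 1 - 1e-16)
        total += k_conf * np.log(p) + k_non * np.log1p(-p)
    return total


class BetaWeightEstimator(BaseEstimator):
    """Maximum-likelihood estimator of the private-information weight beta.

    Treats each incongruent trial as an independent Bernoulli draw whose
    success probability is the weighted posterior at that trial's (n, m)
    configuration (probability matching: the conform probability *is* the
    posterior, with no extra decision noise).  Maximizes the Bernoulli
    log-likelihood over ``log(beta)`` within ``log_beta_bounds`` and
    reports a curvature-based standard error.

    Parameters
    ----------
    p_c : float
        Perceived correct rate used in the posterior; must be in (0.5, 1)
        for beta to be identifiable.
    log_beta_bounds : tuple of float
        Search interval for log(beta).

    Attributes
    ----------
    beta_ : float
        Point estimate.
    se_ : float
        Standard error from the observed information (numerical second
        derivative of the log-likelihood at the optimum); ``nan`` when the
        curvature is not usable (e.g. boundary solutions).
    log_likelihood_ : float
        Log-likelihood at the optimum.
    on_boundary_ : bool
        True when the optimum sits on the search boundary; the estimate
        should then be read as a one-sided bound.
    n_trials_ : int
        Number of trials used in the fit.
    """

    def __init__(self, p_c: float = 0.5524, log_beta_bounds: tuple = (-5.0, 5.0)):
        self.p_c = p_c
        self.log_beta_bounds = log_beta_bounds

    def fit(self, X, y):
        """Fit beta from incongruent trials.

        Parameters
        ----------
        X : array-like of shape (n_trials, 2)
            Columns ``(n, m)``: agreeing count (incl. self) and disagreeing
            count for each trial.
        y : array-like of shape (n_trials,)
            1 if the trial's second response conformed to the peer
            majority, 0 otherwise.
        """
        _validate_pc(self.p_c)
        if self.p_c <= 0.5:
            raise ValueError("p_c must exceed 0.5 for beta to be identifiable")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have shape (n_trials, 2) with columns (n, m)")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        if X.shape[0] < 2:
            raise NonIdentifiableError(
                "at least two trials are required to estimate beta"
            )
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("y must be binary 0/1 conform indicators")
        if y.min() == y.max():
            raise NonIdentifiableError(
                "all trials have the same outcome "
                f"(all {'conform' if y[0] else 'non-conform'}); beta is not "
                "identifiable from a degenerate Bernoulli sample"
            )
        for n, m in np.unique(X, axis=0):
            _validate_counts(int(n), int(m))

        # collapse to sufficient statistics per (n, m) cell
        nm, inverse = np.unique(X.astype(int), axis=0, return_inverse=True)
        k_conf = np.bincount(inverse, weights=y, minlength=len(nm))
        k_non = np.bincount(inverse, weights=1 - y, minlength=len(nm))
        counts = np.column_stack([k_conf, k_non])
        p_c = float(self.p_c)

        lo, hi = self.log_beta_bounds
        res = minimize_scalar(
            lambda lb: -_loglik(lb, p_c, nm, counts),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        log_beta = float(res.x)
        self.on_boundary_ = bool(
            log_beta - lo < 1e-6 * (hi - lo) or hi - log_beta < 1e-6 * (hi - lo)
        )
        self.beta_ = float(np.exp(log_beta))
        self.log_likelihood_ = float(-res.fun)
        self.n_trials_ = int(X.shape[0])

        # observed information on the beta scale via central differences
        h = 1e-4 * max(1.0, self.beta_)

        def ll_beta(b: float) -> float:
            return _loglik(np.log(b), p_c, nm, counts)

        d2 = (ll_beta(self.beta_ + h) - 2 * self.log_likelihood_ + ll_beta(self.beta_ - h)) / h**2
        self.se_ = float(1.0 / np.sqrt(-d2)) if d2 < 0 else float("nan")
        return self

    def predict_proba(self, X):
        """Conform probability for each (n, m) row under the fitted beta."""
        check_is_fitted(self, "beta_")
        X = np.asarray(X, dtype=float)
        p = np.array(
            [weighted_posterior(self.p_c, int(n), int(m), self.beta_) for n, m in X]
        )
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def estimate_beta_mle(
    trials: Sequence[tuple],
    p_c: float,
) -> tuple:
    """Fit beta from ``(n, m, conformed)`` triples; returns ``(beta, se)``.

    Thin functional wrapper around :class:`BetaWeightEstimator`.
    """
    arr = np.asarray(list(trials), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        if arr.shape[0] <= 1:
            raise NonIdentifiableError(
                "at least two trials are required to estimate beta"
            )
        raise ValueError("trials must be (n, m, conformed) triples")
    est = BetaWeightEstimator(p_c=p_c).fit(arr[:, :2], arr[:, 2])
    return est.beta_, est.se_
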