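"""Analytic theory of the at-least-one vote-count score.

With per-effect power delta for the one-sided positive correlation test,
the probability a paper-measure group of k independent effects earns the
maximum score is 1 - (1 - delta)^k — the same algebra as familywise Type I
error.  The expected score is the weighted version

    E[score] = [1 - (1 - d05)^k] + 0.5 * [(1 - d05)^k - (1 - d10)^k]

with d05 and d10 the powers at the significance and marginal levels.  Both
quantities increase monotonically in k for any true effect, including
rho <= 0, which is the sense in which the score carries no evidential
value about effect size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import quad
from scipy.special import gamma as _gamma
from scipy.special import hyp2f1

from .effects import EffectTableError
from .filtering import MARGINAL, SIGNIFICANT, FilterPolicy, classify_effects, critical_r
from .sampling import sample_correlations

__all__ = [
    "PowerSpec",
    "ScoreCurve",
    "power_one_sided_r",
    "prob_at_least_one",
    "prob_none",
    "expected_predictiveness_score",
    "monte_carlo_expected_score",
    "score_curve",
    "POWER_METHODS",
]

POWER_METHODS = ("fisher_z", "noncentral_t", "exact", "monte_carlo")


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a one-sided correlation power calculation."""

    rho: float
    n: int
    alpha: float = 0.05
    tail: str = "one_sided_positive"
    method: str = "noncentral_t"

    def __post_init__(self) -> None:
        if not (-1.0 < self.rho < 1.0):
            raise EffectTableError(f"rho={self.rho} outside (-1, 1)")
        if self.n < 4:
            raise EffectTableError("n must be >= 4")
        if not (0.0 < self.alpha < 1.0):
            raise EffectTableError("alpha outside (0, 1)")
        if self.method not in POWER_METHODS:
            raise EffectTableError(f"unknown power method {self.method!r}; choose from {POWER_METHODS}")


def _r_density(r: float, rho: float, n: int) -> float:
    # sampling density of the Pearson correlation under bivariate normality
    nu = n - 1
    c = (nu - 1) * _gamma(nu) / (np.sqrt(2 * np.pi) * _gamma(nu + 0.5))
    return (
        c
        * (1 - rho**2) ** (nu / 2)
        * (1 - r**2) ** ((nu - 3) / 2)
        * (1 - rho * r) ** (-nu + 0.5)
        * hyp2f1(0.5, 0.5, nu + 0.5, (1 + rho * r) / 2)
    )


def power_one_sided_r(
    rho: float,
    n: int,
    alpha: float = 0.05,
    method: str = "noncentral_t",
    n_reps: int = 1_000_000,
    seed: int | None = None,
) -> float:
    """Probability that a sample correlation clears the one-sided critical r.

    Methods: ``noncentral_t`` (default; t-statistic referred to a
    noncentral-t with noncentrality rho*sqrt(n)/sqrt(1-rho^2)), ``fisher_z``
    (normal approximation on the z scale), ``exact`` (numerical integration
    of the exact sampling density of r), ``monte_carlo`` (exact
    bivariate-normal simulation; the arbiter the approximations are tested
    against).  Conventions differ by 1-2 percentage points at small n;
    every method returns exactly alpha at rho = 0 (Monte Carlo within
    simulation error).
    """
    spec = PowerSpec(rho, n, alpha, method=method)
    rc = critical_r(n, alpha, "one_sided_positive")
    if method == "fisher_z":
        # z_hat ~ N(arctanh(rho), 1/(n-3)) against the normal critical value,
        # so the null returns alpha exactly
        return float(stats.norm.sf(stats.norm.ppf(1.0 - alpha) - np.arctanh(rho) * np.sqrt(n - 3.0)))
    if method == "noncentral_t":
        if rho == 0.0:
            return float(alpha)
        nc = rho * np.sqrt(n) / np.sqrt(1.0 - rho**2)
        tcrit = stats.t.ppf(1.0 - alpha, n - 2)
        return float(stats.nct.sf(tcrit, n - 2, nc))
    if method == "exact":
        val, _ = quad(_r_density, rc, 1.0, args=(rho, n), limit=200)
        return float(val)
    # monte_carlo
    rng = np.random.default_rng(seed)
    r = sample_correlations(spec.rho, spec.n, size=n_reps, rng=rng, method="exact")
    return float((r > rc).mean())


def prob_at_least_one(delta: float, k: int) -> float:
    """``1 - (1 - delta)^k``: at least one of k independent effects clears."""
    _check_delta_k(delta, k)
    return float(1.0 - (1.0 - delta) ** k)


def prob_none(delta: float, k: int) -> float:
    """``(1 - delta)^k``: exact complement of :func:`prob_at_least_one`."""
    _check_delta_k(delta, k)
    return float((1.0 - delta) ** k)


def _check_delta_k(delta: float, k: int) -> None:
    if not (0.0 <= delta <= 1.0):
        raise EffectTableError(f"delta={delta} outside [0, 1]")
    if int(k) != k or k < 1:
        raise EffectTableError(f"k={k} must be a positive integer")


def expected_predictiveness_score(
    rho: float,
    n: int,
    k: int,
    policy: FilterPolicy = FilterPolicy(),
    method: str = "noncentral_t",
) -> float:
    """Expected at-least-one score for k independent effects.

    Weighted at-least-one algebra with powers at the significance and
    marginal levels; under the null both powers equal their alphas exactly.
    Strictly increasing in k whenever the marginal power is positive.
    """
    _check_delta_k(0.0, k)
    d05 = power_one_sided_r(rho, n, policy.alpha_sig, method=method)
    d10 = power_one_sided_r(rho, n, policy.alpha_marginal, method=method)
    none05 = (1.0 - d05) ** k
    none10 = (1.0 - d10) ** k
    return float((1.0 - none05) + 0.5 * (none05 - none10))


def monte_carlo_expected_score(
    rho: float,
    n: int,
    k: int,
    policy: FilterPolicy = FilterPolicy(),
    n_groups: int = 100_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mean at-least-one score over simulated paper-groups, with its MC SE.

    Draws k exact sample correlations per group, classifies them with the
    same rules the filter applies to data, and averages the group scores —
    the simulation cross-check for :func:`expected_predictiveness_score`.
    """
    rng = np.random.default_rng(seed)
    r = sample_correlations(rho, n, size=n_groups * k, rng=rng, method="exact")
    cats = classify_effects(r, n, policy).reshape(n_groups, k)
    any_sig = (cats == SIGNIFICANT).any(axis=1)
    any_marg = (cats == MARGINAL).any(axis=1)
    scores = np.where(any_sig, 1.0, np.where(any_marg, 0.5, 0.0))
    return float(scores.mean()), float(scores.std(ddof=1) / np.sqrt(n_groups))


@dataclass
class ScoreCurve:
    """Per-k at-least-one probabilities and expected scores."""

    table: pd.DataFrame  # columns: k, p_any_sig, p_any_marginal, expected_score
    rho: float
    n: int
    method: str


def score_curve(
    rho: float,
    n: int,
    k_max: int,
    policy: FilterPolicy = FilterPolicy(),
    method: str = "noncentral_t",
) -> ScoreCurve:
    """At-least-one probabilities and expected score on the k-grid 1..k_max."""
    if k_max < 1:
        raise EffectTableError("k_max must be >= 1")
    d05 = power_one_sided_r(rho, n, policy.alpha_sig, method=method)
    d10 = power_one_sided_r(rho, n, policy.alpha_marginal, method=method)
    k = np.arange(1, k_max + 1)
    none05 = (1.0 - d05) ** k
    none10 = (1.0 - d10) ** k
    tab = pd.DataFrame(
        {
            "k": k,
            "p_any_sig": 1.0 - none05,
            "p_any_marginal": 1.0 - none10,
            "expected_score": (1.0 - none05) + 0.5 * (none05 - none10),
        }
    )
    return ScoreCurve(tab, rho, n, method)
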