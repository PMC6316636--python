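"""Analytic power for two-sample Mendelian randomization with a binary outcome.

The causal log-OR per exposure SD is estimated with approximate variance
1 / (N * R^2 * K * (1-K)), where N is the outcome-study sample size, K the
case fraction, and R^2 the share of exposure variance explained by the
instruments.  The two-sided test of a detectable odds ratio OR then has
noncentrality z* = sqrt(N * R^2 * K * (1-K)) * |ln OR| and power

    Phi(z* - z_{1-alpha/2}) + Phi(-z* - z_{1-alpha/2}).

An ``effect_scale="or_minus_1"`` variant replaces |ln OR| with |OR - 1|,
matching a common alternative parameterization; at OR near 1 the two agree
closely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .errors import BoundExceededError, ConfigurationError


@dataclass(frozen=True)
class PowerParams:
    """Inputs to the binary-outcome MR power formula."""

    n_total: float
    case_fraction: float
    r_squared: float
    or_detect: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.n_total > 0:
            raise ConfigurationError("n_total must be positive")
        if not 0.0 < self.case_fraction < 1.0:
            raise ConfigurationError("case_fraction must lie in (0, 1)")
        if not 0.0 < self.r_squared < 1.0:
            raise ConfigurationError("r_squared must lie in (0, 1)")
        if not self.or_detect > 0:
            raise ConfigurationError("or_detect must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")


def mr_power_binary(
    params: PowerParams,
    effect_scale: str = "log_or",
    allow_null: bool = False,
) -> float:
    """Power of the two-sided alpha-level MR test to detect ``or_detect``.

    ``or_detect = 1`` is a degenerate effect: an error unless ``allow_null``
    is set, in which case the size of the test (alpha) is returned.
    """
    if effect_scale not in ("log_or", "or_minus_1"):
        raise ConfigurationError(f"unknown effect_scale {effect_scale!r}")
    if params.or_detect == 1.0:
        if allow_null:
            return params.alpha
        raise ConfigurationError("or_detect = 1 gives no effect to detect (pass allow_null=True)")
    effect = (
        abs(math.log(params.or_detect))
        if effect_scale == "log_or"
        else abs(params.or_detect - 1.0)
    )
    k = params.case_fraction
    ncp = math.sqrt(params.n_total * params.r_squared * k * (1.0 - k)) * effect
    z_crit = stats.norm.ppf(1.0 - params.alpha / 2.0)
    return float(stats.norm.cdf(ncp - z_crit) + stats.norm.cdf(-ncp - z_crit))


_OR_UPPER = 10.0


def min_detectable_or(
    n_total: float,
    case_fraction: float,
    r_squared: float,
    alpha: float = 0.05,
    target_power: float = 0.8,
    effect_scale: str = "log_or",
    tol: float = 1e-8,
) -> float:
    """Smallest odds ratio above 1 detectable with at least ``target_power``.

    Monotone bisection on ln(OR) over (0, ln 10] to ``tol``; raises
    :class:`BoundExceededError` when even OR = 10 is underpowered.
    """
    if not alpha < target_power < 1.0:
        raise ConfigurationError("target_power must lie in (alpha, 1)")

    def power_at(log_or: float) -> float:
        return mr_power_binary(
            PowerParams(n_total, case_fraction, r_squared, math.exp(log_or), alpha),
            effect_scale=effect_scale,
        )

    hi = math.log(_OR_UPPER)
    if power_at(hi) < target_power:
        raise BoundExceededError(
            f"target power {target_power} unreachable below OR = {_OR_UPPER}"
        )
    lo = 0.0  # power -> alpha < target as log_or -> 0+
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return math.exp(hi)
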