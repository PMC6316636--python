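"""Two-sample Mendelian randomization estimators on harmonized instruments.

Implements the per-SNP Wald ratio, inverse-variance weighted (IVW) pooling
(fixed effect or multiplicative random effect), the weighted median
estimator with a parametric-bootstrap standard error, MR-Egger regression,
and Cochran's Q / I-squared heterogeneity.  All estimators operate on the
oriented-exposure scale produced by :mod:`mrkit.summary_data`; rescaling to
odds ratios per SD is the job of :mod:`mrkit.reporting`.

Notation: for SNP j, theta_j = beta_outcome_j / beta_exposure_j is the ratio
estimate of the causal log-OR per unit oriented exposure, with first-order
standard error se_outcome_j / |beta_exposure_j| and inverse-variance weight
w_j = 1 / se(theta_j)^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import (
    ConfigurationError,
    InsufficientInstrumentsError,
    OrientationError,
    UndefinedRatioError,
    ValidationError,
)
from .summary_data import HarmonizedInstrument

#: normal 97.5th percentile used for every 95% confidence bound
Z95 = 1.959964

DEFAULT_N_BOOT = 10_000
DEFAULT_SEED = 20181987


@dataclass(frozen=True)
class RatioEstimate:
    """Per-SNP Wald ratio with first-order SE and inverse-variance weight."""

    rsid: str
    theta: float
    se_theta: float
    weight: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not self.se_theta > 0:
            raise ValidationError(f"{self.rsid}: se_theta must be > 0")
        object.__setattr__(self, "weight", self.se_theta ** -2)


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its degrees of freedom, I^2 (%) and upper-tail p."""

    q: float
    df: int
    i_squared: float
    pvalue: float


@dataclass(frozen=True)
class MrEstimate:
    """A pooled causal estimate (log-OR per unit oriented exposure)."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    heterogeneity: HeterogeneityResult | None = None


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger slope (pleiotropy-adjusted effect) and pleiotropy intercept."""

    slope: MrEstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float


def wald_ratio(instrument: HarmonizedInstrument) -> RatioEstimate:
    """Per-SNP causal estimate: outcome beta over exposure beta.

    The standard error is first order (delta method holding the exposure
    beta fixed): se_outcome / |beta_exposure|.  Standard two-sample
    practice; exposure-side sampling noise is ignored.
    """
    if instrument.beta_exposure == 0:
        raise UndefinedRatioError(f"{instrument.rsid}: beta_exposure is zero, Wald ratio undefined")
    theta = instrument.beta_outcome / instrument.beta_exposure
    se_theta = instrument.se_outcome / abs(instrument.beta_exposure)
    return RatioEstimate(rsid=instrument.rsid, theta=theta, se_theta=se_theta)


def wald_ratios(instruments: Sequence[HarmonizedInstrument]) -> list[RatioEstimate]:
    """Wald ratio for every instrument, in input order."""
    return [wald_ratio(inst) for inst in instruments]


def _as_arrays(ratios: Sequence[RatioEstimate]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    theta = np.array([r.theta for r in ratios], dtype=float)
    se = np.array([r.se_theta for r in ratios], dtype=float)
    w = np.array([r.weight for r in ratios], dtype=float)
    if np.any(w <= 0):
        raise ValidationError("all inverse-variance weights must be positive")
    return theta, se, w


def _normal_estimate(method: str, estimate: float, se: float, n_snps: int,
                     heterogeneity: HeterogeneityResult | None = None) -> MrEstimate:
    p = 2.0 * stats.norm.sf(abs(estimate) / se)
    return MrEstimate(
        method=method,
        estimate=estimate,
        se=se,
        ci_low=estimate - Z95 * se,
        ci_high=estimate + Z95 * se,
        pvalue=float(p),
        n_snps=n_snps,
        heterogeneity=heterogeneity,
    )


def cochran_q(ratios: Sequence[RatioEstimate], pooled: float) -> HeterogeneityResult:
    """Cochran's Q of the ratio estimates about a pooled value, with I^2.

    Q = sum_j w_j (theta_j - pooled)^2 on n-1 degrees of freedom;
    I^2 = max(0, (Q - df) / Q) * 100.
    """
    if len(ratios) < 2:
        raise InsufficientInstrumentsError("heterogeneity needs at least 2 instruments")
    theta, _, w = _as_arrays(ratios)
    q = float(np.sum(w * (theta - pooled) ** 2))
    df = len(ratios) - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    pvalue = float(stats.chi2.sf(q, df))
    return HeterogeneityResult(q=q, df=df, i_squared=i2, pvalue=pvalue)


def ivw(ratios: Sequence[RatioEstimate], model: str = "fixed") -> MrEstimate:
    """Inverse-variance weighted combination of Wald ratios.

    ``model="fixed"`` gives se = (sum w_j)^(-1/2); ``"multiplicative"``
    inflates it by sqrt(Q/df) floored at 1, the multiplicative
    random-effects model.  Cochran's Q about the pooled estimate is attached
    to the result.
    """
    if model not in ("fixed", "multiplicative"):
        raise ConfigurationError(f"unknown IVW model {model!r}")
    if len(ratios) < 2:
        raise InsufficientInstrumentsError("IVW needs at least 2 instruments")
    theta, _, w = _as_arrays(ratios)
    estimate = float(np.sum(w * theta) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    het = cochran_q(ratios, estimate)
    if model == "multiplicative":
        se *= max(1.0, np.sqrt(het.q / het.df))
    method = "ivw_fixed" if model == "fixed" else "ivw_mre"
    return _normal_estimate(method, estimate, se, len(ratios), het)


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Interpolated weighted median along the last axis.

    Sorts theta, forms midpoint cumulative weight fractions
    p_k = cumsum(w')_k - w'_k / 2 with normalized weights, and linearly
    interpolates theta at p = 0.5; outside [p_1, p_n] the boundary value is
    returned.  Works on 1-D and 2-D (replicates x SNPs) input.
    """
    theta = np.atleast_2d(theta)
    w = np.broadcast_to(w, theta.shape)
    order = np.argsort(theta, axis=-1, kind="stable")
    t = np.take_along_axis(theta, order, axis=-1)
    ws = np.take_along_axis(w, order, axis=-1)
    wn = ws / ws.sum(axis=-1, keepdims=True)
    p = np.cumsum(wn, axis=-1) - wn / 2.0
    # index of the first midpoint fraction >= 0.5, clipped for interpolation
    hi = np.sum(p < 0.5, axis=-1)
    n = theta.shape[-1]
    below = hi == 0
    above = hi == n
    hi = np.clip(hi, 1, n - 1)
    lo = hi - 1
    rows = np.arange(theta.shape[0])
    p_lo, p_hi = p[rows, lo], p[rows, hi]
    t_lo, t_hi = t[rows, lo], t[rows, hi]
    frac = np.where(p_hi > p_lo, (0.5 - p_lo) / np.where(p_hi > p_lo, p_hi - p_lo, 1.0), 0.0)
    out = t_lo + frac * (t_hi - t_lo)
    out = np.where(below, t[:, 0], out)
    out = np.where(above, t[:, -1], out)
    return out


def weighted_median(
    ratios: Sequence[RatioEstimate],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_SEED,
) -> MrEstimate:
    """Weighted median of the Wald ratios with a parametric-bootstrap SE.

    The point estimate interpolates the inverse-variance-weighted median of
    the ratio distribution; it is consistent when instruments carrying at
    least half the total weight are valid.  The SE is the standard deviation
    of the weighted median over ``n_boot`` parametric redraws
    theta_j* ~ Normal(theta_j, se_j); confidence interval and p-value are
    then normal-theory.  Deterministic for a given seed.
    """
    if len(ratios) < 3:
        raise InsufficientInstrumentsError("weighted median needs at least 3 instruments")
    if n_boot < 1:
        raise ConfigurationError("n_boot must be >= 1")
    # stable tie-break: pre-sort inputs by (theta, rsid)
    ratios = sorted(ratios, key=lambda r: (r.theta, r.rsid))
    theta, se, w = _as_arrays(ratios)
    point = float(_weighted_median_point(theta, w)[0])
    rng = np.random.default_rng(seed)
    draws = rng.normal(loc=theta, scale=se, size=(n_boot, len(ratios)))
    boot = _weighted_median_point(draws, w)
    se_boot = float(np.std(boot, ddof=1)) if n_boot > 1 else float("nan")
    return _normal_estimate("weighted_median", point, se_boot, len(ratios))


def mr_egger(instruments: Sequence[HarmonizedInstrument], use_t: bool = True) -> EggerResult:
    """MR-Egger: weighted regression of outcome betas on exposure betas.

    Weighted least squares with a free intercept, weights 1/se_outcome^2,
    requiring every beta_exposure > 0 (orientation already applied).  The
    intercept estimates average directional pleiotropy; under the InSIDE
    assumption the slope is a pleiotropy-adjusted causal estimate.
    Standard errors carry a residual-dispersion factor max(1, sqrt(RSS_w /
    (n-2))) (multiplicative random effects floored at one); p-values use
    the t distribution on n-2 df by default (``use_t=False`` for normal).
    """
    if len(instruments) < 3:
        raise InsufficientInstrumentsError("MR-Egger needs at least 3 instruments")
    bad = [i.rsid for i in instruments if not i.beta_exposure > 0]
    if bad:
        raise OrientationError(
            f"MR-Egger requires positive oriented exposure betas; offending SNPs: {', '.join(bad)}"
        )
    bx = np.array([i.beta_exposure for i in instruments], dtype=float)
    by = np.array([i.beta_outcome for i in instruments], dtype=float)
    sy = np.array([i.se_outcome for i in instruments], dtype=float)
    n = len(instruments)
    fit = sm.WLS(by, sm.add_constant(bx), weights=sy ** -2).fit()
    sigma = float(np.sqrt(fit.mse_resid))
    dispersion = max(1.0, sigma)
    se_unit = np.asarray(fit.bse) / sigma  # unit-dispersion SEs from (X'WX)^-1
    se = se_unit * dispersion
    intercept, slope = (float(v) for v in fit.params)
    df = n - 2
    dist_sf = (lambda z: stats.t.sf(z, df)) if use_t else stats.norm.sf
    slope_p = float(2.0 * dist_sf(abs(slope) / se[1]))
    intercept_p = float(2.0 * dist_sf(abs(intercept) / se[0]))
    slope_est = MrEstimate(
        method="egger_slope",
        estimate=slope,
        se=float(se[1]),
        ci_low=slope - Z95 * float(se[1]),
        ci_high=slope + Z95 * float(se[1]),
        pvalue=slope_p,
        n_snps=n,
    )
    return EggerResult(
        slope=slope_est,
        intercept=intercept,
        intercept_se=float(se[0]),
        intercept_pvalue=intercept_p,
    )
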