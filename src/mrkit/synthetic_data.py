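"""Simulate two-sample GWAS summary statistics with known ground truth.

Summary statistics are generated directly at the summary level (no
individual-level genotypes): each SNP j has a true per-allele exposure
effect gamma_j, a direct (pleiotropic) outcome effect alpha_j drawn
independently of gamma_j — so the InSIDE condition holds by construction —
and observed effects with Gaussian sampling noise at the stated standard
errors.  The observed outcome effect per coded allele is

    beta_outcome_j ~ Normal(b * gamma_j + sign(gamma_j) * alpha_j, se_outcome_j)

where b is the causal log-OR per unit exposure.  Pleiotropy is defined per
the exposure-*raising* allele, so after harmonization with
``orientation="exposure_increase"`` the MR-Egger intercept estimates
``pleiotropy_mean`` and the IVW/median/Egger slopes estimate b (the
``exposure_decrease`` orientation estimates -b, the effect per unit
exposure decrease).

Defaults mirror the serum-25OHD / major-depression instrument set that
motivates the package: six instruments with per-allele effects between
0.017 and 0.089 log units, exposure SEs of 0.002-0.003, outcome SEs of
0.008-0.011, no causal effect and no pleiotropy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .summary_data import SnpAssociation, load_vitd_mdd_instruments

_NONPALINDROMIC_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                         ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"))
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for a simulated pair of GWAS.

    ``se_exposure_scale`` / ``se_outcome_scale`` may be a single value or a
    ``(low, high)`` range for per-SNP uniform draws.  A scale of exactly 0
    on the exposure side gives the noise-free-exposure mode used for exact
    recovery checks.
    """

    n_snps: int = 6
    true_causal_effect: float = 0.0
    gamma_low: float = 0.017
    gamma_high: float = 0.089
    se_exposure_scale: float | tuple[float, float] = (0.002, 0.003)
    se_outcome_scale: float | tuple[float, float] = (0.008, 0.011)
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    seed: int = 0
    allow_palindromic: bool = False

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        if not 0 < self.gamma_low <= self.gamma_high:
            raise ConfigurationError("need 0 < gamma_low <= gamma_high (valid instruments)")
        for name in ("se_exposure_scale", "se_outcome_scale"):
            scale = getattr(self, name)
            lo, hi = (scale, scale) if np.isscalar(scale) else scale
            if lo < 0 or hi < lo:
                raise ConfigurationError(f"{name} must be nonnegative (or an increasing range)")
            if name == "se_outcome_scale" and lo <= 0:
                raise ConfigurationError("se_outcome_scale must be positive")
        if self.pleiotropy_sd < 0:
            raise ConfigurationError("pleiotropy_sd must be nonnegative")


def _draw_scale(rng: np.random.Generator, scale, n: int) -> np.ndarray:
    if np.isscalar(scale):
        return np.full(n, float(scale))
    lo, hi = scale
    return rng.uniform(lo, hi, size=n)


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats

    with np.errstate(divide="ignore"):
        p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def generate_two_sample(
    config: SimulationConfig,
) -> tuple[list[SnpAssociation], list[SnpAssociation]]:
    """Simulate exposure and outcome summary statistics for ``config.n_snps`` SNPs.

    Fully reproducible from ``config.seed``.  SE columns report the true
    sampling SDs.  A zero exposure-SE scale makes the observed exposure
    betas equal the true gamma values.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_snps
    gamma_mag = rng.uniform(config.gamma_low, config.gamma_high, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    gamma = gamma_mag * sign
    alpha = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=n)
    se_x = _draw_scale(rng, config.se_exposure_scale, n)
    se_y = _draw_scale(rng, config.se_outcome_scale, n)
    bx = np.where(se_x > 0, rng.normal(gamma, np.where(se_x > 0, se_x, 1.0)), gamma)
    by = rng.normal(config.true_causal_effect * gamma + np.sign(gamma) * alpha, se_y)
    eaf = rng.uniform(0.05, 0.95, size=n)
    pairs = _NONPALINDROMIC_PAIRS + (_PALINDROMIC_PAIRS if config.allow_palindromic else ())
    pair_idx = rng.integers(0, len(pairs), size=n)
    # exposure SEs of exactly 0 are reported at a tiny positive floor to
    # satisfy the se > 0 record invariant while keeping betas noise-free
    se_x_rep = np.where(se_x > 0, se_x, 1e-12)
    exposure, outcome = [], []
    for j in range(n):
        ea, oa = pairs[pair_idx[j]]
        common = dict(rsid=f"sim{j + 1:06d}", effect_allele=ea, other_allele=oa, eaf=float(eaf[j]))
        exposure.append(
            SnpAssociation(
                beta=float(bx[j]), se=float(se_x_rep[j]),
                pvalue=float(_pvalues(bx[j : j + 1], se_x_rep[j : j + 1])[0]), **common,
            )
        )
        outcome.append(
            SnpAssociation(
                beta=float(by[j]), se=float(se_y[j]),
                pvalue=float(_pvalues(by[j : j + 1], se_y[j : j + 1])[0]), **common,
            )
        )
    return exposure, outcome


def simulate_at_fixture_strength(
    seed: int, true_causal_effect: float = 0.0
) -> tuple[list[SnpAssociation], list[SnpAssociation]]:
    """Simulate outcome statistics at the packaged instrument set's strength.

    The exposure side is the six packaged serum-25OHD instruments exactly
    as shipped (per-allele betas and SEs); outcome betas are redrawn as
    Normal(b * gamma_j, se_outcome_j) with the shipped outcome SEs, where
    gamma_j is the per-allele exposure beta and b ``true_causal_effect``.
    Useful for power demonstrations and null (type-I error) calibration at
    the real instrument strength.
    """
    instruments = load_vitd_mdd_instruments()
    rng = np.random.default_rng(seed)
    exposure, outcome = [], []
    for inst in instruments:
        gamma = -inst.beta_exposure  # per-allele effect of the coded (lowering) allele
        by = rng.normal(true_causal_effect * gamma, inst.se_outcome)
        common = dict(rsid=inst.rsid, effect_allele=inst.effect_allele, eaf=inst.eaf)
        exposure.append(SnpAssociation(beta=gamma, se=inst.se_exposure, **common))
        outcome.append(SnpAssociation(beta=float(by), se=inst.se_outcome, **common))
    return exposure, outcome
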