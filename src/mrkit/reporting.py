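"""Rescale causal estimates to odds ratios per SD and assemble report tables.

Estimates from :mod:`mrkit.mr_core` are log odds ratios per *unit* of the
oriented exposure.  Results are conventionally reported per one standard
deviation (SD) of the exposure in a stated direction; for natural-log serum
25-hydroxyvitamin D the default SD is 0.33 ln-nmol/L (about 18 nmol/L).
The log odds ratio scales linearly with the SD, the p-value does not change.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Sequence

from scipy import stats

from .errors import ConfigurationError
from .mr_core import EggerResult, MrEstimate, RatioEstimate, Z95

DEFAULT_SD = 0.33
DEFAULT_SD_NATURAL = "about 18 nmol/L"

_METHOD_LABELS = {
    "ivw_fixed": "IVW (fixed effect)",
    "ivw_mre": "IVW (multiplicative RE)",
    "weighted_median": "Weighted median",
    "egger_slope": "MR-Egger",
}


@dataclass(frozen=True)
class OrReport:
    """An estimate expressed as an odds ratio per ``sd_value`` change of the
    exposure in ``direction``, with 95% CI and the untransformed log-scale
    estimate retained at full precision."""

    label: str
    method: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    pvalue: float
    estimate_log: float
    se_log: float
    sd_value: float = DEFAULT_SD
    sd_natural: str = DEFAULT_SD_NATURAL
    direction: str = "decrease"


def to_per_sd_odds(
    estimate: MrEstimate | RatioEstimate,
    sd_value: float = DEFAULT_SD,
    direction: str = "decrease",
    sd_natural: str = DEFAULT_SD_NATURAL,
) -> OrReport:
    """Convert a per-unit estimate (oriented as exposure decrease) to an OR
    per ``sd_value`` change in ``direction``.

    ``direction="decrease"`` exponentiates estimate * sd_value directly;
    ``"increase"`` negates first, so the OR and CI bounds are reciprocal and
    swapped.  The p-value is scale-invariant and carried through.
    """
    if not sd_value > 0:
        raise ConfigurationError(f"sd_value must be > 0, got {sd_value}")
    if direction not in ("decrease", "increase"):
        raise ConfigurationError(f"unknown direction {direction!r}")
    if isinstance(estimate, RatioEstimate):
        est, se = estimate.theta, estimate.se_theta
        pvalue = float(2.0 * stats.norm.sf(abs(est) / se))
        label, method = estimate.rsid, "wald_ratio"
    else:
        est, se = estimate.estimate, estimate.se
        pvalue = estimate.pvalue
        method = estimate.method
        label = _METHOD_LABELS.get(method, method)
    sign = 1.0 if direction == "decrease" else -1.0
    lo = math.exp(sign * (est - Z95 * se) * sd_value)
    hi = math.exp(sign * (est + Z95 * se) * sd_value)
    return OrReport(
        label=label,
        method=method,
        odds_ratio=math.exp(sign * est * sd_value),
        ci_low=min(lo, hi),
        ci_high=max(lo, hi),
        pvalue=pvalue,
        estimate_log=sign * est * sd_value,
        se_log=se * sd_value,
        sd_value=sd_value,
        sd_natural=sd_natural,
        direction=direction,
    )


def _fmt_row(label: str, report: OrReport) -> str:
    return (
        f"{label:<26} {report.odds_ratio:>6.2f}  "
        f"({report.ci_low:.2f}-{report.ci_high:.2f}) {report.pvalue:>6.2f}"
    )


def forest_table(per_snp: Sequence[OrReport], pooled: Sequence[OrReport] = ()) -> str:
    """Column-aligned text table: one row per SNP, one per pooled method.

    Display rounding only (ORs/CIs and p to 2 decimals, the style of a
    forest plot's annotation column); use :func:`reports_to_dict` for the
    full-precision machine-readable form.
    """
    if not per_snp:
        raise ConfigurationError("forest_table requires at least one per-SNP row")
    direction = per_snp[0].direction
    sd = per_snp[0].sd_value
    lines = [
        f"{'':<26} {'OR':>6}  (95% CI)     p",
        f"-- per SD ({sd:g}) {direction} of exposure --",
    ]
    lines.extend(_fmt_row(r.label, r) for r in per_snp)
    if pooled:
        lines.append("-" * 48)
        lines.extend(_fmt_row(r.label, r) for r in pooled)
    return "\n".join(lines)


def reports_to_dict(
    per_snp: Sequence[OrReport],
    pooled: Sequence[OrReport],
    egger: EggerResult | None = None,
    meta: dict | None = None,
) -> dict:
    """Full-precision nested dict of all results (JSON/TSV serializable)."""
    doc: dict = {
        "per_snp": [asdict(r) for r in per_snp],
        "pooled": [asdict(r) for r in pooled],
    }
    if egger is not None:
        doc["egger_intercept"] = {
            "estimate": egger.intercept,
            "se": egger.intercept_se,
            "pvalue": egger.intercept_pvalue,
        }
    if meta:
        doc["meta"] = meta
    return doc


def reports_to_json(*args, **kwargs) -> str:
    """JSON form of :func:`reports_to_dict` with stable key order."""
    return json.dumps(reports_to_dict(*args, **kwargs), indent=2, sort_keys=True)


def reports_to_tsv(per_snp: Sequence[OrReport], pooled: Sequence[OrReport]) -> str:
    """Flat TSV export, one line per SNP or method, full precision."""
    header = "label\tmethod\tor\tci_low\tci_high\tp\testimate_log\tse_log\tsd\tdirection"
    lines = [header]
    for r in list(per_snp) + list(pooled):
        lines.append(
            "\t".join(
                [
                    r.label,
                    r.method,
                    repr(r.odds_ratio),
                    repr(r.ci_low),
                    repr(r.ci_high),
                    repr(r.pvalue),
                    repr(r.estimate_log),
                    repr(r.se_log),
                    repr(r.sd_value),
                    r.direction,
                ]
            )
        )
    return "\n".join(lines)
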