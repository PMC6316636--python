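"""Read, validate, and harmonize GWAS summary statistics into oriented instruments.

Two-sample Mendelian randomization consumes per-SNP association summaries
from two independent GWAS: one for the exposure, one for the outcome.  This
module provides the record types (:class:`SnpAssociation`,
:class:`HarmonizedInstrument`), delimited-text I/O with a configurable column
map, allele harmonization (effect-allele flips, strand complements,
palindromic exclusion), and the packaged six-SNP vitamin D / major depression
instrument set used throughout the documentation and tests.

Orientation convention
----------------------
Estimates downstream are expressed per unit change of the exposure in a
stated *direction*.  Under ``orientation="exposure_decrease"`` every
instrument is re-coded so that its effect allele lowers the raw exposure and
``beta_exposure`` is the (positive) effect on the derived variable
"exposure decrease", while ``beta_outcome`` keeps the sign it has for that
exposure-lowering allele.  ``"exposure_increase"`` is the mirror coding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, HarmonizationError, ParseError, ValidationError

logger = logging.getLogger(__name__)

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})

#: canonical field names accepted in a column map
CANONICAL_FIELDS = (
    "rsid",
    "chromosome",
    "nearby_gene",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n_cases",
    "n_controls",
)

_FLOAT_FIELDS = {"eaf", "beta", "se", "pvalue"}
_INT_FIELDS = {"n_cases", "n_controls"}


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's summary-statistic record from a single GWAS.

    ``beta`` is the per-allele effect of ``effect_allele``: for a
    quantitative exposure it is on the analysis scale of that trait (here
    natural-log exposure units), for a binary outcome it is a log odds
    ratio.  ``se`` is its standard error on the same scale.
    """

    rsid: str
    beta: float
    se: float
    effect_allele: str | None = None
    other_allele: str | None = None
    eaf: float | None = None
    pvalue: float | None = None
    chromosome: str | None = None
    nearby_gene: str | None = None
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValidationError(f"{self.rsid}: standard error must be > 0, got {self.se}")
        if self.eaf is not None and not 0.0 <= self.eaf <= 1.0:
            raise ValidationError(f"{self.rsid}: effect-allele frequency {self.eaf} outside [0, 1]")
        for name in ("effect_allele", "other_allele"):
            allele = getattr(self, name)
            if allele is not None and allele not in _VALID_ALLELES:
                raise ValidationError(f"{self.rsid}: {name} {allele!r} is not one of A/C/G/T")
        if self.pvalue is not None and not 0.0 < self.pvalue <= 1.0:
            raise ValidationError(f"{self.rsid}: p-value {self.pvalue} outside (0, 1]")
        for name in ("n_cases", "n_controls"):
            count = getattr(self, name)
            if count is not None and count < 0:
                raise ValidationError(f"{self.rsid}: {name} must be nonnegative")

    def flipped(self) -> "SnpAssociation":
        """Return the same association re-coded on the other allele."""
        return replace(
            self,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
        )

    def is_palindromic(self) -> bool:
        """True when both alleles are known and form an A/T or C/G pair."""
        if self.effect_allele is None or self.other_allele is None:
            return False
        return {self.effect_allele, self.other_allele} in _PALINDROMIC_PAIRS


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Paired exposure/outcome effects for one SNP on a common oriented allele."""

    rsid: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    orientation: str = "exposure_decrease"
    effect_allele: str | None = None
    eaf: float | None = None

    def __post_init__(self) -> None:
        if not self.se_exposure > 0 or not self.se_outcome > 0:
            raise ValidationError(f"{self.rsid}: harmonized standard errors must be > 0")
        if self.orientation not in ("exposure_decrease", "exposure_increase"):
            raise ValidationError(f"{self.rsid}: unknown orientation {self.orientation!r}")


def _parse_float(text: str, underflow_floor: bool = False) -> float:
    """Parse a float; a nonzero literal that underflows to 0.0 (GWAS p-values
    such as 1e-343 do) is floored at the smallest positive float."""
    value = float(text)
    if underflow_floor and value == 0.0 and any(c in "123456789" for c in text.partition("e")[0]):
        return 5e-324
    return value


def _resolve_columns(
    header: Sequence[str], column_map: Mapping[str, str | int] | None
) -> dict[str, str]:
    """Map canonical field names to actual column labels.

    Column-map values may be header names or 1-based column positions.
    Without a map, canonical names present in the header are used as-is.
    """
    if column_map is None:
        return {name: name for name in CANONICAL_FIELDS if name in header}
    resolved: dict[str, str] = {}
    for field, ref in column_map.items():
        if field not in CANONICAL_FIELDS:
            raise ConfigurationError(
                f"unknown field {field!r} in column map; expected one of {CANONICAL_FIELDS}"
            )
        if isinstance(ref, int):
            if not 1 <= ref <= len(header):
                raise ConfigurationError(
                    f"column {ref} for field {field!r} out of range (file has {len(header)} columns)"
                )
            resolved[field] = header[ref - 1]
        else:
            if ref not in header:
                raise ConfigurationError(f"mapped column {ref!r} for field {field!r} not in header")
            resolved[field] = ref
    if "rsid" not in resolved or "beta" not in resolved or "se" not in resolved:
        raise ConfigurationError("column map must cover at least rsid, beta and se")
    return resolved


def read_associations(
    path,
    column_map: Mapping[str, str | int] | None = None,
    delimiter: str = "\t",
) -> list[SnpAssociation]:
    """Read per-SNP associations from delimited text (one header row).

    Parameters
    ----------
    path
        File to read.
    column_map
        Maps canonical field names (see :data:`CANONICAL_FIELDS`) to header
        names or 1-based column positions.  ``None`` uses canonical names.
    delimiter
        Field separator; tab by default.
    """
    frame = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    columns = _resolve_columns(list(frame.columns), column_map)
    records: list[SnpAssociation] = []
    for idx, row in enumerate(frame.itertuples(index=False), start=2):  # header is line 1
        values: dict[str, object] = {}
        # positional access keeps duplicate-header behaviour predictable
        raw_row = {col: row[frame.columns.get_loc(col)] for col in columns.values()}
        for field, col in columns.items():
            raw = raw_row[col]
            if raw is None or (isinstance(raw, float) and pd.isna(raw)) or str(raw).strip() == "":
                continue
            text = str(raw).strip().replace("−", "-")  # tolerate unicode minus
            if field in _FLOAT_FIELDS:
                try:
                    values[field] = _parse_float(text, underflow_floor=field == "pvalue")
                except ValueError as exc:
                    raise ParseError(f"line {idx}: cannot parse {field}={text!r} as a number") from exc
            elif field in _INT_FIELDS:
                try:
                    values[field] = int(float(text.replace(",", "")))
                except ValueError as exc:
                    raise ParseError(f"line {idx}: cannot parse {field}={text!r} as an integer") from exc
            else:
                values[field] = text
        if "beta" not in values or "se" not in values:
            raise ParseError(f"line {idx}: missing beta or se value")
        records.append(SnpAssociation(**values))  # type: ignore[arg-type]
    return records


def write_associations(path, associations: Iterable[SnpAssociation], delimiter: str = "\t") -> None:
    """Write associations back to delimited text (round-trips with read)."""
    rows = []
    for assoc in associations:
        rows.append({f.name: getattr(assoc, f.name) for f in fields(assoc)})
    frame = pd.DataFrame(rows, columns=[f.name for f in fields(SnpAssociation)])
    frame.to_csv(path, sep=delimiter, index=False, float_format=None)


def _check_unique(records: Sequence[SnpAssociation], label: str) -> dict[str, SnpAssociation]:
    seen: dict[str, SnpAssociation] = {}
    for rec in records:
        if rec.rsid in seen:
            raise ValidationError(f"duplicate rsID {rec.rsid} in {label} study")
        seen[rec.rsid] = rec
    return seen


def _align_alleles(
    exp: SnpAssociation, out: SnpAssociation, strict: bool
) -> SnpAssociation | None:
    """Re-code the outcome record onto the exposure record's effect allele.

    Returns ``None`` when the pair must be dropped (unresolvable strand
    ambiguity outside strict mode); raises in strict mode.
    """
    if exp.effect_allele is None or out.effect_allele is None:
        return out  # allele-blind data is taken as already aligned
    if out.effect_allele == exp.effect_allele:
        return out
    if exp.other_allele is not None and out.effect_allele == exp.other_allele:
        return out.flipped()
    comp = _COMPLEMENT[out.effect_allele]
    if comp == exp.effect_allele:
        # same allele reported on the opposite strand
        return replace(
            out,
            effect_allele=comp,
            other_allele=None if out.other_allele is None else _COMPLEMENT[out.other_allele],
        )
    if exp.other_allele is not None and comp == exp.other_allele:
        return replace(
            out,
            effect_allele=comp,
            other_allele=None if out.other_allele is None else _COMPLEMENT[out.other_allele],
        ).flipped()
    if exp.other_allele is None:
        # alleles differ and no second allele to disambiguate: simple flip
        return out.flipped()
    msg = f"{exp.rsid}: outcome allele {out.effect_allele} matches neither exposure allele"
    if strict:
        raise HarmonizationError(msg)
    logger.warning("%s; SNP dropped", msg)
    return None


def harmonize(
    exposure: Sequence[SnpAssociation],
    outcome: Sequence[SnpAssociation],
    orientation: str = "exposure_decrease",
    palindromic_eaf_window: float = 0.08,
    strict: bool = False,
) -> list[HarmonizedInstrument]:
    """Pair exposure and outcome records per rsID and orient them.

    The inner join keeps exposure file order.  Outcome records reported on
    the other allele (or other strand) are re-coded onto the exposure's
    effect allele.  Palindromic SNPs (A/T or C/G) whose effect-allele
    frequency lies within ``palindromic_eaf_window`` of 0.5 are ambiguous
    and excluded (a :class:`HarmonizationError` in ``strict`` mode).
    Finally the orientation transform fixes the sign convention described in
    the module docstring.
    """
    if orientation not in ("exposure_decrease", "exposure_increase"):
        raise ConfigurationError(f"unknown orientation {orientation!r}")
    exp_by_rsid = _check_unique(exposure, "exposure")
    _check_unique(outcome, "outcome")
    out_by_rsid = {rec.rsid: rec for rec in outcome}

    instruments: list[HarmonizedInstrument] = []
    n_unmatched = 0
    n_palindromic = 0
    for rsid, exp in exp_by_rsid.items():
        out = out_by_rsid.get(rsid)
        if out is None:
            n_unmatched += 1
            continue
        if exp.is_palindromic() or out.is_palindromic():
            eaf = exp.eaf if exp.eaf is not None else out.eaf
            if eaf is None or abs(eaf - 0.5) < palindromic_eaf_window:
                msg = f"{rsid}: palindromic SNP with ambiguous allele frequency"
                if strict:
                    raise HarmonizationError(msg)
                logger.warning("%s; SNP excluded", msg)
                n_palindromic += 1
                continue
        out = _align_alleles(exp, out, strict)
        if out is None:
            continue
        # orientation: make the coded allele exposure-lowering, then express
        # the exposure effect on the "exposure decrease" (or mirror) scale
        flip_to_lowering = exp.beta > 0
        bx, by = (-exp.beta, -out.beta) if flip_to_lowering else (exp.beta, out.beta)
        eaf = exp.eaf if not flip_to_lowering or exp.eaf is None else 1.0 - exp.eaf
        allele = exp.effect_allele
        if flip_to_lowering:
            allele = exp.other_allele  # may be None
        if orientation == "exposure_decrease":
            beta_exposure, beta_outcome = -bx, by
        else:
            beta_exposure, beta_outcome = -bx, -by
        instruments.append(
            HarmonizedInstrument(
                rsid=rsid,
                beta_exposure=beta_exposure,
                se_exposure=exp.se,
                beta_outcome=beta_outcome,
                se_outcome=out.se,
                orientation=orientation,
                effect_allele=allele,
                eaf=eaf,
            )
        )
    n_dropped = len(exp_by_rsid) - len(instruments)
    if n_dropped:
        logger.info(
            "harmonize: %d instruments kept, %d dropped (%d unmatched, %d palindromic)",
            len(instruments), n_dropped, n_unmatched, n_palindromic,
        )
    return instruments


def load_vitd_mdd_instruments() -> list[HarmonizedInstrument]:
    """Load the packaged six-SNP serum-25OHD / major-depression instrument set.

    Exposure effects (natural-log serum 25-hydroxyvitamin D, SUNLIGHT
    consortium) and outcome effects (log odds of major depression, PGC) are
    both coded per the 25OHD-*decreasing* allele and returned oriented as
    ``exposure_decrease``.
    """
    ref = resources.files("mrkit.data").joinpath("vitd_mdd_instruments.tsv")
    with resources.as_file(ref) as path:
        frame = pd.read_csv(path, sep="\t")
    exposure: list[SnpAssociation] = []
    outcome: list[SnpAssociation] = []
    for row in frame.itertuples(index=False):
        common = dict(
            rsid=row.rsid,
            effect_allele=row.effect_allele,
            eaf=float(row.eaf),
            chromosome=str(row.chromosome),
            nearby_gene=row.nearby_gene,
        )
        exposure.append(
            SnpAssociation(
                beta=float(row.beta_exposure),
                se=float(row.se_exposure),
                pvalue=max(float(row.pvalue_exposure), 5e-324),
                **common,
            )
        )
        outcome.append(
            SnpAssociation(
                beta=float(row.beta_outcome),
                se=float(row.se_outcome),
                pvalue=float(row.pvalue_outcome),
                n_cases=int(row.n_cases),
                n_controls=int(row.n_controls),
                **common,
            )
        )
    return harmonize(exposure, outcome, orientation="exposure_decrease")
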