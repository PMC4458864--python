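"""Summary-association data model, table I/O, SE reconstruction and harmonization.

GWAS consortia publish per-SNP summary tables giving, for each variant, the
effect allele, an effect size (an odds ratio for binary traits, a per-allele
unit change for quantitative traits) and a P value — but frequently not the
standard error. This module holds the record types for such tables, rebuilds
standard errors from (effect, P) pairs under the two-sided Wald-test
assumption, imputes SEs that cannot be rebuilt (an odds ratio printed as 1.00
has a zero log-effect and therefore no recoverable SE), and aligns exposure
and outcome records to a common effect allele.

Odds ratios are stored internally on the natural-log scale; every downstream
computation is on the log scale and exponentiated only for reporting.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from scipy.stats import norm

from .exceptions import (
    DegenerateInputError,
    HarmonizationError,
    InputError,
    RowError,
    SchemaError,
)

logger = logging.getLogger(__name__)

LOG_ODDS = "log_odds"
TRAIT_UNITS = "trait_units"

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {frozenset({"A", "T"}), frozenset({"C", "G"})}


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP's summary association with one trait.

    ``effect`` is the per-allele effect of ``effect_allele``: a natural-log
    odds ratio when ``effect_scale == "log_odds"``, otherwise the change in
    trait units (e.g. mmol/l fasting glucose) per allele copy.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    effect: float
    p_value: float
    se: float | None = None
    effect_scale: str = LOG_ODDS
    locus: str = ""
    trait_id: str = ""

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(
                f"{self.snp_id}: p_value must be in (0, 1], got {self.p_value!r}"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not math.isfinite(self.effect):
            raise ValueError(f"{self.snp_id}: effect must be finite")
        if self.se is not None and not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be > 0 when present")
        if self.effect_scale not in (LOG_ODDS, TRAIT_UNITS):
            raise ValueError(f"{self.snp_id}: unknown effect_scale {self.effect_scale!r}")


@dataclass(frozen=True)
class InstrumentRecord:
    """Harmonized exposure/outcome pair for one SNP.

    ``gamma`` is the exposure effect per copy of the exposure's effect allele;
    ``beta`` is the outcome effect (log-odds of the outcome) aligned to the
    same allele. Only summary effects are carried — allele dosages themselves
    never appear at this level of analysis.
    """

    snp_id: str
    gamma: float
    se_gamma: float
    beta: float
    se_beta: float
    se_beta_imputed: bool = False
    cluster: str | None = None
    pleiotropic: bool | None = None
    locus: str = ""

    def __post_init__(self):
        if not self.se_gamma > 0:
            raise ValueError(f"{self.snp_id}: se_gamma must be > 0")
        if not self.se_beta > 0:
            raise ValueError(f"{self.snp_id}: se_beta must be > 0")


@dataclass(frozen=True)
class TableSchema:
    """Column map from a summary TSV/CSV to :class:`AssociationRecord` fields.

    ``effect`` names the effect-size column. With ``effect_is_or=True`` the
    column holds odds ratios which are converted to ln(OR) on read.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    effect: str
    p_value: str
    effect_is_or: bool = True
    effect_scale: str = LOG_ODDS
    locus: str | None = None
    se: str | None = None
    trait_id: str = ""

    def required_columns(self) -> list[str]:
        cols = [self.snp_id, self.effect_allele, self.other_allele,
                self.effect, self.p_value]
        if self.locus:
            cols.append(self.locus)
        if self.se:
            cols.append(self.se)
        return cols


def read_association_table(path, schema: TableSchema) -> list[AssociationRecord]:
    """Read a TSV/CSV summary table into AssociationRecords, in file order.

    Rows failing record invariants are collected and reported together in a
    :class:`RowError` carrying 1-based data-row numbers; a missing mandatory
    column raises :class:`SchemaError`.
    """
    with open(path, newline="") as fh:
        dialect = "excel-tab" if str(path).endswith((".tsv", ".txt")) else "excel"
        reader = csv.DictReader(fh, dialect=dialect)
        header = reader.fieldnames or []
        missing = [c for c in schema.required_columns() if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
        records: list[AssociationRecord] = []
        bad: list[tuple[int, str, str]] = []
        for i, row in enumerate(reader, start=1):
            try:
                records.append(_record_from_row(row, schema))
            except (ValueError, KeyError) as exc:
                bad.append((i, "", str(exc)))
        if bad:
            detail = "; ".join(f"row {r}: {msg}" for r, _, msg in bad[:10])
            raise RowError(f"{path}: {len(bad)} invalid row(s): {detail}", rows=bad)
    return records


def _record_from_row(row: dict, schema: TableSchema) -> AssociationRecord:
    def num(col: str) -> float:
        raw = row[col].strip()
        try:
            return float(raw)
        except ValueError:
            raise ValueError(f"unparsable numeric {raw!r} in column {col!r}") from None

    effect = num(schema.effect)
    if schema.effect_is_or:
        if effect <= 0:
            raise ValueError(f"odds ratio must be > 0, got {effect}")
        effect = math.log(effect)
    se = num(schema.se) if schema.se and row.get(schema.se, "").strip() else None
    return AssociationRecord(
        snp_id=row[schema.snp_id].strip(),
        effect_allele=row[schema.effect_allele].strip().upper(),
        other_allele=row[schema.other_allele].strip().upper(),
        effect=effect,
        p_value=num(schema.p_value),
        se=se,
        effect_scale=schema.effect_scale,
        locus=row[schema.locus].strip() if schema.locus else "",
        trait_id=schema.trait_id,
    )


def reconstruct_se(effect: float, p_value: float) -> float:
    """Rebuild the standard error from an effect and its two-sided P value.

    Assumes the printed P comes from a two-sided Wald test, so
    SE = |effect| / z with z = Phi^-1(1 - P/2). The inversion is done through
    the survival-function inverse, which is accurate for P values as extreme
    as 1e-215 (well past the smallest P printed in GWAS tables).

    Returns ``nan`` (the undefined flag) when the effect is exactly zero — an
    odds ratio printed as 1.00 carries no SE information — or when P >= 1.
    Raises for P <= 0.
    """
    if p_value <= 0.0:
        raise ValueError(f"p_value must be > 0, got {p_value}")
    if effect == 0.0 or p_value >= 1.0:
        return math.nan
    z = norm.isf(p_value / 2.0)
    return float(abs(effect) / z)


def impute_missing_se(
    records: Sequence[AssociationRecord], policy: str = "median"
) -> list[AssociationRecord]:
    """Fill undefined SEs from the defined SEs of the same record set.

    Records must already carry ``se`` (possibly None for undefined). With
    ``median``/``mean`` the policy value is computed over the defined SEs and
    substituted; with ``drop`` undefined-SE records are removed and logged.
    """
    if policy not in ("median", "mean", "drop"):
        raise InputError(f"unknown SE imputation policy {policy!r}")
    defined = [r.se for r in records if r.se is not None]
    undefined = [r for r in records if r.se is None]
    if not undefined:
        return list(records)
    if policy == "drop":
        for r in undefined:
            logger.info("dropping %s: undefined SE", r.snp_id)
        return [r for r in records if r.se is not None]
    if not defined:
        raise DegenerateInputError("all SEs undefined; cannot impute")
    import statistics

    value = statistics.median(defined) if policy == "median" else statistics.fmean(defined)
    out = []
    for r in records:
        if r.se is None:
            logger.info("imputing SE for %s: %g (%s)", r.snp_id, value, policy)
            out.append(replace(r, se=value))
        else:
            out.append(r)
    return out


def _is_palindromic(a: str, b: str) -> bool:
    return frozenset({a, b}) in _PALINDROMIC


def harmonize(
    exposure: AssociationRecord,
    outcome: AssociationRecord,
    palindrome_policy: str = "flag",
    se_exposure: float | None = None,
    se_outcome: float | None = None,
) -> InstrumentRecord | None:
    """Align an outcome record to the exposure's effect allele.

    The outcome beta is sign-flipped when its effect allele matches the
    exposure's *other* allele (directly or after strand complement).
    Palindromic SNPs (A/T or C/G) are strand-ambiguous; the policy is
    ``flag`` (keep, warn), ``drop`` (return None, log) or ``keep`` (silent).

    SEs default to the records' own ``se`` fields; explicit overrides allow
    harmonizing before imputation.
    """
    if palindrome_policy not in ("flag", "drop", "keep"):
        raise InputError(f"unknown palindrome policy {palindrome_policy!r}")
    if exposure.snp_id != outcome.snp_id:
        raise HarmonizationError(
            f"snp_id mismatch: {exposure.snp_id} vs {outcome.snp_id}"
        )
    exp_alleles = (exposure.effect_allele, exposure.other_allele)
    out_alleles = (outcome.effect_allele, outcome.other_allele)

    if _is_palindromic(*exp_alleles) or _is_palindromic(*out_alleles):
        if palindrome_policy == "drop":
            logger.info("dropping palindromic SNP %s", exposure.snp_id)
            return None
        if palindrome_policy == "flag":
            logger.warning(
                "palindromic SNP %s kept; strand cannot be verified", exposure.snp_id
            )

    flip = _alignment_sign(exp_alleles, out_alleles, exposure.snp_id)
    beta = flip * outcome.effect

    se_g = se_exposure if se_exposure is not None else exposure.se
    se_b = se_outcome if se_outcome is not None else outcome.se
    if se_g is None or se_b is None:
        raise HarmonizationError(
            f"{exposure.snp_id}: SEs must be defined (reconstruct/impute first)"
        )
    return InstrumentRecord(
        snp_id=exposure.snp_id,
        gamma=exposure.effect,
        se_gamma=se_g,
        beta=beta,
        se_beta=se_b,
        locus=exposure.locus,
    )


def _alignment_sign(exp_alleles, out_alleles, snp_id) -> int:
    """+1 if outcome effect allele maps to the exposure effect allele, -1 if swapped."""
    ea, oa = exp_alleles
    candidates = {
        out_alleles: None,
        (_COMPLEMENT.get(out_alleles[0], "?"), _COMPLEMENT.get(out_alleles[1], "?")): None,
    }
    for cand in candidates:
        if cand == (ea, oa):
            return 1
        if cand == (oa, ea):
            return -1
    raise HarmonizationError(
        f"{snp_id}: alleles {out_alleles} irreconcilable with exposure {exp_alleles}"
    )


INSTRUMENT_COLUMNS = [
    "snp_id", "locus", "gamma", "se_gamma", "beta", "se_beta",
    "se_beta_imputed", "cluster", "pleiotropic",
]


def write_instrument_table(records: Iterable[InstrumentRecord], path) -> None:
    """Write harmonized instruments as TSV with a fixed column order."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, dialect="excel-tab")
        writer.writerow(INSTRUMENT_COLUMNS)
        for r in records:
            writer.writerow([
                r.snp_id, r.locus, repr(float(r.gamma)), repr(float(r.se_gamma)),
                repr(float(r.beta)), repr(float(r.se_beta)),
                int(r.se_beta_imputed),
                "" if r.cluster is None else r.cluster,
                "" if r.pleiotropic is None else int(r.pleiotropic),
            ])


def read_instrument_table(path) -> list[InstrumentRecord]:
    """Read a TSV written by :func:`write_instrument_table` (exact round-trip)."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, dialect="excel-tab")
        missing = [c for c in INSTRUMENT_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
        return [
            InstrumentRecord(
                snp_id=row["snp_id"],
                locus=row["locus"],
                gamma=float(row["gamma"]),
                se_gamma=float(row["se_gamma"]),
                beta=float(row["beta"]),
                se_beta=float(row["se_beta"]),
                se_beta_imputed=bool(int(row["se_beta_imputed"])),
                cluster=row["cluster"] or None,
                pleiotropic=None if row["pleiotropic"] == "" else bool(int(row["pleiotropic"])),
            )
            for row in reader
        ]
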