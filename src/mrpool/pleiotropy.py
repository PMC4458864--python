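"""CPMA screening of candidate instruments against confounder-trait P values.

A valid Mendelian randomization instrument must affect the outcome only
through the exposure. A variant that also associates with known confounders
(here, canonically: LDL cholesterol, triglycerides, systolic and diastolic
blood pressure, BMI) violates that exclusion restriction. The cross-phenotype
meta-analysis (CPMA) statistic tests, per SNP, whether its P values across
the confounder traits look uniform (no pleiotropy) or shifted toward small
values.

Under the uniform null, x_j = -ln p_j is Exponential(1). CPMA is the
likelihood-ratio test of rate lambda = 1 against the MLE lambda_hat =
n / sum(x_j):

    CPMA = -2 [ l(1) - l(lambda_hat) ],   l(lambda) = sum_j (ln lambda - lambda x_j)

referred to chi-square with 1 df. Exclusion on *any* detectable confounder
association is deliberately conservative: dropping a good instrument biases
the pooled estimate toward the null, never away from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import stats

from .exceptions import DegenerateInputError, InputError

DEFAULT_CONFOUNDER_TRAITS = ("LDL-C", "TG", "SBP", "DBP", "BMI")
DEFAULT_THRESHOLD = 0.05


@dataclass(frozen=True)
class PleiotropyProfile:
    """Per-SNP confounder P values with the CPMA test result."""

    snp_id: str
    trait_pvalues: Mapping[str, float]
    lambda_hat: float
    cpma_stat: float
    cpma_p: float
    is_pleiotropic: bool


def cpma_statistic(pvalues: Sequence[float]) -> tuple[float, float, float]:
    """Exponential-rate likelihood-ratio test of uniformity of P values.

    Returns ``(lambda_hat, cpma_stat, cpma_p)``. P values equal to 1 exactly
    contribute x_j = 0; if *all* are 1 the rate MLE diverges and the input is
    rejected as degenerate.
    """
    if len(pvalues) < 2:
        raise InputError("cpma_statistic: need at least 2 P values")
    xs = []
    for p in pvalues:
        if not (0.0 < p <= 1.0):
            raise InputError(f"cpma_statistic: P values must be in (0, 1], got {p}")
        xs.append(-math.log(p))
    total = sum(xs)
    n = len(xs)
    if total == 0.0:
        raise DegenerateInputError("cpma_statistic: all P values are 1")
    lam = n / total
    # -2[l(1) - l(lam)] = 2[n ln(lam) - n + total]
    stat = 2.0 * (n * math.log(lam) - n + total)
    stat = max(0.0, stat)  # guard tiny negative roundoff at lam ~= 1
    p = float(stats.chi2.sf(stat, df=1))
    return lam, stat, p


def profile_snp(
    snp_id: str,
    trait_pvalues: Mapping[str, float],
    threshold: float = DEFAULT_THRESHOLD,
) -> PleiotropyProfile:
    """Run CPMA on one SNP's confounder P values and flag at ``threshold``."""
    lam, stat, p = cpma_statistic(list(trait_pvalues.values()))
    return PleiotropyProfile(
        snp_id=snp_id,
        trait_pvalues=dict(trait_pvalues),
        lambda_hat=lam,
        cpma_stat=stat,
        cpma_p=p,
        is_pleiotropic=p < threshold,
    )


def screen_instruments(
    profiles: Sequence[PleiotropyProfile], threshold: float = DEFAULT_THRESHOLD
) -> tuple[list[str], list[str]]:
    """Partition SNPs into (instrument_set, excluded_set) by CPMA P value.

    Both lists are sorted by snp_id. No multiple-testing correction is
    applied across SNPs: over-exclusion only favours the null.
    """
    if not (0.0 < threshold <= 1.0):
        raise InputError(f"screen_instruments: threshold must be in (0, 1], got {threshold}")
    keep, drop = [], []
    for prof in profiles:
        (drop if prof.cpma_p < threshold else keep).append(prof.snp_id)
    return sorted(keep), sorted(drop)


def partition_by_labels(
    labels: Mapping[str, bool]
) -> tuple[list[str], list[str]]:
    """Partition SNPs by precomputed pleiotropy labels (True = pleiotropic).

    Reproduction path for published tables that print a pleiotropy call per
    SNP without the underlying confounder P values.
    """
    keep = sorted(s for s, flag in labels.items() if not flag)
    drop = sorted(s for s, flag in labels.items() if flag)
    return keep, drop
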