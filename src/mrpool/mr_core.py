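"""Wald-ratio estimates and inverse-variance-weighted pooling.

The causal effect alpha of an exposure x on an outcome y (structural model
y = alpha*x + eta, with eta capturing confounding) is estimated per genetic
instrument i as the Wald ratio

    alpha_i = beta_i / gamma_i,      v_i = s(beta_i)^2 / gamma_i^2,

where gamma_i and beta_i are the instrument's summary effects on exposure and
outcome. The per-instrument estimates are pooled exactly as independent
studies are pooled in meta-analysis: a fixed-effects estimate with precision
weights w_i = 1/v_i, and a DerSimonian-Laird random-effects estimate whose
weights 1/(v_i + tau^2) absorb between-instrument heterogeneity. The
first-order variance ignores sampling error in gamma_i, which is the standard
two-sample approximation when instruments reach genome-wide significance.

Heterogeneity is summarized by Cochran's Q and I^2 = max(0, (Q-df)/Q)*100,
with a test-based (Higgins-Thompson) 95% CI on ln H truncated to [0, 100]%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import InputError, WeakInstrumentError
from .summary_data import InstrumentRecord

#: two-sided 95% normal quantile used for every CI in the package
Z95 = 1.959964

FIXED = "fixed"
RANDOM = "random"


@dataclass(frozen=True)
class WaldRatio:
    """Per-SNP causal estimate with its variance and precision weight."""

    snp_id: str
    alpha_i: float
    v_i: float
    w_i: float
    locus: str = ""
    cluster: str | None = None

    def __post_init__(self):
        if not self.v_i > 0:
            raise ValueError(f"{self.snp_id}: v_i must be > 0")


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q, DL tau^2, and I^2 with its test-based 95% CI (percent)."""

    q: float
    df: int
    tau2: float
    i2: float
    i2_ci_low: float
    i2_ci_high: float


@dataclass(frozen=True)
class PooledEstimate:
    """Pooled causal estimate on the log-odds scale with reporting-scale CI.

    ``or_scale``/``ci_low``/``ci_high`` are exponentiated (odds-ratio scale)
    when ``scale == "log_odds"``; for trait-unit exposures pooled through
    :func:`mrpool.pipeline.allele_effect_meta` the native-scale point estimate
    is ``alpha`` itself and ``scale`` says so.
    """

    model: str
    alpha: float
    se: float
    or_scale: float
    ci_low: float
    ci_high: float
    p_value: float
    n_instruments: int
    het: HeterogeneityStats | None
    scale: str = "log_odds"

    @property
    def estimate(self) -> float:
        """Point estimate on the reporting scale."""
        return self.or_scale if self.scale == "log_odds" else self.alpha


def wald_ratio(instr: InstrumentRecord) -> WaldRatio:
    """Single-instrument causal estimate alpha_i = beta_i/gamma_i."""
    if instr.gamma == 0.0:
        raise WeakInstrumentError(
            f"{instr.snp_id}: gamma = 0, Wald ratio undefined"
        )
    alpha = instr.beta / instr.gamma
    v = (instr.se_beta / instr.gamma) ** 2
    return WaldRatio(
        snp_id=instr.snp_id,
        alpha_i=alpha,
        v_i=v,
        w_i=1.0 / v,
        locus=instr.locus,
        cluster=instr.cluster,
    )


def wald_ratios(instruments: Sequence[InstrumentRecord]) -> list[WaldRatio]:
    return [wald_ratio(r) for r in instruments]


def _arrays(ratios: Sequence[WaldRatio]):
    # canonical snp_id order so that pooled results are bit-identical under
    # permutation of the input (float summation is not associative)
    ordered = sorted(ratios, key=lambda r: r.snp_id)
    alpha = np.array([r.alpha_i for r in ordered], dtype=float)
    v = np.array([r.v_i for r in ordered], dtype=float)
    return alpha, v


def _pool(alpha: np.ndarray, v: np.ndarray):
    w = 1.0 / v
    sw = float(np.sum(w))
    a = float(np.sum(w * alpha) / sw)
    se = sw ** -0.5
    return a, se


def _finish(model: str, a: float, se: float, n: int,
            het: HeterogeneityStats | None, scale: str) -> PooledEstimate:
    p = 2.0 * float(stats.norm.sf(abs(a) / se)) if se > 0 else 1.0
    p = min(p, 1.0) if p > 0 else float(np.nextafter(0, 1))
    lo, hi = a - Z95 * se, a + Z95 * se
    if scale == "log_odds":
        point, lo, hi = math.exp(a), math.exp(lo), math.exp(hi)
    else:
        point = math.exp(a)  # or_scale field stays exp(alpha) by definition
    return PooledEstimate(
        model=model, alpha=a, se=se, or_scale=math.exp(a),
        ci_low=lo, ci_high=hi, p_value=p, n_instruments=n, het=het, scale=scale,
    )


def fixed_effects_pool(
    ratios: Sequence[WaldRatio], scale: str = "log_odds"
) -> PooledEstimate:
    """Inverse-variance-weighted fixed-effects pooled estimate.

    alpha = sum(w_i alpha_i)/sum(w_i), se = sum(w_i)^(-1/2); equivalently the
    coefficient of the zero-intercept weighted regression of beta_i on
    gamma_i with error variances s(beta_i)^2.
    """
    if len(ratios) == 0:
        raise InputError("fixed_effects_pool: empty instrument set")
    alpha, v = _arrays(ratios)
    a, se = _pool(alpha, v)
    het = heterogeneity_stats(ratios) if len(ratios) >= 2 else None
    return _finish(FIXED, a, se, len(ratios), het, scale)


def dl_tau2(ratios: Sequence[WaldRatio]) -> float:
    """DerSimonian-Laird moment estimate of the between-instrument variance."""
    alpha, v = _arrays(ratios)
    w = 1.0 / v
    sw = float(np.sum(w))
    a_fixed = float(np.sum(w * alpha) / sw)
    q = float(np.sum(w * (alpha - a_fixed) ** 2))
    df = len(ratios) - 1
    c = sw - float(np.sum(w ** 2)) / sw
    return max(0.0, (q - df) / c) if c > 0 else 0.0


def random_effects_pool(
    ratios: Sequence[WaldRatio], scale: str = "log_odds"
) -> PooledEstimate:
    """DerSimonian-Laird random-effects pooled estimate.

    Weights are deflated to w_i* = 1/(v_i + tau^2); with a homogeneous set
    (Q <= df) tau^2 truncates to zero and the result equals the fixed-effects
    pool exactly. A single ratio degrades to the fixed model with a warning.
    """
    if len(ratios) == 0:
        raise InputError("random_effects_pool: empty instrument set")
    if len(ratios) == 1:
        import warnings

        warnings.warn("single instrument: random-effects degrades to fixed-effects")
        return fixed_effects_pool(ratios, scale=scale)
    alpha, v = _arrays(ratios)
    tau2 = dl_tau2(ratios)
    a, se = _pool(alpha, v + tau2)
    het = heterogeneity_stats(ratios)
    return _finish(RANDOM, a, se, len(ratios), het, scale)


def heterogeneity_stats(ratios: Sequence[WaldRatio]) -> HeterogeneityStats:
    """Cochran's Q, DL tau^2, I^2 and the Higgins-Thompson test-based I^2 CI.

    The CI is built on ln H (H^2 = Q/df): for Q > df the SE of ln H is
    (ln Q - ln df) / (2 (sqrt(2Q) - sqrt(2 df - 1))); otherwise
    sqrt(1/(2(df-1)) * (1 - 1/(3 (df-1)^2))). H bounds are mapped back through
    I^2 = (H^2-1)/H^2 and truncated to [0, 100]. The test-based CI need not
    contain the point estimate and with df = 1 (two instruments) the
    homogeneous-case SE is undefined, so the CI degrades to (0, 100).
    """
    n = len(ratios)
    if n < 2:
        raise InputError("heterogeneity_stats: need at least 2 instruments")
    alpha, v = _arrays(ratios)
    w = 1.0 / v
    a_fixed = float(np.sum(w * alpha) / np.sum(w))
    q = float(np.sum(w * (alpha - a_fixed) ** 2))
    df = n - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0

    if q > df:
        ln_h = 0.5 * (math.log(q) - math.log(df))
        se_ln_h = 0.5 * (math.log(q) - math.log(df)) / (
            math.sqrt(2.0 * q) - math.sqrt(2.0 * df - 1.0)
        )
    else:
        ln_h = 0.0
        if df >= 2:
            se_ln_h = math.sqrt(
                1.0 / (2.0 * (df - 1)) * (1.0 - 1.0 / (3.0 * (df - 1) ** 2))
            )
        else:
            se_ln_h = math.inf

    def _i2_from_ln_h(x: float) -> float:
        if math.isinf(x):
            return 100.0 if x > 0 else 0.0
        h2 = math.exp(2.0 * x)
        return min(100.0, max(0.0, (h2 - 1.0) / h2 * 100.0))

    lo = _i2_from_ln_h(ln_h - Z95 * se_ln_h) if math.isfinite(se_ln_h) else 0.0
    hi = _i2_from_ln_h(ln_h + Z95 * se_ln_h) if math.isfinite(se_ln_h) else 100.0
    return HeterogeneityStats(
        q=q, df=df, tau2=dl_tau2(ratios), i2=i2, i2_ci_low=lo, i2_ci_high=hi
    )
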