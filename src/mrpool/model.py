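"""Statsmodels-style front end: MRModel.fit() -> MRResults.

The model is the two-sample summary-data Mendelian randomization estimator:
per-instrument Wald ratios pooled by inverse-variance weighting, with the
DerSimonian-Laird random-effects model as the default. ``MRResults`` carries
the pooled estimate, its uncertainty, heterogeneity diagnostics, the per-SNP
forest-plot data, and sensitivity analyses (leave-one-out, bounded subset
scan, mechanism subgroups).

Example
-------
>>> from mrpool.datasets import load_t2d_instruments
>>> from mrpool.model import MRModel
>>> res = MRModel.from_instruments(load_t2d_instruments()).fit()
>>> round(res.odds_ratio, 2)
1.11
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import heterogeneity as _het
from . import mr_core, subgroup as _subgroup
from .exceptions import InputError
from .mr_core import Z95, PooledEstimate, WaldRatio
from .summary_data import InstrumentRecord


class MRModel:
    """Two-sample summary-data MR model for one exposure/outcome pair.

    Parameters
    ----------
    gamma, se_gamma : array-like
        Instrument effects on the exposure and their SEs.
    beta, se_beta : array-like
        Instrument effects on the outcome (log-odds), aligned to the same
        effect alleles, and their SEs.
    snp_ids : sequence of str, optional
    clusters : sequence of str or None, optional
        Mechanism-cluster label per instrument.
    exposure, outcome : str
        Trait names used in the summary table.
    scale : {"log_odds", "trait_units"}
        Scale of ``gamma``; determines whether the pooled effect is reported
        as an odds ratio per unit log-odds or per trait unit of exposure.
    """

    def __init__(self, gamma, se_gamma, beta, se_beta, snp_ids=None,
                 clusters=None, loci=None, exposure="exposure",
                 outcome="outcome", scale="log_odds"):
        self.gamma = np.asarray(gamma, dtype=float)
        self.se_gamma = np.asarray(se_gamma, dtype=float)
        self.beta = np.asarray(beta, dtype=float)
        self.se_beta = np.asarray(se_beta, dtype=float)
        n = len(self.gamma)
        if not (len(self.se_gamma) == len(self.beta) == len(self.se_beta) == n):
            raise InputError("MRModel: input arrays must have equal length")
        if n == 0:
            raise InputError("MRModel: empty instrument set")
        self.snp_ids = list(snp_ids) if snp_ids is not None else [f"snp{i}" for i in range(n)]
        self.clusters = list(clusters) if clusters is not None else [None] * n
        self.loci = list(loci) if loci is not None else [""] * n
        self.exposure = exposure
        self.outcome = outcome
        self.scale = scale
        self._instruments = [
            InstrumentRecord(
                snp_id=self.snp_ids[i], gamma=float(self.gamma[i]),
                se_gamma=float(self.se_gamma[i]), beta=float(self.beta[i]),
                se_beta=float(self.se_beta[i]), cluster=self.clusters[i],
                locus=self.loci[i],
            )
            for i in range(n)
        ]

    @classmethod
    def from_instruments(cls, instruments: Sequence[InstrumentRecord],
                         exposure="exposure", outcome="outcome",
                         scale="log_odds") -> "MRModel":
        return cls(
            gamma=[r.gamma for r in instruments],
            se_gamma=[r.se_gamma for r in instruments],
            beta=[r.beta for r in instruments],
            se_beta=[r.se_beta for r in instruments],
            snp_ids=[r.snp_id for r in instruments],
            clusters=[r.cluster for r in instruments],
            loci=[r.locus for r in instruments],
            exposure=exposure, outcome=outcome, scale=scale,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, gamma="gamma", se_gamma="se_gamma",
                       beta="beta", se_beta="se_beta", snp_id="snp_id",
                       cluster=None, **kwargs) -> "MRModel":
        return cls(
            gamma=df[gamma], se_gamma=df[se_gamma], beta=df[beta],
            se_beta=df[se_beta],
            snp_ids=df[snp_id] if snp_id in df else None,
            clusters=df[cluster] if cluster and cluster in df else None,
            **kwargs,
        )

    @property
    def instruments(self) -> list[InstrumentRecord]:
        return list(self._instruments)

    @property
    def n_instruments(self) -> int:
        return len(self._instruments)

    def wald_ratios(self) -> list[WaldRatio]:
        return mr_core.wald_ratios(self._instruments)

    def fit(self, method: str = "random") -> "MRResults":
        """Pool the Wald ratios. ``method`` is ``"random"`` (DL) or ``"fixed"``."""
        ratios = self.wald_ratios()
        if method == "random":
            pooled = mr_core.random_effects_pool(ratios)
        elif method == "fixed":
            pooled = mr_core.fixed_effects_pool(ratios)
        else:
            raise InputError(f"MRModel.fit: unknown method {method!r}")
        return MRResults(self, pooled, ratios)


class MRResults:
    """Fitted pooled MR estimate with diagnostics and sensitivity analyses."""

    def __init__(self, model: MRModel, pooled: PooledEstimate,
                 ratios: Sequence[WaldRatio]):
        self.model = model
        self.pooled = pooled
        self.ratios = list(ratios)

    # -- scalar accessors ---------------------------------------------------
    @property
    def alpha(self) -> float:
        """Pooled causal effect on the log-odds scale."""
        return self.pooled.alpha

    @property
    def bse(self) -> float:
        return self.pooled.se

    @property
    def odds_ratio(self) -> float:
        return self.pooled.or_scale

    @property
    def pvalue(self) -> float:
        return self.pooled.p_value

    @property
    def heterogeneity(self) -> mr_core.HeterogeneityStats | None:
        return self.pooled.het

    @property
    def i2(self) -> float:
        return self.pooled.het.i2 if self.pooled.het else 0.0

    def conf_int(self, exp: bool = True) -> tuple[float, float]:
        """95% CI, on the odds-ratio scale by default."""
        lo = self.alpha - Z95 * self.bse
        hi = self.alpha + Z95 * self.bse
        if exp:
            return float(np.exp(lo)), float(np.exp(hi))
        return lo, hi

    # -- per-SNP forest data ------------------------------------------------
    def forest_data(self) -> pd.DataFrame:
        """Per-instrument rows plus the pooled row: the data behind a forest plot."""
        w_total = sum(r.w_i for r in self.ratios)
        rows = []
        for r in self.ratios:
            se_i = np.sqrt(r.v_i)
            rows.append({
                "snp_id": r.snp_id,
                "locus": r.locus,
                "alpha_i": r.alpha_i,
                "v_i": r.v_i,
                "weight_pct": 100.0 * r.w_i / w_total,
                "or": np.exp(r.alpha_i),
                "or_ci_low": np.exp(r.alpha_i - Z95 * se_i),
                "or_ci_high": np.exp(r.alpha_i + Z95 * se_i),
            })
        lo, hi = self.conf_int()
        rows.append({
            "snp_id": f"pooled ({self.pooled.model})",
            "locus": "",
            "alpha_i": self.alpha, "v_i": self.bse ** 2, "weight_pct": 100.0,
            "or": self.odds_ratio, "or_ci_low": lo, "or_ci_high": hi,
        })
        return pd.DataFrame(rows)

    # -- sensitivity --------------------------------------------------------
    def leave_one_out(self) -> list[_het.SubsetResult]:
        return _het.leave_one_out(self.ratios)

    def subset_scan(self, max_remove: int = _het.DEFAULT_MAX_REMOVE,
                    rank_by: str = "i2", budget: int = _het.DEFAULT_BUDGET):
        return _het.subset_scan(self.ratios, max_remove=max_remove,
                                rank_by=rank_by, budget=budget)

    def subgroups(self, assignments, grouping=_subgroup.BC_VS_REST,
                  min_size: int = 3) -> _subgroup.SubgroupReport:
        return _subgroup.subgroup_estimates(
            self.model.instruments, assignments, grouping=grouping,
            min_size=min_size,
        )

    # -- presentation -------------------------------------------------------
    def summary(self) -> str:
        p = self.pooled
        lo, hi = self.conf_int()
        unit = ("per unit log-odds of " if self.model.scale == "log_odds"
                else "per unit ") + self.model.exposure
        lines = [
            "Mendelian randomization estimate"
            f" ({p.model}-effects, n={p.n_instruments} instruments)",
            f"  exposure: {self.model.exposure}    outcome: {self.model.outcome}",
            f"  OR ({self.model.outcome}) {unit}: "
            f"{p.or_scale:.2f} (95% CI {lo:.2f}-{hi:.2f})",
            f"  alpha = {p.alpha:.4f}  se = {p.se:.4f}  P = {p.p_value:.2e}",
        ]
        if p.het is not None:
            h = p.het
            lines.append(
                f"  heterogeneity: Q = {h.q:.2f} (df {h.df}), tau2 = {h.tau2:.5f}, "
                f"I2 = {h.i2:.1f}% (95% CI {h.i2_ci_low:.1f}-{h.i2_ci_high:.1f}%)"
            )
        return "\n".join(lines)

    def plot_forest(self, ax=None):
        """Forest plot of per-SNP ORs and the pooled estimate (needs matplotlib)."""
        import matplotlib.pyplot as plt

        data = self.forest_data()
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.3 * len(data) + 1))
        y = np.arange(len(data))[::-1]
        ax.hlines(y, data["or_ci_low"], data["or_ci_high"], color="0.2", lw=1)
        sizes = 20 + 2 * data["weight_pct"]
        ax.scatter(data["or"], y, s=sizes, marker="s", color="0.4", zorder=3)
        ax.axvline(1.0, color="0.7", ls="--", lw=0.8)
        ax.set_yticks(y)
        ax.set_yticklabels(data["snp_id"])
        ax.set_xlabel(f"OR for {self.model.outcome}")
        ax.set_xscale("log")
        return ax

    def __repr__(self) -> str:
        return (f"<MRResults {self.pooled.model} n={self.pooled.n_instruments} "
                f"OR={self.odds_ratio:.3f}>")
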