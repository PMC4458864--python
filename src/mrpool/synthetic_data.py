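"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the statistical structure of a summary-level MR
study: per SNP i a true instrument effect gamma_i on the exposure, an
outcome effect beta_i = alpha * gamma_i plus (for a configurable fraction of
SNPs) a pleiotropic direct effect delta_i, Gaussian sampling noise with
known SEs on both, and a matrix of confounder-trait P values that is
Uniform(0,1) for clean SNPs and anti-conservative for pleiotropic ones.
Because the latent truth is recorded alongside the emitted tables, every
pipeline stage — readers, harmonization, CPMA screening, pooling — can be
tested end to end without external data.

The default configuration mirrors the scale of the motivating T2D study:
26 instruments with per-allele exposure ORs in the 1.07-1.18 range,
outcome-effect SEs around 0.01-0.02, and a true causal log-odds ratio of
ln(1.11).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import mr_core, pleiotropy as _pleio
from .exceptions import InputError
from .summary_data import InstrumentRecord

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"),
                 ("C", "A"), ("G", "T"), ("C", "T")]  # non-palindromic


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated two-sample MR dataset.

    ``gamma_dist`` is (mean, sd) of the true per-allele exposure log-odds;
    the default (0.10, 0.025) spans roughly OR 1.05-1.16 per allele.
    ``confounder_effect`` is the mean |z| of a pleiotropic SNP's confounder
    associations (noncentrality of the underlying normal test statistic).
    """

    n_snps: int = 26
    true_alpha: float = math.log(1.11)
    gamma_dist: tuple[float, float] = (0.10, 0.025)
    se_gamma: float = 0.015
    se_beta: float = 0.015
    pleiotropy_fraction: float = 0.0
    direct_effect_dist: tuple[float, float] = (0.0, 0.02)
    n_confounders: int = 5
    confounder_effect: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 2:
            raise InputError("SimulationConfig: n_snps must be >= 2")
        if not (0.0 <= self.pleiotropy_fraction <= 1.0):
            raise InputError("SimulationConfig: pleiotropy_fraction must be in [0, 1]")
        for name in ("gamma_dist", "direct_effect_dist"):
            if getattr(self, name)[1] < 0:
                raise InputError(f"SimulationConfig: {name} sd must be >= 0")
        if self.se_gamma <= 0 or self.se_beta <= 0:
            raise InputError("SimulationConfig: SEs must be > 0")


def generate_study(config: SimulationConfig):
    """Draw one simulated study.

    Returns ``(exposure_df, outcome_df, confounder_df, truth)``: two
    summary-association tables in the TSV dialect the readers consume
    (columns snp, locus, ea, nea, effect, se, p), a SNP-by-trait confounder
    P-value matrix, and a truth dict holding every latent draw. Identical
    seeds give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_snps
    snp_ids = [f"rs{900000 + i}" for i in range(n)]
    alleles = [_ALLELE_PAIRS[int(rng.integers(len(_ALLELE_PAIRS)))] for _ in range(n)]

    gamma_true = rng.normal(*config.gamma_dist, size=n)
    n_pleio = int(round(config.pleiotropy_fraction * n))
    pleio_mask = np.zeros(n, dtype=bool)
    pleio_mask[rng.choice(n, size=n_pleio, replace=False)] = True
    delta = np.where(pleio_mask, rng.normal(*config.direct_effect_dist, size=n), 0.0)

    gamma_hat = gamma_true + rng.normal(0.0, config.se_gamma, size=n)
    beta_true = config.true_alpha * gamma_true + delta
    beta_hat = beta_true + rng.normal(0.0, config.se_beta, size=n)

    def _p(effect, se):
        return 2.0 * stats.norm.sf(np.abs(effect) / se)

    def _table(effect, se):
        return pd.DataFrame({
            "snp": snp_ids,
            "locus": [f"locus{i}" for i in range(n)],
            "ea": [a for a, _ in alleles],
            "nea": [b for _, b in alleles],
            "effect": effect,
            "se": np.full(n, se),
            "p": np.clip(_p(effect, se), np.nextafter(0, 1), 1.0),
        })

    exposure_df = _table(gamma_hat, config.se_gamma)
    outcome_df = _table(beta_hat, config.se_beta)

    traits = [f"trait{j}" for j in range(config.n_confounders)]
    z = rng.normal(0.0, 1.0, size=(n, config.n_confounders))
    z[pleio_mask] += config.confounder_effect * rng.choice(
        [-1.0, 1.0], size=(int(pleio_mask.sum()), config.n_confounders)
    )
    conf_p = 2.0 * stats.norm.sf(np.abs(z))
    conf_p = np.clip(conf_p, np.nextafter(0, 1), 1.0)
    confounder_df = pd.DataFrame(conf_p, index=snp_ids, columns=traits)
    confounder_df.index.name = "snp"

    truth = {
        "config": asdict(config),
        "snp_ids": snp_ids,
        "gamma_true": gamma_true.tolist(),
        "beta_true": beta_true.tolist(),
        "delta": delta.tolist(),
        "pleiotropic": pleio_mask.tolist(),
    }
    return exposure_df, outcome_df, confounder_df, truth


def instruments_from_tables(exposure_df: pd.DataFrame, outcome_df: pd.DataFrame) -> list[InstrumentRecord]:
    """Pair simulated exposure/outcome tables into InstrumentRecords."""
    out = outcome_df.set_index("snp")
    return [
        InstrumentRecord(
            snp_id=row["snp"], locus=row["locus"],
            gamma=float(row["effect"]), se_gamma=float(row["se"]),
            beta=float(out.loc[row["snp"], "effect"]),
            se_beta=float(out.loc[row["snp"], "se"]),
        )
        for _, row in exposure_df.iterrows()
    ]


def write_study(exposure_df, outcome_df, confounder_df, truth, outdir) -> None:
    """Emit one study as TSVs plus a JSON truth record."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exposure_df.to_csv(outdir / "exposure.tsv", sep="\t", index=False)
    outcome_df.to_csv(outdir / "outcome.tsv", sep="\t", index=False)
    confounder_df.to_csv(outdir / "confounders.tsv", sep="\t")
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


def recovery_experiment(
    config: SimulationConfig,
    n_reps: int = 100,
    with_screening: bool = False,
    screening_threshold: float = _pleio.DEFAULT_THRESHOLD,
) -> dict:
    """Monte-Carlo parameter recovery over ``n_reps`` independent studies.

    Each replicate generates a study, optionally CPMA-screens on the
    confounder matrix, pools the Wald ratios with the DL random-effects
    model, and records the estimate, CI coverage of the true alpha, and I^2.
    Returns aggregate bias, RMSE, coverage and mean I^2, each with a
    Monte-Carlo standard error.
    """
    if n_reps < 2:
        raise InputError("recovery_experiment: n_reps must be >= 2")
    est, cover, i2s, n_kept = [], [], [], []
    for rep in range(n_reps):
        cfg = SimulationConfig(**{**asdict(config), "seed": config.seed + rep})
        exposure_df, outcome_df, confounder_df, truth = generate_study(cfg)
        instruments = instruments_from_tables(exposure_df, outcome_df)
        if with_screening:
            profiles = [
                _pleio.profile_snp(s, confounder_df.loc[s].to_dict(),
                                   threshold=screening_threshold)
                for s in confounder_df.index
            ]
            keep, _ = _pleio.screen_instruments(profiles, threshold=screening_threshold)
            keep_set = set(keep)
            instruments = [r for r in instruments if r.snp_id in keep_set]
        if len(instruments) < 2:
            continue
        pooled = mr_core.random_effects_pool(mr_core.wald_ratios(instruments))
        est.append(pooled.alpha)
        lo = pooled.alpha - mr_core.Z95 * pooled.se
        hi = pooled.alpha + mr_core.Z95 * pooled.se
        cover.append(lo <= config.true_alpha <= hi)
        i2s.append(pooled.het.i2)
        n_kept.append(len(instruments))

    est = np.asarray(est)
    cover = np.asarray(cover, dtype=float)
    i2s = np.asarray(i2s)
    k = len(est)
    err = est - config.true_alpha
    return {
        "n_reps_used": k,
        "bias": float(err.mean()),
        "bias_mc_se": float(err.std(ddof=1) / math.sqrt(k)),
        "rmse": float(np.sqrt((err ** 2).mean())),
        "coverage": float(cover.mean()),
        "coverage_mc_se": float(cover.std(ddof=1) / math.sqrt(k)),
        "mean_i2": float(i2s.mean()),
        "mean_i2_mc_se": float(i2s.std(ddof=1) / math.sqrt(k)),
        "mean_n_instruments": float(np.mean(n_kept)),
    }
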