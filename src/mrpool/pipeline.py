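"""End-to-end analysis runs: read -> harmonize -> screen -> pool -> report.

``run_analysis`` executes the full summary-data MR workflow under one
:class:`RunConfig` and writes a fixed set of deterministic report files to
the output directory:

``report.json``      full-precision machine-readable results
``pooled.tsv``       pooled estimates (candidate set, instrument set)
``per_snp.tsv``      per-instrument forest-plot rows
``subset_scan.tsv``  top-ranked leave-k-out subsets
``subgroups.tsv``    mechanism-subgroup estimates (when clusters provided)
``run.log``          every excluded SNP with its reason

Human-readable TSVs round ORs/CIs to 2 decimals and I^2 to 1 decimal; the
JSON report keeps full precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import heterogeneity as _het
from . import mr_core, pleiotropy as _pleio, subgroup as _subgroup
from .exceptions import InputError
from .mr_core import PooledEstimate, Z95
from .summary_data import (
    AssociationRecord,
    InstrumentRecord,
    TableSchema,
    harmonize,
    impute_missing_se,
    read_association_table,
    reconstruct_se,
)

logger = logging.getLogger(__name__)

SCREEN_CPMA = "cpma"
SCREEN_FIXTURE_LABELS = "fixture_labels"
SCREEN_NONE = "none"


@dataclass
class RunConfig:
    """Configuration for one end-to-end analysis run."""

    exposure_path: str
    exposure_schema: TableSchema
    outcome_path: str
    outcome_schema: TableSchema
    confounder_path: str | None = None
    cluster_path: str | None = None
    label_column: str | None = None     # pleiotropy labels in the exposure file
    cluster_column: str | None = None   # physiologic clusters in the exposure file
    screening: str = SCREEN_FIXTURE_LABELS
    screening_threshold: float = _pleio.DEFAULT_THRESHOLD
    se_policy: str = "median"
    palindrome_policy: str = "flag"
    max_remove: int = 3
    min_group_size: int = 3
    subgroup_grouping: str = _subgroup.BC_VS_REST
    scale: str = "log_odds"
    top_subsets: int = 20
    seed: int = 0
    output_dir: str = "mr_output"

    def __post_init__(self):
        if self.screening not in (SCREEN_CPMA, SCREEN_FIXTURE_LABELS, SCREEN_NONE):
            raise InputError(f"unknown screening mode {self.screening!r}")
        if self.screening == SCREEN_CPMA and not self.confounder_path:
            raise InputError("screening=cpma requires confounder_path")
        if self.screening == SCREEN_FIXTURE_LABELS and not self.label_column:
            raise InputError("screening=fixture_labels requires label_column")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        for key in ("exposure_schema", "outcome_schema"):
            raw[key] = TableSchema(**raw[key])
        return cls(**raw)


@dataclass
class AnalysisReport:
    """All results of one run, plus the paths the reports were written to."""

    candidate: PooledEstimate
    instrument: PooledEstimate | None
    per_allele: PooledEstimate
    instruments: list[InstrumentRecord]
    candidate_instruments: list[InstrumentRecord]
    excluded: dict[str, str]            # snp_id -> reason
    subset_results: list[_het.SubsetResult]
    subgroups: _subgroup.SubgroupReport | None
    output_dir: str | None = None


def _with_reconstructed_se(records: Sequence[AssociationRecord]) -> list[AssociationRecord]:
    from dataclasses import replace

    out = []
    for r in records:
        if r.se is not None:
            out.append(r)
            continue
        se = reconstruct_se(r.effect, r.p_value)
        out.append(replace(r, se=None if se != se else se))
    return out


def _build_instruments(
    exposures: Sequence[AssociationRecord],
    outcomes_by_id: dict[str, AssociationRecord],
    config: RunConfig,
    excluded: dict[str, str],
) -> list[InstrumentRecord]:
    """Impute outcome SEs within this set, then harmonize pair by pair."""
    from dataclasses import replace

    outs = [outcomes_by_id[r.snp_id] for r in exposures]
    imputed_ids = {r.snp_id for r in outs if r.se is None}
    outs = impute_missing_se(outs, policy=config.se_policy)
    kept_out = {r.snp_id: r for r in outs}
    instruments = []
    for exp in exposures:
        if exp.snp_id not in kept_out:
            excluded[exp.snp_id] = "outcome SE undefined (dropped by se_policy)"
            continue
        if exp.se is None:
            excluded[exp.snp_id] = "exposure SE undefined"
            continue
        instr = harmonize(exp, kept_out[exp.snp_id],
                          palindrome_policy=config.palindrome_policy)
        if instr is None:
            excluded[exp.snp_id] = "palindromic SNP dropped"
            continue
        instruments.append(replace(instr, se_beta_imputed=exp.snp_id in imputed_ids))
    return instruments


def allele_effect_meta(
    records: Sequence[AssociationRecord], scale: str | None = None
) -> PooledEstimate:
    """Random-effects meta-analysis of the per-allele exposure effects.

    Summarizes what the "typical" significant risk allele does to the
    exposure itself, on the exposure's native scale (OR for a binary trait,
    trait units otherwise).
    """
    records = _with_reconstructed_se(records)
    usable = [r for r in records if r.se is not None]
    if len(usable) < 2:
        raise InputError("allele_effect_meta: need >= 2 records with defined SEs")
    ratios = [
        mr_core.WaldRatio(snp_id=r.snp_id, alpha_i=r.effect, v_i=r.se ** 2,
                          w_i=r.se ** -2, locus=r.locus)
        for r in usable
    ]
    if scale is None:
        scale = usable[0].effect_scale
    return mr_core.random_effects_pool(ratios, scale=scale)


def _screen(
    exposures: Sequence[AssociationRecord],
    config: RunConfig,
    labels: dict[str, bool] | None,
    excluded: dict[str, str],
) -> list[AssociationRecord]:
    if config.screening == SCREEN_NONE:
        return list(exposures)
    if config.screening == SCREEN_FIXTURE_LABELS:
        assert labels is not None
        kept = []
        for r in exposures:
            if labels.get(r.snp_id, False):
                excluded[r.snp_id] = "pleiotropic (fixture label)"
            else:
                kept.append(r)
        return kept
    conf = pd.read_csv(config.confounder_path, sep="\t", index_col=0)
    kept = []
    for r in exposures:
        if r.snp_id not in conf.index:
            excluded[r.snp_id] = "no confounder P values"
            continue
        prof = _pleio.profile_snp(r.snp_id, conf.loc[r.snp_id].to_dict(),
                                  threshold=config.screening_threshold)
        if prof.is_pleiotropic:
            excluded[r.snp_id] = f"pleiotropic (CPMA P={prof.cpma_p:.2e})"
        else:
            kept.append(r)
    return kept


def run_analysis(config: RunConfig, write: bool = True) -> AnalysisReport:
    """Execute the full pipeline under ``config``; optionally write reports."""
    exposures = _with_reconstructed_se(
        read_association_table(config.exposure_path, config.exposure_schema))
    outcomes = _with_reconstructed_se(
        read_association_table(config.outcome_path, config.outcome_schema))
    outcomes_by_id = {r.snp_id: r for r in outcomes}

    excluded: dict[str, str] = {}
    matched = []
    for r in exposures:
        if r.snp_id in outcomes_by_id:
            matched.append(r)
        else:
            excluded[r.snp_id] = "missing outcome data"

    labels = clusters = None
    if config.label_column or config.cluster_column:
        raw = pd.read_csv(config.exposure_path, sep="\t", keep_default_na=False)
        snp_col = config.exposure_schema.snp_id
        if config.label_column:
            labels = {s: str(v).strip().lower() in ("yes", "true", "1")
                      for s, v in zip(raw[snp_col], raw[config.label_column])}
        if config.cluster_column:
            clusters = {s: str(v) for s, v in zip(raw[snp_col], raw[config.cluster_column])}
    if config.cluster_path:
        clusters = {a.snp_id: a.cluster
                    for a in _subgroup.read_cluster_table(config.cluster_path)}

    per_allele = allele_effect_meta(matched)

    candidate_instr = _build_instruments(matched, outcomes_by_id, config, excluded)
    candidate = mr_core.random_effects_pool(
        mr_core.wald_ratios(candidate_instr), scale=config.scale)

    instrument = None
    instrument_instr: list[InstrumentRecord] = []
    subset_results: list[_het.SubsetResult] = []
    subgroups = None
    if config.screening != SCREEN_NONE:
        screened = _screen(matched, config, labels, excluded)
        if not screened:
            raise InputError("screening removed every candidate instrument")
        instrument_instr = _build_instruments(screened, outcomes_by_id, config, excluded)
        if not instrument_instr:
            raise InputError("no instruments left after harmonization/imputation")
        ratios = mr_core.wald_ratios(instrument_instr)
        instrument = mr_core.random_effects_pool(ratios, scale=config.scale)
        if len(ratios) > config.max_remove and config.max_remove > 0:
            subset_results = _het.subset_scan(ratios, max_remove=config.max_remove)
        if clusters:
            from dataclasses import replace

            assigned = [replace(r, cluster=clusters.get(r.snp_id))
                        for r in instrument_instr]
            assignments = [_subgroup.ClusterAssignment(r.snp_id, clusters[r.snp_id])
                           for r in assigned if r.snp_id in clusters]
            try:
                subgroups = _subgroup.subgroup_estimates(
                    assigned, assignments, grouping=config.subgroup_grouping,
                    min_size=config.min_group_size)
            except InputError as exc:
                logger.warning("subgroup analysis skipped: %s", exc)

    report = AnalysisReport(
        candidate=candidate, instrument=instrument, per_allele=per_allele,
        instruments=instrument_instr, candidate_instruments=candidate_instr,
        excluded=excluded, subset_results=subset_results, subgroups=subgroups,
    )
    if write:
        report.output_dir = str(config.output_dir)
        _write_reports(report, config)
    return report


# ---------------------------------------------------------------------------
# report writers


def _pooled_row(name: str, est: PooledEstimate) -> dict:
    h = est.het
    return {
        "analysis": name,
        "model": est.model,
        "n": est.n_instruments,
        "estimate": f"{est.estimate:.2f}",
        "ci_low": f"{est.ci_low:.2f}",
        "ci_high": f"{est.ci_high:.2f}",
        "p_value": f"{est.p_value:.1e}",
        "i2": f"{h.i2:.1f}" if h else "",
        "i2_ci": f"{h.i2_ci_low:.1f}-{h.i2_ci_high:.1f}" if h else "",
    }


def _est_json(est: PooledEstimate | None) -> dict | None:
    if est is None:
        return None
    d = asdict(est)
    return d


def _write_reports(report: AnalysisReport, config: RunConfig) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    rows = [_pooled_row("per_allele_exposure", report.per_allele),
            _pooled_row("candidate_set", report.candidate)]
    if report.instrument is not None:
        rows.append(_pooled_row("instrument_set", report.instrument))
    if report.subgroups is not None:
        for name, est in sorted(report.subgroups.estimates.items()):
            rows.append(_pooled_row(f"subgroup:{name}", est))
    pd.DataFrame(rows).to_csv(outdir / "pooled.tsv", sep="\t", index=False)

    import math

    instr = report.instruments or report.candidate_instruments
    ratios = mr_core.wald_ratios(instr)
    w_total = sum(r.w_i for r in ratios)
    per_snp = pd.DataFrame([
        {
            "snp_id": r.snp_id, "locus": r.locus,
            "alpha_i": repr(r.alpha_i), "v_i": repr(r.v_i),
            "weight_pct": f"{100.0 * r.w_i / w_total:.1f}",
            "or": f"{math.exp(r.alpha_i):.2f}",
            "or_ci_low": f"{math.exp(r.alpha_i - Z95 * math.sqrt(r.v_i)):.2f}",
            "or_ci_high": f"{math.exp(r.alpha_i + Z95 * math.sqrt(r.v_i)):.2f}",
        }
        for r in ratios
    ])
    per_snp.to_csv(outdir / "per_snp.tsv", sep="\t", index=False)

    if report.subset_results:
        top = report.subset_results[: config.top_subsets]
        pd.DataFrame([
            {
                "removed": ",".join(sorted(s.removed_snps)) or "(none)",
                "n": s.n_remaining,
                "or": f"{s.pooled.or_scale:.2f}",
                "ci_low": f"{s.pooled.ci_low:.2f}",
                "ci_high": f"{s.pooled.ci_high:.2f}",
                "p_value": f"{s.pooled.p_value:.1e}",
                "q": f"{s.q:.2f}",
                "i2": f"{s.i2:.1f}",
            }
            for s in top
        ]).to_csv(outdir / "subset_scan.tsv", sep="\t", index=False)

    if report.subgroups is not None:
        pd.DataFrame([
            {
                "group": name,
                "n": est.n_instruments,
                "or": f"{est.or_scale:.2f}",
                "ci_low": f"{est.ci_low:.2f}",
                "ci_high": f"{est.ci_high:.2f}",
                "p_value": f"{est.p_value:.1e}",
                "i2": f"{est.het.i2:.1f}" if est.het else "",
                "members": ",".join(report.subgroups.members[name]),
            }
            for name, est in sorted(report.subgroups.estimates.items())
        ]).to_csv(outdir / "subgroups.tsv", sep="\t", index=False)

    payload = {
        "per_allele": _est_json(report.per_allele),
        "candidate": _est_json(report.candidate),
        "instrument": _est_json(report.instrument),
        "excluded": report.excluded,
        "n_subset_results": len(report.subset_results),
        "subgroups": {
            name: _est_json(est)
            for name, est in (report.subgroups.estimates.items()
                              if report.subgroups else [])
        },
    }
    (outdir / "report.json").write_text(json.dumps(payload, indent=1, sort_keys=True))

    with open(outdir / "run.log", "w") as fh:
        for snp, reason in sorted(report.excluded.items()):
            fh.write(f"{snp}\t{reason}\n")
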