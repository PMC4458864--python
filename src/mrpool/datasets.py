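"""Bundled per-SNP summary tables and ready-made instrument sets.

Two transcribed GWAS summary tables ship with the package:

``t2d_table1.tsv``
    37 genome-wide significant T2D risk variants (DIAGRAMv3 exposure ORs)
    with their CHD ORs (CARDIoGRAMplusC4D / CARDIoGRAM), a per-SNP
    pleiotropy call against five confounder traits, and the Dimas et al.
    physiologic-cluster label.
``fg_table4.tsv``
    33 genome-wide significant fasting-glucose variants (MAGIC, effects in
    mmol/l per allele) with their CHD ORs and pleiotropy calls.

Both tables print effects to 2 decimals and P values to 2 significant
figures and omit SEs; SEs are reconstructed from the (effect, P) pairs and
median-imputed where the outcome OR is printed as 1.00.
"""

from __future__ import annotations

from dataclasses import replace
from importlib import resources
from math import log

import pandas as pd

from .subgroup import ClusterAssignment
from .summary_data import (
    AssociationRecord,
    InstrumentRecord,
    LOG_ODDS,
    TRAIT_UNITS,
    harmonize,
    impute_missing_se,
    reconstruct_se,
)


def _data_path(name: str):
    return resources.files("mrpool.data").joinpath(name)


def load_t2d_table1() -> pd.DataFrame:
    """The 37-SNP T2D candidate table as a DataFrame, in printed row order."""
    with resources.as_file(_data_path("t2d_table1.tsv")) as p:
        # keep_default_na: the "NA" cluster code is a label, not missing data
        return pd.read_csv(p, sep="\t", keep_default_na=False)


def load_fg_table4() -> pd.DataFrame:
    """The 33-SNP fasting-glucose candidate table, in printed row order."""
    with resources.as_file(_data_path("fg_table4.tsv")) as p:
        return pd.read_csv(p, sep="\t", keep_default_na=False)


def _se_or_none(effect: float, p: float) -> float | None:
    se = reconstruct_se(effect, p)
    return None if se != se else se  # nan -> undefined


def build_instruments(
    df: pd.DataFrame,
    gamma_column: str,
    gamma_is_or: bool,
    exposure_trait: str,
    screened: bool = True,
    se_policy: str = "median",
) -> list[InstrumentRecord]:
    """Harmonized instruments from a fixture-style table.

    With ``screened=True`` only rows whose pleiotropy call is "No" are used.
    SE imputation (for outcome ORs printed as 1.00) is computed *within the
    selected set*, so the candidate-set and instrument-set analyses each use
    their own median.
    """
    sel = df if not screened else df[df["pleiotropic"] == "No"]
    exp_records, out_records = [], []
    for _, row in sel.iterrows():
        gamma = log(row[gamma_column]) if gamma_is_or else float(row[gamma_column])
        exp_records.append(AssociationRecord(
            snp_id=row["snp"], effect_allele=row["ea"], other_allele=row["nea"],
            effect=gamma, p_value=float(row["p_exposure"]),
            se=_se_or_none(gamma, float(row["p_exposure"])),
            effect_scale=LOG_ODDS if gamma_is_or else TRAIT_UNITS,
            locus=row["locus"], trait_id=exposure_trait,
        ))
        beta = log(row["or_outcome"])
        out_records.append(AssociationRecord(
            snp_id=row["snp"], effect_allele=row["ea"], other_allele=row["nea"],
            effect=beta, p_value=float(row["p_outcome"]),
            se=_se_or_none(beta, float(row["p_outcome"])),
            effect_scale=LOG_ODDS, locus=row["locus"], trait_id="CHD",
        ))
    imputed_ids = {r.snp_id for r in out_records if r.se is None}
    out_records = impute_missing_se(out_records, policy=se_policy)
    kept = {r.snp_id for r in out_records}

    instruments = []
    out_by_id = {r.snp_id: r for r in out_records}
    extra = dict(zip(sel["snp"], zip(sel["pleiotropic"], sel.get("cluster", [None] * len(sel)))))
    for exp in exp_records:
        if exp.snp_id not in kept:
            continue  # dropped by se_policy="drop"
        instr = harmonize(exp, out_by_id[exp.snp_id], palindrome_policy="keep")
        pleio, cluster = extra[exp.snp_id]
        instruments.append(replace(
            instr,
            se_beta_imputed=exp.snp_id in imputed_ids,
            pleiotropic=(pleio == "Yes"),
            cluster=None if cluster is None else str(cluster),
        ))
    return instruments


def load_t2d_instruments(screened: bool = True, se_policy: str = "median") -> list[InstrumentRecord]:
    """T2D->CHD instruments (n=26 screened; n=37 with ``screened=False``)."""
    return build_instruments(
        load_t2d_table1(), gamma_column="or_exposure", gamma_is_or=True,
        exposure_trait="T2D", screened=screened, se_policy=se_policy,
    )


def load_fg_instruments(screened: bool = True, se_policy: str = "median") -> list[InstrumentRecord]:
    """FG->CHD instruments on the mmol/l scale (n=24 screened; n=33 full)."""
    return build_instruments(
        load_fg_table4(), gamma_column="effect_fg", gamma_is_or=False,
        exposure_trait="FG", screened=screened, se_policy=se_policy,
    )


def load_t2d_clusters() -> list[ClusterAssignment]:
    """Physiologic-cluster assignment for every SNP in the T2D table."""
    df = load_t2d_table1()
    return [ClusterAssignment(snp_id=s, cluster=c) for s, c in zip(df["snp"], df["cluster"])]
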