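"""Mechanism-cluster subgroup estimates for T2D instruments.

Type-2 diabetes risk variants act through distinct physiology: reduced
beta-cell function (BC), insulin resistance (IR), defective pro-insulin
processing (PI), hyperglycemia per se (HG), or unclassified/unknown (UC/NA),
following the Dimas et al. clustering of T2D loci by their glycemic-trait
associations. Pooling the Wald ratios within a cluster asks whether the
causal signal on the outcome is carried by a particular mechanism.

The ``bc_vs_rest`` grouping contrasts the beta-cell cluster against every
other non-pleiotropic instrument combined (UC, NA and the singleton HG/PI
members), the only two groups large enough to pool once pleiotropic variants
are screened out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .exceptions import InputError
from .mr_core import PooledEstimate, random_effects_pool, wald_ratios
from .summary_data import InstrumentRecord

CLUSTERS = ("BC", "IR", "PI", "HG", "UC", "NA")

PER_CLUSTER = "per_cluster"
BC_VS_REST = "bc_vs_rest"


@dataclass(frozen=True)
class ClusterAssignment:
    snp_id: str
    cluster: str

    def __post_init__(self):
        if self.cluster not in CLUSTERS:
            raise ValueError(f"{self.snp_id}: unknown cluster {self.cluster!r}")


@dataclass(frozen=True)
class SubgroupReport:
    """Per-group pooled estimates plus the membership of skipped groups."""

    estimates: Mapping[str, PooledEstimate]
    members: Mapping[str, tuple[str, ...]]
    skipped: Mapping[str, tuple[str, ...]]


def subgroup_estimates(
    instruments: Sequence[InstrumentRecord],
    assignments: Sequence[ClusterAssignment],
    grouping: str = PER_CLUSTER,
    min_size: int = 3,
) -> SubgroupReport:
    """Random-effects pooled estimate per mechanism group.

    Instruments are expected to be pre-screened for pleiotropy. Groups below
    ``min_size`` are not pooled but reported with their membership under
    ``skipped``; no instrument is lost or double-counted.
    """
    if grouping not in (PER_CLUSTER, BC_VS_REST):
        raise InputError(f"subgroup_estimates: unknown grouping {grouping!r}")
    if min_size < 2:
        raise InputError("subgroup_estimates: min_size must be >= 2")
    cluster_of = {a.snp_id: a.cluster for a in assignments}
    unassigned = [r.snp_id for r in instruments if r.snp_id not in cluster_of]
    if unassigned:
        raise InputError(f"subgroup_estimates: no cluster for {unassigned}")

    groups: dict[str, list[InstrumentRecord]] = {}
    for rec in instruments:
        if grouping == BC_VS_REST:
            name = "beta_cell" if cluster_of[rec.snp_id] == "BC" else "rest"
        else:
            name = cluster_of[rec.snp_id]
        groups.setdefault(name, []).append(rec)

    estimates: dict[str, PooledEstimate] = {}
    members: dict[str, tuple[str, ...]] = {}
    skipped: dict[str, tuple[str, ...]] = {}
    for name in sorted(groups):
        ids = tuple(r.snp_id for r in groups[name])
        if len(ids) < min_size:
            skipped[name] = ids
            continue
        members[name] = ids
        estimates[name] = random_effects_pool(wald_ratios(groups[name]))
    if not estimates:
        raise InputError(
            f"subgroup_estimates: no group reaches min_size={min_size}"
        )
    return SubgroupReport(estimates=estimates, members=members, skipped=skipped)


def read_cluster_table(path) -> list[ClusterAssignment]:
    """Read a two-column TSV (snp_id, cluster) of mechanism assignments."""
    import csv

    with open(path, newline="") as fh:
        reader = csv.reader(fh, dialect="excel-tab")
        header = next(reader)
        if len(header) < 2:
            raise InputError(f"{path}: expected two columns (snp_id, cluster)")
        return [ClusterAssignment(snp_id=row[0], cluster=row[1]) for row in reader if row]
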