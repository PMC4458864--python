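"""Combinatorial leave-k-out decomposition of heterogeneity.

When the per-instrument Wald ratios disagree more than their sampling error
allows (I^2 > 0), one or a few variants often drive the excess. This module
exhaustively re-pools every subset obtained by removing up to ``max_remove``
instruments and ranks the subsets, identifying which SNPs are responsible
for the heterogeneity.

Full exhaustion over all 2^n subsets is combinatorially explosive for the
instrument-set sizes typical of GWAS-based analyses (n ~ 25-40); removals are
therefore bounded (default <= 3, covering single-outlier and small-group
diagnostics) with a configurable enumeration budget.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

from .exceptions import InputError
from .mr_core import (
    HeterogeneityStats,
    PooledEstimate,
    WaldRatio,
    heterogeneity_stats,
    random_effects_pool,
)

DEFAULT_MAX_REMOVE = 3
DEFAULT_BUDGET = 200_000


@dataclass(frozen=True)
class SubsetResult:
    """Random-effects re-pool of the instrument set minus ``removed_snps``."""

    removed_snps: frozenset[str]
    n_remaining: int
    pooled: PooledEstimate
    het: HeterogeneityStats

    @property
    def i2(self) -> float:
        return self.het.i2

    @property
    def q(self) -> float:
        return self.het.q


def _scan_one(ratios: Sequence[WaldRatio], removed: tuple[WaldRatio, ...]) -> SubsetResult:
    removed_ids = frozenset(r.snp_id for r in removed)
    kept = [r for r in ratios if r.snp_id not in removed_ids]
    pooled = random_effects_pool(kept)
    return SubsetResult(
        removed_snps=removed_ids,
        n_remaining=len(kept),
        pooled=pooled,
        het=pooled.het,
    )


def subset_scan(
    ratios: Sequence[WaldRatio],
    max_remove: int = DEFAULT_MAX_REMOVE,
    rank_by: str = "i2",
    budget: int = DEFAULT_BUDGET,
) -> list[SubsetResult]:
    """Re-pool all subsets with 0..max_remove instruments removed, ranked.

    ``rank_by="i2"`` sorts ascending by remaining-set I^2; ``"abs_q_drop"``
    sorts descending by the drop in Cochran's Q relative to the full set.
    Ties break toward fewer removals, then lexicographic removed-SNP IDs, so
    the ordering is fully deterministic. The empty removal (the full set) is
    always included.
    """
    n = len(ratios)
    if max_remove >= n:
        raise InputError(f"subset_scan: max_remove={max_remove} must be < n={n}")
    if max_remove < 0:
        raise InputError("subset_scan: max_remove must be >= 0")
    if rank_by not in ("i2", "abs_q_drop"):
        raise InputError(f"subset_scan: unknown rank_by {rank_by!r}")
    if n - max_remove < 2:
        raise InputError("subset_scan: remaining sets need at least 2 instruments")
    total = sum(comb(n, k) for k in range(max_remove + 1))
    if total > budget:
        raise InputError(
            f"subset_scan: {total} subsets exceed budget {budget}; lower "
            f"max_remove or raise budget explicitly"
        )
    ids = [r.snp_id for r in ratios]
    if len(set(ids)) != n:
        raise InputError("subset_scan: duplicate snp_ids in instrument set")

    full_q = heterogeneity_stats(ratios).q
    results = [
        _scan_one(ratios, removed)
        for k in range(max_remove + 1)
        for removed in combinations(ratios, k)
    ]

    def key(res: SubsetResult):
        primary = res.i2 if rank_by == "i2" else -(full_q - res.q)
        return (primary, len(res.removed_snps), tuple(sorted(res.removed_snps)))

    results.sort(key=key)
    return results


def leave_one_out(ratios: Sequence[WaldRatio]) -> list[SubsetResult]:
    """One re-pool per removed SNP, in input order (n results)."""
    if len(ratios) < 3:
        raise InputError("leave_one_out: need at least 3 instruments")
    return [_scan_one(ratios, (r,)) for r in ratios]
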