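"""Taxonomic-resolution analysis: what ASV-level profiling sees that
genus- or species-level collapse hides.

Between-group community differences are quantified at each rank by the
fraction of non-shared taxa (and of reads assigned to them), by the
permANOVA eta-squared effect size on Bray–Curtis distances, and by a
differential-abundance screen (per-taxon rank-sum test, Bonferroni over all
taxa at the rank, minimum fold change on group mean relative abundances).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CountTable, RANKS, collapse_by_rank, to_relative_abundance
from .stats import (
    DEFAULT_PERMUTATIONS,
    PermanovaResult,
    bonferroni,
    pairwise_distances,
    permanova,
    rank_sum_test,
)

#: Screen defaults: minimum fold change and Bonferroni-adjusted alpha.
DEFAULT_MIN_FOLD = 2.0
DEFAULT_ALPHA = 0.05
DEFAULT_TOP_K = 5


@dataclass(frozen=True)
class SharedTaxaSummary:
    rank: str
    n_taxa_group_a: int
    n_taxa_group_b: int
    n_shared: int
    frac_nonshared_taxa: float
    frac_reads_nonshared: float


@dataclass(frozen=True)
class DifferentialTaxon:
    taxon_id: str
    rank: str
    fold_change: float  # >= 1 by orientation
    raw_p: float
    adjusted_p: float
    direction: str  # HIGHER_A / HIGHER_B


def _two_groups(table: CountTable, split_by: str) -> tuple[str, str, pd.Series]:
    col = table.samples[split_by]
    groups = sorted(col.dropna().unique())
    if len(groups) != 2:
        raise ValueError(
            f"split_by={split_by!r} yields {len(groups)} groups, need exactly 2"
        )
    sizes = col.value_counts()
    if (sizes[list(groups)] == 0).any():
        raise ValueError("both groups must be non-empty")
    return groups[0], groups[1], col


def shared_taxa(
    table: CountTable,
    rank: str,
    split_by: str = "site",
    subset: Mapping[str, object] | None = None,
) -> SharedTaxaSummary:
    """Shared vs non-shared taxa between two sample groups at a rank.

    Presence is pooled: a taxon belongs to a group iff it has any read in any
    of the group's samples.  ``frac_nonshared_taxa`` is |symmetric difference|
    / |union| and ``frac_reads_nonshared`` is the fraction of all subset reads
    assigned to non-shared taxa.
    """
    if subset:
        table = table.select(**subset)
    collapsed = collapse_by_rank(table, rank)
    a, b, col = _two_groups(collapsed, split_by)
    pooled_a = collapsed.counts.loc[col == a].sum(axis=0)
    pooled_b = collapsed.counts.loc[col == b].sum(axis=0)
    set_a = set(pooled_a.index[pooled_a > 0])
    set_b = set(pooled_b.index[pooled_b > 0])
    union = set_a | set_b
    shared = set_a & set_b
    nonshared = union - shared
    total_reads = int(collapsed.counts.to_numpy().sum())
    nonshared_reads = (
        int(collapsed.counts[sorted(nonshared)].to_numpy().sum()) if nonshared else 0
    )
    return SharedTaxaSummary(
        rank=rank,
        n_taxa_group_a=len(set_a),
        n_taxa_group_b=len(set_b),
        n_shared=len(shared),
        frac_nonshared_taxa=(len(nonshared) / len(union)) if union else 0.0,
        frac_reads_nonshared=(nonshared_reads / total_reads) if total_reads else 0.0,
    )


def eta_squared_by_resolution(
    table: CountTable,
    ranks: Sequence[str] = RANKS,
    split_by: str = "site",
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
) -> dict[str, PermanovaResult]:
    """permANOVA effect of a two-level grouping at each taxonomic rank.

    Per rank: collapse, renormalize, Bray–Curtis, permANOVA; the eta-squared
    values trace how much of the community variance the grouping explains as
    resolution increases.
    """
    results: dict[str, PermanovaResult] = {}
    for rank in ranks:
        collapsed = collapse_by_rank(table, rank)
        abundance = to_relative_abundance(collapsed)
        d = pairwise_distances(abundance)
        groups = collapsed.samples.loc[list(d.ids), split_by]
        results[rank] = permanova(d, groups, n_permutations=n_permutations, seed=seed)
    return results


def _fold_change(
    mean_a: float, mean_b: float, pseudo_floor: float
) -> tuple[float, str]:
    a = max(mean_a, pseudo_floor)
    b = max(mean_b, pseudo_floor)
    if a >= b:
        return a / b, "HIGHER_A"
    return b / a, "HIGHER_B"


def differential_abundance_screen(
    table: CountTable,
    rank: str = "asv",
    split_by: str = "site",
    min_fold: float = DEFAULT_MIN_FOLD,
    alpha: float = DEFAULT_ALPHA,
) -> list[DifferentialTaxon]:
    """Taxa differing between two groups by rank-sum test and fold change.

    Per taxon at the rank, per-sample relative abundances are compared between
    the groups with the rank-sum test; the Bonferroni family is all taxa
    tested at that rank.  A taxon is reported iff its adjusted p <= alpha and
    its fold change (ratio of group mean relative abundances, oriented so it
    is >= 1) is at least ``min_fold``.  Zero group means are floored at
    ``1 / (2 * median sample depth)`` so taxa absent from one group get a
    finite fold change.
    """
    if min_fold < 1:
        raise ValueError("min_fold must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    collapsed = collapse_by_rank(table, rank)
    a, b, col = _two_groups(collapsed, split_by)
    abundance = to_relative_abundance(collapsed)
    pseudo_floor = 1.0 / (2.0 * float(collapsed.totals().median()))
    mask_a = (col == a).to_numpy()
    mask_b = (col == b).to_numpy()
    values = abundance.values.to_numpy()
    taxa = list(abundance.values.columns)
    raw_ps = []
    stats_rows = []
    for j, taxon in enumerate(taxa):
        va = values[mask_a, j]
        vb = values[mask_b, j]
        _, p = rank_sum_test(va, vb)
        fc, direction = _fold_change(float(va.mean()), float(vb.mean()), pseudo_floor)
        raw_ps.append(p)
        stats_rows.append((taxon, fc, direction))
    adjusted = bonferroni(raw_ps)
    out = []
    for (taxon, fc, direction), raw_p, adj_p in zip(stats_rows, raw_ps, adjusted):
        if adj_p <= alpha and fc >= min_fold:
            out.append(
                DifferentialTaxon(
                    taxon_id=taxon,
                    rank=rank,
                    fold_change=fc,
                    raw_p=raw_p,
                    adjusted_p=adj_p,
                    direction=direction,
                )
            )
    out.sort(key=lambda t: (t.adjusted_p, -t.fold_change, t.taxon_id))
    return out


def top_taxa_comparison(
    table: CountTable,
    rank: str = "asv",
    split_by: str = "site",
    k: int = DEFAULT_TOP_K,
) -> pd.DataFrame:
    """Compare the k most abundant taxa (by pooled read count) between groups.

    Returns a DataFrame with per-group median relative abundances, the raw
    rank-sum p, and the Bonferroni-adjusted p over the k tests.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    collapsed = collapse_by_rank(table, rank)
    a, b, col = _two_groups(collapsed, split_by)
    pooled = collapsed.counts.sum(axis=0).sort_values(ascending=False, kind="stable")
    if k > len(pooled):
        warnings.warn(f"k={k} exceeds {len(pooled)} taxa at rank {rank}; truncating")
        k = len(pooled)
    top = list(pooled.index[:k])
    abundance = to_relative_abundance(collapsed)
    mask_a = (col == a).to_numpy()
    mask_b = (col == b).to_numpy()
    rows = []
    raw_ps = []
    for taxon in top:
        va = abundance.values[taxon].to_numpy()[mask_a]
        vb = abundance.values[taxon].to_numpy()[mask_b]
        _, p = rank_sum_test(va, vb)
        raw_ps.append(p)
        rows.append(
            {
                "taxon_id": taxon,
                "rank": rank,
                f"median_{a}": float(np.median(va)),
                f"median_{b}": float(np.median(vb)),
                "raw_p": p,
            }
        )
    adjusted = bonferroni(raw_ps)
    for row, adj in zip(rows, adjusted):
        row["adjusted_p"] = adj
    return pd.DataFrame(rows).set_index("taxon_id")
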