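"""Antibiotic-resistance-gene (ARG) categorization of ASVs.

Each ASV is matched upstream (by genome-database search, which is an input
here, not a computation) to zero or more sequenced genomes, each flagged for
whether it carries antibiotic-resistance genes.  This induces four exhaustive,
mutually exclusive categories:

* ``ARG_ONLY`` — every matching genome carries ARGs;
* ``AMBIGUOUS`` — some matching genomes carry ARGs, some do not;
* ``NON_ARG`` — no matching genome carries ARGs;
* ``UNMATCHED`` — no matching genome at all.

Category abundances aggregated over time show whether antibiotic treatment
enriches for resistance-carrying community members.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence
import warnings

import pandas as pd

from .core import CountTable, to_relative_abundance

CATEGORIES = ("ARG_ONLY", "AMBIGUOUS", "NON_ARG", "UNMATCHED")


@dataclass
class ArgMatchTable:
    """ASV -> genome matches with per-genome ARG flags.

    ``matches`` has columns ``asv_id, genome_id, has_arg``; ``asv_universe``
    is the full set of ASVs under study (so unmatched ASVs are represented).
    """

    matches: pd.DataFrame
    asv_universe: set[str]

    def __post_init__(self) -> None:
        required = {"asv_id", "genome_id", "has_arg"}
        missing = required - set(self.matches.columns)
        if missing:
            raise ValueError(f"match table missing columns: {sorted(missing)}")
        pairs = self.matches[["asv_id", "genome_id"]]
        if pairs.duplicated().any():
            dups = pairs[pairs.duplicated()].to_records(index=False).tolist()
            raise ValueError(f"duplicate (asv_id, genome_id) pairs: {dups[:5]}")
        unknown = set(self.matches["asv_id"]) - self.asv_universe
        if unknown:
            raise ValueError(
                f"match table references asv ids outside the study: {sorted(unknown)[:10]}"
            )
        self.matches = self.matches.astype({"has_arg": bool})

    def write(self, path: str | Path) -> None:
        out = self.matches.copy()
        out["has_arg"] = out["has_arg"].astype(int)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, asv_universe: set[str]) -> "ArgMatchTable":
        df = pd.read_csv(path, sep="\t", dtype={"asv_id": str, "genome_id": str})
        df["has_arg"] = df["has_arg"].astype(int).astype(bool)
        return cls(matches=df, asv_universe=asv_universe)


def categorize_asvs(matches: ArgMatchTable) -> dict[str, str]:
    """Assign every ASV in the universe to one of the four ARG categories."""
    result = {asv: "UNMATCHED" for asv in matches.asv_universe}
    if len(matches.matches):
        grouped = matches.matches.groupby("asv_id")["has_arg"]
        any_arg = grouped.any()
        all_arg = grouped.all()
        for asv in any_arg.index:
            if all_arg[asv]:
                result[asv] = "ARG_ONLY"
            elif any_arg[asv]:
                result[asv] = "AMBIGUOUS"
            else:
                result[asv] = "NON_ARG"
        none_arg = grouped.apply(lambda s: not s.any())
        for asv in none_arg.index[none_arg]:
            result[asv] = "NON_ARG"
    return result


def category_abundance(
    table: CountTable, categories: Mapping[str, str]
) -> pd.DataFrame:
    """Mean per-category abundance fraction per (site, treatment, day).

    Per sample, relative abundance is summed within each category (the four
    fractions sum to 1); sample fractions are then averaged within each
    stratum.  Returns a DataFrame indexed by (site, treatment, day) with one
    column per category.
    """
    uncovered = set(table.asv_ids) - set(categories)
    if uncovered:
        raise ValueError(f"categories missing for asvs: {sorted(uncovered)[:10]}")
    abundance = to_relative_abundance(table)
    cat_series = pd.Series({a: categories[a] for a in table.asv_ids})
    per_sample = abundance.values.T.groupby(cat_series.values).sum().T
    for cat in CATEGORIES:
        if cat not in per_sample.columns:
            per_sample[cat] = 0.0
    per_sample = per_sample[list(CATEGORIES)]
    joined = per_sample.join(table.samples[["site", "treatment", "day"]])
    return joined.groupby(["site", "treatment", "day"]).mean().sort_index()


def arg_species_trajectory(
    table: CountTable,
    categories: Mapping[str, str],
    k: int = 10,
    treatments: Sequence[str] | None = ("ABX10", "ABX3CMT"),
) -> pd.DataFrame:
    """Per-day mean abundance of the k most abundant species among ARG-only ASVs.

    ASVs in the ``ARG_ONLY`` category are collapsed to species (unlabeled ones
    fall into the sentinel bucket); species are ranked by pooled read count
    within the selected treatment arms, sites combined, with ties broken
    lexicographically by label.  Returns day x species mean relative
    abundances (fractions of the *whole* community) for the top k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sub = table.select(treatment=list(treatments)) if treatments else table
    arg_ids = [a for a in sub.asv_ids if categories.get(a) == "ARG_ONLY"]
    if not arg_ids:
        return pd.DataFrame()
    totals = sub.totals()
    keep = totals.index[totals > 0]
    sub = sub.subset_samples(list(keep))
    abundance = to_relative_abundance(sub)
    species = sub.features.loc[arg_ids, "species"].fillna("UNCLASSIFIED_SPECIES")
    arg_counts = sub.counts[arg_ids]
    pooled = arg_counts.T.groupby(species.values).sum().T.sum(axis=0)
    # rank by pooled count, ties broken lexicographically by label
    ranked = (
        pooled.to_frame("count")
        .assign(label=pooled.index)
        .sort_values(["count", "label"], ascending=[False, True])
    )
    if k > len(ranked):
        warnings.warn(
            f"k={k} exceeds the {len(ranked)} species among ARG-only ASVs; truncating"
        )
    top = list(ranked.index[: min(k, len(ranked))])
    per_sample = abundance.values[arg_ids].T.groupby(species.values).sum().T
    per_sample = per_sample[[s for s in top if s in per_sample.columns]]
    joined = per_sample.join(sub.samples[["day"]])
    return joined.groupby("day").mean().sort_index()
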