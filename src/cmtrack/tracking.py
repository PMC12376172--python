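"""Donor-provenance classification and engraftment tracking.

ASVs are exact sequence variants, so donor membership is decided by exact
sequence identity to the ASVs observed in the sequenced donor inoculum — not
by clustering at a similarity threshold.  On top of that partition this
module computes: newly introduced donor ASVs (absent before transplant and
from all control arms), per-subject engraftment trajectories (donor richness
and abundance fractions over time), cross-site colonization overlap, and
within-subject consecutive-timepoint Bray–Curtis dissimilarities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import CountTable, to_relative_abundance
from .stats import bray_curtis

#: First fecal collection after the transplant gavage on day 4.
DEFAULT_INTRODUCTION_DAY = 5
DEFAULT_CONTROL_TREATMENTS = frozenset({"UNTR", "ABX10"})


@dataclass
class DonorProfile:
    """The sequenced donor inoculum: replicate counts plus ASV sequences.

    ``replicates`` is a (replicate x asv_id) count DataFrame; the donor ASV
    set is derived as every ASV with a nonzero count in any replicate.
    """

    replicates: pd.DataFrame
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.replicates.to_numpy() < 0).any():
            raise ValueError("donor replicate counts must be non-negative")
        if not self.donor_asv_ids:
            raise ValueError("donor profile contains no observed ASVs")

    @property
    def donor_asv_ids(self) -> set[str]:
        present = (self.replicates > 0).any(axis=0)
        return set(self.replicates.columns[present])

    def write(self, path: str | Path) -> None:
        out = self.replicates.T.copy()
        out.index.name = "asv_id"
        out["sequence"] = [self.sequences.get(a, "") for a in out.index]
        out.to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | Path) -> "DonorProfile":
        df = pd.read_csv(path, sep="\t", index_col=0)
        seqs = {}
        if "sequence" in df.columns:
            seqs = {
                a: s for a, s in df["sequence"].items() if isinstance(s, str) and s
            }
            df = df.drop(columns="sequence")
        return cls(replicates=df.T, sequences=seqs)


def classify_donor_asvs(
    features: pd.DataFrame, donor: DonorProfile
) -> dict[str, str]:
    """Partition study ASVs into DONOR / NON_DONOR by exact sequence identity.

    ``features`` is the study feature frame (indexed by asv_id, with a
    ``sequence`` column).  When sequences are absent from *both* sides the
    partition falls back to shared asv-id namespace membership; sequences
    available on only one side are an error, since a silent id fallback could
    misclassify.
    """
    study_has_seqs = (
        "sequence" in features.columns and features["sequence"].notna().all()
    )
    donor_has_seqs = bool(donor.sequences) and all(
        a in donor.sequences for a in donor.donor_asv_ids
    )
    if study_has_seqs and donor_has_seqs:
        donor_seqs = {
            str(donor.sequences[a]).upper() for a in donor.donor_asv_ids
        }
        return {
            asv: ("DONOR" if str(seq).upper() in donor_seqs else "NON_DONOR")
            for asv, seq in features["sequence"].items()
        }
    if not study_has_seqs and not donor_has_seqs:
        donor_ids = donor.donor_asv_ids
        return {
            asv: ("DONOR" if asv in donor_ids else "NON_DONOR")
            for asv in features.index
        }
    raise ValueError(
        "sequences available on only one side; provide sequences for both the "
        "study features and the donor profile (or neither, for id matching)"
    )


def newly_introduced_asvs(
    table: CountTable,
    donor: DonorProfile,
    control_treatments: Iterable[str] = DEFAULT_CONTROL_TREATMENTS,
    introduction_day: int = DEFAULT_INTRODUCTION_DAY,
) -> dict[tuple[str, str], set[str]]:
    """Donor ASVs newly introduced per (site, treatment) after the transplant.

    An ASV qualifies for a (site, treatment) iff it is donor-classified,
    appears in that treatment at that site on or after ``introduction_day``,
    is never seen in any control treatment at that site on any day, and is
    never seen at that site before ``introduction_day`` in any treatment.
    Control treatments therefore always yield empty sets.
    """
    controls = set(control_treatments)
    if not controls:
        raise ValueError("control treatment set must be non-empty")
    missing = controls - set(table.samples["treatment"])
    if missing:
        raise ValueError(f"control treatments absent from metadata: {sorted(missing)}")
    if introduction_day not in table.schedule:
        raise ValueError(
            f"introduction_day {introduction_day} not in schedule {table.schedule}"
        )
    partition = classify_donor_asvs(table.features, donor)
    donor_cols = [a for a in table.asv_ids if partition[a] == "DONOR"]

    result: dict[tuple[str, str], set[str]] = {}
    meta = table.samples
    for site in sorted(meta["site"].unique()):
        site_ids = meta.index[meta["site"] == site]
        site_counts = table.counts.loc[site_ids, donor_cols]
        site_meta = meta.loc[site_ids]
        in_controls = (
            site_counts.loc[site_meta["treatment"].isin(controls)] > 0
        ).any(axis=0)
        before_intro = (
            site_counts.loc[site_meta["day"] < introduction_day] > 0
        ).any(axis=0)
        for treatment in sorted(meta["treatment"].unique()):
            sel = (site_meta["treatment"] == treatment) & (
                site_meta["day"] >= introduction_day
            )
            present_after = (site_counts.loc[site_ids[sel]] > 0).any(axis=0)
            qualified = present_after & ~in_controls & ~before_intro
            if treatment in controls:
                qualified &= False  # controls are their own exclusion set
            result[(site, treatment)] = set(qualified.index[qualified])
    return result


def engraftment_trajectory(
    table: CountTable, donor_partition: Mapping[str, str]
) -> pd.DataFrame:
    """Mean +/- sd donor richness and abundance fractions per (site, treatment, day).

    Per subject-day: donor richness fraction = observed donor ASVs / all
    observed ASVs; donor abundance fraction = summed relative abundance over
    donor ASVs.  Subject-days with zero total count are excluded with a
    warning.
    """
    donor_cols = [a for a in table.asv_ids if donor_partition.get(a) == "DONOR"]
    totals = table.totals()
    zero = totals.index[totals == 0].tolist()
    if zero:
        warnings.warn(f"excluding {len(zero)} zero-count samples: {zero[:5]}")
        table = table.subset_samples(list(totals.index[totals > 0]))
    abundance = to_relative_abundance(table)
    present = table.counts > 0
    donor_rich = present[donor_cols].sum(axis=1)
    total_rich = present.sum(axis=1)
    rich_frac = (donor_rich / total_rich.replace(0, np.nan)).fillna(0.0)
    abund_frac = abundance.values[donor_cols].sum(axis=1)
    per_sample = pd.DataFrame(
        {
            "richness_fraction": rich_frac,
            "abundance_fraction": abund_frac,
        }
    ).join(table.samples[["site", "treatment", "day"]])
    agg = per_sample.groupby(["site", "treatment", "day"]).agg(
        richness_fraction_mean=("richness_fraction", "mean"),
        richness_fraction_sd=("richness_fraction", lambda s: s.std(ddof=0)),
        abundance_fraction_mean=("abundance_fraction", "mean"),
        abundance_fraction_sd=("abundance_fraction", lambda s: s.std(ddof=0)),
        n_subjects=("abundance_fraction", "size"),
    )
    return agg.sort_index()


def cross_site_colonization(
    table: CountTable,
    donor_partition: Mapping[str, str],
    treatment: str,
    final_day: int | None = None,
) -> tuple[float, float]:
    """Cross-site overlap of donor colonization at the final day.

    The colonized set per site is every donor ASV observed in at least one
    final-day sample of the treatment at that site.  Returns
    ``(frac_shared_colonized_taxa, frac_donor_abundance_from_shared)`` where
    the first is |intersection| / |union| and the second is the summed
    relative abundance of intersection ASVs across both sites' final-day
    samples divided by that of all colonized donor ASVs.
    """
    final_day = table.schedule[-1] if final_day is None else final_day
    sub = table.select(treatment=treatment, day=final_day)
    sites = sorted(sub.samples["site"].unique())
    if len(sites) != 2:
        raise ValueError(
            f"treatment {treatment!r} not sampled at both sites on day {final_day}"
        )
    donor_cols = [a for a in sub.asv_ids if donor_partition.get(a) == "DONOR"]
    colonized = {}
    for site in sites:
        site_sub = sub.select(site=site)
        present = (site_sub.counts[donor_cols] > 0).any(axis=0)
        colonized[site] = set(present.index[present])
    union = colonized[sites[0]] | colonized[sites[1]]
    inter = colonized[sites[0]] & colonized[sites[1]]
    if not union:
        warnings.warn("no colonized donor ASVs at either site")
        return 0.0, 0.0
    totals = sub.totals()
    sub = sub.subset_samples(list(totals.index[totals > 0]))
    abundance = to_relative_abundance(sub)
    union_sum = float(abundance.values[sorted(union)].to_numpy().sum())
    inter_sum = float(abundance.values[sorted(inter)].to_numpy().sum()) if inter else 0.0
    frac_taxa = len(inter) / len(union)
    frac_abundance = inter_sum / union_sum if union_sum > 0 else 0.0
    return frac_taxa, frac_abundance


def consecutive_dissimilarity(table: CountTable) -> pd.DataFrame:
    """Within-subject Bray–Curtis between consecutive sampled days.

    For each subject, dissimilarity between its own profiles at consecutive
    available schedule days; rows carry (site, treatment, subject, prev_day,
    day, dissimilarity) so callers can group distributions by (site,
    treatment, later day).  Zero-count samples are skipped per subject.
    """
    totals = table.totals()
    table = table.subset_samples(list(totals.index[totals > 0]))
    abundance = to_relative_abundance(table)
    rows = []
    meta = table.samples
    for subject, group in meta.groupby("subject_id"):
        ordered = group.sort_values("day")
        ids = list(ordered.index)
        for prev_id, cur_id in zip(ids, ids[1:]):
            value = bray_curtis(
                abundance.values.loc[prev_id], abundance.values.loc[cur_id]
            )
            rows.append(
                {
                    "site": ordered.loc[cur_id, "site"],
                    "treatment": ordered.loc[cur_id, "treatment"],
                    "subject_id": subject,
                    "prev_day": int(ordered.loc[prev_id, "day"]),
                    "day": int(ordered.loc[cur_id, "day"]),
                    "dissimilarity": value,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["site", "treatment", "subject_id", "prev_day", "day", "dissimilarity"],
    )
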