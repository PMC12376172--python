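"""Between-site convergence trajectories and the convergence verdict.

The study's operational definition of "standardized" microbiomes: within a
treatment arm, the mean of all cross-site pairwise Bray–Curtis dissimilarities
at the final day must fall strictly below a threshold (default 0.5, a
practical bound separating related from disparate communities).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AbundanceTable, CountTable, SITES, to_relative_abundance
from .stats import bray_curtis, pairwise_distances

DEFAULT_CONVERGENCE_THRESHOLD = 0.5


@dataclass
class ConvergenceTrajectory:
    """Per-day mean +/- sd of cross-site pairwise Bray–Curtis for one arm.

    ``per_day`` has columns ``mean, sd, n_pairs`` indexed by day; when
    ``within_site`` is set (the untreated reference) it summarizes all
    same-site pairs instead.
    """

    treatment: str
    per_day: pd.DataFrame
    within_site: pd.DataFrame | None = None


@dataclass(frozen=True)
class ConvergenceVerdict:
    treatment: str
    final_day: int
    mean_between_site_bc: float
    threshold: float
    convergent: bool


def _pair_values(
    d: np.ndarray, ix_a: np.ndarray, ix_b: np.ndarray
) -> np.ndarray:
    return d[np.ix_(ix_a, ix_b)].ravel()


def between_site_trajectory(
    table: CountTable,
    treatment: str,
    include_within_site: bool = False,
    centroid: bool = False,
) -> ConvergenceTrajectory:
    """Cross-site dissimilarity of one treatment arm over time.

    Per day sampled at both sites, every site-A sample is paired with every
    site-B sample within the arm and the Bray–Curtis values are summarized as
    mean +/- sd.  ``centroid=True`` instead reports the dissimilarity between
    the two site mean profiles.  ``include_within_site`` adds the analogous
    same-site pair summary (the untreated-arm reference curve).
    """
    sub = table.select(treatment=treatment)
    totals = sub.totals()
    sub = sub.subset_samples(list(totals.index[totals > 0]))
    abundance = to_relative_abundance(sub)
    meta = sub.samples
    common_days = sorted(
        set(meta.loc[meta["site"] == SITES[0], "day"])
        & set(meta.loc[meta["site"] == SITES[1], "day"])
    )
    if not common_days:
        raise ValueError(
            f"treatment {treatment!r} has no day sampled at both sites"
        )
    rows = []
    within_rows = []
    for day in common_days:
        ids = meta.index[meta["day"] == day]
        day_meta = meta.loc[ids]
        day_table = abundance.values.loc[ids]
        if centroid:
            mean_a = day_table.loc[day_meta["site"] == SITES[0]].mean(axis=0)
            mean_b = day_table.loc[day_meta["site"] == SITES[1]].mean(axis=0)
            rows.append(
                {"day": day, "mean": bray_curtis(mean_a, mean_b), "sd": 0.0, "n_pairs": 1}
            )
            continue
        d = pairwise_distances(
            AbundanceTable(day_table, day_meta, sub.features)
        ).data
        pos = {sid: i for i, sid in enumerate(ids)}
        ix_a = np.array([pos[s] for s in ids[day_meta["site"] == SITES[0]]])
        ix_b = np.array([pos[s] for s in ids[day_meta["site"] == SITES[1]]])
        values = _pair_values(d, ix_a, ix_b)
        rows.append(
            {
                "day": day,
                "mean": float(values.mean()),
                "sd": float(values.std(ddof=0)),
                "n_pairs": len(values),
            }
        )
        if include_within_site:
            within_vals = []
            for ix in (ix_a, ix_b):
                iu, ju = np.triu_indices(len(ix), k=1)
                within_vals.append(d[np.ix_(ix, ix)][iu, ju])
            wv = np.concatenate(within_vals)
            within_rows.append(
                {
                    "day": day,
                    "mean": float(wv.mean()),
                    "sd": float(wv.std(ddof=0)),
                    "n_pairs": len(wv),
                }
            )
    per_day = pd.DataFrame(rows).set_index("day")
    within = (
        pd.DataFrame(within_rows).set_index("day") if within_rows else None
    )
    return ConvergenceTrajectory(
        treatment=treatment, per_day=per_day, within_site=within
    )


def assess_convergence(
    trajectory: ConvergenceTrajectory,
    threshold: float = DEFAULT_CONVERGENCE_THRESHOLD,
    final_day: int | None = None,
) -> ConvergenceVerdict:
    """Strict-less comparison of the final-day cross-site mean to the threshold."""
    days = list(trajectory.per_day.index)
    final_day = days[-1] if final_day is None else final_day
    if final_day not in days:
        raise ValueError(
            f"final day {final_day} missing from trajectory days {days}"
        )
    mean_bc = float(trajectory.per_day.loc[final_day, "mean"])
    return ConvergenceVerdict(
        treatment=trajectory.treatment,
        final_day=int(final_day),
        mean_between_site_bc=mean_bc,
        threshold=float(threshold),
        convergent=mean_bc < threshold,
    )
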