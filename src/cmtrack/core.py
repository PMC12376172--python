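"""Count-table data model, file I/O, and elementary community transforms.

The central object is a :class:`CountTable`: an integer sample x ASV matrix
joined to per-sample metadata (subject, site, treatment arm, study day, sex)
and per-feature annotations (sequence, species, genus).  Everything downstream
— relative abundances, taxonomic collapse, beta-diversity statistics,
engraftment tracking — consumes this object.

Counts stay integer end to end; relative abundance (:class:`AbundanceTable`)
is the only floating-point representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

SITES = ("SITE_A", "SITE_B")
TREATMENTS = ("UNTR", "ABX10", "ABX3CMT", "CMT")
SEXES = ("F", "M")
RANKS = ("asv", "species", "genus")

#: Default fecal-collection schedule (study days).  Day -2 is the arrival
#: baseline, collected three days before treatment begins on day 1.
DEFAULT_SCHEDULE = (-2, 1, 3, 5, 8, 10, 30, 60)
BASELINE_DAY = -2

#: Default minimum per-sample read total; samples below it are removed.
DEFAULT_MIN_READS = 1000

METADATA_COLUMNS = ("subject_id", "site", "treatment", "day", "sex")


class CountTableError(ValueError):
    """Base error for count-table construction and transforms."""


class ParseError(CountTableError):
    """A cell or field in an input file failed validation."""


class ReconciliationError(CountTableError):
    """Counts and metadata disagree about which samples exist."""


class EmptyStudyError(CountTableError):
    """A filter removed every sample."""


def _unclassified_label(rank: str) -> str:
    return f"UNCLASSIFIED_{rank.upper()}"


@dataclass
class CountTable:
    """Integer sample x ASV matrix with sample metadata and feature annotations.

    Parameters
    ----------
    counts
        DataFrame indexed by sample_id with asv_id columns; non-negative ints.
    samples
        DataFrame indexed by sample_id with columns
        ``subject_id, site, treatment, day, sex`` (and derived ``is_baseline``).
    features
        DataFrame indexed by asv_id with optional columns
        ``sequence, species, genus``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    features: pd.DataFrame
    schedule: tuple[int, ...] = DEFAULT_SCHEDULE
    baseline_day: int = BASELINE_DAY

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.samples = self.samples.copy()
        self.features = self.features.copy()
        self.schedule = tuple(int(d) for d in self.schedule)
        self._validate()

    def _validate(self) -> None:
        if not self.counts.index.equals(self.samples.index):
            extra_counts = sorted(set(self.counts.index) - set(self.samples.index))
            extra_meta = sorted(set(self.samples.index) - set(self.counts.index))
            if extra_counts or extra_meta:
                raise ReconciliationError(
                    "counts and metadata sample ids disagree; "
                    f"only in counts: {extra_counts}; only in metadata: {extra_meta}"
                )
            # same set, different order: align metadata to counts order
            self.samples = self.samples.loc[self.counts.index]
        if not self.counts.index.is_unique:
            dups = sorted(self.counts.index[self.counts.index.duplicated()])
            raise CountTableError(f"duplicate sample ids: {dups}")
        if not self.counts.columns.is_unique:
            dups = sorted(self.counts.columns[self.counts.columns.duplicated()])
            raise CountTableError(f"duplicate asv ids: {dups}")
        if not self.counts.columns.equals(self.features.index):
            missing = sorted(set(self.counts.columns) - set(self.features.index))
            if missing:
                raise ReconciliationError(
                    f"features missing for asv ids: {missing[:10]}"
                )
            self.features = self.features.loc[self.counts.columns]

        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values.astype(float))) or np.any(
                values.astype(float) != np.floor(values.astype(float))
            ):
                bad = np.argwhere(
                    ~np.isfinite(values.astype(float))
                    | (values.astype(float) != np.floor(values.astype(float)))
                )
                i, j = bad[0]
                raise ParseError(
                    f"non-integer count at sample {self.counts.index[i]!r}, "
                    f"asv {self.counts.columns[j]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ParseError(
                f"negative count at sample {self.counts.index[i]!r}, "
                f"asv {self.counts.columns[j]!r}"
            )

        missing_cols = [c for c in METADATA_COLUMNS if c not in self.samples.columns]
        if missing_cols:
            raise CountTableError(f"metadata missing columns: {missing_cols}")
        bad_site = set(self.samples["site"]) - set(SITES)
        if bad_site:
            raise ParseError(f"unknown site values: {sorted(bad_site)}")
        bad_trt = set(self.samples["treatment"]) - set(TREATMENTS)
        if bad_trt:
            raise ParseError(f"unknown treatment values: {sorted(bad_trt)}")
        bad_sex = set(self.samples["sex"]) - set(SEXES)
        if bad_sex:
            raise ParseError(f"unknown sex values: {sorted(bad_sex)}")
        self.samples["day"] = self.samples["day"].astype(int)
        off_schedule = set(self.samples["day"]) - set(self.schedule)
        if off_schedule:
            raise ParseError(
                f"days outside declared schedule {self.schedule}: {sorted(off_schedule)}"
            )
        pair = self.samples[["subject_id", "day"]]
        if pair.duplicated().any():
            dups = pair[pair.duplicated()].to_records(index=False).tolist()
            raise CountTableError(f"duplicate (subject_id, day) pairs: {dups[:5]}")
        if "is_baseline" not in self.samples.columns:
            self.samples["is_baseline"] = self.samples["day"] == self.baseline_day

    # ------------------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def totals(self) -> pd.Series:
        """Per-sample read totals."""
        return self.counts.sum(axis=1)

    def select(self, **filters) -> "CountTable":
        """Subset samples by metadata equality, e.g. ``select(site="SITE_A", day=-2)``.

        A filter value may be a scalar or an iterable of admissible values.
        """
        mask = pd.Series(True, index=self.samples.index)
        for key, value in filters.items():
            if key not in self.samples.columns:
                raise KeyError(f"unknown metadata field {key!r}")
            col = self.samples[key]
            if isinstance(value, (list, tuple, set, frozenset)):
                mask &= col.isin(list(value))
            else:
                mask &= col == value
        return self.subset_samples(self.samples.index[mask])

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        ids = list(sample_ids)
        return CountTable(
            counts=self.counts.loc[ids],
            samples=self.samples.loc[ids],
            features=self.features,
            schedule=self.schedule,
            baseline_day=self.baseline_day,
        )


@dataclass
class AbundanceTable:
    """Relative-abundance counterpart of a :class:`CountTable`; rows sum to 1."""

    values: pd.DataFrame
    samples: pd.DataFrame
    features: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.values.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = self.values.index[np.abs(sums - 1.0) > 1e-9][:5].tolist()
            raise CountTableError(f"abundance rows do not sum to 1: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def read_count_table(
    counts_path: str | Path,
    metadata_path: str | Path,
    fasta_path: str | Path | None = None,
    taxonomy_path: str | Path | None = None,
    schedule: Iterable[int] = DEFAULT_SCHEDULE,
) -> CountTable:
    """Read a count matrix, sample metadata, and optional sequences/taxonomy.

    The counts file is a rectangular tab-separated matrix whose first column
    holds sample ids and whose header row holds asv ids.  Metadata is one row
    per sample with the columns ``sample_id, subject_id, site, treatment, day,
    sex``.  FASTA record ids are asv ids; the taxonomy file has columns
    ``asv_id, species, genus`` with empty fields meaning unlabeled.
    """
    raw = pd.read_csv(counts_path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParseError(
            f"non-numeric count {raw.iat[i, j]!r} at sample {raw.index[i]!r}, "
            f"asv {raw.columns[j]!r} in {counts_path}"
        )
    counts = numeric
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise ParseError(f"metadata {metadata_path} lacks a sample_id column")
    meta = meta.set_index("sample_id")
    only_counts = sorted(set(counts.index) - set(meta.index))
    only_meta = sorted(set(meta.index) - set(counts.index))
    if only_counts or only_meta:
        raise ReconciliationError(
            f"sample ids only in counts: {only_counts}; only in metadata: {only_meta}"
        )
    meta = meta.loc[counts.index]
    meta["day"] = meta["day"].astype(int)
    if "is_baseline" in meta.columns:
        meta["is_baseline"] = meta["is_baseline"].astype(str).isin(("1", "True", "true"))

    features = pd.DataFrame(
        index=pd.Index(counts.columns, name="asv_id"),
        columns=["sequence", "species", "genus"],
        dtype=object,
    )
    if fasta_path is not None:
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            if rec.id in features.index:
                features.loc[rec.id, "sequence"] = str(rec.seq).upper()
    if taxonomy_path is not None:
        tax = pd.read_csv(taxonomy_path, sep="\t", dtype=str).set_index("asv_id")
        for col in ("species", "genus"):
            if col in tax.columns:
                shared = tax.index.intersection(features.index)
                features.loc[shared, col] = tax.loc[shared, col]
    features = features.where(features.notna() & (features != ""), other=pd.NA)

    return CountTable(counts=counts, samples=meta, features=features, schedule=schedule)


def write_count_table(
    table: CountTable,
    counts_path: str | Path,
    metadata_path: str | Path,
    fasta_path: str | Path | None = None,
    taxonomy_path: str | Path | None = None,
) -> None:
    """Write a CountTable back to the tab-separated/FASTA external formats."""
    out = table.counts.copy()
    out.index.name = "sample_id"
    out.to_csv(counts_path, sep="\t")
    meta = table.samples.copy()
    meta.index.name = "sample_id"
    meta = meta[[c for c in (*METADATA_COLUMNS, "is_baseline") if c in meta.columns]]
    meta.to_csv(metadata_path, sep="\t")
    if fasta_path is not None:
        records = [
            SeqRecord(Seq(str(seq)), id=str(asv_id), description="")
            for asv_id, seq in table.features["sequence"].items()
            if pd.notna(seq)
        ]
        SeqIO.write(records, str(fasta_path), "fasta")
    if taxonomy_path is not None:
        tax = table.features[["species", "genus"]].copy()
        tax.index.name = "asv_id"
        tax.to_csv(taxonomy_path, sep="\t", na_rep="")


# ----------------------------------------------------------------------
# Transforms
# ----------------------------------------------------------------------

def to_relative_abundance(table: CountTable) -> AbundanceTable:
    """Divide each row by its total; rows with zero total are rejected.

    Callers should depth-filter first (:func:`filter_low_depth_samples`).
    """
    totals = table.totals()
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise CountTableError(
            f"cannot normalize samples with zero total count: {zero}"
        )
    values = table.counts.div(totals, axis=0)
    return AbundanceTable(values=values, samples=table.samples, features=table.features)


def collapse_by_rank(table: CountTable, rank: str) -> CountTable:
    """Sum ASV columns sharing a species/genus label; conserve row totals.

    ``rank="asv"`` returns the table unchanged.  Features lacking a label are
    pooled into a per-rank sentinel bucket (``UNCLASSIFIED_SPECIES`` /
    ``UNCLASSIFIED_GENUS``) rather than dropped, so per-sample totals — and
    hence downstream abundance fractions — are conserved.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}, got {rank!r}")
    if rank == "asv":
        return CountTable(
            counts=table.counts,
            samples=table.samples,
            features=table.features,
            schedule=table.schedule,
            baseline_day=table.baseline_day,
        )
    labels = table.features[rank].fillna(_unclassified_label(rank)).astype(str)
    labels = labels.where(labels != "", _unclassified_label(rank))
    collapsed = table.counts.T.groupby(labels.values).sum().T
    collapsed = collapsed[sorted(collapsed.columns)]
    feat = pd.DataFrame(
        index=pd.Index(collapsed.columns, name="taxon_id"),
        columns=["sequence", "species", "genus"],
        dtype=object,
    )
    feat[rank] = feat.index
    if rank == "species":
        # carry a genus label when it is unambiguous within the species
        genus_map = (
            table.features.assign(_label=labels)
            .groupby("_label")["genus"]
            .agg(lambda g: g.dropna().iloc[0] if g.dropna().nunique() == 1 else pd.NA)
        )
        feat["genus"] = genus_map.reindex(feat.index)
    return CountTable(
        counts=collapsed,
        samples=table.samples,
        features=feat,
        schedule=table.schedule,
        baseline_day=table.baseline_day,
    )


def richness(table: CountTable) -> pd.Series:
    """Number of features with nonzero count per sample.

    Rank-specific richness (species, genus) is obtained by collapsing first.
    """
    return (table.counts > 0).sum(axis=1).rename("richness")


def filter_low_depth_samples(table: CountTable, min_reads: int = DEFAULT_MIN_READS) -> CountTable:
    """Remove samples whose read total is below ``min_reads``.

    Features are never removed.  Removals are logged with their sample ids.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    totals = table.totals()
    keep = totals.index[totals >= min_reads]
    removed = totals.index.difference(keep).tolist()
    if removed:
        logger.info("removed %d low-depth samples: %s", len(removed), removed)
    if len(keep) == 0:
        raise EmptyStudyError(
            f"min_reads={min_reads} removed every sample (max total {totals.max()})"
        )
    return table.subset_samples(list(keep))
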