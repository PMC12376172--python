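"""End-to-end pipeline orchestration.

Runs, in order: depth filtering, relative abundance, per-rank resolution
analysis at baseline, per-day site-persistence permANOVA on the untreated
arm, transplant tracking (donor classification, newly introduced ASVs,
engraftment trajectories, cross-site colonization, consecutive-timepoint
dissimilarity), ARG categorization and trajectories, and the between-site
convergence assessment for every arm.  All outputs are plain tab-separated
tables plus a JSON run manifest (seed, config echo, package version,
per-stage row counts) that fully determines the results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .argclass import (
    ArgMatchTable,
    arg_species_trajectory,
    categorize_asvs,
    category_abundance,
)
from .convergence import (
    DEFAULT_CONVERGENCE_THRESHOLD,
    assess_convergence,
    between_site_trajectory,
)
from .core import (
    CountTable,
    DEFAULT_MIN_READS,
    RANKS,
    TREATMENTS,
    filter_low_depth_samples,
    read_count_table,
    to_relative_abundance,
)
from .resolution import (
    differential_abundance_screen,
    eta_squared_by_resolution,
    shared_taxa,
    top_taxa_comparison,
)
from .simulate import SimulationConfig, simulate_study
from .stats import DEFAULT_PERMUTATIONS, pairwise_distances, permanova
from .tracking import (
    DEFAULT_INTRODUCTION_DAY,
    DonorProfile,
    classify_donor_asvs,
    consecutive_dissimilarity,
    cross_site_colonization,
    engraftment_trajectory,
    newly_introduced_asvs,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a stage fails; names the stage and offending entity."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Top-level run configuration; one seed drives every stochastic stage."""

    seed: int = 0
    outdir: str | Path = "cmtrack_out"
    min_reads: int = DEFAULT_MIN_READS
    n_permutations: int = DEFAULT_PERMUTATIONS
    ranks: tuple[str, ...] = RANKS
    convergence_threshold: float = DEFAULT_CONVERGENCE_THRESHOLD
    introduction_day: int = DEFAULT_INTRODUCTION_DAY
    top_k: int = 5
    arg_top_k: int = 10
    # either simulate ...
    simulation: SimulationConfig | None = None
    # ... or read input files
    counts_path: str | None = None
    metadata_path: str | None = None
    fasta_path: str | None = None
    taxonomy_path: str | None = None
    donor_path: str | None = None
    arg_matches_path: str | None = None


@dataclass
class ReportBundle:
    """In-memory results of a pipeline run; all tables are also on disk."""

    table: CountTable
    trajectories: dict[str, object]
    verdicts: pd.DataFrame
    persistence: pd.DataFrame
    resolution_eta: pd.DataFrame
    shared_taxa: pd.DataFrame
    engraftment: pd.DataFrame | None
    manifest: dict


def _load_inputs(config: RunConfig):
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        table, donor, matches, truth = simulate_study(sim)
        return table, donor, matches
    if config.counts_path is None or config.metadata_path is None:
        raise FileNotFoundError("counts_path and metadata_path are required")
    for path in (config.counts_path, config.metadata_path):
        if not Path(path).exists():
            raise FileNotFoundError(f"missing input file: {path}")
    table = read_count_table(
        config.counts_path,
        config.metadata_path,
        fasta_path=config.fasta_path,
        taxonomy_path=config.taxonomy_path,
    )
    donor = DonorProfile.read(config.donor_path) if config.donor_path else None
    matches = (
        ArgMatchTable.read(config.arg_matches_path, set(table.asv_ids))
        if config.arg_matches_path
        else None
    )
    return table, donor, matches


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute every analysis stage and write the report tables."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "version": __version__,
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "tables": {},
    }
    manifest["config"]["outdir"] = str(config.outdir)

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise PipelineError(name, exc) from exc

        return wrap

    table, donor, matches = stage("load_inputs")(_load_inputs, config)
    table = stage("depth_filter")(filter_low_depth_samples, table, config.min_reads)

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t")
        manifest["tables"][name] = {"path": path.name, "rows": int(len(df))}

    # --- resolution analysis on baseline samples -------------------------
    baseline = table.select(day=table.baseline_day)
    eta = stage("resolution_eta")(
        eta_squared_by_resolution,
        baseline,
        ranks=config.ranks,
        split_by="site",
        n_permutations=config.n_permutations,
        seed=config.seed,
    )
    eta_df = pd.DataFrame(
        [
            {
                "rank": rank,
                "eta_squared": res.eta_squared,
                "pseudo_F": res.pseudo_F,
                "p_value": res.p_value,
                "n_permutations": res.n_permutations,
            }
            for rank, res in eta.items()
        ]
    ).set_index("rank")
    emit("resolution_eta", eta_df)

    shared_rows = []
    for rank in config.ranks:
        s = stage("shared_taxa")(shared_taxa, baseline, rank, "site")
        shared_rows.append(dataclasses.asdict(s))
    shared_df = pd.DataFrame(shared_rows).set_index("rank")
    emit("shared_taxa", shared_df)

    screens = []
    for rank in config.ranks:
        hits = stage("differential_screen")(
            differential_abundance_screen, baseline, rank, "site"
        )
        screens.extend(dataclasses.asdict(h) for h in hits)
    emit("differential_screen", pd.DataFrame(screens))

    top_frames = [
        stage("top_taxa")(top_taxa_comparison, baseline, rank, "site", config.top_k)
        for rank in config.ranks
    ]
    emit("top_taxa", pd.concat(top_frames))

    # --- persistence: per-day site effect in the untreated arm -----------
    untr = table.select(treatment="UNTR")
    persistence_rows = []
    for day in sorted(untr.samples["day"].unique()):
        day_table = untr.select(day=day)
        if day_table.samples["site"].nunique() < 2:
            continue
        abundance = to_relative_abundance(day_table)
        d = pairwise_distances(abundance)
        res = stage("persistence")(
            permanova,
            d,
            day_table.samples.loc[list(d.ids), "site"],
            config.n_permutations,
            config.seed,
        )
        persistence_rows.append(
            {
                "day": day,
                "eta_squared": res.eta_squared,
                "pseudo_F": res.pseudo_F,
                "p_value": res.p_value,
            }
        )
    persistence_df = pd.DataFrame(persistence_rows).set_index("day")
    emit("persistence", persistence_df)

    # --- consecutive-timepoint stability ---------------------------------
    consec = stage("consecutive_dissimilarity")(consecutive_dissimilarity, table)
    emit("consecutive_dissimilarity", consec.set_index("subject_id"))

    # --- transplant tracking ----------------------------------------------
    engraft_df = None
    if donor is not None:
        partition = stage("classify_donor")(
            classify_donor_asvs, table.features, donor
        )
        emit(
            "donor_partition",
            pd.Series(partition, name="provenance").rename_axis("asv_id").to_frame(),
        )
        introduced = stage("newly_introduced")(
            newly_introduced_asvs,
            table,
            donor,
            introduction_day=config.introduction_day,
        )
        emit(
            "newly_introduced",
            pd.DataFrame(
                [
                    {"site": site, "treatment": trt, "n_new_asvs": len(asvs)}
                    for (site, trt), asvs in sorted(introduced.items())
                ]
            ).set_index(["site", "treatment"]),
        )
        engraft_df = stage("engraftment")(engraftment_trajectory, table, partition)
        emit("engraftment", engraft_df)
        colonization_rows = []
        for trt in ("CMT", "ABX3CMT"):
            if trt in set(table.samples["treatment"]):
                frac_taxa, frac_abund = stage("cross_site_colonization")(
                    cross_site_colonization, table, partition, trt
                )
                colonization_rows.append(
                    {
                        "treatment": trt,
                        "frac_shared_colonized_taxa": frac_taxa,
                        "frac_donor_abundance_from_shared": frac_abund,
                    }
                )
        emit(
            "cross_site_colonization",
            pd.DataFrame(colonization_rows).set_index("treatment"),
        )

    # --- ARG categorization ------------------------------------------------
    if matches is not None:
        categories = stage("categorize_asvs")(categorize_asvs, matches)
        emit(
            "arg_categories",
            pd.Series(categories, name="category").rename_axis("asv_id").to_frame(),
        )
        cat_ab = stage("category_abundance")(category_abundance, table, categories)
        emit("arg_category_abundance", cat_ab)
        traj = stage("arg_species_trajectory")(
            arg_species_trajectory, table, categories, config.arg_top_k
        )
        emit("arg_species_trajectory", traj)

    # --- convergence --------------------------------------------------------
    trajectories: dict[str, object] = {}
    verdict_rows = []
    for trt in TREATMENTS:
        if trt not in set(table.samples["treatment"]):
            continue
        traj = stage("between_site_trajectory")(
            between_site_trajectory, table, trt, trt == "UNTR"
        )
        trajectories[trt] = traj
        emit(f"convergence_trajectory_{trt}", traj.per_day)
        if traj.within_site is not None:
            emit(f"within_site_trajectory_{trt}", traj.within_site)
        verdict = stage("assess_convergence")(
            assess_convergence, traj, config.convergence_threshold
        )
        verdict_rows.append(dataclasses.asdict(verdict))
    verdicts = pd.DataFrame(verdict_rows).set_index("treatment")
    emit("convergence_verdicts", verdicts)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("pipeline complete; %d tables in %s", len(manifest["tables"]), outdir)

    return ReportBundle(
        table=table,
        trajectories=trajectories,
        verdicts=verdicts,
        persistence=persistence_df,
        resolution_eta=eta_df,
        shared_taxa=shared_df,
        engraftment=engraft_df,
        manifest=manifest,
    )
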