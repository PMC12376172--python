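"""Synthetic longitudinal ASV-community studies.

Generates complete two-site, four-arm transplant studies — counts, metadata,
sequences, taxonomy, donor profile, resistance-gene annotations, and ground
truth — with the statistical structure the downstream analysis assumes:

* two sites whose baseline communities share a core of taxa but are strongly
  differentiated in composition (site-specific ASVs plus independent
  abundances of shared ASVs);
* four arms: untreated (UNTR), ten days of antibiotics (ABX10), three days of
  antibiotics followed by cecal transplant (ABX3CMT), and transplant alone
  (CMT);
* antibiotic knockdown that spares carriers of antibiotic-resistance genes,
  with stochastic per-subject recolonization of suppressed taxa afterwards;
* engraftment from a single shared donor inoculum, mixed into the recipient's
  latent profile on the transplant day; and
* multinomial read sampling at Poisson-distributed depth.

Latent dynamics operate on relative abundances, renormalized after every
intervention, mirroring the compositional nature of the real data.  All
randomness descends from a single seed; per-(subject, day) substreams are
derived by stable hashing so results do not depend on iteration order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .argclass import ArgMatchTable
from .core import (
    CountTable,
    DEFAULT_SCHEDULE,
    SITES,
    TREATMENTS,
    write_count_table,
)
from .tracking import DonorProfile

#: Calendar day on which the cecal transplant is gavaged (CMT and ABX3CMT).
CMT_DAY = 4
#: Antibiotic dosing windows per arm (inclusive calendar-day ranges).
ABX_WINDOWS = {"ABX10": (1, 10), "ABX3CMT": (1, 3)}

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study generator.

    Defaults reproduce the study design (two sites, four arms, eight sampling
    days, 20 subjects per arm and site) with generator dynamics calibrated so
    that baseline communities are strongly site-differentiated
    (between-site Bray–Curtis around 0.8), antibiotics collapse richness to a
    small resistant remnant, and a shared inoculum drives the CMT arm below
    the 0.5 between-site convergence threshold by the final day.
    """

    seed: int = 42
    n_subjects_per_group: int = 20
    schedule: tuple[int, ...] = DEFAULT_SCHEDULE
    n_shared_asvs: int = 60
    n_siteA_asvs: int = 40
    n_siteB_asvs: int = 40
    n_donor_asvs: int = 80
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 2.0
    #: multiplicative log-normal sigma applied per site to shared-taxon
    #: template abundances; controls how far the two baseline communities sit
    #: apart on shared taxa (site-specific taxa are fully independent).
    site_jitter_sigma: float = 1.2
    dirichlet_concentration: float = 150.0
    depth_mean: float = 20_000.0
    abx_survival_sensitive: float = 0.001
    abx_survival_arg: float = 0.5
    engraftment_weight: float = 0.8
    recolonization_rate: float = 0.01
    frac_arg_asvs: float = 0.10
    #: Fraction of (subject, day) cells dropped at random to emulate missing
    #: samples (early euthanasia, failed extractions); 0 disables.
    missing_fraction: float = 0.0

    def validate(self) -> None:
        fractions = {
            "abx_survival_sensitive": self.abx_survival_sensitive,
            "abx_survival_arg": self.abx_survival_arg,
            "engraftment_weight": self.engraftment_weight,
            "recolonization_rate": self.recolonization_rate,
            "frac_arg_asvs": self.frac_arg_asvs,
            "missing_fraction": self.missing_fraction,
        }
        for name, value in fractions.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        counts = {
            "n_subjects_per_group": self.n_subjects_per_group,
            "n_shared_asvs": self.n_shared_asvs,
            "n_siteA_asvs": self.n_siteA_asvs,
            "n_siteB_asvs": self.n_siteB_asvs,
            "n_donor_asvs": self.n_donor_asvs,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        sched = tuple(self.schedule)
        if len(sched) < 2 or any(b <= a for a, b in zip(sched, sched[1:])):
            raise ValueError(f"schedule must be strictly increasing, got {sched}")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")
        if self.lognormal_sigma <= 0:
            raise ValueError("lognormal_sigma must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "schedule" in data:
            data["schedule"] = tuple(int(d) for d in data["schedule"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["schedule"] = list(self.schedule)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class SimulationTruth:
    """Generator bookkeeping enabling ground-truth recovery tests."""

    donor_asv_ids: set[str]
    siteA_specific_ids: set[str]
    siteB_specific_ids: set[str]
    shared_ids: set[str]
    arg_asv_ids: set[str]
    #: latent relative-abundance profile of each subject at each sampled day
    latent_trajectories: dict[str, pd.DataFrame] = field(default_factory=dict)

    def origin_of(self, asv_id: str) -> str:
        if asv_id in self.donor_asv_ids:
            return "donor"
        if asv_id in self.shared_ids:
            return "shared"
        if asv_id in self.siteA_specific_ids:
            return "site_a"
        if asv_id in self.siteB_specific_ids:
            return "site_b"
        raise KeyError(asv_id)


def default_scenario() -> SimulationConfig:
    """Calibrated default scenario used by the acceptance checks.

    Ten subjects per arm and site (for speed), strong baseline site
    differentiation, and a shared inoculum whose engraftment drives the CMT
    arm convergent while UNTR stays apart.  The seed is the fixed documented
    integer 42.
    """
    return SimulationConfig(n_subjects_per_group=10, seed=42)


# ----------------------------------------------------------------------
# RNG substreams
# ----------------------------------------------------------------------

def _substream(seed: int, *tokens) -> np.random.Generator:
    """Deterministic generator derived from the root seed and string tokens.

    Uses BLAKE2 of the token tuple (not Python's randomized ``hash``) so the
    stream is stable across processes and iteration orders.
    """
    key = "|".join(str(t) for t in tokens).encode()
    digest = hashlib.blake2b(key, digest_size=8).digest()
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int.from_bytes(digest, "big")])
    )


def _random_sequences(rng: np.random.Generator, n: int, length: int = 80) -> list[str]:
    seqs: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        seq = "".join(_BASES[rng.integers(0, 4, size=length)])
        if seq not in seqs:
            seqs.add(seq)
            out.append(seq)
    return out


# ----------------------------------------------------------------------
# Study assembly
# ----------------------------------------------------------------------

def _feature_frame(config: SimulationConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Feature table (sequence, species, genus) plus origin index masks.

    Taxonomy is constructed so that site-specific ASVs pair up into species
    shared across sites: the sites then differ by *which* ASV of a shared
    species dominates, the situation where ASV-level resolution outperforms
    species-level collapse.  A few donor ASVs are placed into those same
    species to emulate species containing both donor and non-donor strains.
    """
    shared = [f"SH{i:04d}" for i in range(config.n_shared_asvs)]
    site_a = [f"LA{i:04d}" for i in range(config.n_siteA_asvs)]
    site_b = [f"LB{i:04d}" for i in range(config.n_siteB_asvs)]
    donor = [f"DN{i:04d}" for i in range(config.n_donor_asvs)]
    all_ids = shared + site_a + site_b + donor

    species: dict[str, str] = {}
    for i, asv in enumerate(shared):
        species[asv] = f"Sp_shared_{i // 2:03d}"
    n_cross = max(config.n_siteA_asvs, config.n_siteB_asvs)
    for i, asv in enumerate(site_a):
        species[asv] = f"Sp_cross_{i:03d}"
    for i, asv in enumerate(site_b):
        species[asv] = f"Sp_cross_{i % n_cross:03d}"
    for i, asv in enumerate(donor):
        if i < 4 and n_cross >= 2:
            # donor strains of species also present in the environment
            species[asv] = f"Sp_cross_{i // 2:03d}"
        else:
            species[asv] = f"Sp_donor_{i // 2:03d}"

    def genus_of(sp: str) -> str:
        stem, idx = sp.rsplit("_", 1)
        return f"Gen{stem.removeprefix('Sp')}_{int(idx) // 3:03d}"

    seqs = _random_sequences(rng, len(all_ids))
    features = pd.DataFrame(
        {
            "sequence": seqs,
            "species": [species[a] for a in all_ids],
            "genus": [genus_of(species[a]) for a in all_ids],
        },
        index=pd.Index(all_ids, name="asv_id"),
    )
    masks = {
        "shared": np.isin(all_ids, shared),
        "site_a": np.isin(all_ids, site_a),
        "site_b": np.isin(all_ids, site_b),
        "donor": np.isin(all_ids, donor),
    }
    return features, masks


def _site_templates(
    config: SimulationConfig,
    seed: int,
    masks: dict[str, np.ndarray],
    n_features: int,
) -> dict[str, np.ndarray]:
    """Baseline latent profiles per site.

    Shared taxa draw a common abundance once, then each site multiplies it by
    an independent log-normal jitter; site-specific taxa draw independently
    per site.  The jitter magnitude sets how dissimilar the two baseline
    communities are despite their overlapping membership.
    """
    rng_common = _substream(seed, "template-common")
    common = np.zeros(n_features)
    common[masks["shared"]] = rng_common.lognormal(
        config.lognormal_mu, config.lognormal_sigma, size=int(masks["shared"].sum())
    )
    out = {}
    for site, specific in (("SITE_A", "site_a"), ("SITE_B", "site_b")):
        rng = _substream(seed, "template", site)
        values = np.zeros(n_features)
        values[masks["shared"]] = common[masks["shared"]] * rng.lognormal(
            0.0, config.site_jitter_sigma, size=int(masks["shared"].sum())
        )
        values[masks[specific]] = rng.lognormal(
            config.lognormal_mu, config.lognormal_sigma, size=int(masks[specific].sum())
        )
        out[site] = values / values.sum()
    return out


def _donor_template(
    config: SimulationConfig, rng: np.random.Generator, donor_mask: np.ndarray
) -> np.ndarray:
    values = np.zeros(donor_mask.shape[0])
    raw = rng.lognormal(config.lognormal_mu, config.lognormal_sigma, size=int(donor_mask.sum()))
    raw = raw / raw.sum()
    # floor rare inoculum members so deep replicate sequencing observes them all
    raw = np.maximum(raw, 2e-4)
    values[donor_mask] = raw / raw.sum()
    return values


def _dirichlet_perturb(
    rng: np.random.Generator, template: np.ndarray, concentration: float
) -> np.ndarray:
    out = np.zeros_like(template)
    support = template > 0
    alpha = template[support] * concentration
    out[support] = rng.dirichlet(alpha)
    return out


def _arg_match_table(
    config: SimulationConfig,
    rng: np.random.Generator,
    features: pd.DataFrame,
    arg_ids: set[str],
) -> ArgMatchTable:
    rows = []
    for asv in features.index:
        if asv in arg_ids:
            for g in range(int(rng.integers(1, 3))):
                rows.append((asv, f"GEN_{asv}_{g}", True))
        else:
            u = rng.random()
            if u < 0.65:  # matched, resistance-free genomes
                for g in range(int(rng.integers(1, 3))):
                    rows.append((asv, f"GEN_{asv}_{g}", False))
            elif u < 0.75:  # ambiguous: hits both kinds of genomes
                rows.append((asv, f"GEN_{asv}_0", True))
                rows.append((asv, f"GEN_{asv}_1", False))
            # else unmatched: no genome hits at all
    df = pd.DataFrame(rows, columns=["asv_id", "genome_id", "has_arg"])
    return ArgMatchTable(matches=df, asv_universe=set(features.index))


def simulate_study(
    config: SimulationConfig,
) -> tuple[CountTable, DonorProfile, ArgMatchTable, SimulationTruth]:
    """Simulate a complete two-site four-arm transplant study.

    Deterministic given ``config.seed``.  Per subject, the baseline latent
    profile is the site template perturbed by symmetric Dirichlet resampling;
    each calendar day applies, in order: sample emission (collections precede
    that day's dosing), antibiotic knockdown (multiplying non-resistant taxa
    by ``abx_survival_sensitive`` and resistance-gene carriers by
    ``abx_survival_arg`` per dosing day), transplant mixing on the gavage day
    (donor profile mixed in at ``engraftment_weight``), and stochastic
    rebound of antibiotic-suppressed taxa at ``recolonization_rate`` per day
    with a random per-event magnitude.  Observed counts are multinomial at
    Poisson(``depth_mean``) depth; the donor inoculum is emitted as two
    deeply sequenced replicate samples.
    """
    config.validate()
    seed = config.seed
    features, masks = _feature_frame(config, _substream(seed, "features"))
    n_feat = len(features)
    env_mask = masks["shared"] | masks["site_a"] | masks["site_b"]
    env_ids = features.index[env_mask]

    templates = _site_templates(config, seed, masks, n_feat)
    donor_template = _donor_template(config, _substream(seed, "donor"), masks["donor"])

    n_arg = int(round(config.frac_arg_asvs * len(env_ids)))
    arg_ids = set(
        _substream(seed, "arg").choice(env_ids.to_numpy(), size=n_arg, replace=False)
    )
    arg_mask = features.index.isin(arg_ids).astype(bool)

    match_table = _arg_match_table(config, _substream(seed, "argtable"), features, arg_ids)

    schedule = tuple(config.schedule)
    baseline_day = schedule[0]
    n_per = config.n_subjects_per_group

    rows: list[np.ndarray] = []
    meta_rows: list[dict] = []
    latent: dict[str, pd.DataFrame] = {}
    drop_rng = _substream(seed, "missing")

    for site in SITES:
        for arm in TREATMENTS:
            for i in range(n_per):
                subject = f"{site[-1]}-{arm}-{i:02d}"
                sex = "F" if i < (n_per + 1) // 2 else "M"
                rng_subj = _substream(seed, "subject", subject)
                baseline = _dirichlet_perturb(
                    rng_subj, templates[site], config.dirichlet_concentration
                )
                profile = baseline.copy()
                suppressed = np.zeros(n_feat, dtype=bool)
                subj_days: dict[int, np.ndarray] = {}
                abx_window = ABX_WINDOWS.get(arm)
                gets_cmt = arm in ("CMT", "ABX3CMT")
                for day in range(baseline_day, schedule[-1] + 1):
                    rng_day = _substream(seed, "dyn", subject, day)
                    if day in schedule:
                        if config.missing_fraction > 0 and drop_rng.random() < config.missing_fraction:
                            pass  # sample lost (failed extraction / early euthanasia)
                        else:
                            depth = max(int(rng_day.poisson(config.depth_mean)), 1)
                            total = profile.sum()
                            if total > 0:
                                counts = rng_day.multinomial(depth, profile / total)
                            else:
                                counts = np.zeros(n_feat, dtype=np.int64)
                            rows.append(counts.astype(np.int64))
                            meta_rows.append(
                                {
                                    "sample_id": f"{subject}-d{day}",
                                    "subject_id": subject,
                                    "site": site,
                                    "treatment": arm,
                                    "day": day,
                                    "sex": sex,
                                }
                            )
                            subj_days[day] = (
                                profile / total if total > 0 else profile.copy()
                            )
                    if abx_window and abx_window[0] <= day <= abx_window[1]:
                        if config.abx_survival_sensitive < 1:
                            sens = ~arg_mask
                            profile[sens] *= config.abx_survival_sensitive
                            suppressed |= sens & (baseline > 0)
                        if config.abx_survival_arg < 1:
                            profile[arg_mask] *= config.abx_survival_arg
                            suppressed |= arg_mask & (baseline > 0)
                        total = profile.sum()
                        if total > 0:
                            profile /= total
                    if gets_cmt and day == CMT_DAY:
                        total = profile.sum()
                        if total > 0:
                            profile = (
                                (1 - config.engraftment_weight) * profile / total
                                + config.engraftment_weight * donor_template
                            )
                        else:
                            profile = donor_template.copy()
                        profile /= profile.sum()
                    if config.recolonization_rate > 0 and suppressed.any():
                        sup_ix = np.flatnonzero(suppressed)
                        hits = sup_ix[
                            rng_day.random(len(sup_ix)) < config.recolonization_rate
                        ]
                        if len(hits):
                            profile[hits] = baseline[hits] * rng_day.lognormal(
                                0.0, 0.75, size=len(hits)
                            )
                            suppressed[hits] = False
                            profile /= profile.sum()
                if subj_days:
                    latent[subject] = pd.DataFrame(
                        subj_days, index=features.index
                    ).T.sort_index()

    counts_df = pd.DataFrame(
        np.vstack(rows),
        index=[m["sample_id"] for m in meta_rows],
        columns=features.index,
    )
    samples_df = pd.DataFrame(meta_rows).set_index("sample_id")
    table = CountTable(
        counts=counts_df,
        samples=samples_df,
        features=features,
        schedule=schedule,
        baseline_day=baseline_day,
    )

    rng_donor_rep = _substream(seed, "donor-replicates")
    donor_ids = features.index[masks["donor"]]
    donor_probs = donor_template[masks["donor"]]
    replicates = pd.DataFrame(
        [
            rng_donor_rep.multinomial(
                max(int(rng_donor_rep.poisson(5 * config.depth_mean)), 1), donor_probs
            )
            for _ in range(2)
        ],
        index=["DONOR_R1", "DONOR_R2"],
        columns=donor_ids,
    )
    donor_profile = DonorProfile(
        replicates=replicates,
        sequences={a: features.loc[a, "sequence"] for a in donor_ids},
    )

    truth = SimulationTruth(
        donor_asv_ids=set(donor_ids),
        siteA_specific_ids=set(features.index[masks["site_a"]]),
        siteB_specific_ids=set(features.index[masks["site_b"]]),
        shared_ids=set(features.index[masks["shared"]]),
        arg_asv_ids=arg_ids,
        latent_trajectories=latent,
    )
    return table, donor_profile, match_table, truth


# ----------------------------------------------------------------------
# File emission (CLI backend)
# ----------------------------------------------------------------------

def write_study(
    outdir: str | Path,
    table: CountTable,
    donor: DonorProfile,
    matches: ArgMatchTable,
    truth: SimulationTruth,
) -> dict[str, Path]:
    """Write the simulated study as the plain-text external formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "metadata.tsv",
        "fasta": outdir / "asvs.fasta",
        "taxonomy": outdir / "taxonomy.tsv",
        "donor": outdir / "donor_profile.tsv",
        "matches": outdir / "arg_matches.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_count_table(
        table, paths["counts"], paths["metadata"], paths["fasta"], paths["taxonomy"]
    )
    donor.write(paths["donor"])
    matches.write(paths["matches"])
    truth_df = pd.DataFrame(
        {
            "asv_id": list(table.features.index),
            "origin": [truth.origin_of(a) for a in table.features.index],
            "is_arg": [int(a in truth.arg_asv_ids) for a in table.features.index],
        }
    )
    truth_df.to_csv(paths["truth"], sep="\t", index=False)
    return paths
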