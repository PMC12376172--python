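import dataclasses

import numpy as np
import pandas as pd
import pytest

from cmtrack.core import CountTable
from cmtrack.simulate import SimulationConfig, default_scenario, simulate_study


def build_table(
    counts,
    sites=None,
    treatments=None,
    days=None,
    subjects=None,
    species=None,
    genus=None,
    sequences=None,
    schedule=(-2, 1, 3, 5, 8, 10, 30, 60),
):
    """Construct a small valid CountTable from a 2-D array of counts."""
    counts = np.asarray(counts)
    n, m = counts.shape
    sample_ids = [f"s{i}" for i in range(n)]
    asv_ids = [f"asv{j}" for j in range(m)]
    meta = pd.DataFrame(
        {
            "subject_id": subjects or [f"m{i}" for i in range(n)],
            "site": sites or ["SITE_A"] * n,
            "treatment": treatments or ["UNTR"] * n,
            "day": days or [-2] * n,
            "sex": ["F" if i % 2 == 0 else "M" for i in range(n)],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    feat = pd.DataFrame(
        {
            "sequence": sequences or [None] * m,
            "species": species or [None] * m,
            "genus": genus or [None] * m,
        },
        index=pd.Index(asv_ids, name="asv_id"),
    )
    return CountTable(
        counts=pd.DataFrame(counts, index=sample_ids, columns=asv_ids),
        samples=meta,
        features=feat,
        schedule=schedule,
    )


#: Compact simulation used where full study size is unnecessary.
SMALL_SIM = SimulationConfig(
    seed=7,
    n_subjects_per_group=3,
    n_shared_asvs=20,
    n_siteA_asvs=10,
    n_siteB_asvs=10,
    n_donor_asvs=20,
    depth_mean=5000,
)


@pytest.fixture(scope="session")
def small_sim():
    return simulate_study(dataclasses.replace(SMALL_SIM))


@pytest.fixture(scope="session")
def default_sim():
    """The calibrated default scenario (seed 42)."""
    return simulate_study(default_scenario())


@pytest.fixture(scope="session")
def default_sims_by_seed():
    """Default-scenario studies for seeds 1..5 (shared across modules)."""
    out = {}
    for seed in range(1, 6):
        cfg = dataclasses.replace(default_scenario(), seed=seed)
        out[seed] = simulate_study(cfg)
    return out
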