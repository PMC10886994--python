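import numpy as np
import pandas as pd
import pytest

from abvs import CohortConfig, generate_cohort, simulate_external_table, simulate_feature_table
from abvs.features import FEATURES_4


def random_toy_table(
    rng: np.random.Generator,
    n_subjects: int = 5,
    features: tuple[str, ...] = ("HR", "PEP", "LVET", "PEP_LVET"),
    beats: int = 20,
) -> pd.DataFrame:
    """Small random feature table with baseline and stabilization rows."""
    rows = []
    for s in range(n_subjects):
        sid = f"s{s}"
        weight = float(rng.uniform(40, 90))
        for phase, label, step in (("baseline", 0.0, 0), ("stabilization", 50.0, 1),
                                   ("stabilization", 100.0, 2)):
            for _ in range(beats // 2 if phase == "baseline" else beats):
                row = {"subject_id": sid, "phase": phase, "step_index": step,
                       "abvs_label": label, "weight_kg": weight}
                for f in features:
                    row[f] = float(rng.uniform(0.5, 2.0))
                rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def cohort_config() -> CohortConfig:
    return CohortConfig(seed=0)


@pytest.fixture(scope="session")
def feature_table(cohort_config) -> pd.DataFrame:
    profiles = generate_cohort(cohort_config)
    return simulate_feature_table(profiles, cohort_config)


@pytest.fixture(scope="session")
def external_table(cohort_config) -> pd.DataFrame:
    return simulate_external_table(18, cohort_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_table(rng) -> pd.DataFrame:
    return random_toy_table(rng)


@pytest.fixture()
def toy_weights(toy_table) -> dict[str, float]:
    return (
        toy_table.groupby("subject_id", sort=False)["weight_kg"].first().astype(float).to_dict()
    )


@pytest.fixture(scope="session")
def model_features() -> list[str]:
    return list(FEATURES_4)
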