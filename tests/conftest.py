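import numpy as np
import pandas as pd
import pytest

from tivbias.config import CohortConfig, MatchingConfig
from tivbias.synth import generate_cohort


def make_subjects(
    n_per_sex: int = 50,
    sites=("siteA",),
    tiv_f: float = 1350.0,
    tiv_m: float = 1550.0,
    tiv_sd: float = 120.0,
    age_lo: float = 18.0,
    age_hi: float = 65.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Minimal subject table without features, for matcher/audit tests."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_sex
    sex = np.array(["F"] * n_per_sex + ["M"] * n_per_sex)
    tiv = np.concatenate(
        [rng.normal(tiv_f, tiv_sd, n_per_sex), rng.normal(tiv_m, tiv_sd, n_per_sex)]
    )
    return pd.DataFrame(
        {
            "id": [f"s{i:04d}" for i in range(n)],
            "site": rng.choice(list(sites), size=n),
            "sex": sex,
            "gender_group": np.where(sex == "F", "CW", "CM"),
            "age": rng.uniform(age_lo, age_hi, n),
            "tiv": tiv,
            "total_gmv": rng.normal(600.0, 30.0, n),
        }
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small but signal-bearing cohort reused across pipeline tests."""
    cfg = CohortConfig(
        n_per_sex=120, n_sites=2, n_features=60, signal_amplitude=2.0,
        scaling_leak=0.5, noise_sd=1.0, seed=123,
    )
    subjects, features = generate_cohort(cfg)
    return cfg, subjects, features


@pytest.fixture()
def matching_config():
    return MatchingConfig()
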