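import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import anoxmeta as am

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_study() -> am.ExpressionStudy:
    """2 conditions x 3 reps, 6 genes, deterministic values."""
    rng = np.random.default_rng(11)
    genes = [f"g{i}" for i in range(6)]
    samples = ["c_r1", "c_r2", "c_r3", "t_r1", "t_r2", "t_r3"]
    values = pd.DataFrame(rng.normal(8, 1, size=(6, 6)), index=genes, columns=samples)
    design = pd.DataFrame(
        {
            "sample": samples,
            "condition": ["control"] * 3 + ["treatment"] * 3,
            "timepoint": [pd.NA] * 6,
            "replicate": [1, 2, 3, 1, 2, 3],
        }
    ).set_index("sample")
    return am.ExpressionStudy("toy", values, design)


@pytest.fixture(scope="session")
def pair_fixture():
    """The default two-species compendium (shared; treat as read-only)."""
    return am.generate_species_pair(seed=0)


@pytest.fixture(scope="session")
def pair_results(pair_fixture):
    from anoxmeta.pipeline import run_species_pair

    return run_species_pair(pair_fixture, seed=0)
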