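import numpy as np
import pandas as pd
import pytest

from splitclust import (
    AnalysisConfig,
    Cohort,
    SyntheticConfig,
    default_schema,
    generate_cohort,
    transform_cohort,
)


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort: 36 CVS + 30 no-CVS patients."""
    return generate_cohort(SyntheticConfig(rng_seed=7))


@pytest.fixture(scope="session")
def transformed(cohort):
    out, _ = transform_cohort(cohort)
    return out


def make_cohort(frame: pd.DataFrame, schema) -> Cohort:
    """Wrap a raw data frame (id column added if absent) into a Cohort."""
    df = frame.copy()
    if schema.id_column not in df.columns:
        df.insert(0, schema.id_column, [f"P{i:04d}" for i in range(len(df))])
    return Cohort(df, schema)


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


def spawned_seeds(base: int, n: int) -> list[int]:
    """Independent replicate seeds below 2**31."""
    return [
        int(ss.generate_state(1)[0] % 2**31)
        for ss in np.random.SeedSequence(base).spawn(n)
    ]
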