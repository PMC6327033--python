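import numpy as np
import pandas as pd
import pytest

from rumengwas import AbundanceMatrix, PhenotypeTable, SimulationConfig, simulate_cohorts


def make_abundance(values, unit="counts", sample_prefix="s", feature_prefix="f"):
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        values,
        index=pd.Index([f"{sample_prefix}{i}" for i in range(values.shape[0])], name="sample_id"),
        columns=[f"{feature_prefix}{j}" for j in range(values.shape[1])],
    )
    return AbundanceMatrix(df, unit=unit)


def make_phenotypes(n=6, population="herd", seed=0, **overrides):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "animal_id": [f"cow{i}" for i in range(n)],
        "milk_yield": rng.uniform(20, 40, n),
        "dmi": rng.uniform(15, 25, n),
        "body_weight": rng.uniform(550, 750, n),
        "parity": rng.choice(["primiparous", "multiparous"], n),
        "population": population,
    })
    for key, vals in overrides.items():
        df[key] = vals
    return PhenotypeTable(df)


@pytest.fixture(scope="session")
def small_cohorts():
    """Small but signal-rich synthetic cohorts shared across tests."""
    cfg = SimulationConfig(n_contigs=400, n_informative=25, n_informative_dmi=25,
                           effect_size=2.0, library_size_range=(50_000, 120_000),
                           rng_seed=42)
    return simulate_cohorts(cfg)
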