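import numpy as np
import pytest

import lendingrisk as lr


@pytest.fixture(scope="session")
def small_study():
    """One 10x10 simulated study shared across read-only tests."""
    cfg = lr.SimulationConfig(n_rows=10, n_cols=10, seed=42)
    table, adj, truth = lr.simulate_study(cfg)
    return cfg, table, adj, truth


@pytest.fixture(scope="session")
def fitted_trajectory_model(small_study):
    """Trajectory-model BYM fit on the shared study (generative labels)."""
    _, table, adj, truth = small_study
    df = lr.add_covariates(
        table.assign(trajectory=truth.latent_trajectory, exclusion_reason="")
    )
    X, names = lr.build_design(df, ("trajectory",))
    y = df["homicide_count"].to_numpy(dtype=float)
    E = df["expected_count"].to_numpy(dtype=float)
    draws = lr.fit_bym(
        y, E, X, adj,
        lr.ModelSpec(covariates=("trajectory",)),
        lr.MCMCSettings(chains=2, iterations=2000, burn_in=500, thin=2, seed=7),
        coefficient_names=names,
    )
    return draws, y, E, X, names, adj
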