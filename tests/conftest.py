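import numpy as np
import pandas as pd
import pytest

from uwatt import (
    default_config,
    fit_selection,
    match_nearest,
    predict_propensity,
    simulate_sites,
)


@pytest.fixture(scope="session")
def default_sim():
    """Reference scenario at seed 1: (config, sites, truth)."""
    config = default_config(seed=1)
    sites, truth = simulate_sites(config)
    return config, sites, truth


@pytest.fixture(scope="session")
def fitted_default(default_sim):
    """Selection fit, propensities and k=2 caliper matches for the reference
    scenario (matching stage in isolation, no support trimming)."""
    config, sites, _ = default_sim
    model = fit_selection(sites, config.covariate_names)
    p = predict_propensity(model, sites)
    matches = match_nearest(
        p,
        sites["D"].to_numpy(),
        k=2,
        caliper=0.01,
        site_id=sites["site_id"].to_numpy(),
        outcome=sites["Q"].to_numpy(dtype=float),
    )
    return model, p, matches


def make_sites(p=None, D=None, Q=None, **covariates):
    """Small handmade site table for targeted unit tests."""
    n = len(D)
    data = {"site_id": np.arange(1, n + 1)}
    data.update({k: np.asarray(v, dtype=float) for k, v in covariates.items()})
    data["D"] = np.asarray(D)
    data["Q"] = np.asarray(Q) if Q is not None else np.zeros(n, dtype=int)
    return pd.DataFrame(data)
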