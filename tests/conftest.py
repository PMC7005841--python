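import numpy as np
import pandas as pd
import pytest

from gqay.aggregate import aggregate_annual, filter_swards
from gqay.chemistry import add_quality_columns
from gqay.experiment import SimulationParams, build_design, build_swards, simulate_cuts

ZERO_CHEM_SIGMA = {k: 0.0 for k in ("gas", "cp", "ee", "ndf", "ash")}


@pytest.fixture(scope="session")
def plots():
    return build_design(seed=1)


@pytest.fixture(scope="session")
def swards(plots):
    return build_swards(plots)


@pytest.fixture(scope="session")
def annual_table(swards):
    """Annual table from one simulated experiment with default parameters."""
    cuts = simulate_cuts(swards, SimulationParams(seed=1))
    kept, _ = filter_swards(add_quality_columns(cuts))
    return aggregate_annual(kept)


@pytest.fixture(scope="session")
def noise_free_annual(swards):
    """Annual table from a fully deterministic simulation (all SDs zero)."""
    params = SimulationParams(
        sigma_block=0.0, sigma_plot=0.0, sigma_resid=0.0,
        chem_sigma=dict(ZERO_CHEM_SIGMA), ucp_sigma=0.0, seed=1,
    )
    cuts = simulate_cuts(swards, params)
    kept, _ = filter_swards(add_quality_columns(cuts))
    return aggregate_annual(kept)


def annual_biomass_table(cuts: pd.DataFrame) -> pd.DataFrame:
    """Fast annual biomass sums with design covariates (no chemistry needed)."""
    covs = [
        "plot_id", "block", "management", "richness", "n_functional_groups",
        "legume_present", "legume_share", "grass_present", "tall_herb_present",
    ]
    first = cuts.groupby("sward_id", sort=False)[covs].first()
    out = first.assign(biomass_yield=cuts.groupby("sward_id", sort=False)["biomass"].sum())
    return out.reset_index()
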