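import numpy as np
import pandas as pd
import pytest

import carisk as ck
from carisk.access import AccessConfig, access_index, provider_ratios


@pytest.fixture(scope="session")
def toy_region():
    """Hand-enumerable region: 3 areas and 2 provider sites on a line.

    With d0 = 30 km: site S0 (3 GPs at x=5) reaches areas at x=0 and x=10
    (pop 100+200) so R0 = 3/300; site S1 (2 GPs at x=35) reaches areas at
    x=10 and x=40 (pop 200+300) so R1 = 2/500. Access: A(0)=0.010,
    A(10)=0.014, A(40)=0.004.
    """
    areas = pd.DataFrame({
        "area_id": ["A0", "A1", "A2"],
        "x_km": [0.0, 10.0, 40.0],
        "y_km": [0.0, 0.0, 0.0],
        "adult_pop": [100, 200, 300],
        "irsd": [900.0, 1000.0, 1100.0],
        "access": np.nan,
    })
    providers = pd.DataFrame({
        "site_id": ["S0", "S1"],
        "x_km": [5.0, 35.0],
        "y_km": [0.0, 0.0],
        "gp_count": [3, 2],
        "ratio": np.nan,
    })
    return areas, providers


@pytest.fixture(scope="session")
def small_region_with_access():
    """A generated 80-area region with the 2SFCA index already computed."""
    cfg = ck.RegionConfig(
        n_areas=80, pop_range=(100, 300), n_provider_sites=12, gp_total=48,
        region_extent=(50.0, 40.0), irsd_missing_frac=0.0, seed=11,
    )
    areas = ck.generate_areas(cfg)
    providers = ck.generate_providers(cfg, areas)
    acfg = AccessConfig(buffer_km=30.0)
    providers = provider_ratios(providers, areas, acfg)
    areas = access_index(areas, providers, acfg)
    return cfg, areas, providers


@pytest.fixture(scope="session")
def simulated_cohort(small_region_with_access):
    """One-CMRF simulated cohort (records already dichotomized)."""
    _, areas, _ = small_region_with_access
    params = ck.OutcomeModelParams(
        intercept=-1.2, beta_male=0.3,
        beta_age=(0.2, 0.4, 0.6, 0.7, 0.6, 0.3),
        beta_irsd=-0.2, beta_access=-0.1, tau2=0.15,
    )
    records = ck.generate_persons(areas, seed=7, cmrfs=("BMI",),
                                  sampling_fraction=1.0, repeat_rate=0.0)
    records = ck.simulate_outcomes(records, areas, params, seed=7)
    records = records.merge(areas[["area_id", "irsd", "access"]], on="area_id")
    return areas, records, params
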