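import numpy as np
import pandas as pd
import pytest

from no2burden import SyntheticConfig, generate_bundle
from no2burden.synthetic import InputBundle


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticConfig:
    return SyntheticConfig(n_cities=6, n_provinces=3, seed=11)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_config):
    return generate_bundle(tiny_config)


def make_oracle_bundle() -> InputBundle:
    """Two population groups (one city, one age group, both sexes) with
    zero-variance exposures and hand-picked round numbers, so every pipeline
    quantity has a closed form a test can recompute by hand."""
    rows = []
    # (sex, household, cooking, ambient, indoor_smoking)
    strata = [
        ("boy", "non-smoking", 10.0, 30.0, np.nan),
        ("boy", "smoking", 10.0, 30.0, 15.0),
        ("girl", "non-smoking", 8.0, 25.0, np.nan),
        ("girl", "smoking", 8.0, 25.0, 12.0),
    ]
    for sex, hh, cook, amb, ind in strata:
        rows.append(
            dict(
                city="C001", province="P01", age_group="3-6", sex=sex,
                household=hh, cooking_mean=cook, cooking_sd=0.0,
                ambient_mean=amb, ambient_sd=0.0,
                indoor_smoking_mean=ind,
                indoor_smoking_sd=0.0 if hh == "smoking" else np.nan,
            )
        )
    exposure = pd.DataFrame(rows)
    population = pd.DataFrame(
        [
            dict(city="C001", province="P01", age_group="3-6", sex="boy",
                 N=100_000, IR=0.008),
            dict(city="C001", province="P01", age_group="3-6", sex="girl",
                 N=90_000, IR=0.006),
        ]
    )
    province = pd.DataFrame([dict(province="P01", f_exp=0.7, p_shs=0.4)])
    cost = pd.DataFrame(
        [
            dict(city="C001", age_group="3-6", sex="boy",
                 cost_direct=1000.0, treatment_days=3.0, gdp_daily=300.0),
            dict(city="C001", age_group="3-6", sex="girl",
                 cost_direct=1100.0, treatment_days=2.0, gdp_daily=300.0),
        ]
    )
    return InputBundle(exposure=exposure, population=population,
                       province=province, cost=cost)


@pytest.fixture()
def oracle_bundle() -> InputBundle:
    return make_oracle_bundle()


def zero_variance(bundle: InputBundle) -> InputBundle:
    """Copy of a bundle with every exposure SD forced to zero."""
    exposure = bundle.exposure.copy()
    for col in ("cooking_sd", "ambient_sd", "indoor_smoking_sd"):
        smoking_only = col.startswith("indoor")
        vals = np.where(
            exposure[col].notna() if smoking_only else True, 0.0, np.nan
        )
        exposure[col] = vals if smoking_only else 0.0
    return InputBundle(
        exposure=exposure, population=bundle.population,
        province=bundle.province, cost=bundle.cost, config=bundle.config,
    )
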