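"""Configuration models and domain constants.

All quantitative assumptions of the pipeline — the concentration-response
parameters, the counterfactual scenario targets, the Monte Carlo draw counts
and the synthetic-data generator settings — live here as validated pydantic
models, so computation modules never hard-code them.

Units used throughout the package:

* concentrations: µg/m³ (exposure) or ppb (the concentration-response scale);
* incidence: new cases per child per year;
* costs: nominal 2019 RMB; daily per-capita GDP in RMB/day.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

# ---------------------------------------------------------------------------
# Domain constants

AGE_GROUPS: tuple[str, ...] = ("0-0.5", "0.5-1", "1-2", "3-6", "7-11", "12-17")
SEXES: tuple[str, ...] = ("boy", "girl")
HOUSEHOLDS: tuple[str, ...] = ("non-smoking", "smoking")
SOURCES: tuple[str, ...] = ("ambient", "cooking", "shs")

#: Approximate year-width of each age group, used to split child population.
AGE_GROUP_WIDTHS: tuple[float, ...] = (0.5, 0.5, 2.0, 4.0, 5.0, 6.0)


class No2BurdenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(No2BurdenError):
    """Invalid configuration value."""


class SchemaError(No2BurdenError):
    """An input table violates the published data dictionary."""


class MissingContextError(No2BurdenError):
    """A city's province lacks an exposure-factor or SHS-proportion entry."""


class DegenerateInputError(No2BurdenError):
    """Input outside the mathematical domain of an operation."""


# ---------------------------------------------------------------------------
# Concentration-response function


class CRFunction(BaseModel):
    """Log-linear concentration-response relationship for NO₂ and new-onset
    pediatric asthma.

    Relative risk is ``rr0 ** ((C - lc) / delta_c0)`` for equivalent ambient
    concentration ``C`` (ppb) above the low-concentration threshold ``lc``,
    and 1 below it.  Central values follow the Khreis et al. meta-analysis:
    RR 1.26 (95% UI 1.10–1.37) per 10 ppb, threshold 2 ppb (range 0–5).

    ``ugm3_to_ppb`` converts NO₂ mass concentration to mixing ratio as
    ``ppb = 0.487 × µg/m³``; the factor is configurable so a sensitivity
    analysis can substitute, e.g., an East-Asia pooled risk coefficient.
    """

    model_config = ConfigDict(frozen=True)

    rr0: float = 1.26
    rr0_ui: tuple[float, float] = (1.10, 1.37)
    delta_c0: float = 10.0  # ppb
    lc: float = 2.0  # ppb
    lc_range: tuple[float, float] = (0.0, 5.0)  # ppb
    ugm3_to_ppb: float = 0.487

    @model_validator(mode="after")
    def _check(self) -> "CRFunction":
        if self.rr0 <= 0 or self.delta_c0 <= 0 or self.ugm3_to_ppb <= 0:
            raise ConfigurationError("rr0, delta_c0 and ugm3_to_ppb must be positive")
        if self.lc < 0:
            raise ConfigurationError("low-concentration threshold must be >= 0")
        lo, hi = self.rr0_ui
        if not (0 < lo <= self.rr0 <= hi):
            raise ConfigurationError("rr0_ui must bracket rr0")
        lo, hi = self.lc_range
        if not (0 <= lo <= self.lc <= hi):
            raise ConfigurationError("lc_range must bracket lc")
        return self


# ---------------------------------------------------------------------------
# Scenarios


class Scenario(BaseModel):
    """A named counterfactual transformation of baseline exposure.

    * ``BASELINE2019`` — identity.
    * ``SB`` — smoking ban: concentrations unchanged, P_SHS set to 0.
    * ``EC`` — electric cooking: cooking-source exposure set to 0.
    * ``IT1``/``IT2``/``IT3``/``AQG`` — outdoor air capped at the WHO interim
      targets / guideline (``outdoor_target`` µg/m³); cities already at or
      below the target are left unchanged.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    outdoor_target: Optional[float] = None  # µg/m³

    @model_validator(mode="after")
    def _check(self) -> "Scenario":
        if self.outdoor_target is not None and self.outdoor_target <= 0:
            raise ConfigurationError("outdoor_target must be positive")
        return self


BASELINE = Scenario(name="BASELINE2019")

#: Registry of the restriction scenarios, in increasing order of stringency
#: for the outdoor ones.
SCENARIOS: dict[str, Scenario] = {
    "SB": Scenario(name="SB"),
    "EC": Scenario(name="EC"),
    "IT1": Scenario(name="IT1", outdoor_target=40.0),
    "IT2": Scenario(name="IT2", outdoor_target=30.0),
    "IT3": Scenario(name="IT3", outdoor_target=20.0),
    "AQG": Scenario(name="AQG", outdoor_target=10.0),
}


def get_scenario(name: str) -> Scenario:
    if name == BASELINE.name:
        return BASELINE
    try:
        return SCENARIOS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown scenario {name!r}; expected one of "
            f"{[BASELINE.name, *SCENARIOS]}"
        ) from None


# ---------------------------------------------------------------------------
# Monte Carlo configuration


class MCConfig(BaseModel):
    """Two-stage Monte Carlo settings.

    The inner (variability) stage resamples individual exposure around each
    stratum's mean/SD; the outer (uncertainty) stage resamples the
    concentration-response parameters, baseline incidence, direct cost and
    treatment days.  Defaults are 2000 variability × 1000 uncertainty draws
    and a 250-repeat robustness check.
    """

    model_config = ConfigDict(frozen=True)

    n_variability: int = Field(default=2000, ge=1)
    n_uncertainty: int = Field(default=1000, ge=1)
    n_robustness_repeats: int = Field(default=250, ge=1)

    #: Intra-population exposure family: lognormal (default; positive and
    #: right-skewed) or a normal truncated at zero.
    exposure_family: str = "lognormal"
    #: RR0 uncertainty: lognormal matched to the printed median and 95% UI,
    #: or "degenerate" (point value).
    rr0_dist: str = "lognormal"
    #: LC uncertainty: triangular(min, mode, max) over lc_range with mode lc
    #: (default), "uniform" over lc_range, or "degenerate".
    lc_dist: str = "triangular"

    #: Coefficients of variation of the national multiplicative uncertainty
    #: factors (truncated normal, mean 1, floor 0) applied to incidence,
    #: direct cost, and treatment days.
    ir_cv: float = Field(default=0.1, ge=0)
    cost_cv: float = Field(default=0.1, ge=0)
    tdays_cv: float = Field(default=0.1, ge=0)

    #: Strata are processed in blocks of this many population groups so the
    #: working set stays proportional to chunk × n_variability.
    chunk_groups: int = Field(default=2000, ge=1)

    @model_validator(mode="after")
    def _check(self) -> "MCConfig":
        if self.exposure_family not in ("lognormal", "truncnorm"):
            raise ConfigurationError("exposure_family must be lognormal|truncnorm")
        if self.rr0_dist not in ("lognormal", "degenerate"):
            raise ConfigurationError("rr0_dist must be lognormal|degenerate")
        if self.lc_dist not in ("triangular", "uniform", "degenerate"):
            raise ConfigurationError("lc_dist must be triangular|uniform|degenerate")
        return self

    def degenerate(self) -> "MCConfig":
        """Copy with every uncertainty distribution collapsed to its centre;
        with zero exposure SDs the whole pipeline then becomes deterministic."""
        return self.model_copy(
            update=dict(rr0_dist="degenerate", lc_dist="degenerate",
                        ir_cv=0.0, cost_cv=0.0, tdays_cv=0.0)
        )


# ---------------------------------------------------------------------------
# Synthetic-data generator configuration


class SyntheticConfig(BaseModel):
    """Parameters of the synthetic study population.

    The generator emulates the schema and statistical structure of the
    source-apportioned exposure study this pipeline consumes: 330 urban
    cities in 31 provinces, positive right-skewed exposure concentrations,
    an indoor-share gradient increasing with latitude, and age-declining
    asthma incidence that is higher in boys than girls.
    """

    model_config = ConfigDict(frozen=True)

    n_cities: int = Field(default=330, ge=1)
    n_provinces: int = Field(default=31, ge=1)
    seed: int = 20190101

    #: City-level mean exposure to outdoor-source NO₂, µg/m³ (uniform range).
    ambient_mean_range: tuple[float, float] = (8.0, 35.0)
    #: Target national mean share of cooking in (cooking + ambient) exposure.
    cooking_share_target: float = Field(default=0.25, ge=0, le=0.9)
    #: Amplitude of the latitude gradient of the cooking share: the share runs
    #: from target×(1−g) in the far south to target×(1+g) in the far north.
    share_gradient: float = Field(default=0.4, ge=0, le=1)
    #: Second-hand-smoke increment of indoor exposure in smoking households,
    #: µg/m³ (uniform range across cities).  Small relative to cooking and
    #: ambient: tobacco combustion contributes only a percent or two of
    #: population NO₂ exposure.
    shs_mean_range: tuple[float, float] = (0.5, 2.5)
    #: Within-stratum coefficient of variation (SD/mean) of exposure.
    cv_within_group: float = Field(default=0.3, ge=0)

    fexp_range: tuple[float, float] = (0.5, 0.9)
    pshs_range: tuple[float, float] = (0.3, 0.6)

    #: Annual asthma incidence per child, by sex then age group; must decline
    #: with age and be >= in boys at every age.
    incidence_by_age_sex: dict[str, tuple[float, ...]] = {
        "boy": (0.012, 0.011, 0.010, 0.008, 0.005, 0.004),
        "girl": (0.009, 0.008, 0.0075, 0.006, 0.0038, 0.003),
    }
    #: Optional multiplicative province modifiers of incidence.
    province_ir_modifiers: dict[str, float] = {}

    #: Total urban child population (<18 y) across all cities.
    population_total: float = Field(default=1.77e8, gt=0)
    boy_fraction: float = Field(default=0.52, gt=0, lt=1)
    #: Dispersion (lognormal sigma) of city population sizes; heavy-tailed so
    #: a few municipalities dominate, as in the real city-size distribution.
    city_size_sigma: float = Field(default=1.0, ge=0)

    cost_direct_range: tuple[float, float] = (900.0, 1600.0)  # RMB per case
    treatment_days_range: tuple[float, float] = (2.0, 5.0)  # days per case
    gdp_daily_range: tuple[float, float] = (150.0, 450.0)  # RMB/day

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        for name in ("ambient_mean_range", "shs_mean_range", "cost_direct_range",
                     "treatment_days_range", "gdp_daily_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo or hi <= 0:
                raise ConfigurationError(f"{name} must be a non-negative interval")
        lo, hi = self.fexp_range
        if not (0 < lo <= hi <= 1):
            raise ConfigurationError("fexp_range must lie in (0, 1]")
        lo, hi = self.pshs_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigurationError("pshs_range must lie in [0, 1]")
        if set(self.incidence_by_age_sex) != set(SEXES):
            raise ConfigurationError("incidence_by_age_sex needs 'boy' and 'girl'")
        for sex, rates in self.incidence_by_age_sex.items():
            if len(rates) != len(AGE_GROUPS):
                raise ConfigurationError(f"need {len(AGE_GROUPS)} rates for {sex}")
            if any(not (0 < r < 1) for r in rates):
                raise ConfigurationError("incidence rates must lie in (0, 1)")
            if any(a < b for a, b in zip(rates, rates[1:])):
                raise ConfigurationError(f"incidence must not increase with age ({sex})")
        boys = self.incidence_by_age_sex["boy"]
        girls = self.incidence_by_age_sex["girl"]
        if any(b < g for b, g in zip(boys, girls)):
            raise ConfigurationError("incidence must be >= in boys at every age")
        if self.n_provinces > self.n_cities:
            raise ConfigurationError("cannot have more provinces than cities")
        for p, m in self.province_ir_modifiers.items():
            if m <= 0:
                raise ConfigurationError(f"province modifier for {p} must be > 0")
        return self
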