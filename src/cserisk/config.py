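"""Configuration models for the CSE risk pipeline.

All tunable quantities — the synthetic-census generator, the income-draw
conventions, poverty guidelines, payment-burden scenarios and association
settings — are pydantic models so that a JSON config file is validated
before any computation starts. Money is in nominal US dollars per year
unless a field name says otherwise (``rent_*`` fields are per month).
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional, Sequence

from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ConfigError

#: Default WHO catastrophic-expenditure threshold: OOP payment > 40% of
#: annual non-subsistence expenditure.
DEFAULT_CSE_THRESHOLD = 0.40

#: Average 2018 Florida cholecystectomy cost (AHRQ), US dollars.
DEFAULT_PROCEDURE_COST = 17_875.0

#: Out-of-pocket burden fractions: insured average, uninsured negotiated
#: average, and full list price (IOM 2003 hospitalization estimates).
DEFAULT_BURDENS = {"uninsured_100pct": 1.0, "uninsured_38pct": 0.38, "insured_6.5pct": 0.065}

#: Self-reported uninsured fraction of the modeled cohort.
DEFAULT_P_UNINSURED = 0.804


class AffineModel(BaseModel):
    """An affine function of annual income plus Gaussian noise.

    value = intercept + slope * income + Normal(0, noise_sd), floored at 0.
    """

    intercept: float = 0.0
    slope: float = 0.0
    noise_sd: float = Field(default=0.0, ge=0.0)


class AdiDistribution(BaseModel):
    """Marginal distribution of ADI scores over the integers 1..100.

    ``uniform`` draws each score with equal probability.  ``beta_binomial``
    draws score = 1 + BetaBinomial(n=99, a, b), which reproduces skewed
    cohorts (the study population has median ADI 59, quartiles 46/75).
    """

    kind: Literal["uniform", "beta_binomial"] = "uniform"
    a: float = Field(default=1.0, gt=0.0)
    b: float = Field(default=1.0, gt=0.0)


class GeneratorConfig(BaseModel):
    """Parameters of the synthetic block-group / household generator."""

    n_blockgroups: int = Field(default=120, gt=0)
    n_households: int = Field(default=758, gt=0)
    adi_distribution: AdiDistribution = AdiDistribution()
    #: Change in median household income per ADI point; <= 0 encodes the
    #: deprivation-income gradient the analysis assumes.
    adi_income_slope: float = -450.0
    income_base: float = 75_000.0
    income_noise_sd: float = Field(default=12_000.0, ge=0.0)
    #: Lowest publishable block-group median income (ACS publishes no
    #: negative medians).
    income_floor: float = Field(default=2_000.0, ge=0.0)
    #: ACS 90%-CI margin of error as a fraction of the point estimate.
    moe_fraction: float = Field(default=0.15, ge=0.0)
    #: If larger than moe_fraction, each block group's MOE fraction is drawn
    #: uniformly from [moe_fraction, moe_fraction_max] — ACS margins vary
    #: widely with block-group sample size, independently of deprivation.
    moe_fraction_max: float | None = None
    #: Median monthly rent as a function of annual income (default: 30%
    #: of income spent on housing).
    rent_model: AffineModel = AffineModel(intercept=0.0, slope=0.30 / 12.0, noise_sd=120.0)
    #: Annual food expenditure as a function of annual income.
    food_model: AffineModel = AffineModel(intercept=4_000.0, slope=0.05, noise_sd=400.0)
    #: Probability of each household size 1..15.
    household_size_distribution: tuple[float, ...] = tuple(
        [0.35, 0.25, 0.13, 0.10, 0.07, 0.04, 0.02, 0.015, 0.01, 0.005, 0.004, 0.003, 0.001, 0.001, 0.001]
    )
    p_uninsured: float = Field(default=DEFAULT_P_UNINSURED, ge=0.0, le=1.0)
    seed: int = 0

    @field_validator("household_size_distribution")
    @classmethod
    def _check_size_pmf(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if len(v) != 15:
            raise ConfigError("household_size_distribution must have 15 entries (sizes 1..15)")
        arr = list(v)
        if any(p < 0 or p > 1 for p in arr):
            raise ConfigError("household size probabilities must lie in [0, 1]")
        if abs(sum(arr) - 1.0) > 1e-9:
            raise ConfigError(f"household size probabilities must sum to 1 (got {sum(arr)!r})")
        return v


class IncomeDrawConfig(BaseModel):
    """How household income is imputed from block-group estimates.

    The published margin of error is a 90% CI half-width by ACS convention
    (sd = moe / 1.645); the ``sd`` convention treats the MOE as a standard
    deviation directly.  The draw is uniform (or truncated-normal) on
    [median - sd, median + sd], then rescaled by the equivalence scale
    (size / reference_size) ** beta.
    """

    distribution: Literal["uniform", "truncated_normal"] = "uniform"
    moe_convention: Literal["acs90", "sd"] = "acs90"
    size_adjust: bool = True
    #: Equivalence-scale exponent from the WHO catastrophic-expenditure
    #: literature.
    beta: float = Field(default=0.56, ge=0.0)
    #: Cohort median household size.
    reference_size: int = Field(default=2, gt=0)


class PovertyGuideline(BaseModel):
    """HHS federal poverty guideline: base for one person plus a per-person
    increment (2018, 48 contiguous states, by default)."""

    year: int = 2018
    base: float = Field(default=12_140.0, gt=0.0)
    increment: float = Field(default=4_320.0, gt=0.0)

    def threshold(self, size):
        """Poverty-line income for a household of ``size`` persons."""
        import numpy as np

        size = np.asarray(size)
        return self.base + self.increment * (size - 1)


class Scenario(BaseModel):
    """A named out-of-pocket payment-burden assumption for one procedure."""

    name: str
    burden: float = Field(gt=0.0, le=1.0)
    procedure_cost: float = Field(default=DEFAULT_PROCEDURE_COST, gt=0.0)
    threshold: float = Field(default=DEFAULT_CSE_THRESHOLD, gt=0.0, lt=1.0)


def default_scenarios(procedure_cost: float = DEFAULT_PROCEDURE_COST) -> list[Scenario]:
    """The three insurance scenarios: full list price, uninsured negotiated
    average, insured deductible + co-insurance average."""
    return [
        Scenario(name=name, burden=burden, procedure_cost=procedure_cost)
        for name, burden in DEFAULT_BURDENS.items()
    ]


class AssociationConfig(BaseModel):
    """Settings for the ADI-association stage."""

    n_bins_adi: int = Field(default=10, gt=1)
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)


class RunConfig(BaseModel):
    """Full pipeline configuration.

    Either a generator config (synthesize the census tables) or paths to
    existing ``blockgroups.csv`` / ``households.csv`` must be provided.
    """

    generator: Optional[GeneratorConfig] = GeneratorConfig()
    blockgroups_csv: Optional[str] = None
    households_csv: Optional[str] = None
    scenarios: list[Scenario] = Field(default_factory=default_scenarios)
    income_draw: IncomeDrawConfig = IncomeDrawConfig()
    poverty_guideline: PovertyGuideline = PovertyGuideline()
    association: AssociationConfig = AssociationConfig()
    p_uninsured: float = Field(default=DEFAULT_P_UNINSURED, ge=0.0, le=1.0)
    outdir: str = "cserisk_out"
    seed: int = 0

    @model_validator(mode="after")
    def _check_inputs(self) -> "RunConfig":
        has_csv = self.blockgroups_csv is not None and self.households_csv is not None
        if self.generator is None and not has_csv:
            raise ConfigError("either a generator config or both input CSV paths are required")
        if not self.scenarios:
            raise ConfigError("at least one scenario is required")
        return self

    def config_hash(self) -> str:
        """SHA-256 of the canonical JSON serialization, for the run manifest."""
        canonical = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def load_run_config(path: str) -> RunConfig:
    """Read and validate a JSON run configuration.

    All validation failures, including pydantic field errors, surface as
    :class:`~cserisk.errors.ConfigError`.
    """
    from pydantic import ValidationError

    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"config {path} is not valid JSON: {exc}") from exc
    try:
        return RunConfig.model_validate(payload)
    except ValidationError as exc:
        raise ConfigError(f"invalid run config {path}: {exc}") from exc
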