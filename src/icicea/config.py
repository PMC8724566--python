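"""Typed model configuration: the single source of truth all stages consume.

Every numeric model input (drug prices, hazard ratios, utilities, unit
costs, patient characteristics, ...) is a named :class:`ParameterSpec`
carrying its baseline value, deterministic sensitivity range and
probabilistic sampling family.  Strategies reference parameters *by name*
so that sensitivity analyses can override any input without rebuilding
the configuration.
"""
from __future__ import annotations

import enum
import json
import math
import pathlib
from typing import Optional, Union

import yaml
from pydantic import BaseModel, Field, model_validator

SCHEMA_VERSION = 1

#: days per model cycle (3 weeks)
CYCLE_DAYS = 21.0
DAYS_PER_MONTH = 30.44
DAYS_PER_YEAR = 365.25


class ConfigError(ValueError):
    """Raised when a configuration fails validation; the message enumerates
    *all* violations, not just the first."""


class Distribution(str, enum.Enum):
    beta = "beta"
    gamma = "gamma"
    lognormal = "lognormal"
    normal = "normal"
    fixed = "fixed"


class DosingRule(str, enum.Enum):
    flat_mg = "flat_mg"
    per_kg = "per_kg"
    per_m2 = "per_m2"
    calvert_auc = "calvert_auc"


class ParameterSpec(BaseModel):
    """One model input with baseline, DSA range and PSA distribution family."""

    name: str
    baseline: float
    low: Optional[float] = None
    high: Optional[float] = None
    distribution: Distribution = Distribution.fixed
    units: str = ""
    source: str = ""

    def validation_errors(self) -> list[str]:
        errs: list[str] = []
        if not math.isfinite(self.baseline):
            errs.append(f"{self.name}: baseline is not finite")
            return errs
        if (self.low is None) != (self.high is None):
            errs.append(f"{self.name}: low and high must be given together")
        if self.low is not None and self.high is not None:
            if not (self.low <= self.baseline <= self.high):
                errs.append(
                    f"{self.name}: baseline {self.baseline} outside "
                    f"[{self.low}, {self.high}]"
                )
        if self.distribution is Distribution.beta:
            if not (0.0 <= self.baseline <= 1.0):
                errs.append(f"{self.name}: beta-distributed baseline not in [0, 1]")
        if self.distribution in (Distribution.gamma, Distribution.lognormal):
            if self.baseline < 0:
                errs.append(f"{self.name}: {self.distribution.value} baseline < 0")
        return errs

    def range(self) -> tuple[float, float]:
        """DSA range: the stored range if present, else baseline * (0.5, 1.5)."""
        if self.low is not None and self.high is not None:
            return (self.low, self.high)
        lo, hi = 0.5 * self.baseline, 1.5 * self.baseline
        return (min(lo, hi), max(lo, hi))


class PatientProfile(BaseModel):
    """Base-case patient used for body-size-dependent dosing."""

    body_weight: float = Field(gt=0, description="kg")
    body_surface_area: float = Field(gt=0, description="m^2")
    creatinine_clearance: float = Field(gt=0, description="mL/min")


class CEASettings(BaseModel):
    """Global simulation settings."""

    cycle_length_days: float = Field(default=CYCLE_DAYS, gt=0)
    horizon_cycles: int = Field(default=1220, gt=0)
    discount_rate_annual: float = Field(default=0.03, ge=0, lt=1)
    wtp_threshold: float = Field(default=100_000.0, gt=0)
    half_cycle_correction: bool = True
    #: how Table-style (theta, kappa) parameters map onto S(t) = 1/(1 + lam*t^kappa):
    #: "lambda_direct" uses lam = theta; "exp_theta" uses lam = exp(theta).
    loglogistic_form: str = "lambda_direct"
    #: unit of t in the log-logistic formula ("months" or "cycles")
    loglogistic_time_unit: str = "months"
    #: cycle beyond which extrapolated OS is blended with the life table
    blend_start_cycle: int = 36
    #: scalar applied to every price_* parameter (DSA hook on prices)
    price_multiplier: float = 1.0

    @property
    def cycles_per_month(self) -> float:
        return DAYS_PER_MONTH / self.cycle_length_days

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_days / DAYS_PER_YEAR


class DrugDose(BaseModel):
    """One drug within a regimen, dosed per administration.

    ``frequency_cycles`` is the number of cycles between administrations
    (2/3 for a q2w drug on a 3-week grid, 0.5 for day-1/day-8 dosing), so
    administrations per cycle is 1/frequency_cycles.
    """

    drug: str
    dosing_rule: DosingRule
    amount: float = Field(gt=0)
    frequency_cycles: float = Field(default=1.0, gt=0)
    n_cycles_max: Optional[int] = Field(default=None, gt=0)

    @property
    def admins_per_cycle(self) -> float:
        return 1.0 / self.frequency_cycles


class SubsequentRegimen(BaseModel):
    """A post-progression regimen received by a share of PD-state patients.

    ``per_cycle_components`` accrue every cycle of PD-state occupancy
    (optionally only before ``per_cycle_max_model_cycle``);
    ``course_components`` are charged as a fixed-length course
    (``course_cycles`` cycles) to incident PD entrants.
    """

    name: str
    proportion: float = Field(ge=0, le=1)
    per_cycle_components: list[DrugDose] = Field(default_factory=list)
    per_cycle_max_model_cycle: Optional[int] = None
    course_components: list[DrugDose] = Field(default_factory=list)
    course_cycles: int = 0
    infusion_hours: float = Field(default=1.0, ge=0)
    sessions_per_cycle: float = Field(default=1.0, ge=0)


class NativeSurvival(BaseModel):
    type: str = "native"
    os_theta_param: str = "os_theta"
    os_kappa_param: str = "os_kappa"
    pfs_theta_param: str = "pfs_theta"
    pfs_kappa_param: str = "pfs_kappa"


class HazardRatioSurvival(BaseModel):
    type: str = "hazard_ratio"
    reference: str
    hr_os_param: str
    hr_pfs_param: str


class StrategyDefinition(BaseModel):
    """One treatment arm."""

    name: str
    survival: Union[NativeSurvival, HazardRatioSurvival]
    first_line: list[DrugDose]
    first_line_infusion_hours: float = 1.0
    first_line_sessions_per_cycle: float = 1.0
    max_treatment_cycles: Optional[int] = None
    ae_discontinuation_param: str = ""
    ae_cost_param: str = ""
    ae_disutility_param: str = ""
    subsequent: list[SubsequentRegimen] = Field(default_factory=list)
    #: scenario switch: alternative arm keeps its own PFS but adopts the
    #: reference arm's post-progression survival pool ("adopt-survival"
    #: reading of a shared-subsequent-therapy scenario)
    post_progression_like_reference: bool = False

    def validation_errors(self) -> list[str]:
        errs = []
        total = sum(r.proportion for r in self.subsequent)
        if total > 1.0 + 1e-9:
            errs.append(
                f"strategy {self.name}: subsequent-therapy proportions sum to "
                f"{total:.4f} > 1"
            )
        return errs


class ModelConfig(BaseModel):
    """Bundle of all inputs: parameters, settings, strategies, life table."""

    schema_version: int = SCHEMA_VERSION
    settings: CEASettings = Field(default_factory=CEASettings)
    parameters: dict[str, ParameterSpec]
    strategies: list[StrategyDefinition]
    reference_strategy: str = "cemiplimab"
    #: cumulative survival after end-stage blending entry: rows of
    #: (years_since_entry, survival_fraction), starting at (0, 1)
    life_table: list[tuple[float, float]]

    @classmethod
    def model_validate(cls, *args, **kwargs):  # noqa: D102 - see ConfigError
        import pydantic

        try:
            return super().model_validate(*args, **kwargs)
        except pydantic.ValidationError as exc:
            raise ConfigError(str(exc)) from exc

    @model_validator(mode="after")
    def _validate(self) -> "ModelConfig":
        errs: list[str] = []
        for name, spec in self.parameters.items():
            if spec.name != name:
                errs.append(f"parameter key {name!r} != spec.name {spec.name!r}")
            errs.extend(spec.validation_errors())
        names = {s.name for s in self.strategies}
        for strat in self.strategies:
            errs.extend(strat.validation_errors())
            for ref in self._param_refs(strat):
                if ref and ref not in self.parameters:
                    errs.append(
                        f"strategy {strat.name}: missing required parameter {ref!r}"
                    )
            if isinstance(strat.survival, HazardRatioSurvival):
                if strat.survival.reference not in names:
                    errs.append(
                        f"strategy {strat.name}: unknown reference strategy "
                        f"{strat.survival.reference!r}"
                    )
        if self.reference_strategy not in names:
            errs.append(f"unknown reference strategy {self.reference_strategy!r}")
        if self.life_table:
            fracs = [s for _, s in self.life_table]
            if self.life_table[0][1] > 1.0 + 1e-12:
                errs.append("life table must start at survival <= 1")
            if any(b > a + 1e-12 for a, b in zip(fracs, fracs[1:])):
                errs.append("life-table survival fractions must be non-increasing")
        else:
            errs.append("life table is empty")
        for drug in self._drugs_used():
            if f"price_{drug}" not in self.parameters:
                errs.append(f"missing required parameter 'price_{drug}'")
        if errs:
            raise ConfigError("; ".join(errs))
        return self

    @staticmethod
    def _param_refs(strat: StrategyDefinition) -> list[str]:
        refs = [
            strat.ae_discontinuation_param,
            strat.ae_cost_param,
            strat.ae_disutility_param,
        ]
        if isinstance(strat.survival, NativeSurvival):
            refs += [
                strat.survival.os_theta_param,
                strat.survival.os_kappa_param,
                strat.survival.pfs_theta_param,
                strat.survival.pfs_kappa_param,
            ]
        else:
            refs += [strat.survival.hr_os_param, strat.survival.hr_pfs_param]
        return refs

    def _drugs_used(self) -> set[str]:
        drugs: set[str] = set()
        for strat in self.strategies:
            for d in strat.first_line:
                drugs.add(d.drug)
            for reg in strat.subsequent:
                for d in reg.per_cycle_components + reg.course_components:
                    drugs.add(d.drug)
        return drugs

    # -- value access -------------------------------------------------

    def baseline_values(self) -> dict[str, float]:
        """Mapping of parameter name -> baseline value."""
        return {k: v.baseline for k, v in self.parameters.items()}

    def get_strategy(self, name: str) -> StrategyDefinition:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(f"no strategy named {name!r}")

    def patient(self, values: Optional[dict[str, float]] = None) -> PatientProfile:
        v = values or self.baseline_values()
        return PatientProfile(
            body_weight=v["body_weight"],
            body_surface_area=v["body_surface_area"],
            creatinine_clearance=v["creatinine_clearance"],
        )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_config(config: ModelConfig, path: Union[str, pathlib.Path]) -> None:
    """Write the configuration as YAML or JSON (by extension)."""
    path = pathlib.Path(path)
    payload = config.model_dump(mode="json")
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def load_config(path: Union[str, pathlib.Path]) -> ModelConfig:
    """Read a configuration file (YAML or JSON) and validate it."""
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(payload, dict):
        raise ConfigError(f"{path}: does not parse as a mapping")
    version = payload.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version}")
    return ModelConfig.model_validate(payload)


# ---------------------------------------------------------------------------
# bundled default configuration
# ---------------------------------------------------------------------------

# name: (baseline, low, high, distribution, units)
_DEFAULT_PARAMS: dict[str, tuple] = {
    # log-logistic OS/PFS for first-line cemiplimab (EMPOWER-Lung 1 fit)
    "os_theta": (0.02432, None, None, "fixed", ""),
    "os_kappa": (1.11748, None, None, "fixed", ""),
    "pfs_theta": (0.09810, None, None, "fixed", ""),
    "pfs_kappa": (1.14350, None, None, "fixed", ""),
    # hazard ratios vs first-line cemiplimab (network meta-analysis)
    "hr_os_pembrolizumab": (1.17, 0.82, 1.27, "lognormal", ""),
    "hr_pfs_pembrolizumab": (1.21, 1.12, 1.48, "lognormal", ""),
    "hr_os_atezolizumab": (1.04, 0.63, 1.71, "lognormal", ""),
    "hr_pfs_atezolizumab": (1.16, 0.32, 4.32, "lognormal", ""),
    # per-cycle probability of treatment discontinuation due to AEs
    "p_disc_cemiplimab": (0.00303, 0.00151, 0.00454, "beta", "per cycle"),
    "p_disc_pembrolizumab": (0.00499, 0.00250, 0.00749, "beta", "per cycle"),
    "p_disc_atezolizumab": (0.00188, 0.00094, 0.00283, "beta", "per cycle"),
    # drug prices (2021 CMS average sales price)
    "price_cemiplimab": (27.58, 13.79, 41.37, "gamma", "$/mg"),
    "price_pembrolizumab": (51.35, 25.67, 77.02, "gamma", "$/mg"),
    "price_atezolizumab": (7.98, 3.99, 11.97, "gamma", "$/mg"),
    "price_ramucirumab": (12.48, 6.24, 18.71, "gamma", "$/mg"),
    "price_nivolumab": (28.90, 14.45, 43.34, "gamma", "$/mg"),
    "price_docetaxel": (0.54, 0.27, 0.81, "gamma", "$/mg"),
    "price_pemetrexed": (7.42, 3.71, 11.13, "gamma", "$/mg"),
    "price_gemcitabine": (0.02, 0.01, 0.03, "gamma", "$/mg"),
    "price_paclitaxel": (0.13, 0.07, 0.20, "gamma", "$/mg"),
    "price_carboplatin": (0.05, 0.02, 0.07, "gamma", "$/mg"),
    "price_cisplatin": (0.18, 0.09, 0.28, "gamma", "$/mg"),
    # grade III/IV adverse-event management, one course per line started
    "ae_cost_cemiplimab": (351.05, 175.52, 526.57, "gamma", "$"),
    "ae_cost_pembrolizumab": (1092.31, 546.16, 1638.47, "gamma", "$"),
    "ae_cost_atezolizumab": (713.04, 356.52, 1069.56, "gamma", "$"),
    # administration (CMS physician fee schedule)
    "admin_first_hour": (148.30, 74.15, 222.45, "gamma", "$"),
    "admin_additional_hour": (31.40, 15.70, 47.10, "gamma", "$"),
    # routine follow-up, supportive and terminal care
    "cost_physician_visit_monthly": (183.19, 91.60, 274.79, "gamma", "$/month"),
    "cost_imaging_three_monthly": (117.59, 58.80, 176.39, "gamma", "$/13 weeks"),
    "cost_bsc_monthly": (637.00, 318.50, 955.50, "gamma", "$/month"),
    "cost_death": (9433.00, 4716.50, 14149.50, "gamma", "$"),
    # time-to-death utilities (EQ-5D-3L, KEYNOTE-024)
    "u_ge12m": (0.805, 0.767, 0.843, "beta", "utility"),
    "u_6_12m": (0.726, 0.684, 0.767, "beta", "utility"),
    "u_1_6m": (0.632, 0.592, 0.672, "beta", "utility"),
    "u_le1m": (0.573, 0.425, 0.650, "beta", "utility"),
    # per-cycle AE disutility while on first-line treatment
    "disutility_cemiplimab": (0.006, 0.003, 0.009, "beta", "utility"),
    "disutility_pembrolizumab": (0.014, 0.007, 0.020, "beta", "utility"),
    "disutility_atezolizumab": (0.005, 0.003, 0.008, "beta", "utility"),
    # patient characteristics
    "body_weight": (70.32, 69.71, 70.93, "normal", "kg"),
    "body_surface_area": (1.79, 1.78, 1.80, "normal", "m^2"),
    "creatinine_clearance": (70.00, 35.00, 105.00, "normal", "mL/min"),
    # structural: share of progressors ineligible for subsequent therapy
    "endstage_split": (0.5, 0.25, 0.75, "fixed", "fraction"),
}


def _doses(*specs) -> list[DrugDose]:
    return [
        DrugDose(drug=d, dosing_rule=DosingRule(r), amount=a, frequency_cycles=f)
        for d, r, a, f in specs
    ]


def default_strategies() -> list[StrategyDefinition]:
    """The three first-line ICI monotherapy arms with documented defaults.

    Subsequent-therapy regimen mixes are calibrated assumptions (see
    docs/methods.md): the trial-level regimen breakdowns behind the
    published per-arm totals are not public, so the mixes are set to
    reproduce those totals and exposed here for the user to override.
    """
    ramucirumab_docetaxel = SubsequentRegimen(
        name="ramucirumab_docetaxel",
        proportion=0.20,
        per_cycle_components=_doses(
            ("ramucirumab", "per_kg", 10.0, 1.0),
            ("docetaxel", "per_m2", 75.0, 1.0),
        ),
        infusion_hours=2.0,
    )
    docetaxel = SubsequentRegimen(
        name="docetaxel",
        proportion=0.30,
        per_cycle_components=_doses(("docetaxel", "per_m2", 75.0, 1.0)),
        infusion_hours=3.0,
    )
    pemetrexed = SubsequentRegimen(
        name="pemetrexed",
        proportion=0.04,
        per_cycle_components=_doses(("pemetrexed", "per_m2", 500.0, 1.0)),
        infusion_hours=3.0,
    )
    gemcitabine = SubsequentRegimen(
        name="gemcitabine",
        proportion=0.46,
        per_cycle_components=_doses(("gemcitabine", "per_m2", 1250.0, 0.5)),
        infusion_hours=1.0,
        sessions_per_cycle=2.0,
    )
    nivolumab = SubsequentRegimen(
        name="nivolumab",
        proportion=0.15,
        per_cycle_components=_doses(("nivolumab", "flat_mg", 240.0, 2.0 / 3.0)),
        infusion_hours=1.0,
        sessions_per_cycle=1.5,
    )

    cemiplimab = StrategyDefinition(
        name="cemiplimab",
        survival=NativeSurvival(),
        first_line=_doses(("cemiplimab", "flat_mg", 350.0, 1.0)),
        first_line_infusion_hours=1.0,
        max_treatment_cycles=36,  # 108 weeks, trial protocol cap
        ae_discontinuation_param="p_disc_cemiplimab",
        ae_cost_param="ae_cost_cemiplimab",
        ae_disutility_param="disutility_cemiplimab",
        subsequent=[
            SubsequentRegimen(
                name="cemiplimab_continuation_plus_chemo",
                proportion=1.0,
                # continued cemiplimab within the 108-week overall window
                per_cycle_components=_doses(("cemiplimab", "flat_mg", 350.0, 1.0)),
                per_cycle_max_model_cycle=36,
                # plus 4 cycles of platinum-doublet chemotherapy at progression
                course_components=_doses(
                    ("carboplatin", "calvert_auc", 5.0, 1.0),
                    ("pemetrexed", "per_m2", 500.0, 1.0),
                ),
                course_cycles=4,
                infusion_hours=3.0,
            )
        ],
    )
    pembrolizumab = StrategyDefinition(
        name="pembrolizumab",
        survival=HazardRatioSurvival(
            reference="cemiplimab",
            hr_os_param="hr_os_pembrolizumab",
            hr_pfs_param="hr_pfs_pembrolizumab",
        ),
        first_line=_doses(("pembrolizumab", "flat_mg", 200.0, 1.0)),
        first_line_infusion_hours=1.0,
        max_treatment_cycles=35,  # 2 years
        ae_discontinuation_param="p_disc_pembrolizumab",
        ae_cost_param="ae_cost_pembrolizumab",
        ae_disutility_param="disutility_pembrolizumab",
        subsequent=[
            ramucirumab_docetaxel.model_copy(deep=True),
            docetaxel.model_copy(deep=True),
            pemetrexed.model_copy(deep=True),
            gemcitabine.model_copy(deep=True),
        ],
    )
    atezolizumab = StrategyDefinition(
        name="atezolizumab",
        survival=HazardRatioSurvival(
            reference="cemiplimab",
            hr_os_param="hr_os_atezolizumab",
            hr_pfs_param="hr_pfs_atezolizumab",
        ),
        first_line=_doses(("atezolizumab", "flat_mg", 1200.0, 1.0)),
        first_line_infusion_hours=1.0,
        max_treatment_cycles=None,  # until progression
        ae_discontinuation_param="p_disc_atezolizumab",
        ae_cost_param="ae_cost_atezolizumab",
        ae_disutility_param="disutility_atezolizumab",
        subsequent=[
            nivolumab.model_copy(deep=True),
            ramucirumab_docetaxel.model_copy(deep=True),
            pemetrexed.model_copy(update={"proportion": 0.05}),
            docetaxel.model_copy(deep=True),
            gemcitabine.model_copy(update={"proportion": 0.30}),
        ],
    )
    return [cemiplimab, pembrolizumab, atezolizumab]


def default_config() -> ModelConfig:
    """The bundled base-case configuration."""
    from .synthetic import default_life_table_rows

    params = {
        name: ParameterSpec(
            name=name,
            baseline=b,
            low=lo,
            high=hi,
            distribution=Distribution(dist),
            units=units,
        )
        for name, (b, lo, hi, dist, units) in _DEFAULT_PARAMS.items()
    }
    return ModelConfig(
        parameters=params,
        strategies=default_strategies(),
        life_table=default_life_table_rows(),
    )
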