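"""Scenario orchestration: the base case and declarative variants.

A scenario is a pure set of overrides of the base configuration plus
optionally added parameters and strategies.  Two builders mirror common
questions: harmonising subsequent therapy across arms, and adding an
ICI-plus-chemotherapy arm driven by externally supplied hazard ratios.
"""
from __future__ import annotations

from typing import Any, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field

from .config import (
    ConfigError,
    DosingRule,
    DrugDose,
    HazardRatioSurvival,
    ModelConfig,
    ParameterSpec,
    StrategyDefinition,
)
from .engine import run_cohort
from .outcomes import CEResult, compare_strategies, results_frame

__all__ = [
    "Scenario",
    "apply_scenario",
    "run_base_case",
    "run_all",
    "scenario_same_subsequent",
    "scenario_pembrolizumab_chemo",
]


class Scenario(BaseModel):
    name: str
    #: dotted config paths -> replacement values; strategies are addressed
    #: as ``strategies.<name>.<field>``
    overrides: dict[str, Any] = Field(default_factory=dict)
    added_parameters: dict[str, ParameterSpec] = Field(default_factory=dict)
    added_strategies: list[StrategyDefinition] = Field(default_factory=list)


def _set_path(payload: dict, strategy_index: dict[str, int], path: str, value) -> None:
    parts = path.split(".")
    node: Any = payload
    if parts[0] == "strategies":
        if len(parts) < 3 or parts[1] not in strategy_index:
            raise ConfigError(f"unknown override path {path!r}")
        node = payload["strategies"][strategy_index[parts[1]]]
        parts = parts[2:]
    for key in parts[:-1]:
        if not isinstance(node, dict) or key not in node:
            raise ConfigError(f"unknown override path {path!r}")
        node = node[key]
    leaf = parts[-1]
    if not isinstance(node, dict) or leaf not in node:
        raise ConfigError(f"unknown override path {path!r}")
    node[leaf] = value


def apply_scenario(
    base: ModelConfig, scenario: Scenario, audit: Optional[list[str]] = None
) -> ModelConfig:
    """Return a new validated config with the scenario applied.

    The base config is never mutated; every change is appended to
    ``audit`` when a list is supplied.
    """
    payload = base.model_dump(mode="python")
    strategy_index = {s["name"]: i for i, s in enumerate(payload["strategies"])}
    for name, spec in scenario.added_parameters.items():
        payload["parameters"][name] = spec.model_dump(mode="python")
        if audit is not None:
            audit.append(f"add parameter {name} = {spec.baseline}")
    for strat in scenario.added_strategies:
        payload["strategies"].append(strat.model_dump(mode="python"))
        strategy_index[strat.name] = len(payload["strategies"]) - 1
        if audit is not None:
            audit.append(f"add strategy {strat.name}")
    for path, value in scenario.overrides.items():
        if hasattr(value, "model_dump"):
            value = value.model_dump(mode="python")
        elif isinstance(value, list):
            value = [v.model_dump(mode="python") if hasattr(v, "model_dump") else v for v in value]
        _set_path(payload, strategy_index, path, value)
        if audit is not None:
            audit.append(f"set {path}")
    return ModelConfig.model_validate(payload)


def run_base_case(config: ModelConfig, wtp: Optional[float] = None) -> list[CEResult]:
    """Deterministic run of every strategy plus pairwise comparison
    against the reference."""
    wtp = wtp if wtp is not None else config.settings.wtp_threshold
    totals = {}
    order = []
    for strat in config.strategies:
        trace = run_cohort(strat, config)
        totals[strat.name] = (trace.total_cost, trace.total_qaly)
        order.append(strat.name)
    return compare_strategies(totals, config.reference_strategy, wtp, order=order)


def run_all(
    config: ModelConfig, scenarios: Sequence[Scenario] = ()
) -> dict[str, pd.DataFrame]:
    """Base case plus each scenario as summary-table DataFrames.

    A failing scenario aborts only itself; its entry records the error.
    """
    bundle: dict[str, pd.DataFrame] = {
        "base_case": results_frame(run_base_case(config))
    }
    for sc in scenarios:
        try:
            cfg = apply_scenario(config, sc)
            reference = (
                sc.added_strategies[-1].name if sc.added_strategies
                else cfg.reference_strategy
            )
            cfg = cfg.model_copy(update={"reference_strategy": reference})
            bundle[sc.name] = results_frame(
                compare_strategies(
                    {
                        s.name: (
                            (tr := run_cohort(s, cfg)).total_cost, tr.total_qaly
                        )
                        for s in cfg.strategies
                    },
                    reference,
                    cfg.settings.wtp_threshold,
                )
            )
        except Exception as exc:  # noqa: BLE001 - isolate scenario failures
            bundle[sc.name] = pd.DataFrame([{"error": str(exc)}])
    return bundle


# ---------------------------------------------------------------------------
# bundled scenario builders
# ---------------------------------------------------------------------------


def scenario_same_subsequent(
    config: ModelConfig, adopt_survival: bool = True
) -> Scenario:
    """All arms receive the reference arm's subsequent therapy.

    With ``adopt_survival`` the alternative arms also adopt the reference
    arm's post-progression survival pool (their own PFS is kept); without
    it only the cost side changes.
    """
    ref = config.get_strategy(config.reference_strategy)
    overrides: dict[str, Any] = {}
    for strat in config.strategies:
        if strat.name == ref.name:
            continue
        overrides[f"strategies.{strat.name}.subsequent"] = [
            r.model_copy(deep=True) for r in ref.subsequent
        ]
        if adopt_survival:
            overrides[f"strategies.{strat.name}.post_progression_like_reference"] = True
    return Scenario(name="same_subsequent_therapy", overrides=overrides)


def scenario_pembrolizumab_chemo(
    hr_os_vs_pembrolizumab: float = 0.83,
    hr_os_ci: tuple[float, float] = (0.72, 0.96),
    hr_pfs_vs_pembrolizumab: float = 0.62,
    hr_pfs_ci: tuple[float, float] = (0.50, 0.77),
) -> Scenario:
    """Add a pembrolizumab-plus-chemotherapy arm.

    The hazard ratios versus pembrolizumab monotherapy come from an
    external indirect comparison and are shipped as placeholders
    (source "external") that the user should confirm before relying on
    this scenario; the module never invents efficacy silently.
    """
    params = {
        "hr_os_pembro_chemo": ParameterSpec(
            name="hr_os_pembro_chemo",
            baseline=hr_os_vs_pembrolizumab,
            low=hr_os_ci[0],
            high=hr_os_ci[1],
            distribution="lognormal",
            source="external",
        ),
        "hr_pfs_pembro_chemo": ParameterSpec(
            name="hr_pfs_pembro_chemo",
            baseline=hr_pfs_vs_pembrolizumab,
            low=hr_pfs_ci[0],
            high=hr_pfs_ci[1],
            distribution="lognormal",
            source="external",
        ),
    }
    doublet = [
        DrugDose(drug="pembrolizumab", dosing_rule=DosingRule.flat_mg, amount=200.0,
                 n_cycles_max=35),
        DrugDose(drug="carboplatin", dosing_rule=DosingRule.calvert_auc, amount=5.0,
                 n_cycles_max=4),
        DrugDose(drug="pemetrexed", dosing_rule=DosingRule.per_m2, amount=500.0),
    ]
    strategy = StrategyDefinition(
        name="pembrolizumab_chemo",
        survival=HazardRatioSurvival(
            reference="pembrolizumab",
            hr_os_param="hr_os_pembro_chemo",
            hr_pfs_param="hr_pfs_pembro_chemo",
        ),
        first_line=doublet,
        first_line_infusion_hours=3.0,
        max_treatment_cycles=None,
        ae_discontinuation_param="p_disc_pembrolizumab",
        ae_cost_param="ae_cost_pembrolizumab",
        ae_disutility_param="disutility_pembrolizumab",
        subsequent=[],
    )
    return Scenario(
        name="pembrolizumab_plus_chemotherapy",
        added_parameters=params,
        added_strategies=[strategy],
    )
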