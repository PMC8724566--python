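"""Per-cycle cost and utility attachment.

Costs: first- and second-line drug acquisition (weight-, BSA- and
creatinine-clearance-based dosing), intravenous administration fees,
adverse-event management (one course per line of therapy started),
routine follow-up while on active management, best supportive care in the
end-stage state, and a one-off terminal-care cost at death.

Utilities: the time-to-death approach — the alive cohort at each cycle is
partitioned by conditional time until death (>=12, 6-12, 1-6, <=1 months)
and valued with the band utilities; a per-cycle disutility applies while
on first-line treatment.
"""
from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .config import (
    CEASettings,
    ConfigError,
    DosingRule,
    DrugDose,
    ModelConfig,
    PatientProfile,
    StrategyDefinition,
    SubsequentRegimen,
)

__all__ = [
    "dose_mg",
    "administration_cost",
    "ae_course_cost",
    "TimeToDeathUtilitySet",
    "time_to_death_utility",
    "cycle_qaly",
    "accrue",
]


def dose_mg(dose: DrugDose, patient: PatientProfile) -> float:
    """Milligrams per administration under the dose's rule.

    flat_mg -> amount; per_kg -> amount * body weight; per_m2 ->
    amount * body surface area; calvert_auc -> amount * (CrCl + 25)
    (the Calvert carboplatin formula, AUC in mg/mL*min).
    """
    rule = dose.dosing_rule
    if rule is DosingRule.flat_mg:
        return dose.amount
    if rule is DosingRule.per_kg:
        return dose.amount * patient.body_weight
    if rule is DosingRule.per_m2:
        return dose.amount * patient.body_surface_area
    if rule is DosingRule.calvert_auc:
        return dose.amount * (patient.creatinine_clearance + 25.0)
    raise ValueError(f"unknown dosing rule {rule!r}")


def administration_cost(
    infusion_hours: float, first_hour: float, additional_hour: float
) -> float:
    """Intravenous administration fee for one session.

    Zero hours costs nothing; otherwise the first hour plus each
    additional (started) hour.
    """
    if infusion_hours < 0:
        raise ValueError("infusion_hours must be >= 0")
    if infusion_hours == 0:
        return 0.0
    return first_hour + (math.ceil(infusion_hours) - 1) * additional_hour


def ae_course_cost(
    incidences: Sequence[tuple[str, float]],
    unit_costs: dict[str, float],
) -> float:
    """Sum of incidence * management cost over grade III/IV adverse events,
    charged once per patient starting the line of therapy."""
    total = 0.0
    for ae, frac in incidences:
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"incidence for {ae!r} outside [0, 1]")
        if ae not in unit_costs:
            raise ConfigError(f"adverse event {ae!r} has no unit cost")
        total += frac * unit_costs[ae]
    return total


class TimeToDeathUtilitySet(BaseModel):
    """Band utilities by proximity to death."""

    u_ge12m: float = Field(default=0.805, ge=0, le=1)
    u_6_12m: float = Field(default=0.726, ge=0, le=1)
    u_1_6m: float = Field(default=0.632, ge=0, le=1)
    u_le1m: float = Field(default=0.573, ge=0, le=1)

    @model_validator(mode="after")
    def _ordered(self):
        seq = [self.u_ge12m, self.u_6_12m, self.u_1_6m, self.u_le1m]
        if any(b > a + 1e-12 for a, b in zip(seq, seq[1:])):
            raise ValueError("utilities must be non-increasing toward death")
        return self


def _ttd_weights(s_now, s_1m, s_6m, s_12m):
    """Band occupancy fractions of the currently alive cohort."""
    s_now = np.maximum(s_now, 1e-300)
    p1 = 1.0 - s_1m / s_now
    p6 = 1.0 - s_6m / s_now
    p12 = 1.0 - s_12m / s_now
    p1, p6, p12 = (np.clip(p, 0.0, 1.0) for p in (p1, p6, p12))
    p6 = np.maximum(p6, p1)
    p12 = np.maximum(p12, p6)
    return p1, p6 - p1, p12 - p6, 1.0 - p12


def ttd_utility_grid(
    t_query: np.ndarray,
    t_ext: np.ndarray,
    os_ext: np.ndarray,
    cycles_per_month: float,
    utilities: tuple[float, float, float, float],
) -> np.ndarray:
    """Vectorized band-weighted mean utility of the alive cohort.

    ``utilities`` is (u_ge12m, u_6_12m, u_1_6m, u_le1m); the survival grid
    must extend at least 12 months past the last query time.
    """
    S = lambda x: np.interp(x, t_ext, os_ext)
    w1, w16, w612, w12 = _ttd_weights(
        S(t_query),
        S(t_query + 1 * cycles_per_month),
        S(t_query + 6 * cycles_per_month),
        S(t_query + 12 * cycles_per_month),
    )
    u_ge12, u_612, u_16, u_le1 = utilities
    return u_le1 * w1 + u_16 * w16 + u_612 * w612 + u_ge12 * w12


def time_to_death_utility(
    alive_curve,
    cycle: float,
    utilities: TimeToDeathUtilitySet,
    cycles_per_month: float = 30.44 / 21.0,
) -> float:
    """Mean utility of the cohort alive at ``cycle`` (scalar convenience)."""
    s_now = float(alive_curve(cycle))
    if s_now <= 0.0:
        warnings.warn("alive fraction is zero; utility undefined, returning 0")
        return 0.0
    w1, w16, w612, w12 = _ttd_weights(
        s_now,
        float(alive_curve(cycle + 1 * cycles_per_month)),
        float(alive_curve(cycle + 6 * cycles_per_month)),
        float(alive_curve(cycle + 12 * cycles_per_month)),
    )
    return (
        utilities.u_le1m * w1
        + utilities.u_1_6m * w16
        + utilities.u_6_12m * w612
        + utilities.u_ge12m * w12
    )


def cycle_qaly(utility: float, cycle_length_days: float, disutility: float = 0.0) -> float:
    """Undiscounted QALY accrued over one cycle at the given utility,
    floored at zero after subtracting any on-treatment disutility."""
    return max(utility - disutility, 0.0) * cycle_length_days / 365.25


# ---------------------------------------------------------------------------
# accrual over a cohort trace
# ---------------------------------------------------------------------------


def _regimen_cycle_cost(
    components: Sequence[DrugDose],
    patient: PatientProfile,
    prices: dict[str, float],
    infusion_hours: float,
    sessions_per_cycle: float,
    first_hour: float,
    additional_hour: float,
) -> tuple[float, float]:
    """(drug $, administration $) for one cycle of a regimen."""
    drug = sum(
        dose_mg(c, patient) * prices[c.drug] * c.admins_per_cycle for c in components
    )
    admin = administration_cost(infusion_hours, first_hour, additional_hour) * sessions_per_cycle
    return drug, admin


def accrue(
    *,
    t: np.ndarray,
    alive: np.ndarray,
    pfs: np.ndarray,
    pd_state: np.ndarray,
    endstage: np.ndarray,
    on_treatment: np.ndarray,
    pd_entrants: np.ndarray,
    os_ext_t: np.ndarray,
    os_ext: np.ndarray,
    strategy: StrategyDefinition,
    config: ModelConfig,
    values: dict[str, float],
) -> dict:
    """Attach discounted costs and QALYs to state-membership arrays.

    Returns per-interval arrays: ``qaly`` plus a cost dictionary keyed by
    ledger category (drug, administration, ae, followup, bsc, death), with
    undiscounted twins, and a finer component breakdown for diagnostics.
    """
    st = config.settings
    n = len(t) - 1
    cyc_years = st.cycle_years
    rate = st.discount_rate_annual

    disc_pt = (1.0 + rate) ** (-(t[:-1]) * cyc_years)
    if st.half_cycle_correction:
        disc_mid = (1.0 + rate) ** (-(t[:-1] + 0.5) * cyc_years)
        occ = lambda x: 0.5 * (x[:-1] + x[1:])
    else:
        disc_mid = disc_pt
        occ = lambda x: x[:-1]

    occ_alive, occ_pfs, occ_pd, occ_es = (occ(x) for x in (alive, pfs, pd_state, endstage))
    occ_on = occ(on_treatment)
    deaths = alive[:-1] - alive[1:]

    patient = config.patient(values)
    mult = st.price_multiplier
    prices = {
        name[len("price_"):]: spec_val * mult
        for name, spec_val in values.items()
        if name.startswith("price_")
    }
    first_hr = values["admin_first_hour"]
    add_hr = values["admin_additional_hour"]

    # --- QALYs (time-to-death utilities, AE disutility while on treatment)
    u_bands = (values["u_ge12m"], values["u_6_12m"], values["u_1_6m"], values["u_le1m"])
    u_grid = ttd_utility_grid(t, os_ext_t, os_ext, st.cycles_per_month, u_bands)
    u_occ = occ(u_grid)
    disut = values.get(strategy.ae_disutility_param, 0.0) if strategy.ae_disutility_param else 0.0
    qaly = np.maximum(occ_alive * u_occ - disut * occ_on, 0.0) * cyc_years
    qaly_disc = qaly * disc_mid

    # --- first-line drug + administration (dispensed at cycle starts)
    drug_u = np.zeros(n)
    admin_u = np.zeros(n)
    on_pt = on_treatment[:-1]
    idx = t[:-1]
    for comp in strategy.first_line:
        mg = dose_mg(comp, patient)
        active = on_pt if comp.n_cycles_max is None else np.where(
            idx < comp.n_cycles_max, on_pt, 0.0
        )
        drug_u += active * mg * prices[comp.drug] * comp.admins_per_cycle
    admin_session = administration_cost(strategy.first_line_infusion_hours, first_hr, add_hr)
    admin_u += on_pt * admin_session * strategy.first_line_sessions_per_cycle

    # --- subsequent therapy in the PD state
    sub_drug_u = np.zeros(n)
    sub_admin_u = np.zeros(n)
    for reg in strategy.subsequent:
        if reg.per_cycle_components:
            d, a = _regimen_cycle_cost(
                reg.per_cycle_components, patient, prices,
                reg.infusion_hours, reg.sessions_per_cycle, first_hr, add_hr,
            )
            mask = (
                np.ones(n)
                if reg.per_cycle_max_model_cycle is None
                else (idx < reg.per_cycle_max_model_cycle).astype(float)
            )
            sub_drug_u += pd_state[:-1] * mask * reg.proportion * d
            sub_admin_u += pd_state[:-1] * mask * reg.proportion * a
        if reg.course_components and reg.course_cycles > 0:
            d, a = _regimen_cycle_cost(
                reg.course_components, patient, prices,
                reg.infusion_hours, reg.sessions_per_cycle, first_hr, add_hr,
            )
            sub_drug_u += pd_entrants * reg.proportion * reg.course_cycles * d
            sub_admin_u += pd_entrants * reg.proportion * reg.course_cycles * a

    # --- adverse-event management: one course at line start
    ae_u = np.zeros(n)
    if strategy.ae_cost_param:
        ae_u[0] = values[strategy.ae_cost_param]

    # --- follow-up, supportive care, death
    per_cycle_followup = (
        values["cost_physician_visit_monthly"] * st.cycle_length_days / 30.44
        + values["cost_imaging_three_monthly"] * st.cycle_length_days / (13 * 7)
    )
    followup_u = (occ_pfs + occ_pd) * per_cycle_followup
    bsc_u = occ_es * values["cost_bsc_monthly"] * st.cycle_length_days / 30.44
    death_u = deaths * values["cost_death"]

    undiscounted = {
        "drug": drug_u + sub_drug_u,
        "administration": admin_u + sub_admin_u,
        "ae": ae_u,
        "followup": followup_u,
        "bsc": bsc_u,
        "death": death_u,
    }
    point_categories = {"drug", "administration", "ae"}
    discounted = {
        cat: arr * (disc_pt if cat in point_categories else disc_mid)
        for cat, arr in undiscounted.items()
    }
    components = {
        "first_line_drug": float(np.sum(drug_u * disc_pt)),
        "first_line_administration": float(np.sum(admin_u * disc_pt)),
        "subsequent_drug": float(np.sum(sub_drug_u * disc_pt)),
        "subsequent_administration": float(np.sum(sub_admin_u * disc_pt)),
    }
    return {
        "qaly": qaly_disc,
        "qaly_undiscounted": qaly,
        "cost": discounted,
        "cost_undiscounted": undiscounted,
        "components": components,
        "life_years": occ_alive * cyc_years * disc_mid,
    }
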