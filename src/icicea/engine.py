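"""Four-state cohort simulation over a lifetime horizon.

State occupancy is read directly from the overall-survival and
progression-free-survival curves (partitioned-survival form of the
four-state model): PFS patients are those progression-free, the
progressed pool (alive minus progression-free) is split between the
progressive-disease state (eligible for subsequent therapy) and the
end-stage state (best supportive care), and deaths close the balance, so
state fractions sum to one by construction.

Beyond the end of observed trial follow-up the extrapolated OS curve is
blended with a registry-style life table by taking, cycle by cycle, the
larger of the parametric and life-table hazards — the extrapolated tail
can never predict better survival than observed long-term cohorts.
"""
from __future__ import annotations

import dataclasses
import logging
import math
import pathlib
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import valuation
from .config import (
    CEASettings,
    ConfigError,
    HazardRatioSurvival,
    ModelConfig,
    NativeSurvival,
    StrategyDefinition,
)
from .survival import LogLogisticParams, SurvivalCurve, curve_from_shape_params

logger = logging.getLogger(__name__)

__all__ = [
    "LifeTable",
    "CohortTrace",
    "per_cycle_probability",
    "rate_to_probability",
    "discount_factor",
    "blend_life_table",
    "state_memberships",
    "run_cohort",
]


# ---------------------------------------------------------------------------
# probability / rate conversions and discounting
# ---------------------------------------------------------------------------


def rate_to_probability(rate: float, t: float = 1.0) -> float:
    """p = 1 - exp(-r t) for a constant instantaneous rate r over time t."""
    if rate < 0 or t < 0:
        raise ValueError("rate and t must be >= 0")
    return 1.0 - math.exp(-rate * t)


def per_cycle_probability(P: float, D: float) -> float:
    """Convert a trial-period probability into a one-cycle probability.

    The event probability P observed over D cycles implies the constant
    rate r = -ln(1-P)/D; the one-cycle probability is 1 - exp(-r).
    """
    if not (0.0 <= P < 1.0):
        raise ValueError("P must be in [0, 1)")
    if D <= 0:
        raise ValueError("D must be > 0")
    r = -math.log(1.0 - P) / D
    return rate_to_probability(r, 1.0)


def discount_factor(cycle, settings: CEASettings):
    """(1 + annual rate)^(-years elapsed at the given cycle index)."""
    cycle = np.asarray(cycle, dtype=float)
    if np.any(cycle < 0):
        raise ValueError("cycle must be >= 0")
    out = (1.0 + settings.discount_rate_annual) ** (-cycle * settings.cycle_years)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# life table
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class LifeTable:
    """Cumulative survival by years since end-stage blending entry.

    Interpolation between rows is hazard-constant; beyond the last row the
    final interval's hazard continues.
    """

    rows: Sequence[tuple[float, float]]
    cycle_days: float = 21.0

    def __post_init__(self):
        if not self.rows:
            raise ValueError("life table is empty")
        years = [y for y, _ in self.rows]
        fracs = [s for _, s in self.rows]
        if years[0] != 0.0 or abs(fracs[0] - 1.0) > 1e-12:
            raise ValueError("life table must start at (0, 1.0)")
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("years must be strictly increasing")
        if any(b > a + 1e-12 for a, b in zip(fracs, fracs[1:])):
            raise ValueError("survival fractions must be non-increasing")

    def cumulative_hazard(self, years) -> np.ndarray:
        """-ln S at arbitrary (non-negative) years, extrapolating the last
        interval's hazard; infinite once the table reaches zero survival."""
        years_arr = np.atleast_1d(np.asarray(years, dtype=float))
        ys = np.array([y for y, _ in self.rows])
        H = -np.log(np.maximum(np.array([s for _, s in self.rows]), 0.0))
        out = np.interp(years_arr, ys, H)
        if len(ys) >= 2 and np.isfinite(H[-1]):
            slope = (H[-1] - H[-2]) / (ys[-1] - ys[-2])
            beyond = years_arr > ys[-1]
            out[beyond] = H[-1] + slope * (years_arr[beyond] - ys[-1])
        return out

    def survival(self, years) -> np.ndarray:
        return np.exp(-self.cumulative_hazard(years))

    @classmethod
    def from_rows(cls, rows, cycle_days: float = 21.0) -> "LifeTable":
        return cls(rows=[(float(y), float(s)) for y, s in rows], cycle_days=cycle_days)

    @classmethod
    def from_csv(cls, path, cycle_days: float = 21.0) -> "LifeTable":
        df = pd.read_csv(path)
        needed = {"years_since_entry", "survival_fraction"}
        if not needed <= set(df.columns):
            raise ValueError(f"life-table CSV needs columns {sorted(needed)}")
        return cls.from_rows(
            list(zip(df["years_since_entry"], df["survival_fraction"])), cycle_days
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(self.rows, columns=["years_since_entry", "survival_fraction"]).to_csv(
            path, index=False
        )


def _blend_grid(os_grid: np.ndarray, life_table: LifeTable, blend_cycle: int,
                cycle_years: float) -> np.ndarray:
    """Hazard-max blend of a gridded OS curve with the life table."""
    with np.errstate(divide="ignore"):
        log_s = np.log(np.maximum(os_grid, 1e-300))
    h_par = -(np.diff(log_s))
    n = len(h_par)
    idx = np.arange(n, dtype=float)
    y0 = np.maximum(idx - blend_cycle, 0.0) * cycle_years
    y1 = np.maximum(idx + 1 - blend_cycle, 0.0) * cycle_years
    h_lt = life_table.cumulative_hazard(y1) - life_table.cumulative_hazard(y0)
    blended = np.concatenate([[1.0], np.exp(-np.cumsum(np.maximum(h_par, h_lt)))])
    return blended * os_grid[0]  # os_grid[0] is 1 by contract


def blend_life_table(
    os_curve: SurvivalCurve,
    life_table: LifeTable,
    blend_cycle: int,
    settings: Optional[CEASettings] = None,
    horizon: Optional[int] = None,
) -> SurvivalCurve:
    """Blend an OS curve with the life table beyond ``blend_cycle``.

    For t <= blend_cycle the curve is unchanged; beyond, the per-cycle
    hazard is the maximum of the parametric and life-table hazards.
    """
    settings = settings or CEASettings()
    if blend_cycle > settings.horizon_cycles:
        raise ValueError("blend_cycle must lie within the horizon")
    n = horizon if horizon is not None else settings.horizon_cycles
    t = np.arange(n + 1, dtype=float)
    grid = np.asarray(os_curve(t), dtype=float)
    blended = _blend_grid(grid, life_table, blend_cycle, settings.cycle_years)
    return SurvivalCurve.from_grid(t, blended, provenance="life-table-blended")


# ---------------------------------------------------------------------------
# cohort trace
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CohortTrace:
    """Per-cycle state memberships with accrued discounted streams.

    State arrays are cohort fractions at cycle grid points (length
    horizon+1); cost and QALY increments are per cycle interval (length
    horizon).
    """

    strategy: str
    t: np.ndarray
    pfs: np.ndarray
    pd: np.ndarray
    endstage: np.ndarray
    dead: np.ndarray
    on_treatment: np.ndarray
    qaly_increments: Optional[np.ndarray] = None
    cost_increments: Optional[dict[str, np.ndarray]] = None
    qaly_increments_undiscounted: Optional[np.ndarray] = None
    cost_increments_undiscounted: Optional[dict[str, np.ndarray]] = None
    life_year_increments: Optional[np.ndarray] = None
    cost_components: Optional[dict[str, float]] = None

    @property
    def alive(self) -> np.ndarray:
        return 1.0 - self.dead

    @property
    def total_qaly(self) -> float:
        return float(np.sum(self.qaly_increments))

    @property
    def total_cost(self) -> float:
        return float(sum(np.sum(v) for v in self.cost_increments.values()))

    @property
    def total_life_years(self) -> float:
        return float(np.sum(self.life_year_increments))

    def max_mass_error(self) -> float:
        total = self.pfs + self.pd + self.endstage + self.dead
        return float(np.max(np.abs(total - 1.0)))

    def to_frame(self) -> pd.DataFrame:
        n = len(self.t) - 1
        cost = np.zeros(n)
        if self.cost_increments:
            for v in self.cost_increments.values():
                cost = cost + v
        qaly = self.qaly_increments if self.qaly_increments is not None else np.zeros(n)
        return pd.DataFrame(
            {
                "cycle": self.t[:-1].astype(int),
                "pfs": self.pfs[:-1],
                "pd": self.pd[:-1],
                "endstage": self.endstage[:-1],
                "dead": self.dead[:-1],
                "on_treatment": self.on_treatment[:-1],
                "cost_increment": cost,
                "qaly_increment": qaly,
            }
        )

    def ledger_frame(self) -> pd.DataFrame:
        """Cost ledger: one row per (cycle, category) with any accrual."""
        frames = []
        for cat, disc in self.cost_increments.items():
            undisc = self.cost_increments_undiscounted[cat]
            mask = (disc != 0) | (undisc != 0)
            frames.append(
                pd.DataFrame(
                    {
                        "cycle": self.t[:-1][mask].astype(int),
                        "category": cat,
                        "undiscounted": undisc[mask],
                        "discounted": disc[mask],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True).sort_values(
            ["cycle", "category"], ignore_index=True
        )


# ---------------------------------------------------------------------------
# curve resolution and state memberships
# ---------------------------------------------------------------------------


def _resolve_curves_grid(
    strategy: StrategyDefinition,
    config: ModelConfig,
    values: dict[str, float],
    t: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw (un-blended) OS and PFS grids for a strategy, chaining hazard
    ratios back to a natively-parameterized reference arm."""
    st = config.settings
    hr_os = 1.0
    hr_pfs = 1.0
    current = strategy
    seen = {strategy.name}
    while isinstance(current.survival, HazardRatioSurvival):
        hr_os *= values[current.survival.hr_os_param]
        hr_pfs *= values[current.survival.hr_pfs_param]
        ref_name = current.survival.reference
        if ref_name in seen and ref_name != current.name:
            raise ConfigError(f"circular survival reference via {ref_name!r}")
        if ref_name in seen:
            raise ConfigError(f"strategy {current.name!r} references itself")
        seen.add(ref_name)
        current = config.get_strategy(ref_name)
    sv = current.survival
    os_params = LogLogisticParams(values[sv.os_theta_param], values[sv.os_kappa_param])
    pfs_params = LogLogisticParams(values[sv.pfs_theta_param], values[sv.pfs_kappa_param])
    kw = dict(
        form=st.loglogistic_form,
        time_unit=st.loglogistic_time_unit,
        cycle_days=st.cycle_length_days,
    )
    os_grid = np.asarray(curve_from_shape_params(os_params, **kw)(t)) ** hr_os
    pfs_grid = np.asarray(curve_from_shape_params(pfs_params, **kw)(t)) ** hr_pfs

    if strategy.post_progression_like_reference and current is not strategy:
        # adopt the reference arm's post-progression pool wholesale
        ref_os = np.asarray(curve_from_shape_params(os_params, **kw)(t))
        ref_pfs = np.asarray(curve_from_shape_params(pfs_params, **kw)(t))
        os_grid = np.clip(pfs_grid + np.maximum(ref_os - ref_pfs, 0.0), 0.0, 1.0)
        os_grid = np.minimum.accumulate(os_grid)
    return os_grid, pfs_grid


def state_memberships(
    os_curve: SurvivalCurve,
    pfs_curve: SurvivalCurve,
    endstage_split: float,
    life_table: Optional[LifeTable],
    settings: CEASettings,
) -> CohortTrace:
    """State-membership trace (no costs/QALYs attached).

    ``endstage_split`` is the fraction of the progressed pool occupying the
    end-stage (BSC) state; the rest occupy PD and receive subsequent
    therapy.  OS is life-table blended when a table is supplied; PFS is
    clamped to never exceed OS.
    """
    n = settings.horizon_cycles
    t = np.arange(n + 1, dtype=float)
    os_grid = np.asarray(os_curve(t), dtype=float)
    pfs_grid = np.asarray(pfs_curve(t), dtype=float)
    if abs(os_grid[0] - 1.0) > 1e-9 or abs(pfs_grid[0] - 1.0) > 1e-9:
        raise ValueError("survival curves must satisfy S(0) = 1")
    if life_table is not None:
        os_grid = _blend_grid(os_grid, life_table, settings.blend_start_cycle,
                              settings.cycle_years)
    if np.any(pfs_grid > os_grid + 1e-12):
        logger.debug("PFS exceeded OS on %d cycles; clamping",
                     int(np.sum(pfs_grid > os_grid + 1e-12)))
    pfs_grid = np.minimum(pfs_grid, os_grid)
    progressed = os_grid - pfs_grid
    return CohortTrace(
        strategy="",
        t=t,
        pfs=pfs_grid,
        pd=progressed * (1.0 - endstage_split),
        endstage=progressed * endstage_split,
        dead=1.0 - os_grid,
        on_treatment=np.zeros_like(os_grid),
    )


def _pd_entrants(os_grid, pfs_grid, endstage_split) -> np.ndarray:
    """Per-interval incidence of entry into the PD state.

    New progressors equal the growth of the progressed pool plus its
    proportional share of deaths (deaths are apportioned across alive
    states by occupancy — a smoothness assumption of the partitioned
    form).
    """
    prog = os_grid - pfs_grid
    deaths = os_grid[:-1] - os_grid[1:]
    share = np.divide(prog[:-1], np.maximum(os_grid[:-1], 1e-300))
    return np.maximum(np.diff(prog) + deaths * share, 0.0) * (1.0 - endstage_split)


def run_cohort(
    strategy: Union[str, StrategyDefinition],
    config: ModelConfig,
    values: Optional[dict[str, float]] = None,
) -> CohortTrace:
    """Full cohort simulation of one arm: states, treatment occupancy,
    discounted costs and QALYs."""
    if isinstance(strategy, str):
        strategy = config.get_strategy(strategy)
    st = config.settings
    vals = values if values is not None else config.baseline_values()
    n = st.horizon_cycles
    # pad the grid 12 months past the horizon for time-to-death lookahead
    pad = int(math.ceil(12 * st.cycles_per_month)) + 2
    t_ext = np.arange(n + pad + 1, dtype=float)

    os_ext, pfs_ext = _resolve_curves_grid(strategy, config, vals, t_ext)
    life_table = LifeTable.from_rows(config.life_table, st.cycle_length_days)
    os_ext = _blend_grid(os_ext, life_table, st.blend_start_cycle, st.cycle_years)
    pfs_ext = np.minimum(pfs_ext, os_ext)

    t = t_ext[: n + 1]
    os_grid = os_ext[: n + 1]
    pfs_grid = pfs_ext[: n + 1]
    if os_grid[-1] > 1e-3:
        logger.warning(
            "alive fraction at horizon is %.4f (>0.1%%); extend horizon_cycles",
            os_grid[-1],
        )

    split = vals.get("endstage_split", 0.5)
    progressed = os_grid - pfs_grid

    p_disc = vals.get(strategy.ae_discontinuation_param, 0.0) if strategy.ae_discontinuation_param else 0.0
    on = pfs_grid * (1.0 - p_disc) ** t
    if strategy.max_treatment_cycles is not None:
        on = np.where(t < strategy.max_treatment_cycles, on, 0.0)

    accrued = valuation.accrue(
        t=t,
        alive=os_grid,
        pfs=pfs_grid,
        pd_state=progressed * (1.0 - split),
        endstage=progressed * split,
        on_treatment=on,
        pd_entrants=_pd_entrants(os_grid, pfs_grid, split),
        os_ext_t=t_ext,
        os_ext=os_ext,
        strategy=strategy,
        config=config,
        values=vals,
    )
    return CohortTrace(
        strategy=strategy.name,
        t=t,
        pfs=pfs_grid,
        pd=progressed * (1.0 - split),
        endstage=progressed * split,
        dead=1.0 - os_grid,
        on_treatment=on,
        qaly_increments=accrued["qaly"],
        cost_increments=accrued["cost"],
        qaly_increments_undiscounted=accrued["qaly_undiscounted"],
        cost_increments_undiscounted=accrued["cost_undiscounted"],
        life_year_increments=accrued["life_years"],
        cost_components=accrued["components"],
    )
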