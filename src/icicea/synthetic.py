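"""Synthetic inputs: pseudo individual-patient survival data with known
parameters, surrogate life tables, and perturbed configurations.

Everything the pipeline consumes can be generated here without downloads.
The pseudo-IPD generator stands in for survival data reconstructed from
published Kaplan-Meier figures; the surrogate life table stands in for a
registry extract of long-term advanced-NSCLC survival.
"""
from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field


class SyntheticCohortSpec(BaseModel):
    """Specification of a simulated survival cohort."""

    n_patients: int = Field(ge=1)
    family: str = "loglogistic"
    #: family-specific parameters, e.g. {"lam": 0.0243, "kappa": 1.117}
    true_params: dict[str, float]
    censoring_rate: float = Field(default=0.0, ge=0, lt=1)
    max_followup: float = Field(default=math.inf, gt=0)
    seed: int = 0


def _inverse_cdf(family: str, u: np.ndarray, p: dict[str, float]) -> np.ndarray:
    """Event times by inverse survival: solve S(t) = u."""
    if family == "loglogistic":
        # S(t) = 1/(1 + lam t^kappa)  =>  t = ((1-u)/(u lam))^(1/kappa)
        return ((1.0 - u) / (u * p["lam"])) ** (1.0 / p["kappa"])
    if family == "exponential":
        return -np.log(u) / p["rate"]
    if family == "weibull":
        # S(t) = exp(-(t/scale)^shape)
        return p["scale"] * (-np.log(u)) ** (1.0 / p["shape"])
    raise ValueError(f"unsupported family {family!r}")


def simulate_ipd(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Draw a pseudo individual-patient dataset (columns time_months, event).

    Event times come from the inverse CDF of the requested family.  A
    ``censoring_rate`` fraction of patients receive an independent uniform
    censoring time on (0, max_followup]; everyone is additionally
    administratively censored at ``max_followup``.
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(size=spec.n_patients)
    t_event = _inverse_cdf(spec.family, u, spec.true_params)
    t_obs = t_event.copy()
    event = np.ones(spec.n_patients, dtype=int)

    if spec.censoring_rate > 0:
        censored = rng.uniform(size=spec.n_patients) < spec.censoring_rate
        cap = spec.max_followup if math.isfinite(spec.max_followup) else np.quantile(
            t_event, 0.95
        )
        t_cens = rng.uniform(0.0, cap, size=spec.n_patients)
        hit = censored & (t_cens < t_obs)
        t_obs[hit] = t_cens[hit]
        event[hit] = 0
    if math.isfinite(spec.max_followup):
        late = t_obs > spec.max_followup
        t_obs[late] = spec.max_followup
        event[late] = 0
    return pd.DataFrame({"time_months": t_obs, "event": event})


# ---------------------------------------------------------------------------
# surrogate life table
# ---------------------------------------------------------------------------

# Synthetic surrogate annual hazards (per year) for the bundled default life
# table.  They emulate registry conditional survival of advanced-NSCLC
# patients who are still alive at the end of trial follow-up (the point at
# which extrapolated survival is blended with the table): roughly 20%/year,
# declining toward a ~9%/year floor comparable to elderly background
# mortality.  Substitute a real registry extract via the config to override.
_DEFAULT_ANNUAL_HAZARD_KNOTS = ([0.0, 3.0, 8.0, 20.0], [0.20, 0.15, 0.11, 0.09])


def default_life_table_rows(n_years: int = 45) -> list[tuple[float, float]]:
    """Annual cumulative-survival rows for the bundled synthetic life table."""
    years, hazards = _DEFAULT_ANNUAL_HAZARD_KNOTS
    rows = [(0.0, 1.0)]
    s = 1.0
    for y in range(n_years):
        h = float(np.interp(y + 0.5, years, hazards))
        s *= math.exp(-h)
        rows.append((float(y + 1), s))
    return rows


def surrogate_life_table(
    annual_survival: Sequence[float],
    cycle_days: float = 21.0,
):
    """Build a :class:`~icicea.engine.LifeTable` from annual survival fractions.

    ``annual_survival[k]`` is cumulative survival at the end of year k+1
    (the table implicitly starts at 1.0 in year 0).  Interpolation between
    annual anchors is hazard-constant, so monotonicity is preserved at
    cycle resolution.
    """
    from .engine import LifeTable

    fracs = list(annual_survival)
    if not fracs:
        raise ValueError("annual_survival must be non-empty")
    if fracs[0] > 1.0 + 1e-12:
        raise ValueError("annual survival must start at <= 1")
    if any(b > a + 1e-12 for a, b in zip(fracs, fracs[1:])):
        raise ValueError("annual survival fractions must be non-increasing")
    rows = [(0.0, 1.0)] + [(float(k + 1), float(s)) for k, s in enumerate(fracs)]
    return LifeTable(rows=rows, cycle_days=cycle_days)


# ---------------------------------------------------------------------------
# configuration jitter
# ---------------------------------------------------------------------------

#: parameters that define the model structure rather than an input magnitude
_STRUCTURAL = {"endstage_split"}


def jitter_config(config, relative_sd: float, seed: int = 0):
    """Multiply every non-structural parameter by log-normal noise.

    Beta-distributed parameters are clamped back into [0, 1]; DSA ranges
    are widened where needed so ``low <= baseline <= high`` still holds.
    Used to assert the engine runs on any plausible input set.
    """
    if relative_sd < 0:
        raise ValueError("relative_sd must be >= 0")
    out = config.model_copy(deep=True)
    if relative_sd == 0:
        return out
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + relative_sd**2))
    for name, spec in out.parameters.items():
        if name in _STRUCTURAL:
            continue
        factor = float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))
        b = spec.baseline * factor
        if spec.distribution.value == "beta":
            b = min(max(b, 0.0), 1.0)
        spec.baseline = b
        if spec.low is not None:
            spec.low = min(spec.low, b)
        if spec.high is not None:
            spec.high = max(spec.high, b)
    return type(config).model_validate(out.model_dump())
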