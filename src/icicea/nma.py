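"""Fixed-effect indirect treatment comparison on the log hazard-ratio scale.

A star network (each immunotherapy compared with a common chemotherapy
control in its own trial) admits the Bucher adjusted indirect comparison:

    log HR(B vs A) = log HR(B vs C) - log HR(A vs C)
    SE = sqrt(SE_A^2 + SE_B^2)

Direct evidence for the same contrast is pooled by inverse variance.
The base-case model reads hazard ratios from its configuration; this
module lets users regenerate them from trial summaries.
"""
from __future__ import annotations

import math
import pathlib
from typing import Sequence, Union

import pandas as pd
from pydantic import BaseModel, Field, model_validator

Z95 = 1.959963984540054


class TrialEffect(BaseModel):
    trial_id: str
    treatment: str
    comparator: str
    log_hr: float
    se_log_hr: float = Field(gt=0)

    @classmethod
    def from_hr_ci(
        cls, trial_id: str, treatment: str, comparator: str,
        hr: float, ci_low: float, ci_high: float,
    ) -> "TrialEffect":
        """Back-derive the SE from a 95% CI: (ln hi - ln lo) / (2*1.96)."""
        if not (0 < ci_low <= hr <= ci_high):
            raise ValueError(f"{trial_id}: need 0 < ci_low <= hr <= ci_high")
        return cls(
            trial_id=trial_id,
            treatment=treatment,
            comparator=comparator,
            log_hr=math.log(hr),
            se_log_hr=(math.log(ci_high) - math.log(ci_low)) / (2 * Z95),
        )


class HazardRatioEstimate(BaseModel):
    hr: float = Field(gt=0)
    ci_low: float = Field(gt=0)
    ci_high: float = Field(gt=0)

    @model_validator(mode="after")
    def _ordered(self):
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError("need ci_low <= hr <= ci_high")
        return self


def pool_direct(effects: Sequence[TrialEffect]) -> TrialEffect:
    """Inverse-variance-weighted pooling of effects for one contrast."""
    effects = list(effects)
    if not effects:
        raise ValueError("no effects to pool")
    contrast = (effects[0].treatment, effects[0].comparator)
    if any((e.treatment, e.comparator) != contrast for e in effects):
        raise ValueError("effects mix different treatment/comparator contrasts")
    if len(effects) == 1:
        return effects[0]
    weights = [1.0 / e.se_log_hr**2 for e in effects]
    total = sum(weights)
    pooled = sum(w * e.log_hr for w, e in zip(weights, effects)) / total
    return TrialEffect(
        trial_id="+".join(e.trial_id for e in effects),
        treatment=contrast[0],
        comparator=contrast[1],
        log_hr=pooled,
        se_log_hr=math.sqrt(1.0 / total),
    )


def indirect_hr(a_vs_common: TrialEffect, b_vs_common: TrialEffect) -> HazardRatioEstimate:
    """Bucher contrast of B versus A through the shared comparator."""
    if a_vs_common.comparator != b_vs_common.comparator:
        raise ValueError(
            f"comparators differ: {a_vs_common.comparator!r} vs "
            f"{b_vs_common.comparator!r}"
        )
    log_hr = b_vs_common.log_hr - a_vs_common.log_hr
    se = math.hypot(a_vs_common.se_log_hr, b_vs_common.se_log_hr)
    return HazardRatioEstimate(
        hr=math.exp(log_hr),
        ci_low=math.exp(log_hr - Z95 * se),
        ci_high=math.exp(log_hr + Z95 * se),
    )


def effects_from_csv(path: Union[str, pathlib.Path]) -> list[TrialEffect]:
    """Read trial effects from CSV columns
    trial_id,treatment,comparator,hr,ci_low,ci_high."""
    df = pd.read_csv(path)
    required = {"trial_id", "treatment", "comparator", "hr", "ci_low", "ci_high"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    return [
        TrialEffect.from_hr_ci(
            str(r.trial_id), str(r.treatment), str(r.comparator),
            float(r.hr), float(r.ci_low), float(r.ci_high),
        )
        for r in df.itertuples()
    ]
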