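"""Cost-effectiveness arithmetic: ICERs, dominance, net monetary benefit."""
from __future__ import annotations

import dataclasses
import enum
import math
from typing import Optional, Sequence, Union

import pandas as pd


class Verdict(str, enum.Enum):
    cost_effective = "cost_effective"
    not_cost_effective = "not_cost_effective"
    dominant = "dominant"
    dominated = "dominated"
    equivalent = "equivalent"


def icer(delta_cost: float, delta_qaly: float) -> Union[float, Verdict]:
    """Incremental cost-effectiveness ratio, or a dominance verdict.

    A positive ratio is returned when both increments share a sign
    (north-east or south-west quadrant of the CE plane); a strategy that
    is cheaper and at least as effective is dominant, one that is
    costlier and less effective is dominated.
    """
    if not (math.isfinite(delta_cost) and math.isfinite(delta_qaly)):
        raise ValueError("increments must be finite")
    if delta_cost == 0.0 and delta_qaly == 0.0:
        return Verdict.equivalent
    if delta_cost <= 0.0 and delta_qaly >= 0.0:
        return Verdict.dominant
    if delta_cost >= 0.0 and delta_qaly <= 0.0:
        return Verdict.dominated
    return delta_cost / delta_qaly


def classify_vs_wtp(icer_or_verdict: Union[float, Verdict], wtp: float,
                    delta_qaly: Optional[float] = None) -> Verdict:
    """Compare an ICER with the willingness-to-pay threshold.

    Dominance verdicts pass through.  For a ratio, more-costly/more-
    effective strategies are cost-effective at or below the threshold;
    in the cheaper/less-effective quadrant (``delta_qaly < 0``) the logic
    inverts — forgoing QALYs is acceptable only if the saving per QALY
    exceeds the threshold.
    """
    if wtp <= 0:
        raise ValueError("wtp must be > 0")
    if isinstance(icer_or_verdict, Verdict):
        return icer_or_verdict
    ratio = float(icer_or_verdict)
    if delta_qaly is not None and delta_qaly < 0:
        return Verdict.cost_effective if ratio >= wtp else Verdict.not_cost_effective
    return Verdict.cost_effective if ratio <= wtp else Verdict.not_cost_effective


def nmb(total_cost: float, total_qaly: float, wtp: float) -> float:
    """Net monetary benefit: QALYs valued at the threshold, minus cost."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    return total_qaly * wtp - total_cost


def icer_value(delta_cost: float, delta_qaly: float, wtp: float,
               cap_multiple: float = 5.0) -> float:
    """ICER mapped to a bounded tornado-friendly number.

    Dominant outcomes map to 0 (maximally favourable), dominated ones to
    ``cap_multiple * wtp`` (maximally unfavourable); genuine ratios are
    clipped to the same interval.
    """
    v = icer(delta_cost, delta_qaly)
    if v is Verdict.dominant or v is Verdict.equivalent:
        return 0.0
    if v is Verdict.dominated:
        return cap_multiple * wtp
    if delta_qaly < 0:  # cheaper and less effective: report the saving ratio
        return float(min(max(v, 0.0), cap_multiple * wtp))
    return float(min(max(v, 0.0), cap_multiple * wtp))


@dataclasses.dataclass
class CEResult:
    """Per-strategy totals and, for comparators, pairwise increments."""

    strategy: str
    total_cost: float
    total_qaly: float
    comparator: Optional[str] = None
    delta_cost: Optional[float] = None
    delta_qaly: Optional[float] = None
    icer: Optional[Union[float, Verdict]] = None
    verdict: Optional[Verdict] = None


def compare_strategies(
    totals: dict[str, tuple[float, float]],
    reference: str,
    wtp: float,
    order: Optional[Sequence[str]] = None,
) -> list[CEResult]:
    """Pairwise comparison of the reference strategy against each other.

    ``totals`` maps strategy name to (total cost, total QALYs).  Each
    comparator row carries the increments of the *reference* relative to
    that comparator, mirroring a summary table in which the reference is
    the intervention of interest.
    """
    if reference not in totals:
        raise KeyError(f"reference {reference!r} not among results")
    ref_cost, ref_qaly = totals[reference]
    results = [CEResult(strategy=reference, total_cost=ref_cost, total_qaly=ref_qaly)]
    names = order if order is not None else list(totals)
    for name in names:
        if name == reference:
            continue
        cost, qaly = totals[name]
        d_cost = ref_cost - cost
        d_qaly = ref_qaly - qaly
        ratio = icer(d_cost, d_qaly)
        results.append(
            CEResult(
                strategy=name,
                total_cost=cost,
                total_qaly=qaly,
                comparator=name,
                delta_cost=d_cost,
                delta_qaly=d_qaly,
                icer=ratio,
                verdict=classify_vs_wtp(ratio, wtp, d_qaly),
            )
        )
    return results


def results_frame(results: Sequence[CEResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        icer_repr = ""
        if r.icer is not None:
            icer_repr = (
                r.icer.value if isinstance(r.icer, Verdict) else f"{r.icer:.0f}"
            )
        rows.append(
            {
                "strategy": r.strategy,
                "cost": r.total_cost,
                "qalys": r.total_qaly,
                "delta_cost": r.delta_cost,
                "delta_qalys": r.delta_qaly,
                "icer": icer_repr,
                "verdict": r.verdict.value if r.verdict else "",
            }
        )
    return pd.DataFrame(rows)
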