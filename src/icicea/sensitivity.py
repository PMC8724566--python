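"""Deterministic (one-way) and probabilistic sensitivity analysis.

DSA varies each parameter to the ends of its range with everything else
held at baseline, records the ICER of the contrast of interest at both
bounds, and sorts by swing (tornado order).  PSA samples every
distributional parameter (moment-matched to its baseline and range),
re-runs the model per draw, and summarises cost-effectiveness
acceptability across a willingness-to-pay grid.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import warnings
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import Distribution, ModelConfig, ParameterSpec
from .engine import run_cohort
from .outcomes import Verdict, icer, icer_value, nmb

__all__ = [
    "DsaRecord",
    "dsa_ranges",
    "run_dsa",
    "find_threshold_value",
    "psa_distribution",
    "PsaResult",
    "run_psa",
]

Z95_SPAN = 3.92  # width of a 95% interval in standard deviations


def dsa_ranges(spec: ParameterSpec) -> tuple[float, float]:
    """The stored range if present, else baseline * (0.5, 1.5)."""
    return spec.range()


@dataclasses.dataclass
class DsaRecord:
    parameter: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float
    verdict_at_low: str
    verdict_at_high: str
    swing: float
    crossing: str  # none | ratio | dominance
    error: Optional[str] = None


def _contrast_icer(config: ModelConfig, contrast: tuple[str, str],
                   values: dict[str, float], wtp: float):
    a = run_cohort(contrast[0], config, values)
    b = run_cohort(contrast[1], config, values)
    d_cost = a.total_cost - b.total_cost
    d_qaly = a.total_qaly - b.total_qaly
    return d_cost, d_qaly, icer(d_cost, d_qaly), icer_value(d_cost, d_qaly, wtp)


def run_dsa(
    config: ModelConfig,
    contrast: tuple[str, str],
    wtp: Optional[float] = None,
    parameters: Optional[Sequence[str]] = None,
) -> list[DsaRecord]:
    """One-way DSA for one strategy pair, sorted by swing descending.

    Parameters without a stated range (the fixed survival shape
    parameters) are skipped unless explicitly requested.  A bound that
    breaks model validity is recorded as failed, not dropped.
    """
    wtp = wtp if wtp is not None else config.settings.wtp_threshold
    base_values = config.baseline_values()
    if parameters is None:
        parameters = [
            name for name, spec in config.parameters.items() if spec.low is not None
        ]
    records: list[DsaRecord] = []
    for name in parameters:
        spec = config.parameters[name]
        lo, hi = dsa_ranges(spec)
        row: dict = {"parameter": name, "low": lo, "high": hi}
        try:
            out = {}
            dq_sign = {}
            for bound, value in (("low", lo), ("high", hi)):
                values = dict(base_values)
                values[name] = value
                d_cost, d_qaly, verdict, num = _contrast_icer(config, contrast, values, wtp)
                out[bound] = (num, verdict, d_qaly)
                dq_sign[bound] = d_qaly > 0
            num_lo, v_lo, _ = out["low"]
            num_hi, v_hi, _ = out["high"]
            both_ratio = dq_sign["low"] and dq_sign["high"]
            lo_num, hi_num = sorted((num_lo, num_hi))
            if both_ratio and lo_num <= wtp < hi_num:
                crossing = "ratio"
            elif not (dq_sign["low"] and dq_sign["high"]):
                crossing = "dominance"
            else:
                crossing = "none"
            records.append(
                DsaRecord(
                    parameter=name,
                    low=lo,
                    high=hi,
                    icer_at_low=num_lo,
                    icer_at_high=num_hi,
                    verdict_at_low=v_lo.value if isinstance(v_lo, Verdict) else "ratio",
                    verdict_at_high=v_hi.value if isinstance(v_hi, Verdict) else "ratio",
                    swing=abs(num_hi - num_lo),
                    crossing=crossing,
                )
            )
        except Exception as exc:  # noqa: BLE001 - per-spec: record, don't drop
            records.append(
                DsaRecord(
                    parameter=name, low=lo, high=hi,
                    icer_at_low=math.nan, icer_at_high=math.nan,
                    verdict_at_low="error", verdict_at_high="error",
                    swing=0.0, crossing="none", error=str(exc),
                )
            )
    records.sort(key=lambda r: -r.swing)
    return records


def find_threshold_value(
    config: ModelConfig,
    contrast: tuple[str, str],
    parameter: str,
    wtp: Optional[float] = None,
    tol: float = 1e-3,
) -> Optional[float]:
    """Parameter value inside its DSA range at which the contrast ICER
    equals the threshold (bisection); None if the range never crosses."""
    wtp = wtp if wtp is not None else config.settings.wtp_threshold
    lo, hi = dsa_ranges(config.parameters[parameter])
    base = config.baseline_values()

    def f(x: float) -> float:
        values = dict(base)
        values[parameter] = x
        *_, num = _contrast_icer(config, contrast, values, wtp)
        return num - wtp

    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        return None
    a, b = lo, hi
    for _ in range(60):
        mid = 0.5 * (a + b)
        if b - a < tol * max(1.0, abs(mid)):
            return mid
        if f(a) * f(mid) <= 0:
            b = mid
        else:
            a = mid
    return 0.5 * (a + b)


def dsa_frame(records: Sequence[DsaRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "low": r.low,
                "high": r.high,
                "icer_low": r.icer_at_low,
                "icer_high": r.icer_at_high,
                "swing": r.swing,
                "crossing": r.crossing,
                "error": r.error or "",
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


def psa_distribution(spec: ParameterSpec) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Sampler for one parameter, moment-matched to baseline and range.

    The (low, high) range is read as a central 95% interval, so
    sigma = (high - low) / 3.92.  Normal uses (baseline, sigma); Gamma
    shape = (mean/sigma)^2 with rate = shape/mean; Beta alpha/beta by
    method of moments; LogNormal has sigma on the log scale derived from
    the log-range and its mean equal to the baseline.  Fixed parameters
    are degenerate at baseline.
    """
    m = spec.baseline
    dist = Distribution(spec.distribution)
    if dist is Distribution.fixed or spec.low is None or spec.low == spec.high:
        return lambda rng, n: np.full(n, m)
    lo, hi = spec.range()
    sigma = (hi - lo) / Z95_SPAN
    if dist is Distribution.normal:
        return lambda rng, n: rng.normal(m, sigma, size=n)
    if dist is Distribution.gamma:
        shape = (m / sigma) ** 2
        scale = m / shape
        return lambda rng, n: rng.gamma(shape, scale, size=n)
    if dist is Distribution.lognormal:
        s_log = (math.log(hi) - math.log(lo)) / Z95_SPAN
        mu = math.log(m) - 0.5 * s_log**2  # mean = baseline
        return lambda rng, n: rng.lognormal(mu, s_log, size=n)
    if dist is Distribution.beta:
        if sigma**2 >= m * (1.0 - m) or m <= 0.0 or m >= 1.0:
            warnings.warn(
                f"{spec.name}: infeasible beta moments; sampling uniformly on the range"
            )
            return lambda rng, n: rng.uniform(max(lo, 0.0), min(hi, 1.0), size=n)
        nu = m * (1.0 - m) / sigma**2 - 1.0
        a, b = m * nu, (1.0 - m) * nu
        return lambda rng, n: rng.beta(a, b, size=n)
    raise ValueError(f"unsupported distribution {dist!r}")


@dataclasses.dataclass
class PsaResult:
    """Draw-level outcomes plus acceptability summaries."""

    draws: pd.DataFrame          # one row per draw: per-strategy cost/qaly
    samples: pd.DataFrame        # sampled parameter values per draw
    ceac: pd.DataFrame           # columns wtp, strategy, probability
    summary: dict                # pairwise fractions vs the reference at WTP
    seed: int
    n_draws: int
    n_rejected: int
    config_hash: str

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "n_draws": self.n_draws,
            "n_rejected": self.n_rejected,
            "config_hash": self.config_hash,
        }


def _config_hash(config: ModelConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_psa(
    config: ModelConfig,
    n_draws: int,
    seed: int,
    wtp_grid: Optional[Sequence[float]] = None,
    strategies: Optional[Sequence[str]] = None,
) -> PsaResult:
    """Monte-Carlo parameter uncertainty analysis.

    Each parameter draws from its own substream spawned off the master
    seed, so adding a parameter does not shuffle the others' draws.
    Draws yielding a non-finite model output are rejected and resampled
    from a reserve stream (count reported).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    st = config.settings
    wtps = (
        np.asarray(list(wtp_grid), dtype=float)
        if wtp_grid is not None
        else np.arange(0.0, 200_001.0, 10_000.0)
    )
    if st.wtp_threshold not in wtps:
        wtps = np.sort(np.append(wtps, st.wtp_threshold))
    names = sorted(config.parameters)
    ss = np.random.SeedSequence(seed)
    streams = {n: np.random.default_rng(c) for n, c in zip(names, ss.spawn(len(names)))}
    samples = {
        name: psa_distribution(config.parameters[name])(streams[name], n_draws)
        for name in names
    }
    strat_names = list(strategies) if strategies else [s.name for s in config.strategies]

    base = config.baseline_values()
    cost = {s: np.empty(n_draws) for s in strat_names}
    qaly = {s: np.empty(n_draws) for s in strat_names}
    n_rejected = 0
    reserve = np.random.default_rng(ss.spawn(1)[0])
    for i in range(n_draws):
        for attempt in range(100):
            values = dict(base)
            for name in names:
                values[name] = float(samples[name][i])
            ok = True
            for s in strat_names:
                try:
                    trace = run_cohort(s, config, values)
                    c, q = trace.total_cost, trace.total_qaly
                except (ValueError, ZeroDivisionError):
                    # e.g. a Normal tail draw produced a non-physical input
                    ok = False
                    break
                if not (math.isfinite(c) and math.isfinite(q)):
                    ok = False
                    break
                cost[s][i], qaly[s][i] = c, q
            if ok:
                break
            n_rejected += 1
            for name in names:  # resample the whole vector
                samples[name][i] = psa_distribution(config.parameters[name])(reserve, 1)[0]
        else:  # pragma: no cover - would indicate a structural problem
            raise RuntimeError("draw could not be made valid after 100 attempts")

    # cost-effectiveness acceptability: P(strategy has maximal NMB)
    ceac_rows = []
    nmb_stack = {s: None for s in strat_names}
    for w in wtps:
        mat = np.column_stack([qaly[s] * w - cost[s] for s in strat_names])
        best = np.argmax(mat, axis=1)
        for j, s in enumerate(strat_names):
            ceac_rows.append(
                {"wtp": w, "strategy": s, "probability": float(np.mean(best == j))}
            )
    ceac = pd.DataFrame(ceac_rows)

    # pairwise fractions vs the reference at the base threshold
    ref = config.reference_strategy
    summary: dict = {"wtp": st.wtp_threshold}
    if ref in strat_names:
        for s in strat_names:
            if s == ref:
                continue
            d_cost = cost[ref] - cost[s]
            d_qaly = qaly[ref] - qaly[s]
            dominant = (d_cost <= 0) & (d_qaly >= 0) & ~((d_cost == 0) & (d_qaly == 0))
            dominated = (d_cost >= 0) & (d_qaly <= 0) & ~((d_cost == 0) & (d_qaly == 0))
            ratio_ce = (d_qaly > 0) & (d_cost > 0) & (d_cost <= st.wtp_threshold * d_qaly)
            acceptable = (d_qaly * st.wtp_threshold - d_cost) >= 0
            summary[s] = {
                "cost_effective_frac": float(np.mean(ratio_ce)),
                "dominant_frac": float(np.mean(dominant)),
                "dominated_frac": float(np.mean(dominated)),
                "acceptable_frac": float(np.mean(acceptable)),
            }

    draws = pd.DataFrame(
        {
            **{f"cost_{s}": cost[s] for s in strat_names},
            **{f"qaly_{s}": qaly[s] for s in strat_names},
        }
    )
    return PsaResult(
        draws=draws,
        samples=pd.DataFrame(samples),
        ceac=ceac,
        summary=summary,
        seed=seed,
        n_draws=n_draws,
        n_rejected=n_rejected,
        config_hash=_config_hash(config),
    )
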