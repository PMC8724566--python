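"""Human-readable outputs: summary tables, tornado and CEAC exports.

Every figure has a CSV twin holding exactly the plotted numbers; plotting
itself is optional (matplotlib imported only when a plot is requested).
"""
from __future__ import annotations

import hashlib
import json
import pathlib
import sys
from typing import Optional, Sequence, Union

import pandas as pd

from .outcomes import CEResult, Verdict
from .sensitivity import DsaRecord, PsaResult, dsa_frame

__all__ = ["render_summary", "render_tornado", "render_ceac", "write_manifest"]


def _fmt_currency(x: Optional[float]) -> str:
    return "" if x is None else f"{x:,.0f}"


def render_summary(
    results: Sequence[CEResult], path: Optional[Union[str, pathlib.Path]] = None
) -> pd.DataFrame:
    """Summary table: cost, QALYs, increments and ICER/verdict per row.

    The reference strategy leads; each comparator row shows the
    reference's increments against it, with dominance of the reference
    printed as "Dominated" in the comparator row.
    """
    if not results:
        raise ValueError("no results to render")
    rows = []
    for r in results:
        icer_text = ""
        if r.comparator is not None:
            if r.icer is Verdict.dominant:
                icer_text = "Dominated"
            elif r.icer is Verdict.dominated:
                icer_text = "Dominant"
            elif r.icer is Verdict.equivalent:
                icer_text = "Equivalent"
            elif r.icer is not None:
                label = (
                    "cost-effective"
                    if r.verdict is Verdict.cost_effective
                    else "not cost-effective"
                )
                icer_text = f"{r.icer:,.0f} ({label})"
        rows.append(
            {
                "strategy": r.strategy,
                "cost": _fmt_currency(r.total_cost),
                "qalys": f"{r.total_qaly:.2f}",
                "incremental_cost": _fmt_currency(r.delta_cost),
                "incremental_qalys": "" if r.delta_qaly is None else f"{r.delta_qaly:.2f}",
                "icer": icer_text,
            }
        )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def render_tornado(
    records: Sequence[DsaRecord],
    top_k: int = 10,
    csv_path: Optional[Union[str, pathlib.Path]] = None,
    plot_path: Optional[Union[str, pathlib.Path]] = None,
    wtp: float = 100_000.0,
) -> pd.DataFrame:
    """Top-k tornado rows (by swing) with optional horizontal-bar plot."""
    if not records:
        raise ValueError("no DSA records; nothing to plot")
    df = dsa_frame(records).head(top_k)
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 0.5 * len(df) + 1.5))
        order = df.iloc[::-1]
        base = order[["icer_low", "icer_high"]].mean(axis=1)
        ax.barh(
            order["parameter"],
            order["icer_high"] - order["icer_low"],
            left=order["icer_low"],
            color="#4878CF",
        )
        ax.axvline(wtp, color="crimson", linestyle="--", label=f"WTP ${wtp:,.0f}/QALY")
        ax.set_xlabel("ICER ($/QALY)")
        ax.legend(loc="lower right")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return df


def render_ceac(
    psa: PsaResult,
    csv_path: Optional[Union[str, pathlib.Path]] = None,
    plot_path: Optional[Union[str, pathlib.Path]] = None,
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves (CSV twin + optional plot)."""
    df = psa.ceac.copy()
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4.5))
        for name, grp in df.groupby("strategy"):
            ax.plot(grp["wtp"], grp["probability"], label=name)
        ax.set_xlabel("Willingness to pay ($/QALY)")
        ax.set_ylabel("Probability cost-effective")
        ax.set_ylim(0, 1)
        ax.legend()
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return df


def write_manifest(
    path: Union[str, pathlib.Path],
    config,
    seed: Optional[int] = None,
    n_draws: Optional[int] = None,
    extra: Optional[dict] = None,
) -> dict:
    """JSON run manifest: seed, draw count, config hash, versions."""
    import icicea

    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    manifest = {
        "config_hash": hashlib.sha256(payload.encode()).hexdigest()[:16],
        "seed": seed,
        "n_draws": n_draws,
        "python": sys.version.split()[0],
        "icicea": icicea.__version__,
    }
    if extra:
        manifest.update(extra)
    pathlib.Path(path).write_text(json.dumps(manifest, indent=2))
    return manifest
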