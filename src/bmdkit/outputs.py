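"""Summary files, curve plots and the reproducibility report.

Three CSV outputs mirror the fitted state: ``benchmark_dose.csv`` (one
row per group: selected model, BMD10/BMDL/BMD50, status), ``dose.csv``
(per-dose counts with Wilson 95% binomial intervals) and ``fits.csv``
(points along each selected curve).  The markdown/HTML report records
every parameter and count that shaped the run so a reader can reproduce
it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .core_data import DoseResponseGroup
from .filtering import FILTER_ORDER, FilterResult, filter_summary
from .models import MODEL_ORDER
from .selection import BMDResult

BENCHMARK_COLUMNS = [
    "chemical_id", "endpoint", "selected_model", "bmd10", "bmdl", "bmd50",
    "status", "gof_pvalue", "aic",
]


def wilson_interval(affected, total, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
    """Wilson score interval for a binomial proportion, clipped to [0, 1]."""
    lo, hi = proportion_confint(affected, total, alpha=1 - level, method="wilson")
    return np.clip(lo, 0.0, 1.0), np.clip(hi, 0.0, 1.0)


def benchmark_dose_table(results: list[BMDResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "chemical_id": r.chemical_id,
                "endpoint": r.endpoint,
                "selected_model": r.selected_model,
                "bmd10": r.bmd10,
                "bmdl": r.bmdl,
                "bmd50": r.bmd50,
                "status": r.status if not r.flags else f"{r.status}:{'+'.join(r.flags)}",
                "gof_pvalue": r.gof_pvalue,
                "aic": r.aic,
            }
        )
    return pd.DataFrame(rows, columns=BENCHMARK_COLUMNS)


def dose_table(groups: list[DoseResponseGroup], level: float = 0.95) -> pd.DataFrame:
    """Per-dose pooled counts and binomial confidence intervals."""
    rows = []
    for g in groups:
        d = g.doses[g.doses["total"] > 0]
        lo, hi = wilson_interval(d["affected"].to_numpy(), d["total"].to_numpy(), level)
        for i, (_, row) in enumerate(d.iterrows()):
            rows.append(
                {
                    "chemical_id": g.chemical_id,
                    "endpoint": g.endpoint,
                    "concentration": row["concentration"],
                    "affected": row["affected"],
                    "total": row["total"],
                    "proportion": row["affected"] / row["total"],
                    "ci_lower": float(np.atleast_1d(lo)[i]),
                    "ci_upper": float(np.atleast_1d(hi)[i]),
                }
            )
    return pd.DataFrame(rows)


def _dose_grid(concentrations: np.ndarray, n_points: int) -> np.ndarray:
    pos = concentrations[concentrations > 0]
    lo, hi = pos.min() / 10.0, pos.max()
    return np.concatenate([[0.0], np.geomspace(lo, hi, n_points)])


def fits_table(
    results: list[BMDResult], groups: list[DoseResponseGroup], n_points: int = 100
) -> pd.DataFrame:
    """Points along each fitted group's selected curve (log-spaced + dose 0)."""
    by_key = {g.key: g for g in groups}
    rows = []
    for r in results:
        if r.status != "fitted" or r.params is None:
            continue
        g = by_key[(r.chemical_id, r.endpoint)]
        grid = _dose_grid(g.concentrations, n_points)
        from .models import response_probability

        probs = response_probability(r.selected_model, r.params, grid)
        for d, p in zip(grid, probs):
            rows.append(
                {
                    "chemical_id": r.chemical_id,
                    "endpoint": r.endpoint,
                    "model": r.selected_model,
                    "dose": d,
                    "probability": p,
                }
            )
    return pd.DataFrame(rows)


def response_curve_plot(
    group: DoseResponseGroup,
    result: BMDResult | None = None,
    path: str | None = None,
    n_points: int = 100,
    level: float = 0.95,
):
    """Observed proportions with binomial CIs, the fitted curve, and BMD markers.

    Dose 0 is drawn at the grid origin (smallest positive dose / 10) on
    the log axis.  When the group is unfitted a data-only plot with a
    notice is produced.  Returns (figure, underlying DataFrame); when
    ``path`` is given the figure and its CSV twin are written there.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    obs = dose_table([group], level=level)
    grid_origin = group.concentrations[group.concentrations > 0].min() / 10.0
    x_obs = np.where(obs["concentration"] > 0, obs["concentration"], grid_origin)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(
        x_obs,
        obs["proportion"],
        yerr=[obs["proportion"] - obs["ci_lower"], obs["ci_upper"] - obs["proportion"]],
        fmt="o", color="black", capsize=3, label="observed ± 95% CI",
    )
    fitted = result is not None and result.status == "fitted" and result.params is not None
    if fitted:
        from .models import response_probability

        grid = _dose_grid(group.concentrations, n_points)
        probs = response_probability(result.selected_model, result.params, grid)
        xg = np.where(grid > 0, grid, grid_origin)
        ax.plot(xg, probs, color="tab:blue", label=result.selected_model)
        if np.isfinite(result.bmd10):
            ax.axvline(result.bmd10, color="tab:red", ls="--", lw=1, label="BMD10")
        if np.isfinite(result.bmdl):
            ax.axvline(result.bmdl, color="tab:orange", ls=":", lw=1, label="BMDL")
        curve_df = pd.DataFrame({"dose": grid, "probability": probs})
    else:
        ax.text(0.05, 0.9, "no curve fit for this group", transform=ax.transAxes, color="tab:red")
        curve_df = pd.DataFrame(columns=["dose", "probability"])
    ax.set_xscale("log")
    ax.set_xlabel("concentration (µM)")
    ax.set_ylabel("proportion affected")
    ax.set_title(f"{group.chemical_id} — {group.endpoint}")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        csv_twin = str(path).rsplit(".", 1)[0] + ".csv"
        curve_df.to_csv(csv_twin, index=False)
    return fig, curve_df


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------


@dataclass
class ReportBundle:
    """Everything the reproducibility report needs, in pipeline order."""

    input_summary: dict  # rows, chemicals, endpoints, data type
    preprocessing_steps: list[str]
    filter_result: FilterResult | None
    results: list[BMDResult]
    parameters: dict  # every knob that shaped the run, seed included
    version: str = "0.1.0"
    warnings: list[str] = field(default_factory=list)


def _model_counts(results: list[BMDResult]) -> dict[str, int]:
    counts = {m: 0 for m in MODEL_ORDER}
    for r in results:
        if r.status == "fitted" and r.selected_model:
            counts[r.selected_model] += 1
    return counts


def render_report(bundle: ReportBundle, reproducible: bool = False) -> str:
    """Render the markdown report; deterministic given identical state.

    Under ``reproducible`` no timestamp appears in the body, so identical
    pipeline state renders byte-identically.
    """
    lines = ["# Benchmark dose modeling report", ""]
    if not reproducible:
        import datetime

        lines += [f"_Generated: {datetime.datetime.now().isoformat(timespec='seconds')}_", ""]
    lines += [f"_bmdkit version {bundle.version}_", ""]

    lines += ["## Data Input", ""]
    for k, v in bundle.input_summary.items():
        lines.append(f"- {k}: {v}")
    lines.append("")

    lines += ["## Pre-processing", ""]
    if bundle.preprocessing_steps:
        for i, step in enumerate(bundle.preprocessing_steps, 1):
            lines.append(f"{i}. {step}")
    else:
        lines.append("No pre-processing steps were applied.")
    lines.append("")

    lines += ["## Filtering", ""]
    if bundle.filter_result is not None:
        s = filter_summary(bundle.filter_result)
        lines.append(f"- Input groups: {s['input_groups']}")
        for name in FILTER_ORDER:
            lines.append(f"- Removed by {name.replace('_', ' ')} filter: {s['removed_per_filter'][name]}")
        lines.append(f"- Groups kept for modeling: {s['kept_groups']}")
    else:
        lines.append("No filters were applied (models were fit to unfiltered data).")
    lines.append("")

    lines += ["## Model Fitting", ""]
    status_counts: dict[str, int] = {}
    for r in bundle.results:
        status_counts[r.status] = status_counts.get(r.status, 0) + 1
    for status in sorted(status_counts):
        lines.append(f"- {status}: {status_counts[status]}")
    lines.append("")
    lines.append("Selected model counts:")
    lines.append("")
    lines.append("| model | selected |")
    lines.append("| --- | --- |")
    for m, c in _model_counts(bundle.results).items():
        lines.append(f"| {m} | {c} |")
    lines.append("")

    lines += ["## Parameters", ""]
    for k in sorted(bundle.parameters):
        lines.append(f"- {k}: {bundle.parameters[k]}")
    lines.append("")

    if bundle.warnings:
        lines += ["## Warnings", ""]
        for w in bundle.warnings:
            lines.append(f"- {w}")
        lines.append("")
    return "\n".join(lines)


def write_report(
    bundle: ReportBundle, path: str, fmt: str = "markdown", reproducible: bool = False
) -> str:
    md = render_report(bundle, reproducible=reproducible)
    if fmt == "markdown":
        text = md
    elif fmt == "html":
        body = md.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        text = (
            "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
            "<title>Benchmark dose modeling report</title></head>\n"
            f"<body><pre>\n{body}\n</pre></body></html>\n"
        )
    else:
        raise ValueError("fmt must be 'markdown' or 'html'")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)
    return path
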