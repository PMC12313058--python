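"""EPA eligibility filters for dose-response groups.

Three filters run in a fixed order, each with the EPA-recommended default:

1. negative control — plates whose 0-µM (control) response exceeds 50%
   are dropped from every group of that chemical, and the surviving
   plates re-aggregated; a group losing all its data is removed here.
2. minimum concentration — groups with fewer than 3 distinct non-zero
   concentrations (with observed wells) are removed.
3. correlation — groups whose pooled response is not positively
   rank-correlated with concentration (Spearman ρ < 0.2) are removed;
   ρ with fewer than 3 usable dose points or zero variance counts as
   degenerate and is removed too.

A ledger records, for every input group, whether it was kept, the first
filter that removed it, and the deciding statistics; the summary feeds
the removal-count and ρ-histogram visualizations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import CONCENTRATION, PLATE, DoseResponseGroup

NEGATIVE_CONTROL, MIN_CONCENTRATION, CORRELATION = (
    "negative_control",
    "minimum_concentration",
    "correlation",
)
FILTER_ORDER = (NEGATIVE_CONTROL, MIN_CONCENTRATION, CORRELATION)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the three filters (defaults = EPA recommendations)."""

    negative_control_threshold: float = 0.50
    min_nonzero_concentrations: int = 3
    correlation_threshold: float = 0.2

    def __post_init__(self):
        if not 0 <= self.negative_control_threshold <= 1:
            raise ValueError("negative_control_threshold must be in [0, 1]")
        if self.min_nonzero_concentrations < 1:
            raise ValueError("min_nonzero_concentrations must be >= 1")
        if not -1 <= self.correlation_threshold <= 1:
            raise ValueError("correlation_threshold must be in [-1, 1]")


@dataclass
class FilterResult:
    kept: list[DoseResponseGroup]
    ledger: pd.DataFrame  # one row per input group
    plate_controls: pd.DataFrame  # per (chemical, plate): control response, removed
    config: FilterConfig
    filters_applied: tuple[str, ...] = FILTER_ORDER
    warnings: list[str] = field(default_factory=list)


def spearman_rho(concentrations, responses) -> float:
    """Spearman rank correlation with NA-pair removal and mid-ranks for ties.

    Returns NaN when fewer than 3 complete pairs remain or either vector
    is constant (the correlation is then undefined, not zero).
    """
    x = np.asarray(concentrations, float)
    y = np.asarray(responses, float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


# --------------------------------------------------------------------------
# individual filters
# --------------------------------------------------------------------------


def plate_control_responses(groups: list[DoseResponseGroup]) -> pd.DataFrame:
    """Control (0 µM) response per (chemical, plate), pooled across endpoints."""
    frames = []
    for g in groups:
        if g.plate_counts is None:
            continue
        at0 = g.plate_counts[g.plate_counts[CONCENTRATION] == 0]
        if at0.empty:
            continue
        frames.append(at0.assign(chemical_id=g.chemical_id)[["chemical_id", PLATE, "affected", "total"]])
    if not frames:
        return pd.DataFrame(columns=["chemical_id", PLATE, "affected", "total", "control_response"])
    pooled = (
        pd.concat(frames)
        .groupby(["chemical_id", PLATE], as_index=False)[["affected", "total"]]
        .sum()
    )
    pooled["control_response"] = pooled["affected"] / pooled["total"]
    return pooled


def negative_control_filter(
    groups: list[DoseResponseGroup], threshold: float = 0.50
) -> tuple[list[DoseResponseGroup], pd.DataFrame, pd.DataFrame]:
    """Drop plates with control response strictly above the threshold.

    Plate removal is chemical-wide: a failing plate leaves every group of
    that chemical, and groups are re-aggregated from the surviving
    plates.  Groups without plate information, or without any 0-µM data,
    pass with a flag.  Returns (surviving groups, per-group entries,
    per-plate table).
    """
    plates = plate_control_responses(groups)
    bad = plates[plates["control_response"] > threshold]
    bad_keys = set(map(tuple, bad[["chemical_id", PLATE]].to_numpy()))
    plates = plates.assign(removed=plates.apply(
        lambda r: (r["chemical_id"], r[PLATE]) in bad_keys, axis=1
    ) if not plates.empty else False)

    survivors, entries = [], []
    for g in groups:
        entry = {
            "chemical_id": g.chemical_id,
            "endpoint": g.endpoint,
            "removed_by_negative_control": False,
            "max_plate_control_response": np.nan,
        }
        if g.plate_counts is None:
            g = _flagged(g, "no_plate_info")
            survivors.append(g)
        elif (g.plate_counts[CONCENTRATION] == 0).sum() == 0:
            g = _flagged(g, "no_control_data")
            survivors.append(g)
        else:
            mine = plates[plates["chemical_id"] == g.chemical_id]
            entry["max_plate_control_response"] = float(mine["control_response"].max())
            keep_pc = g.plate_counts[
                ~g.plate_counts[PLATE].map(lambda p: (g.chemical_id, p) in bad_keys)
            ]
            if keep_pc.empty or keep_pc["total"].sum() == 0:
                entry["removed_by_negative_control"] = True
            else:
                survivors.append(
                    DoseResponseGroup.from_plate_counts(g.chemical_id, g.endpoint, keep_pc, g.flags)
                )
        entries.append(entry)
    return survivors, pd.DataFrame(entries), plates


def minimum_concentration_filter(
    groups: list[DoseResponseGroup], min_count: int = 3
) -> tuple[list[DoseResponseGroup], pd.DataFrame]:
    """Keep groups with >= min_count distinct non-zero concentrations observed."""
    survivors, entries = [], []
    for g in groups:
        n = g.n_nonzero_concentrations()
        removed = n < min_count
        if not removed:
            survivors.append(g)
        entries.append(
            {
                "chemical_id": g.chemical_id,
                "endpoint": g.endpoint,
                "n_nonzero_concentrations": n,
                "removed_by_minimum_concentration": removed,
            }
        )
    return survivors, pd.DataFrame(entries)


def correlation_filter(
    groups: list[DoseResponseGroup], threshold: float = 0.2
) -> tuple[list[DoseResponseGroup], pd.DataFrame]:
    """Keep groups whose Spearman ρ(concentration, response) >= threshold.

    Degenerate ρ (too few dose points or zero variance) removes the group
    with reason "degenerate"; ρ exactly at the threshold is kept.
    """
    survivors, entries = [], []
    for g in groups:
        rho = spearman_rho(g.concentrations, g.response)
        degenerate = np.isnan(rho)
        # small slack so a rho that is exactly the threshold up to float error is kept
        removed = degenerate or rho < threshold - 1e-12
        if not removed:
            survivors.append(g)
        entries.append(
            {
                "chemical_id": g.chemical_id,
                "endpoint": g.endpoint,
                "spearman_rho": rho,
                "removed_by_correlation": removed,
                "correlation_degenerate": degenerate,
            }
        )
    return survivors, pd.DataFrame(entries)


def _flagged(g: DoseResponseGroup, flag: str) -> DoseResponseGroup:
    if flag not in g.flags:
        g.flags.append(flag)
    return g


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------


def apply_filters(
    groups: list[DoseResponseGroup], config: FilterConfig | None = None
) -> FilterResult:
    """Run the three filters in order and build the per-group ledger.

    Each removed group is attributed to the first filter that failed it;
    conservation holds: kept + per-filter removals = input group count.
    Spearman ρ is recorded for every group (on its data as of the
    correlation stage, or its input data if removed earlier) so the
    keep/remove histogram covers the whole input.
    """
    config = config or FilterConfig()
    index = [(g.chemical_id, g.endpoint) for g in groups]
    ledger = pd.DataFrame(
        {
            "chemical_id": [k[0] for k in index],
            "endpoint": [k[1] for k in index],
            "status": "kept",
            "removing_filter": pd.Series([None] * len(index), dtype=object),
        }
    )

    def mark(entries: pd.DataFrame, col: str, name: str):
        if entries.empty:
            return
        for _, r in entries[entries[col]].iterrows():
            i = index.index((r["chemical_id"], r["endpoint"]))
            ledger.loc[i, "status"] = "removed"
            ledger.loc[i, "removing_filter"] = name

    surv, nc_entries, plates = negative_control_filter(groups, config.negative_control_threshold)
    ledger["max_plate_control_response"] = nc_entries["max_plate_control_response"].to_numpy()
    mark(nc_entries, "removed_by_negative_control", NEGATIVE_CONTROL)

    surv, mc_entries = minimum_concentration_filter(surv, config.min_nonzero_concentrations)
    ledger["n_nonzero_concentrations"] = np.nan
    for _, r in mc_entries.iterrows():
        i = index.index((r["chemical_id"], r["endpoint"]))
        ledger.loc[i, "n_nonzero_concentrations"] = r["n_nonzero_concentrations"]
    mark(mc_entries, "removed_by_minimum_concentration", MIN_CONCENTRATION)

    surv, corr_entries = correlation_filter(surv, config.correlation_threshold)
    rho_by_key = {
        (r["chemical_id"], r["endpoint"]): r["spearman_rho"] for _, r in corr_entries.iterrows()
    }
    # groups removed before the correlation stage still get a rho on their input data
    ledger["spearman_rho"] = [
        rho_by_key.get(k, spearman_rho(g.concentrations, g.response))
        for k, g in zip(index, groups)
    ]
    mark(corr_entries, "removed_by_correlation", CORRELATION)

    return FilterResult(kept=surv, ledger=ledger, plate_controls=plates, config=config)


def filter_summary(result: FilterResult, n_bins: int = 40) -> dict:
    """Removal bookkeeping plus the keep/remove ρ histogram (bin edges in [-1, 1])."""
    ledger = result.ledger
    removed = ledger[ledger["status"] == "removed"]
    per_filter = {name: int((removed["removing_filter"] == name).sum()) for name in FILTER_ORDER}
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    rho = ledger["spearman_rho"].to_numpy(float)
    kept_mask = (ledger["status"] == "kept").to_numpy()
    ok = ~np.isnan(rho)
    return {
        "input_groups": len(ledger),
        "kept_groups": int(kept_mask.sum()),
        "removed_per_filter": per_filter,
        "rho_bin_edges": edges,
        "rho_hist_keep": np.histogram(rho[ok & kept_mask], bins=edges)[0],
        "rho_hist_remove": np.histogram(rho[ok & ~kept_mask], bins=edges)[0],
        "rho_threshold": result.config.correlation_threshold,
        "plate_controls": result.plate_controls,
    }
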