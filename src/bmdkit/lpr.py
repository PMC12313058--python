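"""Larval photomotor response (LPR): continuous traces to binary endpoints.

A larva's movement is recorded over alternating light and dark phases.
Two per-well summaries are computed against the phase plan: AUC, the
dark-minus-light difference in area under the movement trace (trapezoidal
integration, summed over cycles), and MOV, the movement at the first dark
timepoint minus the movement at the last light timepoint of each cycle,
summed over cycles.  Each summary is then dichotomized per chemical
against the distribution of same-chemical control (0 µM) scores: wells
scoring outside an inclusive central percentile band of the controls are
called abnormal (1), wells inside normal (0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import CHEMICAL, CONCENTRATION, ENDPOINT, PLATE, TIME, VALUE, WELL

logger = logging.getLogger("bmdkit")

_WELL_KEY = [CHEMICAL, CONCENTRATION, PLATE, WELL]


@dataclass(frozen=True)
class CyclePlan:
    """Timing of the light/dark exposure protocol.

    cycle_length: duration of each light and each dark phase (time units).
    transition_gap: time between a phase's end and the next phase's start;
        gap timepoints belong to neither phase.
    first_phase: which phase starts at time 0.
    n_cycles: number of light+dark cycles scored.
    """

    cycle_length: float
    transition_gap: float = 0.0
    first_phase: str = "light"
    n_cycles: int = 1

    def __post_init__(self):
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be > 0")
        if self.transition_gap < 0:
            raise ValueError("transition_gap must be >= 0")
        if self.first_phase not in ("light", "dark"):
            raise ValueError("first_phase must be 'light' or 'dark'")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    @property
    def period(self) -> float:
        return 2 * (self.cycle_length + self.transition_gap)


def label_times(times: np.ndarray, plan: CyclePlan) -> tuple[np.ndarray, np.ndarray]:
    """Label each timepoint light/dark/gap/unused and assign its cycle index.

    Phases are half-open intervals: with light first, cycle c covers
    [c*P, c*P + L) light, then gap, then [c*P + L + G, c*P + 2L + G) dark,
    with P the period 2*(L+G).  Times at or beyond n_cycles periods are
    'unused'.
    """
    t = np.asarray(times, float)
    L, G, P = plan.cycle_length, plan.transition_gap, plan.period
    cycle = np.floor(t / P).astype(int)
    u = t - cycle * P
    first, second = (
        ("light", "dark") if plan.first_phase == "light" else ("dark", "light")
    )
    labels = np.where(
        u < L, first, np.where(u < L + G, "gap", np.where(u < 2 * L + G, second, "gap"))
    ).astype(object)
    labels[cycle >= plan.n_cycles] = "unused"
    return labels, cycle


def segment_cycles(lpr: pd.DataFrame, plan: CyclePlan) -> pd.DataFrame:
    """Attach phase labels and cycle indices to a canonical LPR table.

    Expects columns (chemical_id, concentration, plate_id, well, time,
    value); times per well must be strictly increasing from 0.
    """
    out = lpr.sort_values(_WELL_KEY + [TIME]).reset_index(drop=True)
    if (out[TIME] < 0).any():
        raise ValueError("negative time values in LPR table")
    steps = out.groupby(_WELL_KEY, dropna=False)[TIME].diff()
    if (steps <= 0).any():
        raise ValueError("times per well must be strictly increasing")
    labels, cycles = label_times(out[TIME].to_numpy(float), plan)
    out["phase"] = labels
    out["cycle"] = cycles
    return out


def _trapz_or_nan(values: np.ndarray, times: np.ndarray) -> float:
    if len(values) < 2 or np.isnan(values).any():
        return np.nan
    return float(np.trapezoid(values, times))


def score_well(segments: pd.DataFrame, plan: CyclePlan) -> tuple[float, float]:
    """AUC and MOV scores for one well's labeled segments.

    Per cycle: auc = trapezoid(dark) - trapezoid(light); mov = value at
    the first dark timepoint - value at the last light timepoint.  Scores
    are summed across the plan's cycles; any cycle with missing values at
    the needed timepoints, or with fewer than two samples in either
    phase, makes the corresponding score NA.
    """
    auc_total, mov_total = 0.0, 0.0
    for c in range(plan.n_cycles):
        cyc = segments[segments["cycle"] == c]
        light = cyc[cyc["phase"] == "light"]
        dark = cyc[cyc["phase"] == "dark"]
        auc_l = _trapz_or_nan(light[VALUE].to_numpy(float), light[TIME].to_numpy(float))
        auc_d = _trapz_or_nan(dark[VALUE].to_numpy(float), dark[TIME].to_numpy(float))
        auc_total += auc_d - auc_l  # NaN propagates
        if light.empty or dark.empty:
            mov_total = np.nan
        else:
            mov_total += dark.iloc[0][VALUE] - light.iloc[-1][VALUE]
    return float(auc_total), float(mov_total)


def score_wells(lpr: pd.DataFrame, plan: CyclePlan) -> pd.DataFrame:
    """Score every well; wells with traces shorter than one full cycle are NA."""
    segments = segment_cycles(lpr, plan)
    rows = []
    for key, sub in segments.groupby(_WELL_KEY, sort=True, dropna=False):
        auc, mov = score_well(sub, plan)
        if np.isnan(auc) and np.isnan(mov):
            logger.warning("well %s: trace insufficient for the cycle plan; scored NA", (key,))
        rows.append(dict(zip(_WELL_KEY, key)) | {"auc_diff": auc, "mov_diff": mov})
    return pd.DataFrame(rows)


def dichotomize_scores(
    scores: pd.DataFrame,
    min_controls: int = 10,
    lower_pct: float = 2.5,
    upper_pct: float = 97.5,
) -> pd.DataFrame:
    """Convert AUC/MOV well scores to binary endpoints against controls.

    Per chemical and metric, the reference band is the inclusive
    [lower_pct, upper_pct] percentile interval (linear interpolation) of
    that chemical's non-NA control scores; a well is abnormal (1) when its
    score falls strictly outside the band.  Chemicals with fewer than
    ``min_controls`` usable control scores have that endpoint skipped with
    a logged reason.  Returns a canonical binary long table with
    endpoints "AUC" and "MOV".
    """
    out_rows = []
    for metric, endpoint in (("auc_diff", "AUC"), ("mov_diff", "MOV")):
        for chem, sub in scores.groupby(CHEMICAL, sort=True):
            ctrl = sub.loc[sub[CONCENTRATION] == 0, metric].dropna()
            if len(ctrl) < min_controls:
                logger.warning(
                    "chemical %s endpoint %s skipped: %d non-NA control scores (< %d)",
                    chem, endpoint, len(ctrl), min_controls,
                )
                continue
            lo, hi = np.percentile(ctrl, [lower_pct, upper_pct], method="linear")
            vals = sub[metric].to_numpy(float)
            binary = np.where(np.isnan(vals), np.nan, ((vals < lo) | (vals > hi)).astype(float))
            block = sub[_WELL_KEY].copy()
            block[ENDPOINT] = endpoint
            block[VALUE] = binary
            out_rows.append(block)
    if not out_rows:
        return pd.DataFrame(columns=_WELL_KEY + [ENDPOINT, VALUE])
    return pd.concat(out_rows, ignore_index=True)
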