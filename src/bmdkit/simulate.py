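"""Synthetic plate-based screening data with known ground truth.

The generator emulates a high-throughput developmental toxicology screen:
one organism per well, plates of wells exposed to a shared concentration
series (a 0 µM negative control plus an ascending dose ladder), binary
endpoints drawn binomially from a chosen true dose-response curve.  The
default design mirrors a typical zebrafish assay unit: six
concentrations {0, 0.5, 1, 5, 10, 50} µM, 32 wells per concentration
split over two plates, a quantal-linear truth with 5% background and
slope 0.2 per µM.  An optional LPR-style trace generator produces
light/dark movement traces whose dark-phase response attenuates with
dose.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import (
    CHEMICAL, CONCENTRATION, ENDPOINT, PLATE, TIME, VALUE, WELL,
    DoseResponseGroup,
)
from .models import MODELS, response_probability

DEFAULT_DOSES = (0.0, 0.5, 1.0, 5.0, 10.0, 50.0)
DEFAULT_WELLS_PER_DOSE = 32
DEFAULT_PLATES = 2
DEFAULT_MODEL = "quantal_linear"
DEFAULT_PARAMS = (0.05, 0.2)  # background 5%, slope 0.2 per µM


@dataclass(frozen=True)
class TruthSpec:
    """Ground truth for one simulated (chemical, endpoint) group."""

    model: str = DEFAULT_MODEL
    params: tuple[float, ...] = DEFAULT_PARAMS
    doses: tuple[float, ...] = DEFAULT_DOSES
    wells_per_dose: int = DEFAULT_WELLS_PER_DOSE
    n_plates: int = DEFAULT_PLATES
    chemical_id: str = "CHEM1"
    endpoint: str = "MORT"

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {list(MODELS)}")
        response_probability(self.model, self.params, 0.0)  # validates constraints
        if self.wells_per_dose % self.n_plates:
            raise ValueError("wells_per_dose must divide evenly across plates")

    def true_probability(self, dose) -> np.ndarray | float:
        return response_probability(self.model, self.params, dose)


def simulate_wells(truth: TruthSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Per-well binary draws from the truth curve, in the canonical long layout."""
    per_plate = truth.wells_per_dose // truth.n_plates
    rows = []
    for dose in truth.doses:
        p = float(truth.true_probability(dose))
        for plate in range(1, truth.n_plates + 1):
            vals = rng.binomial(1, p, size=per_plate)
            for w, v in enumerate(vals, 1):
                rows.append(
                    {
                        CHEMICAL: truth.chemical_id,
                        CONCENTRATION: dose,
                        PLATE: f"{truth.chemical_id}-P{plate}",
                        WELL: f"W{w:02d}",
                        ENDPOINT: truth.endpoint,
                        VALUE: float(v),
                    }
                )
    return pd.DataFrame(rows)


def simulate_group(truth: TruthSpec, rng: np.random.Generator) -> DoseResponseGroup:
    """Binomial counts aggregated directly (fast path for simulation studies)."""
    per_plate = truth.wells_per_dose // truth.n_plates
    recs = []
    for dose in truth.doses:
        p = float(truth.true_probability(dose))
        for plate in range(1, truth.n_plates + 1):
            recs.append(
                {
                    CONCENTRATION: dose,
                    PLATE: f"{truth.chemical_id}-P{plate}",
                    "affected": float(rng.binomial(per_plate, p)),
                    "total": float(per_plate),
                }
            )
    return DoseResponseGroup.from_plate_counts(
        truth.chemical_id, truth.endpoint, pd.DataFrame(recs)
    )


@dataclass(frozen=True)
class LPRTruthSpec:
    """Light/dark movement traces whose dark response shrinks with dose.

    Healthy larvae move little in light and burst in darkness; exposure
    attenuates the dark burst.  ``attenuation_ec`` is the concentration
    halving the dark response.
    """

    chemical_id: str = "CHEM1"
    doses: tuple[float, ...] = DEFAULT_DOSES
    wells_per_dose: int = 32
    n_plates: int = DEFAULT_PLATES
    cycle_length: float = 3.0
    transition_gap: float = 0.0
    n_cycles: int = 2
    samples_per_phase: int = 6
    light_level: float = 1.0
    dark_level: float = 5.0
    noise_sd: float = 0.3
    attenuation_ec: float = 10.0


def simulate_lpr(truth: LPRTruthSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Canonical long LPR table (chemical, concentration, plate, well, time, value)."""
    from .lpr import CyclePlan, label_times

    plan = CyclePlan(truth.cycle_length, truth.transition_gap, "light", truth.n_cycles)
    dt = truth.cycle_length / truth.samples_per_phase
    times = np.arange(0.0, plan.period * truth.n_cycles, dt)
    labels, _ = label_times(times, plan)
    per_plate = truth.wells_per_dose // truth.n_plates
    rows = []
    for dose in truth.doses:
        dark_mean = truth.light_level + (truth.dark_level - truth.light_level) / (
            1.0 + dose / truth.attenuation_ec
        )
        for plate in range(1, truth.n_plates + 1):
            for w in range(1, per_plate + 1):
                mean = np.where(labels == "dark", dark_mean, truth.light_level)
                vals = np.clip(mean + rng.normal(0, truth.noise_sd, size=times.shape), 0, None)
                for t, v in zip(times, vals):
                    rows.append(
                        {
                            CHEMICAL: truth.chemical_id,
                            CONCENTRATION: dose,
                            PLATE: f"{truth.chemical_id}-P{plate}",
                            WELL: f"W{w:02d}",
                            TIME: t,
                            VALUE: float(v),
                        }
                    )
    return pd.DataFrame(rows)


def generate_fixture(
    out_dir: str | Path,
    truths: list[TruthSpec] | None = None,
    seed: int = 7,
    layout: str = "long",
    lpr_truths: list[LPRTruthSpec] | None = None,
) -> dict[str, Path]:
    """Write synthetic CSV fixtures plus a ground-truth sidecar JSON.

    Returns the paths written: ``binary.csv`` (and ``lpr.csv`` when LPR
    truths are given) and ``truth.json`` describing every generating
    parameter, so recovery tests can compare estimates to the truth.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    truths = truths if truths is not None else [TruthSpec()]
    paths: dict[str, Path] = {}
    if truths:
        binary = pd.concat([simulate_wells(t, rng) for t in truths], ignore_index=True)
        if layout == "wide":
            from .core_data import widen

            binary = widen(binary)
        elif layout != "long":
            raise ValueError("layout must be 'long' or 'wide'")
        paths["binary"] = out_dir / "binary.csv"
        binary.to_csv(paths["binary"], index=False)

    if lpr_truths:
        lpr = pd.concat([simulate_lpr(t, rng) for t in lpr_truths], ignore_index=True)
        paths["lpr"] = out_dir / "lpr.csv"
        lpr.to_csv(paths["lpr"], index=False)

    sidecar = {
        "seed": seed,
        "layout": layout,
        "groups": [
            {
                "chemical_id": t.chemical_id,
                "endpoint": t.endpoint,
                "model": t.model,
                "params": list(t.params),
                "doses": list(t.doses),
                "wells_per_dose": t.wells_per_dose,
                "n_plates": t.n_plates,
            }
            for t in truths
        ],
        "lpr_groups": [
            {"chemical_id": t.chemical_id, "doses": list(t.doses)} for t in (lpr_truths or [])
        ],
    }
    paths["truth"] = out_dir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return paths


def default_study(
    n_active: int = 12,
    n_flat: int = 4,
    n_sparse: int = 2,
    n_high_control: int = 2,
    seed: int = 7,
) -> tuple[list[TruthSpec], pd.DataFrame]:
    """A mixed synthetic study exercising every filter and fit status.

    Active chemicals follow varied model truths; flat chemicals have no
    concentration effect (background only); sparse chemicals carry too
    few non-zero concentrations; high-control chemicals get one plate
    whose 0 µM response is forced above the negative-control threshold.
    Returns (truth specs, canonical binary long table).
    """
    rng = np.random.default_rng(seed)
    active_cycle = [
        ("quantal_linear", (0.05, 0.2)),
        ("weibull", (0.05, 1.5, 0.02)),
        ("log_logistic", (0.05, -3.0, 1.5)),
        ("logistic", (-3.0, 0.15)),
    ]
    truths: list[TruthSpec] = []
    for i in range(n_active):
        model, params = active_cycle[i % len(active_cycle)]
        truths.append(TruthSpec(model=model, params=params, chemical_id=f"ACT{i + 1:02d}"))
    for i in range(n_flat):
        truths.append(
            TruthSpec(model="quantal_linear", params=(0.05, 0.0), chemical_id=f"FLAT{i + 1:02d}")
        )
    for i in range(n_sparse):
        truths.append(
            TruthSpec(
                model="quantal_linear", params=(0.05, 0.2), doses=(0.0, 1.0, 10.0),
                chemical_id=f"SPARSE{i + 1:02d}",
            )
        )
    tables = [simulate_wells(t, rng) for t in truths]
    for i in range(n_high_control):
        t = TruthSpec(model="quantal_linear", params=(0.05, 0.2), chemical_id=f"HICTL{i + 1:02d}")
        truths.append(t)
        tbl = simulate_wells(t, rng)
        # force one plate's control wells to 75% response
        plate = f"{t.chemical_id}-P1"
        mask = (tbl[PLATE] == plate) & (tbl[CONCENTRATION] == 0)
        idx = tbl.index[mask]
        vals = np.zeros(len(idx))
        vals[: int(round(0.75 * len(idx)))] = 1.0
        tbl.loc[idx, VALUE] = vals
        tables.append(tbl)
    return truths, pd.concat(tables, ignore_index=True)
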