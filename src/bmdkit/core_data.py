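"""Ingestion, validation and reshaping of dichotomous screening data.

Three kinds of input are supported: per-well binary (0/1/NA) phenotype
observations in long or wide layout, pre-computed proportional responses,
and continuous larval photomotor response traces (handled in
:mod:`bmdkit.lpr` after ingestion here).  Binary observations are
aggregated per (chemical, endpoint) into dose-response groups of
affected/total counts, the unit everything downstream operates on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("bmdkit")

#: canonical column names used internally for all tables
CHEMICAL, CONCENTRATION, PLATE, WELL, ENDPOINT, VALUE, TIME = (
    "chemical_id",
    "concentration",
    "plate_id",
    "well",
    "endpoint",
    "value",
    "time",
)


class SchemaError(ValueError):
    """A required column/role is missing or mapped inconsistently."""


class DataValidationError(ValueError):
    """Cell-level contents violate the data-type contract."""


# --------------------------------------------------------------------------
# column mapping
# --------------------------------------------------------------------------

#: roles required for each data type; wide binary infers endpoint/value by melting
_REQUIRED_ROLES = {
    ("binary", "long"): ("chemical", "concentration", "plate", "well", "endpoint", "value"),
    ("binary", "wide"): ("chemical", "concentration", "plate", "well"),
    ("proportional", "long"): ("chemical", "concentration", "endpoint", "value"),
    ("lpr", "long"): ("chemical", "concentration", "plate", "well", "time", "value"),
}


@dataclass(frozen=True)
class ColumnMapping:
    """Maps the caller's column names onto the roles the pipeline needs.

    Only the roles a data type requires have to be supplied: binary data
    needs everything but ``time``; proportional data needs no plate/well;
    LPR traces need ``time`` but no ``endpoint``.
    """

    chemical: str
    concentration: str
    plate: str | None = None
    well: str | None = None
    endpoint: str | None = None
    value: str | None = None
    time: str | None = None

    def role_items(self) -> dict[str, str]:
        return {
            role: name
            for role, name in (
                ("chemical", self.chemical),
                ("concentration", self.concentration),
                ("plate", self.plate),
                ("well", self.well),
                ("endpoint", self.endpoint),
                ("value", self.value),
                ("time", self.time),
            )
            if name is not None
        }

    def validate(self, columns: Iterable[str], data_type: str, layout: str = "long") -> None:
        key = (data_type, layout)
        if key not in _REQUIRED_ROLES:
            raise SchemaError(f"unknown data type/layout combination: {data_type}/{layout}")
        provided = self.role_items()
        required = _REQUIRED_ROLES[key]
        for role in required:
            if role not in provided:
                raise SchemaError(f"{data_type} ({layout}) data requires a column for role '{role}'")
        columns = set(columns)
        # only the roles this data type/layout uses must resolve to real columns
        used = {role: provided[role] for role in required}
        for role, name in used.items():
            if name not in columns:
                raise SchemaError(f"mapped column '{name}' (role '{role}') not found in table")
        names = list(used.values())
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"column(s) mapped to more than one role: {dupes}")


# --------------------------------------------------------------------------
# value coercion
# --------------------------------------------------------------------------

_NA_STRINGS = {"", "na", "nan", "none", "null"}


def _coerce_binary_series(s: pd.Series) -> tuple[pd.Series, np.ndarray]:
    """Coerce a raw column to float {0.0, 1.0, NaN}.

    Returns (coerced, bad_index_positions).  Accepts numeric 0/1 (any
    float/int dtype) and the strings "0"/"1" (plus decimal spellings);
    empty strings and NA spellings become NaN.
    """
    raw = s.copy()
    as_str = raw.astype("string").str.strip().str.lower()
    is_na = raw.isna() | as_str.isin(_NA_STRINGS)
    numeric = pd.to_numeric(raw.where(~is_na), errors="coerce")
    ok = is_na | numeric.isin([0, 1])
    coerced = numeric.where(~is_na).astype(float)
    return coerced, np.flatnonzero(~ok.to_numpy())


def _parse_concentration(s: pd.Series) -> pd.Series:
    conc = pd.to_numeric(s, errors="coerce")
    bad = conc.isna() & s.notna()
    if bad.any():
        raise DataValidationError(
            f"non-numeric concentration at row(s) {list(np.flatnonzero(bad.to_numpy())[:5])}"
        )
    if conc.isna().any():
        raise DataValidationError("missing concentration values are not allowed")
    if (conc < 0).any():
        rows = list(np.flatnonzero((conc < 0).to_numpy())[:5])
        raise DataValidationError(f"negative concentration at row(s) {rows}")
    return conc.astype(float)


# --------------------------------------------------------------------------
# ingestion
# --------------------------------------------------------------------------

_KEY_COLS = [CHEMICAL, CONCENTRATION, PLATE, WELL, ENDPOINT]


def ingest_binary(raw: pd.DataFrame, mapping: ColumnMapping, layout: str = "long") -> pd.DataFrame:
    """Ingest per-well binary phenotype data into the canonical long table.

    In wide layout every column not mapped to chemical/concentration/plate/
    well is treated as one phenotype (endpoint); columns whose values are
    not coercible to {0, 1, NA} are reported as an error rather than
    silently dropped, since they signal an upload mistake.

    Returns a DataFrame with columns (chemical_id, concentration, plate_id,
    well, endpoint, value), value in {0.0, 1.0, NaN}, and unique keys.
    """
    if layout not in ("long", "wide"):
        raise SchemaError(f"layout must be 'long' or 'wide', got {layout!r}")
    mapping.validate(raw.columns, "binary", layout)

    if layout == "wide":
        id_raw = [mapping.chemical, mapping.concentration, mapping.plate, mapping.well]
        endpoint_cols = [c for c in raw.columns if c not in id_raw]
        if not endpoint_cols:
            raise SchemaError("wide table has no endpoint columns beyond the mapped identifiers")
        bad_cols = []
        for c in endpoint_cols:
            _, bad = _coerce_binary_series(raw[c])
            if bad.size:
                bad_cols.append(c)
        if bad_cols:
            raise DataValidationError(
                "wide-layout column(s) with values outside {0, 1, NA} "
                f"(remove non-phenotype columns before ingesting): {bad_cols}"
            )
        long = raw.melt(
            id_vars=id_raw, value_vars=endpoint_cols, var_name=ENDPOINT, value_name=VALUE
        )
        mapping = replace(mapping, endpoint=ENDPOINT, value=VALUE)
        raw = long

    out = pd.DataFrame(
        {
            CHEMICAL: raw[mapping.chemical].to_numpy(),
            CONCENTRATION: _parse_concentration(raw[mapping.concentration]).to_numpy(),
            PLATE: raw[mapping.plate].to_numpy(),
            WELL: raw[mapping.well].to_numpy(),
            ENDPOINT: raw[mapping.endpoint].to_numpy(),
        }
    )
    coerced, bad = _coerce_binary_series(raw[mapping.value])
    if bad.size:
        raise DataValidationError(
            f"value outside {{0, 1, NA}} at row(s) {list(bad[:10])} of the value column"
        )
    out[VALUE] = coerced.to_numpy()

    dup = out.duplicated(subset=_KEY_COLS, keep=False)
    if dup.any():
        keys = out.loc[dup, _KEY_COLS].drop_duplicates().head(5).to_dict("records")
        raise DataValidationError(
            f"duplicate (chemical, concentration, plate, well, endpoint) rows, e.g. {keys}"
        )
    return out.reset_index(drop=True)


def ingest_proportion(raw: pd.DataFrame, mapping: ColumnMapping) -> pd.DataFrame:
    """Ingest pre-computed proportional responses.

    Output columns: chemical_id, concentration, endpoint, response and —
    when 'affected'/'total' columns are present in the input — the counts,
    validated for consistency (response == affected/total).  Rows with NA
    response are preserved and flagged in the ``is_na`` column.
    """
    mapping.validate(raw.columns, "proportional")
    out = pd.DataFrame(
        {
            CHEMICAL: raw[mapping.chemical].to_numpy(),
            CONCENTRATION: _parse_concentration(raw[mapping.concentration]).to_numpy(),
            ENDPOINT: raw[mapping.endpoint].to_numpy(),
            "response": pd.to_numeric(raw[mapping.value], errors="coerce").to_numpy(),
        }
    )
    out["is_na"] = out["response"].isna() | raw[mapping.value].isna().to_numpy()
    bad = (~out["is_na"]) & ((out["response"] < 0) | (out["response"] > 1))
    if bad.any():
        rows = list(np.flatnonzero(bad.to_numpy())[:5])
        raise DataValidationError(f"response outside [0, 1] at row(s) {rows}")

    if "affected" in raw.columns and "total" in raw.columns:
        affected = pd.to_numeric(raw["affected"], errors="coerce")
        total = pd.to_numeric(raw["total"], errors="coerce")
        if ((affected < 0) | (affected > total)).any():
            raise DataValidationError("affected counts must satisfy 0 <= affected <= total")
        with np.errstate(invalid="ignore", divide="ignore"):
            implied = affected / total
        mism = (~out["is_na"]) & total.notna() & (np.abs(implied - out["response"]) > 1e-9)
        if mism.any():
            rows = list(np.flatnonzero(mism.to_numpy())[:5])
            raise DataValidationError(f"response != affected/total at row(s) {rows}")
        out["affected"] = affected.to_numpy()
        out["total"] = total.to_numpy()
    return out.reset_index(drop=True)


# --------------------------------------------------------------------------
# dose-response groups
# --------------------------------------------------------------------------


@dataclass
class DoseResponseGroup:
    """One (chemical, endpoint) unit of affected/total counts per dose.

    ``doses`` holds the pooled counts (one row per distinct concentration,
    ascending); ``plate_counts`` holds the plate-resolved sub-counts when
    the input carried plate information, else None.
    """

    chemical_id: object
    endpoint: str
    doses: pd.DataFrame  # columns: concentration, affected, total
    plate_counts: pd.DataFrame | None = None  # + plate_id column
    flags: list[str] = field(default_factory=list)

    @property
    def key(self) -> tuple:
        return (self.chemical_id, self.endpoint)

    @property
    def response(self) -> np.ndarray:
        return self.doses["affected"].to_numpy(float) / self.doses["total"].to_numpy(float)

    @property
    def concentrations(self) -> np.ndarray:
        return self.doses[CONCENTRATION].to_numpy(float)

    def control_response(self) -> float:
        """Pooled response at concentration 0, NaN when absent."""
        at0 = self.doses[self.doses[CONCENTRATION] == 0]
        if at0.empty or at0["total"].sum() == 0:
            return float("nan")
        return float(at0["affected"].sum() / at0["total"].sum())

    def n_nonzero_concentrations(self) -> int:
        d = self.doses
        return int(((d[CONCENTRATION] > 0) & (d["total"] > 0)).sum())

    @classmethod
    def from_plate_counts(
        cls, chemical_id, endpoint, plate_counts: pd.DataFrame, flags: Sequence[str] = ()
    ) -> "DoseResponseGroup":
        pc = plate_counts[plate_counts["total"] > 0].reset_index(drop=True)
        pooled = (
            pc.groupby(CONCENTRATION, as_index=False)[["affected", "total"]]
            .sum()
            .sort_values(CONCENTRATION)
            .reset_index(drop=True)
        )
        return cls(chemical_id, endpoint, pooled, pc, list(flags))


def aggregate_to_groups(binary: pd.DataFrame) -> list[DoseResponseGroup]:
    """Aggregate a canonical binary long table to dose-response groups.

    Per (chemical, endpoint, concentration, plate): affected = number of
    wells with value 1, total = number of non-NA wells; NA wells count in
    neither.  Concentrations (or whole groups) left without any observed
    well are dropped, the latter with a logged warning.
    """
    counts = (
        binary.groupby([CHEMICAL, ENDPOINT, CONCENTRATION, PLATE], sort=True, dropna=False)[VALUE]
        .agg(affected=lambda v: float((v == 1).sum()), total="count")
        .reset_index()
    )
    groups: list[DoseResponseGroup] = []
    for (chem, ep), sub in counts.groupby([CHEMICAL, ENDPOINT], sort=True):
        sub = sub[sub["total"] > 0]
        if sub.empty:
            logger.warning("group (%s, %s) has no observed wells at any concentration; dropped", chem, ep)
            warnings.warn(f"group ({chem}, {ep}) dropped: all wells NA", stacklevel=2)
            continue
        pc = sub[[CONCENTRATION, PLATE, "affected", "total"]].reset_index(drop=True)
        groups.append(DoseResponseGroup.from_plate_counts(chem, ep, pc))
    return groups


def proportions_to_groups(ptable: pd.DataFrame) -> list[DoseResponseGroup]:
    """Build groups from a proportional table (no plate resolution).

    When affected/total counts are present they are used directly; plain
    proportions are carried with a unit total per row, which keeps the
    binomial likelihood well defined but weights every row equally (the
    group is flagged ``unit_totals``).
    """
    groups = []
    has_counts = "affected" in ptable.columns and "total" in ptable.columns
    for (chem, ep), sub in ptable.groupby([CHEMICAL, ENDPOINT], sort=True):
        sub = sub[~sub["is_na"]]
        if sub.empty:
            continue
        flags = []
        if has_counts and sub["total"].notna().all():
            agg = sub.groupby(CONCENTRATION, as_index=False)[["affected", "total"]].sum()
        else:
            flags.append("unit_totals")
            tmp = sub.assign(affected=sub["response"], total=1.0)
            agg = tmp.groupby(CONCENTRATION, as_index=False)[["affected", "total"]].sum()
        agg = agg.sort_values(CONCENTRATION).reset_index(drop=True)
        groups.append(DoseResponseGroup(chem, ep, agg, None, flags))
    return groups


def widen(binary: pd.DataFrame) -> pd.DataFrame:
    """Pivot a canonical long binary table to wide layout (round-trip aid)."""
    wide = binary.pivot_table(
        index=[CHEMICAL, CONCENTRATION, PLATE, WELL],
        columns=ENDPOINT,
        values=VALUE,
        aggfunc="first",
        dropna=False,
    ).reset_index()
    wide.columns.name = None
    return wide
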