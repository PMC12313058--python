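"""Endpoint algebra applied to the binary long table before aggregation.

Three operations: OR-combination of endpoints into a new aggregate
phenotype (e.g. a "head" endpoint from cranium and jaw abnormalities),
removal of endpoints from model consideration, and invalidation of
specific wells (all their endpoint values set to NA), either by explicit
(plate, well) selectors or via a marker endpoint such as "do not count".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_data import CHEMICAL, CONCENTRATION, ENDPOINT, PLATE, VALUE, WELL

_WELL_KEY = [CHEMICAL, CONCENTRATION, PLATE, WELL]


@dataclass(frozen=True)
class EndpointCombination:
    new_name: str
    sources: tuple[str, ...]

    def __post_init__(self):
        if not self.sources:
            raise ValueError("combination needs at least one source endpoint")


def combine_endpoints(table: pd.DataFrame, combo: EndpointCombination) -> pd.DataFrame:
    """Add an inclusive-OR aggregate endpoint over the source endpoints.

    Per well the new value is 1 if any source is 1, 0 if all non-NA
    sources are 0, NA if every source is NA.  Source endpoint rows are
    left untouched; exactly one new row is added per well that has at
    least one source observation.
    """
    present = set(table[ENDPOINT].unique())
    if combo.new_name in present:
        raise ValueError(f"endpoint {combo.new_name!r} already exists")
    missing = [s for s in combo.sources if s not in present]
    if missing:
        raise ValueError(f"source endpoint(s) not in data: {missing}")

    src = table[table[ENDPOINT].isin(combo.sources)]
    agg = src.groupby(_WELL_KEY, sort=False, dropna=False)[VALUE].agg(
        any_one=lambda v: (v == 1).any(), any_obs="count"
    )
    value = np.where(agg["any_one"], 1.0, np.where(agg["any_obs"] > 0, 0.0, np.nan))
    new_rows = agg.reset_index()[_WELL_KEY]
    new_rows[ENDPOINT] = combo.new_name
    new_rows[VALUE] = value
    return pd.concat([table, new_rows[table.columns]], ignore_index=True)


def remove_endpoints(table: pd.DataFrame, names: Iterable[str]) -> pd.DataFrame:
    """Drop all rows of the named endpoints (e.g. after combining them)."""
    names = list(names)
    if not names:
        return table.copy()
    known = set(table[ENDPOINT].unique())
    unknown = [n for n in names if n not in known]
    if unknown:
        raise ValueError(f"unknown endpoint(s) {unknown}; known endpoints: {sorted(map(str, known))}")
    out = table[~table[ENDPOINT].isin(names)].reset_index(drop=True)
    if out.empty:
        warnings.warn("all endpoints removed; table is empty", stacklevel=2)
    return out


def invalidate_wells(
    table: pd.DataFrame,
    wells: Sequence[tuple[object, object]] | None = None,
    marker_endpoint: str | None = None,
) -> pd.DataFrame:
    """Set every endpoint value of the selected wells to NA.

    Selection is either an explicit list of (plate_id, well) pairs or a
    marker endpoint: wells where the marker is 1 are invalidated (the
    marker rows included — remove the marker endpoint afterwards to keep
    it out of modeling).  A selector matching no wells warns but does not
    raise, since an empty exclusion list is a no-op, not a mistake.
    """
    if (wells is None) == (marker_endpoint is None):
        raise ValueError("provide exactly one of wells= or marker_endpoint=")
    out = table.copy()
    if marker_endpoint is not None:
        if marker_endpoint not in set(table[ENDPOINT].unique()):
            raise ValueError(f"marker endpoint {marker_endpoint!r} not present")
        hits = table[(table[ENDPOINT] == marker_endpoint) & (table[VALUE] == 1)]
        keys = set(map(tuple, hits[[CHEMICAL, PLATE, WELL]].to_numpy()))
        mask = pd.Series(
            [k in keys for k in map(tuple, out[[CHEMICAL, PLATE, WELL]].to_numpy())],
            index=out.index,
        )
    else:
        keys = set((str(p), str(w)) for p, w in wells)
        mask = pd.Series(
            [(str(p), str(w)) in keys for p, w in zip(out[PLATE], out[WELL])], index=out.index
        )
    if not mask.any():
        warnings.warn("well invalidation selector matched no wells", stacklevel=2)
        return out
    out.loc[mask, VALUE] = np.nan
    return out
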