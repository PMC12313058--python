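import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bmdkit.core_data import (
    ColumnMapping,
    DataValidationError,
    SchemaError,
    aggregate_to_groups,
    ingest_binary,
    ingest_proportion,
    proportions_to_groups,
    widen,
)

from conftest import group_from_counts  # noqa: F401  (helper import)


class TestIngestBinary:
    def test_wide_row_melts_to_one_row_per_endpoint(self, mapping):
        wide = pd.DataFrame(
            [{"chemical.id": "C1", "conc": 1.0, "plate.id": "P1", "well": "A1", "MORT": 1, "YSE": 0}]
        )
        long = ingest_binary(wide, mapping, layout="wide")
        assert len(long) == 2
        assert set(long["endpoint"]) == {"MORT", "YSE"}
        assert long.set_index("endpoint")["value"].to_dict() == {"MORT": 1.0, "YSE": 0.0}

    def test_long_ingest_is_idempotent(self, long_binary_raw, mapping):
        once = ingest_binary(long_binary_raw, mapping, layout="long")
        again = ingest_binary(
            once.rename(
                columns={"chemical_id": "chemical.id", "concentration": "conc", "plate_id": "plate.id"}
            ),
            mapping,
            layout="long",
        )
        pd.testing.assert_frame_equal(once, again)

    def test_wide_non_binary_column_is_an_error_not_dropped(self, mapping):
        wide = pd.DataFrame(
            [{"chemical.id": "C1", "conc": 1.0, "plate.id": "P1", "well": "A1", "MORT": 2, "YSE": 0}]
        )
        with pytest.raises(DataValidationError, match="MORT"):
            ingest_binary(wide, mapping, layout="wide")

    def test_long_bad_value_names_row(self, long_binary_raw, mapping):
        bad = long_binary_raw.copy()
        bad.loc[3, "value"] = 7
        with pytest.raises(DataValidationError, match=r"\b3\b"):
            ingest_binary(bad, mapping, layout="long")

    @pytest.mark.parametrize(
        "raw,expected",
        [("0", 0.0), ("1", 1.0), (0, 0.0), (1, 1.0), ("", np.nan), ("NA", np.nan), ("NaN", np.nan)],
    )
    def test_value_coercion_dialects(self, mapping, raw, expected):
        df = pd.DataFrame(
            [{"chemical.id": "C1", "conc": 1.0, "plate.id": "P1", "well": "A1",
              "endpoint": "MORT", "value": raw}]
        )
        got = ingest_binary(df, mapping)["value"].iloc[0]
        assert got == expected or (np.isnan(expected) and np.isnan(got))

    def test_duplicate_key_rows_are_a_hard_error(self, long_binary_raw, mapping):
        dup = pd.concat([long_binary_raw, long_binary_raw.iloc[[5]]], ignore_index=True)
        with pytest.raises(DataValidationError, match="duplicate"):
            ingest_binary(dup, mapping)

    def test_missing_required_column_names_the_role(self, long_binary_raw, mapping):
        with pytest.raises(SchemaError, match="plate"):
            ingest_binary(long_binary_raw.drop(columns=["plate.id"]), mapping)

    def test_negative_concentration_rejected(self, long_binary_raw, mapping):
        bad = long_binary_raw.copy()
        bad.loc[0, "conc"] = -1.0
        with pytest.raises(DataValidationError, match="negative"):
            ingest_binary(bad, mapping)


class TestIngestProportion:
    def _map(self):
        return ColumnMapping(chemical="chem", concentration="conc", endpoint="ep", value="resp")

    def test_control_row_accepted(self):
        df = pd.DataFrame([{"chem": "C1", "conc": 0.0, "ep": "MORT", "resp": 0.0}])
        out = ingest_proportion(df, self._map())
        assert out["response"].iloc[0] == 0.0 and not out["is_na"].iloc[0]

    def test_response_above_one_rejected(self):
        df = pd.DataFrame([{"chem": "C1", "conc": 10.0, "ep": "MORT", "resp": 1.2}])
        with pytest.raises(DataValidationError, match=r"\[0, 1\]"):
            ingest_proportion(df, self._map())

    def test_consistent_counts_accepted(self):
        df = pd.DataFrame(
            [{"chem": "C1", "conc": 10.0, "ep": "MORT", "resp": 0.25, "affected": 2, "total": 8}]
        )
        out = ingest_proportion(df, self._map())
        assert out["affected"].iloc[0] == 2 and out["total"].iloc[0] == 8

    def test_inconsistent_counts_rejected(self):
        df = pd.DataFrame(
            [{"chem": "C1", "conc": 10.0, "ep": "MORT", "resp": 0.5, "affected": 2, "total": 8}]
        )
        with pytest.raises(DataValidationError, match="affected/total"):
            ingest_proportion(df, self._map())

    def test_na_rows_preserved_and_flagged(self):
        df = pd.DataFrame(
            [
                {"chem": "C1", "conc": 0.0, "ep": "MORT", "resp": 0.1},
                {"chem": "C1", "conc": 1.0, "ep": "MORT", "resp": None},
            ]
        )
        out = ingest_proportion(df, self._map())
        assert len(out) == 2 and out["is_na"].tolist() == [False, True]

    def test_counts_flow_into_groups(self):
        df = pd.DataFrame(
            [
                {"chem": "C1", "conc": c, "ep": "MORT", "resp": a / 8, "affected": a, "total": 8}
                for c, a in [(0.0, 0), (1.0, 2), (10.0, 6)]
            ]
        )
        groups = proportions_to_groups(ingest_proportion(df, self._map()))
        assert len(groups) == 1
        assert groups[0].doses["total"].tolist() == [8.0, 8.0, 8.0]
        assert groups[0].plate_counts is None


class TestAggregation:
    def _table(self, wells):
        return pd.DataFrame(
            [
                {"chemical_id": "C1", "concentration": 1.0, "plate_id": "P1",
                 "well": f"A{i}", "endpoint": "MORT", "value": v}
                for i, v in enumerate(wells)
            ]
        )

    def test_na_wells_leave_numerator_and_denominator(self):
        groups = aggregate_to_groups(self._table([1.0, 0.0, np.nan]))
        d = groups[0].doses
        assert d["affected"].iloc[0] == 1 and d["total"].iloc[0] == 2
        assert groups[0].response[0] == 0.5

    def test_all_na_concentration_absent(self):
        t = pd.concat(
            [self._table([np.nan, np.nan]), self._table([1.0, 0.0]).assign(concentration=2.0)],
            ignore_index=True,
        )
        t["well"] = [f"A{i}" for i in range(len(t))]
        groups = aggregate_to_groups(t)
        assert groups[0].concentrations.tolist() == [2.0]

    def test_plates_pool_additively(self):
        rows = []
        for plate, affected in (("P1", 1), ("P2", 3)):
            for i in range(4):
                rows.append(
                    {"chemical_id": "C1", "concentration": 1.0, "plate_id": plate,
                     "well": f"A{i}", "endpoint": "MORT", "value": float(i < affected)}
                )
        g = aggregate_to_groups(pd.DataFrame(rows))[0]
        assert g.doses["affected"].iloc[0] == 4 and g.doses["total"].iloc[0] == 8
        plate_resp = (g.plate_counts["affected"] / g.plate_counts["total"]).tolist()
        assert sorted(plate_resp) == [0.25, 0.75]

    def test_group_with_no_observed_wells_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped"):
            groups = aggregate_to_groups(self._table([np.nan, np.nan]))
        assert groups == []

    def test_pooled_response_within_plate_range(self, long_binary_raw, mapping):
        binary = ingest_binary(long_binary_raw, mapping)
        for g in aggregate_to_groups(binary):
            pr = g.plate_counts.assign(r=g.plate_counts["affected"] / g.plate_counts["total"])
            for _, row in g.doses.iterrows():
                mine = pr[pr["concentration"] == row["concentration"]]["r"]
                pooled = row["affected"] / row["total"]
                assert mine.min() - 1e-12 <= pooled <= mine.max() + 1e-12


@settings(max_examples=25, deadline=None)
@given(
    st.integers(1, 3),  # number of concentrations
    st.integers(1, 3),  # wells per concentration
    st.integers(1, 2),  # number of endpoints
    st.integers(0, 2**31 - 1),
)
def test_widen_ingest_round_trip(n_conc, n_well, n_ep, seed):
    """Widening a complete long table and re-ingesting reproduces the row multiset."""
    rng = np.random.default_rng(seed)
    long = pd.DataFrame(
        [
            {"chemical_id": "C1", "concentration": float(c), "plate_id": "P1",
             "well": f"W{w}", "endpoint": f"EP{e}",
             "value": rng.choice([0.0, 1.0, np.nan])}
            for c in range(n_conc)
            for w in range(n_well)
            for e in range(n_ep)
        ]
    )
    m = ColumnMapping(chemical="chemical_id", concentration="concentration",
                      plate="plate_id", well="well")
    back = ingest_binary(widen(long), m, layout="wide")
    key = ["chemical_id", "concentration", "plate_id", "well", "endpoint"]
    orig = long.sort_values(key).reset_index(drop=True)
    back = back.sort_values(key).reset_index(drop=True)
    pd.testing.assert_frame_equal(orig[key + ["value"]], back[key + ["value"]])


def test_aggregation_conserves_well_counts(long_binary_raw, mapping):
    binary = ingest_binary(long_binary_raw, mapping)
    groups = aggregate_to_groups(binary)
    for g in groups:
        sub = binary[(binary["chemical_id"] == g.chemical_id) & (binary["endpoint"] == g.endpoint)]
        n_na = sub["value"].isna().sum()
        affected = g.doses["affected"].sum()
        unaffected = (g.doses["total"] - g.doses["affected"]).sum()
        assert affected + unaffected + n_na == len(sub)
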