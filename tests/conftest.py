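import numpy as np
import pandas as pd
import pytest

from bmdkit.core_data import ColumnMapping, DoseResponseGroup


@pytest.fixture
def mapping():
    """Table-1-style column names mapped onto the canonical roles."""
    return ColumnMapping(
        chemical="chemical.id",
        concentration="conc",
        plate="plate.id",
        well="well",
        endpoint="endpoint",
        value="value",
    )


@pytest.fixture
def long_binary_raw():
    """Two chemicals x two endpoints, two plates, with one NA well."""
    rows = []
    for chem in ("C1", "C2"):
        for conc in (0.0, 1.0, 10.0):
            for plate in ("P1", "P2"):
                for well in ("A1", "A2"):
                    for ep in ("MORT", "YSE"):
                        rows.append(
                            {
                                "chemical.id": chem,
                                "conc": conc,
                                "plate.id": f"{chem}-{plate}",
                                "well": well,
                                "endpoint": ep,
                                "value": 1 if (conc == 10.0 and well == "A1") else 0,
                            }
                        )
    df = pd.DataFrame(rows)
    df["value"] = df["value"].astype(object)
    df.loc[0, "value"] = "NA"
    return df


def group_from_counts(conc, affected, total, chem="C1", ep="MORT"):
    """Pooled-only dose-response group straight from count vectors."""
    df = (
        pd.DataFrame(
            {
                "concentration": np.asarray(conc, float),
                "affected": np.asarray(affected, float),
                "total": np.asarray(total, float),
            }
        )
        .sort_values("concentration")
        .reset_index(drop=True)
    )
    return DoseResponseGroup(chem, ep, df)


def group_from_plates(records, chem="C1", ep="MORT"):
    """Group from (concentration, plate_id, affected, total) tuples."""
    pc = pd.DataFrame(records, columns=["concentration", "plate_id", "affected", "total"])
    return DoseResponseGroup.from_plate_counts(chem, ep, pc)


@pytest.fixture
def counts_group():
    return group_from_counts([0, 0.5, 1, 5, 10, 50], [2, 4, 6, 14, 24, 31], [32] * 6)
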