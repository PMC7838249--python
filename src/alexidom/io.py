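"""CSV interchange for item-level and scored cohort tables.

The item-level layout is one participant per row with columns::

    id,group,age,sex,piq,viq,aq_01..aq_50,tas_01..tas_20,bdi_01..bdi_21

Missing item responses are empty fields in the CSV and ``NaN`` in the
DataFrame — never a sentinel code. ``sex`` is ``male``/``female``;
``group`` is the diagnostic label (``ASD+`` / ``ASD-`` by default).

Scored tables add ``aq,dif,ddf,eot,tas_total,bdi`` plus flag/band and
eligibility columns (see :mod:`alexidom.scoring`).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .keys import AQ_N_ITEMS, BDI_N_ITEMS, TAS_N_ITEMS

AQ_COLS = [f"aq_{i:02d}" for i in range(1, AQ_N_ITEMS + 1)]
TAS_COLS = [f"tas_{i:02d}" for i in range(1, TAS_N_ITEMS + 1)]
BDI_COLS = [f"bdi_{i:02d}" for i in range(1, BDI_N_ITEMS + 1)]
DEMO_COLS = ["id", "group", "age", "sex", "piq", "viq"]
ITEM_TABLE_COLS = DEMO_COLS + AQ_COLS + TAS_COLS + BDI_COLS

_ITEM_RANGES = {"aq": (1, 4), "tas": (1, 5), "bdi": (0, 3)}


def item_columns(instrument: str) -> list[str]:
    """Column names for one instrument (``aq`` | ``tas`` | ``bdi``)."""
    return {"aq": AQ_COLS, "tas": TAS_COLS, "bdi": BDI_COLS}[instrument]


def validate_item_table(table: pd.DataFrame) -> None:
    """Check schema and response ranges of an item-level table.

    Raises ``ValueError`` naming the offending columns. Missing cells
    (NaN) are always legal; present values must lie within each
    instrument's closed response range.
    """
    missing = [c for c in ITEM_TABLE_COLS if c not in table.columns]
    if missing:
        raise ValueError(f"item table lacks columns: {missing[:5]}...")
    if table["id"].duplicated().any():
        raise ValueError("duplicate participant ids")
    bad_sex = set(table["sex"].dropna().unique()) - {"male", "female"}
    if bad_sex:
        raise ValueError(f"unrecognised sex codes: {bad_sex}")
    for inst, (lo, hi) in _ITEM_RANGES.items():
        vals = table[item_columns(inst)].to_numpy(dtype=float)
        present = ~np.isnan(vals)
        if ((vals[present] < lo) | (vals[present] > hi)).any():
            raise ValueError(f"{inst} responses outside [{lo}, {hi}]")


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write an item-level cohort; missing responses become empty fields."""
    out = table.copy()
    # keep integer item responses as integers in the CSV (pandas would
    # otherwise print 3.0 once a column holds NaN)
    for col in AQ_COLS + TAS_COLS + BDI_COLS:
        out[col] = out[col].astype("Int64")
    out.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read an item-level cohort CSV written by :func:`write_cohort_csv`."""
    table = pd.read_csv(path, dtype={"id": str, "group": str, "sex": str})
    for col in AQ_COLS + TAS_COLS + BDI_COLS:
        table[col] = table[col].astype("Int64")
    validate_item_table(table)
    return table
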