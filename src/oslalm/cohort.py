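"""Synthetic pre-TAVI patient cohort and its summary arithmetic.

The packaged fixture emulates a 128-patient severe-aortic-stenosis cohort
through its published marginal counts only: clinical manifestations
(angina, fainting, dyspnea), comorbidities (hypertension, diabetes, renal
insufficiency, cerebrovascular disease, atrial flutter/fibrillation) and
valve morphology (bicuspid vs trilobular). The joint distribution is
unreported, so columns are filled independently by seeded assignment; only
marginal counts and percentages are ever meaningful.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = ["COHORT_SIZE", "COHORT_MARGINS", "make_cohort_fixture", "summarize_cohort"]

COHORT_SIZE = 128

#: positive counts per binary column, and the valve-morphology split
COHORT_MARGINS = {
    "angina": 25,
    "fainting": 27,
    "dyspnea": 49,
    "hypertension": 59,
    "diabetes": 26,
    "renal_insufficiency": 9,
    "cerebrovascular": 21,
    "af_flutter": 19,
}
VALVE_SPLIT = {"bicuspid": 71, "trilobular": 57}


def make_cohort_fixture(seed: int = 0) -> pd.DataFrame:
    """128-row cohort table whose column margins match the published counts.

    Deterministic given ``seed``; two calls with the same seed are identical.
    """
    rng = np.random.default_rng(seed)
    n = COHORT_SIZE
    data = {"patient_id": np.arange(1, n + 1)}
    for col, count in COHORT_MARGINS.items():
        v = np.zeros(n, dtype=int)
        v[rng.permutation(n)[:count]] = 1
        data[col] = v
    morph = np.array(
        ["bicuspid"] * VALVE_SPLIT["bicuspid"] + ["trilobular"] * VALVE_SPLIT["trilobular"]
    )
    data["valve_morphology"] = morph[rng.permutation(n)]
    return pd.DataFrame(data)


def _round_half_up(value: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_cohort(table: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Counts and percentages (half-away-from-zero rounded) per column.

    Binary columns contribute their positive count; the valve-morphology
    column contributes one row per category. Percentages are
    ``100 * count / n_rows`` rounded to ``decimals``.
    """
    if len(table) == 0:
        raise ValueError("cohort table is empty")
    n = len(table)
    rows = []
    for col in table.columns:
        if col == "patient_id":
            continue
        if col == "valve_morphology":
            for cat, cnt in table[col].value_counts().sort_index().items():
                rows.append((str(cat), int(cnt), _round_half_up(100.0 * cnt / n, decimals)))
        else:
            cnt = int(table[col].sum())
            rows.append((col, cnt, _round_half_up(100.0 * cnt / n, decimals)))
    return pd.DataFrame(rows, columns=["label", "count", "percent"])
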