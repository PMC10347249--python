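"""Per-crop, per-salinity-class farm economics from household survey records.

Each survey record carries one household-crop's production input cost (seed,
fertilizer, pesticide, labor, harvest) and output value (yield x local
price), both in CNY/ha, tagged with the saline-alkali class of the plot.
The comparison table reports the mean input-output ratio (output/input as a
percentage) and mean economic output per (crop, class) cell; combinations
never planted are carried as an explicit "not planted" sentinel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "SALINITY_CLASSES",
    "NOT_PLANTED",
    "input_output_ratio",
    "summarize_economics",
    "rank_crops",
    "to_comparison_table",
]

SALINITY_CLASSES = (
    "non saline-alkali",
    "mildly saline-alkali",
    "moderately saline-alkali",
    "heavily saline-alkali",
)
NOT_PLANTED = "/"


def input_output_ratio(input_cost: float, output_value: float) -> float:
    """Output value over input cost, as a percentage."""
    if input_cost <= 0:
        raise ValueError("input cost must be positive")
    if output_value < 0:
        raise ValueError("output value must be nonnegative")
    return 100.0 * output_value / input_cost


def summarize_economics(records: pd.DataFrame, weight_by_area: bool = False) -> pd.DataFrame:
    """Mean input-output ratio and economic output per (crop, salinity class).

    ``records`` needs columns crop, salinity_class, input_cost, output_value
    (CNY/ha); optionally ``area_ha`` when ``weight_by_area``. Returns one row
    per observed (crop, class) with columns ratio_pct, output_cny_ha, n.
    """
    if len(records) == 0:
        raise ValueError("no survey records supplied")
    req = {"crop", "salinity_class", "input_cost", "output_value"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"survey records missing columns: {sorted(missing)}")
    bad = records[records["salinity_class"].isin(SALINITY_CLASSES) == False]  # noqa: E712
    if len(bad):
        raise ValueError(f"unknown salinity classes: {sorted(bad['salinity_class'].unique())}")

    df = records.copy()
    df["ratio_pct"] = [
        input_output_ratio(c, v) for c, v in zip(df["input_cost"], df["output_value"])
    ]

    def agg(group: pd.DataFrame) -> pd.Series:
        if weight_by_area:
            w = group["area_ha"].to_numpy(dtype=float)
            return pd.Series(
                {
                    "ratio_pct": float(np.average(group["ratio_pct"], weights=w)),
                    "output_cny_ha": float(np.average(group["output_value"], weights=w)),
                    "n": len(group),
                }
            )
        return pd.Series(
            {
                "ratio_pct": float(group["ratio_pct"].mean()),
                "output_cny_ha": float(group["output_value"].mean()),
                "n": len(group),
            }
        )

    out = (
        df.groupby(["crop", "salinity_class"], sort=False)
        .apply(agg, include_groups=False)
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out


def rank_crops(summary: pd.DataFrame, salinity_class: str) -> list[str]:
    """Crops in a class ordered by input-output ratio (desc), ties by output then name."""
    sel = summary[summary["salinity_class"] == salinity_class]
    sel = sel.sort_values(
        ["ratio_pct", "output_cny_ha", "crop"], ascending=[False, False, True]
    )
    return list(sel["crop"])


def to_comparison_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Wide crop x class table of 'ratio | output' cells with '/' for absent."""
    table = pd.DataFrame(index=sorted(summary["crop"].unique()), columns=list(SALINITY_CLASSES))
    table[:] = NOT_PLANTED
    for row in summary.itertuples():
        table.loc[row.crop, row.salinity_class] = f"{row.ratio_pct:.2f} | {row.output_cny_ha:.2f}"
    table.index.name = "crop"
    return table
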