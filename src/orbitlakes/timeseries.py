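"""Monthly surface-area series and aggregates from corrected stacks."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import AREA_TABLE_COLUMNS
from .orbit import CorrectedStack

DEFAULT_IMPUTED_PCT_THRESHOLD = 50.0
DEFAULT_RUN_LENGTH = 2
SIZE_BOUNDARY_KM2 = 100.0


def area_series(corrected: CorrectedStack, lake_id: int = 0) -> pd.DataFrame:
    """Per-month water pixel counts and areas, with correction metadata.

    area_km2 = water_pixel_count * pixel_area_km2; months whose input was
    entirely missing keep their (imputed) counts but carry
    all_missing_flag=True so the time axis stays rectangular.
    """
    counts = corrected.binary.sum(axis=(1, 2)).astype(int)
    ts = corrected.timestamps or [
        (2000 + i // 12, 1 + i % 12) for i in range(len(counts))
    ]
    meta = corrected.metadata
    return pd.DataFrame(
        {
            "lake_id": lake_id,
            "year": [y for y, _ in ts],
            "month": [m for _, m in ts],
            "water_pixel_count": counts,
            "area_km2": counts * corrected.pixel_area_km2,
            "pct_imputed": meta["pct_imputed"].to_numpy(),
            "pct_corrected": meta["pct_corrected"].to_numpy(),
            "all_missing_flag": meta["all_missing_flag"].to_numpy(),
        }
    )[AREA_TABLE_COLUMNS]


def flag_low_confidence_runs(
    table: pd.DataFrame,
    imputed_pct_threshold: float = DEFAULT_IMPUTED_PCT_THRESHOLD,
    run_length: int = DEFAULT_RUN_LENGTH,
) -> pd.DataFrame:
    """Mark months inside runs of >= run_length consecutive heavily-imputed
    frames (pct_imputed > threshold); isolated high-imputation months pass.

    Adds a boolean ``low_confidence_flag`` column; imputation quality
    degrades with consecutive gaps, so such runs should be ignored in
    trend analysis.
    """
    out = table.copy()
    flags = np.zeros(len(out), dtype=bool)
    high = (out["pct_imputed"].to_numpy() > imputed_pct_threshold)
    # flag per lake so runs never span different lakes
    for _, idx in out.groupby("lake_id").indices.items():
        h = high[idx]
        run_start = 0
        for i in range(len(h) + 1):
            if i == len(h) or not h[i]:
                if i - run_start >= run_length:
                    flags[idx[run_start:i]] = True
                run_start = i + 1
    out["low_confidence_flag"] = flags
    return out


def aggregate(
    tables: list[pd.DataFrame],
    group_by: str = "all",
    size_boundary_km2: float = SIZE_BOUNDARY_KM2,
    exclude_low_confidence: bool = False,
) -> pd.DataFrame:
    """Monthly total area (km^2) and contributing-lake counts per group.

    group_by: "all" for a single series, or "size-class" to split lakes at
    ``size_boundary_km2`` (classes "small" and "large") by each lake's
    maximum monthly area.  All tables must share one (year, month) axis.
    """
    if not tables:
        return pd.DataFrame(columns=["group", "year", "month", "total_area_km2", "n_lakes"])
    axes = {tuple(map(tuple, t[["year", "month"]].to_numpy())) for t in tables}
    if len(axes) != 1:
        raise ValueError("lake tables do not share a common time axis")
    df = pd.concat(tables, ignore_index=True)
    if exclude_low_confidence:
        if "low_confidence_flag" not in df.columns:
            raise ValueError("run flag_low_confidence_runs first")
        df = df[~df["low_confidence_flag"]]
    if group_by == "all":
        df = df.assign(group="all")
    elif group_by == "size-class":
        max_area = df.groupby("lake_id")["area_km2"].transform("max")
        df = df.assign(group=np.where(max_area < size_boundary_km2, "small", "large"))
    else:
        raise ValueError(f"unknown group_by {group_by!r}")
    agg = (
        df.groupby(["group", "year", "month"], as_index=False)
        .agg(total_area_km2=("area_km2", "sum"), n_lakes=("lake_id", "nunique"))
    )
    return agg
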