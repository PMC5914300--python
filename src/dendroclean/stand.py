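"""Stand-level validation statistics.

Digit-preference (heaping) detection for measurement-quality auditing, and
per-hectare stand summaries: stem number, quadratic mean diameter ``dg``,
dominant diameter ``d50`` (50th strongest tree per hectare), basal-area
weighted mean height ``hg``, dominant height ``h50``, standing basal area,
periodic annual increment and mean annual increment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Point, Polygon

from .data_model import decimal_year

__all__ = [
    "digit_preference_test",
    "StandSummary",
    "stand_summary",
    "summarize_dataset",
]


def digit_preference_test(values, divisor: int = 10):
    """Chi-square test of uniform terminal digits.

    ``values`` are integer readings in their recording unit (diameter mm,
    height dm); the remainders modulo ``divisor`` are compared against a
    uniform expectation with a Pearson chi-square test
    (df = ``divisor`` - 1). Readings heaped on 0/5 show up as a large
    statistic.
    """
    v = np.asarray(values)
    if v.size and not np.all(np.equal(np.mod(v, 1), 0)):
        raise ValueError("digit-preference test needs integer readings")
    v = v.astype(int)
    counts = np.bincount(v % divisor, minlength=divisor)
    stat, p = stats.chisquare(counts)
    return float(stat), divisor - 1, float(p)


@dataclass
class StandSummary:
    plot: int
    t: float
    n_trees: int
    n_per_ha: float
    dg_cm: float
    d50_cm: float
    hg_m: float
    h50_m: float
    basal_area_m2_ha: float
    removed_basal_area_m2_ha: float
    pai_m2_ha_yr: float | None = None  # periodic annual BA increment
    mai_m2_ha_yr: float | None = None  # mean annual BA increment

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def _rank_value(sorted_desc: np.ndarray, area_m2: float, rank_per_ha: int = 50):
    k = math.ceil(rank_per_ha * area_m2 / 1e4)
    if k < 1 or k > sorted_desc.size:
        return float("nan")
    return float(sorted_desc[k - 1])


def stand_summary(records: pd.DataFrame, positions: pd.DataFrame,
                  area_m2: float, *, polygon: Polygon | None = None,
                  stand_age: float | None = None,
                  removed_ba_m2: float = 0.0) -> StandSummary:
    """Per-hectare stand summary for one plot at one date.

    ``records`` must carry one row per standing tree with columns ``d`` (mm)
    and ``h`` (dm); ``positions`` maps trees to coordinates so that only
    trees inside the corner polygon are counted (all trees if no polygon is
    given).
    """
    if area_m2 <= 0:
        raise ValueError("plot area must be positive")
    df = records.merge(positions[["plot", "tree", "x", "y"]],
                       on=["plot", "tree"], how="left")
    if polygon is not None:
        inside = [polygon.covers(Point(x, y))
                  for x, y in zip(df["x"], df["y"])]
        df = df[np.asarray(inside, dtype=bool)]
    n = len(df)
    d_cm = df["d"].to_numpy(dtype=float) / 10.0
    h_m = df["h"].to_numpy(dtype=float) / 10.0
    ba = np.pi * (d_cm / 200.0) ** 2  # m^2 per tree
    scale = 1e4 / area_m2
    dg = float(2.0 * np.sqrt(np.mean(ba) / np.pi) * 100.0) if n else np.nan
    hg = float(np.sum(ba * h_m) / np.sum(ba)) if n and ba.sum() > 0 else np.nan
    d_sorted = np.sort(d_cm)[::-1]
    h_sorted = np.sort(h_m)[::-1]
    total_ba = float(ba.sum())
    mai = None
    if stand_age is not None and stand_age > 0:
        mai = (total_ba + removed_ba_m2) * scale / stand_age
    return StandSummary(
        plot=int(records["plot"].iloc[0]) if n else -1,
        t=float(records["t"].iloc[0]) if "t" in records and n else np.nan,
        n_trees=n, n_per_ha=n * scale, dg_cm=dg,
        d50_cm=_rank_value(d_sorted, area_m2),
        hg_m=hg, h50_m=_rank_value(h_sorted, area_m2),
        basal_area_m2_ha=total_ba * scale,
        removed_basal_area_m2_ha=removed_ba_m2 * scale,
        mai_m2_ha_yr=mai)


def summarize_dataset(tables: dict, processed: pd.DataFrame,
                      *, germination_year: int | None = None
                      ) -> pd.DataFrame:
    """Stand summaries for every plot x campaign of a processed dataset.

    ``processed`` is a dhc-style frame (plot, tree, year, obs, d mm, h dm).
    Standing trees at a campaign are those not yet removed; removed basal
    area accumulates from each removed tree's last processed diameter.
    Periodic annual increments are computed from total (standing + removed)
    basal area between successive campaigns.
    """
    pos = tables["pos"]
    area = {int(p): float(a) for p, a in zip(tables["area"]["plot"],
                                             tables["area"]["area"])}
    dates = tables["date"].copy()
    dates["t"] = dates["date"].map(decimal_year)
    polygons = {}
    if "corner" in tables:
        for p, grp in tables["corner"].groupby("plot"):
            grp = grp.sort_values("corner")
            if len(grp) >= 3:
                polygons[int(p)] = Polygon(
                    list(zip(grp["x"].astype(float), grp["y"].astype(float))))
    removal = {(int(p), int(tr)): (pd.Timestamp(d) if pd.notna(d) else None)
               for p, tr, d in zip(pos["plot"], pos["tree"],
                                   pos["removeDate"])}
    proc = processed.merge(dates[["plot", "year", "obs", "t", "date"]],
                           on=["plot", "year", "obs"], how="left",
                           suffixes=("", "_cal"))
    if "t" not in processed.columns:
        proc = proc.rename(columns={"t_cal": "t"})
    rows = []
    for plot, pgrp in proc.groupby("plot"):
        plot = int(plot)
        cal = dates[dates["plot"] == plot].sort_values("t")
        prev = None
        last = pgrp.sort_values("t").groupby("tree").tail(1)
        last_ba = {int(tr): np.pi * (d / 2000.0) ** 2
                   for tr, d in zip(last["tree"], last["d"])}
        removed_trees = [(tr, removal[(plot, tr)]) for tr in last_ba
                         if removal.get((plot, tr)) is not None]
        for _, crow in cal.iterrows():
            tcamp, dcamp = float(crow["t"]), pd.Timestamp(crow["date"])
            at = pgrp[(pgrp["year"] == crow["year"])
                      & (pgrp["obs"] == crow["obs"])]
            if at.empty:
                continue
            standing_mask = []
            for _, r in at.iterrows():
                rd = removal.get((plot, int(r["tree"])))
                standing_mask.append(rd is None or rd >= dcamp)
            standing = at[np.asarray(standing_mask, dtype=bool)]
            # removed BA: last processed diameter of trees removed by now
            removed_ba = float(sum(last_ba[tr] for tr, rd in removed_trees
                                   if rd < dcamp))
            age = (tcamp - germination_year) if germination_year else None
            summ = stand_summary(standing.assign(t=tcamp), pos,
                                 area[plot], polygon=polygons.get(plot),
                                 stand_age=age, removed_ba_m2=removed_ba)
            summ.plot = plot
            summ.t = tcamp
            if prev is not None:
                dt = tcamp - prev[0]
                total_now = (summ.basal_area_m2_ha
                             + summ.removed_basal_area_m2_ha)
                if dt > 0:
                    summ.pai_m2_ha_yr = (total_now - prev[1]) / dt
            prev = (tcamp, summ.basal_area_m2_ha
                    + summ.removed_basal_area_m2_ha)
            rows.append(summ.as_dict())
    return pd.DataFrame(rows)
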