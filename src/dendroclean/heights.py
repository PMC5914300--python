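"""Height curation: outlier filters, disc-based levelling, height-age model,
ratio smoothing and observation anchoring.

Heights were measured on changing subsamples with changing instruments, so a
tree's height record is sparse and carries era-specific bias. The stage:

1. computes heights from raw triangulation fields where needed, drops
   implausible increments (a decrease of more than 1 m without a recorded
   crown break, or growth above 1 m per year);
2. levels each plot x year campaign with the median ratio of stem-analysis
   reference heights (disc height vs ring-count age, interpolated by a
   monotone spline, the counted age reduced by half a year because a disc
   height is reached mid-season) to the measured heights;
3. enforces monotone growth between crown breaks (isotonic regression),
   giving ``hMon``;
4. fits the height-age curve ``h = c0 * log(1 + exp(c2) * age^c3)^c1`` to
   unbroken trees that survived to the final survey, and smooths the ratio
   ``hMon / h_age(age)`` across trees with an additive spline model (age,
   diameter, and stand position for spruce) with per-tree shrunken
   intercepts;
5. anchors the smoothed heights back onto the measured ``hMon`` values with
   a linearly interpolated multiplier, once using all observations and once
   ignoring those after the first crown break;
6. removes negative and zero increments that survive (isotonic projection
   per break segment; flat runs re-dated at their mean date).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .data_model import decimal_year
from .diameter import StemDiscGrowth
from .hypsometry import heights_from_observations
from .monotone import isotonic_fit, mean_date_flat_runs, monotone_interpolator
from .smoothing import AdditiveSplineSmoother

__all__ = [
    "HeightConfig",
    "HeightAgeModel",
    "filter_height_outliers",
    "disc_height_age",
    "level_height_bias",
    "segment_isotonic",
    "anchor_to_observations",
    "finalize_heights",
    "run_height_pipeline",
]

BREAK_CODES = frozenset({1, 2, 6})  # broken top / substituted top / re-broken


@dataclass
class HeightConfig:
    break_codes: frozenset = BREAK_CODES
    exclude_hmk: frozenset = frozenset({6})  # flagged outlier measurements
    max_drop_dm: float = 10.0
    max_rise_rate_dm_yr: float = 10.0
    min_group_obs: int = 3
    n_knots: int = 8
    spruce_covariates: tuple = ("age", "d", "x", "y")
    other_covariates: tuple = ("age", "d")


# ---------------------------------------------------------------------------
# height-age model

class HeightAgeModel:
    """Nonlinear height-age curve ``h = c0 * log(1 + exp(c2)*age^c3)^c1``.

    Fitted by multi-start nonlinear least squares; heights in dm, age in
    years since germination.
    """

    def __init__(self, c0=None, c1=None, c2=None, c3=None):
        self.params_ = (None if c0 is None
                        else np.array([c0, c1, c2, c3], dtype=float))

    @staticmethod
    def curve(age, c0, c1, c2, c3):
        age = np.asarray(age, dtype=float)
        return c0 * np.log1p(np.exp(c2) * age ** c3) ** c1

    def predict(self, age) -> np.ndarray:
        if self.params_ is None:
            raise RuntimeError("model is not fitted")
        return self.curve(age, *self.params_)

    def fit(self, age, h) -> "HeightAgeModel":
        age = np.asarray(age, dtype=float)
        h = np.asarray(h, dtype=float)
        if age.size < 4 or np.unique(age).size < 3:
            raise ValueError("need >= 4 observations over >= 3 distinct ages")
        if np.ptp(h) <= 0:
            raise RuntimeError("degenerate data: heights show no growth, "
                               "height-age fit cannot converge")

        def resid(p):
            return self.curve(age, *p) - h

        lo = [1e-3, 0.05, -30.0, 0.05]
        hi = [1e5, 10.0, 10.0, 6.0]
        best = None
        for c2 in (-8.0, -5.0, -2.0):
            for c3 in (1.0, 2.0, 3.0):
                base = np.log1p(np.exp(c2) * np.max(age) ** c3)
                c0 = float(np.max(h) / max(base, 1e-6))
                p0 = np.clip([c0, 1.2, c2, c3], lo, hi)
                try:
                    sol = least_squares(resid, p0, bounds=(lo, hi),
                                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
                except ValueError:
                    continue
                if best is None or sol.cost < best.cost:
                    best = sol
        if best is None or not np.isfinite(best.cost):
            raise RuntimeError("height-age fit did not converge from any "
                               "starting point")
        self.params_ = best.x
        self.residual_norm_ = float(np.sqrt(2 * best.cost))
        grid = np.linspace(age.min(), age.max(), 200)
        pred = self.curve(grid, *best.x)
        if np.any(np.diff(pred) < -1e-9) or np.any(pred <= 0):
            raise RuntimeError("fitted height-age curve is not positive "
                               "non-decreasing on the data range")
        return self


# ---------------------------------------------------------------------------
# per-series operations

def filter_height_outliers(t, h, break_at_obs=None, *,
                           max_drop_dm: float = 10.0,
                           max_rise_rate_dm_yr: float = 10.0):
    """Keep mask removing implausible height increments.

    A decrease beyond ``max_drop_dm`` is accepted only when a crown event is
    recorded at the later observation; growth above ``max_rise_rate_dm_yr``
    is never accepted. The later point of a violating pair is removed,
    iteratively, keeping at least one observation.
    """
    t = np.asarray(t, dtype=float)
    h = np.asarray(h, dtype=float)
    n = h.size
    brk = (np.zeros(n, dtype=bool) if break_at_obs is None
           else np.asarray(break_at_obs, dtype=bool))
    keep = np.ones(n, dtype=bool)
    changed = True
    while changed and keep.sum() > 1:
        changed = False
        idx = np.flatnonzero(keep)
        for a, b in zip(idx[:-1], idx[1:]):
            dt = max(t[b] - t[a], 1e-9)
            inc = h[b] - h[a]
            if inc < -max_drop_dm and not brk[b]:
                keep[b] = False
                changed = True
                break
            if inc / dt > max_rise_rate_dm_yr:
                keep[b] = False
                changed = True
                break
    return keep


def disc_height_age(growth: StemDiscGrowth, germination_year: int):
    """Height(age) function of one stem-analysis tree.

    Each disc pins down the age at which the tree top passed the disc height:
    the year before the disc's first ring formed, plus half a year because a
    given height is reached mid-season. A monotone cubic spline through the
    (age, height) knots interpolates between discs; no extrapolation.

    Returns ``(interpolator in dm over age, (age_min, age_max))``.
    """
    pairs = []
    for disc_id, d in growth.discs.items():
        if np.isnan(d["h"]):
            continue
        age = d["years"][0] - germination_year - 0.5
        pairs.append((float(age), float(d["h"]) * 10.0))  # m -> dm
    if len(pairs) < 2:
        raise ValueError("need at least two discs for a height-age function")
    pairs.sort()
    ages = np.array([p[0] for p in pairs])
    hs = np.array([p[1] for p in pairs])
    if np.any(np.diff(ages) <= 0) or np.any(np.diff(hs) < 0):
        raise ValueError("inconsistent ring counts: a higher disc implies an "
                         "older or equal age")
    interp = monotone_interpolator(ages, hs)
    return interp, (float(ages.min()), float(ages.max()))


def level_height_bias(obs: pd.DataFrame, references: dict,
                      germination: dict, *, group_cols=("plot", "year")):
    """Multiply each plot x year group by the median reference/measured ratio.

    ``references`` maps (plot, tree) to a ``(height_fn, (age_lo, age_hi))``
    pair from :func:`disc_height_age`; ``germination`` maps (plot, tree) to
    the germination year. Groups without a usable reference keep factor 1
    (flagged).
    """
    obs = obs.copy()
    factors = []
    for key, grp in obs.groupby(list(group_cols)):
        ratios = []
        for _, row in grp.iterrows():
            ref = references.get((row["plot"], row["tree"]))
            if ref is None or row["h"] <= 0:
                continue
            fn, (lo, hi) = ref
            age = row["t"] - germination[(row["plot"], row["tree"])]
            if lo <= age <= hi:
                ratios.append(float(fn(age)) / float(row["h"]))
        if ratios:
            factors.append((*key, float(np.median(ratios)), len(ratios),
                            False))
        else:
            factors.append((*key, 1.0, 0, True))
    fac = pd.DataFrame(factors, columns=[*group_cols, "h_factor", "n_ref",
                                         "no_reference"])
    obs = obs.merge(fac[[*group_cols, "h_factor"]], on=list(group_cols),
                    how="left")
    obs["h_factor"] = obs["h_factor"].fillna(1.0)
    obs["h_lev"] = obs["h"] * obs["h_factor"]
    return obs, fac


def _segments(t, break_times, tol=1e-6):
    t = np.asarray(t, dtype=float)
    seg = np.zeros(t.size, dtype=int)
    for tb in sorted(break_times):
        seg += (t >= tb - tol).astype(int)
    return seg


def segment_isotonic(t, h, break_times=()) -> np.ndarray:
    """Isotonic projection applied separately between crown breaks."""
    t = np.asarray(t, dtype=float)
    h = np.asarray(h, dtype=float)
    out = h.copy()
    seg = _segments(t, break_times)
    for s in np.unique(seg):
        m = seg == s
        out[m] = isotonic_fit(t[m], h[m])
    return out


def anchor_to_observations(t_grid, h_smooth, t_anchor, h_anchor):
    """Scale a smoothed curve so it passes through the measured heights.

    At each anchor date the multiplier is measured/smoothed; between anchors
    it is linearly interpolated in decimal years and held constant beyond the
    first and last anchor. With no anchors the curve is returned unchanged.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    h_smooth = np.asarray(h_smooth, dtype=float)
    if np.any(h_smooth <= 0):
        raise ValueError("smoothed heights must be positive for anchoring")
    t_anchor = np.asarray(t_anchor, dtype=float)
    h_anchor = np.asarray(h_anchor, dtype=float)
    if t_anchor.size == 0:
        return h_smooth.copy()
    order = np.argsort(t_anchor)
    t_anchor, h_anchor = t_anchor[order], h_anchor[order]
    h_at_anchor = np.interp(t_anchor, t_grid, h_smooth)
    m = h_anchor / h_at_anchor
    mult = np.interp(t_grid, t_anchor, m)
    return h_smooth * mult


def finalize_heights(t, h, break_times=()) -> np.ndarray:
    """Remove residual negative/zero increments between crown breaks."""
    t = np.asarray(t, dtype=float)
    out = np.asarray(h, dtype=float).copy()
    seg = _segments(t, break_times)
    for s in np.unique(seg):
        m = seg == s
        out[m] = mean_date_flat_runs(t[m], isotonic_fit(t[m], out[m]))
    return out


# ---------------------------------------------------------------------------
# whole-dataset driver

def _crown_break_times(tables: dict, cfg: HeightConfig) -> dict:
    dates = tables["date"].copy()
    dates["t"] = dates["date"].map(decimal_year)
    obs = tables["dbhObs"].merge(dates[["plot", "year", "obs", "t"]],
                                 on=["plot", "year", "obs"], how="inner")
    brk = obs[obs["crown"].isin(list(cfg.break_codes))]
    out: dict = {}
    for (p, tr), grp in brk.groupby(["plot", "tree"]):
        out[(int(p), int(tr))] = sorted(grp["t"].tolist())
    return out


def build_height_observations(tables: dict, cfg: HeightConfig | None = None
                              ) -> pd.DataFrame:
    """Per-measurement height frame (plot, tree, year, obs, t, h dm)."""
    cfg = cfg or HeightConfig()
    dates = tables["date"].copy()
    dates["t"] = dates["date"].map(decimal_year)
    obs = tables["dbhObs"].merge(dates[["plot", "year", "obs", "t"]],
                                 on=["plot", "year", "obs"], how="inner")
    h = heights_from_observations(obs)
    keep = h.notna() & ~obs["hmk"].isin(list(cfg.exclude_hmk))
    crown_flag = obs["crown"].isin(list(cfg.break_codes)).fillna(False)
    out = pd.DataFrame({
        "plot": obs["plot"].astype(int), "tree": obs["tree"].astype(int),
        "year": obs["year"].astype(int), "obs": obs["obs"].astype(int),
        "t": obs["t"].astype(float), "h": h.astype(float),
        "break_here": crown_flag.astype(bool)})
    return out[keep.to_numpy()].reset_index(drop=True)


def build_height_references(tables: dict, germination: dict) -> dict:
    refs = {}
    if "saIr" not in tables or "saDisc" not in tables:
        return refs
    keys = tables["saDisc"][["plot", "tree"]].drop_duplicates()
    for _, row in keys.iterrows():
        plot, tree = int(row["plot"]), int(row["tree"])
        try:
            g = StemDiscGrowth.from_tables(tables["saIr"], tables["saDisc"],
                                           plot, tree)
            refs[(plot, tree)] = disc_height_age(g, germination[(plot, tree)])
        except (ValueError, KeyError):
            continue
    return refs


def run_height_pipeline(tables: dict, diameter_records: pd.DataFrame,
                        cfg: HeightConfig | None = None):
    """Full height stage.

    ``diameter_records`` (from the diameter stage) defines the calendar slots
    to cover and supplies the diameter covariate. Returns ``(records,
    aux)``: per-slot heights ``h_all`` / ``h_nobreak`` in dm, and a dict with
    the fitted height-age model, levelling factors and the ratio smoothers.
    """
    cfg = cfg or HeightConfig()
    pos = tables["pos"]
    germination = {(int(p), int(tr)): int(g) for p, tr, g in zip(
        pos["plot"], pos["tree"], pos["germinationYear"])}
    species = {(int(p), int(tr)): s for p, tr, s in zip(
        pos["plot"], pos["tree"], pos["species"])}
    xy = {(int(p), int(tr)): (float(x), float(y)) for p, tr, x, y in zip(
        pos["plot"], pos["tree"], pos["x"], pos["y"])}
    breaks = _crown_break_times(tables, cfg)

    hobs = build_height_observations(tables, cfg)
    refs = build_height_references(tables, germination)
    hobs, factors = level_height_bias(hobs, refs, germination)

    # per-tree filtering + monotonisation
    mon_rows = []
    for (p, tr), grp in hobs.groupby(["plot", "tree"]):
        grp = grp.sort_values("t")
        keep = filter_height_outliers(
            grp["t"].to_numpy(), grp["h_lev"].to_numpy(),
            grp["break_here"].to_numpy(), max_drop_dm=cfg.max_drop_dm,
            max_rise_rate_dm_yr=cfg.max_rise_rate_dm_yr)
        g = grp[keep].copy()
        g["hMon"] = segment_isotonic(g["t"].to_numpy(),
                                     g["h_lev"].to_numpy(),
                                     breaks.get((p, tr), ()))
        mon_rows.append(g)
    hmon = (pd.concat(mon_rows, ignore_index=True) if mon_rows
            else hobs.iloc[0:0].assign(hMon=[]))

    # height-age curve from unbroken survivors
    surv = set(zip(pos.loc[pos["removeDate"].isna(), "plot"].astype(int),
                   pos.loc[pos["removeDate"].isna(), "tree"].astype(int)))
    fit_mask = hmon.apply(
        lambda r: (r["plot"], r["tree"]) in surv
        and (r["plot"], r["tree"]) not in breaks, axis=1)
    fit_rows = hmon[fit_mask] if fit_mask.any() else hmon
    ages = fit_rows["t"].to_numpy() - np.array(
        [germination[(p, tr)] for p, tr in zip(fit_rows["plot"],
                                               fit_rows["tree"])])
    model = HeightAgeModel().fit(ages, fit_rows["hMon"].to_numpy())

    # ratio smoothing across trees
    hmon = hmon.copy()
    hmon["age"] = hmon["t"] - np.array(
        [germination[(p, tr)] for p, tr in zip(hmon["plot"], hmon["tree"])])
    hmon["ratio"] = hmon["hMon"] / model.predict(hmon["age"].to_numpy())
    hmon["species"] = [species[(p, tr)] for p, tr in zip(hmon["plot"],
                                                         hmon["tree"])]
    hmon["x"] = [xy[(p, tr)][0] for p, tr in zip(hmon["plot"], hmon["tree"])]
    hmon["y"] = [xy[(p, tr)][1] for p, tr in zip(hmon["plot"], hmon["tree"])]
    dkey = {(p, tr, y, o): d for p, tr, y, o, d in zip(
        diameter_records["plot"], diameter_records["tree"],
        diameter_records["year"], diameter_records["obs"],
        diameter_records["d"])}
    hmon["d"] = [dkey.get((p, tr, y, o), np.nan) for p, tr, y, o in zip(
        hmon["plot"], hmon["tree"], hmon["year"], hmon["obs"])]
    train = hmon[hmon["d"].notna()]

    slots = diameter_records.copy()
    slots["species"] = [species[(p, tr)] for p, tr in zip(slots["plot"],
                                                          slots["tree"])]
    slots["age"] = slots["t"] - np.array(
        [germination[(p, tr)] for p, tr in zip(slots["plot"], slots["tree"])])
    slots["x"] = [xy[(p, tr)][0] for p, tr in zip(slots["plot"],
                                                  slots["tree"])]
    slots["y"] = [xy[(p, tr)][1] for p, tr in zip(slots["plot"],
                                                  slots["tree"])]
    slots["ratio_pred"] = np.nan

    smoothers = {}
    for is_spruce, cov in ((True, cfg.spruce_covariates),
                           (False, cfg.other_covariates)):
        tr_mask = (train["species"] == "PCAB") == is_spruce
        sl_mask = (slots["species"] == "PCAB") == is_spruce
        sub = train[tr_mask]
        if not sl_mask.any():
            continue
        if len(sub) < 10:
            # too little signal for a spline: carry the overall mean ratio
            slots.loc[sl_mask, "ratio_pred"] = (
                float(sub["ratio"].mean()) if len(sub) else 1.0)
            continue
        sm = AdditiveSplineSmoother(cov, n_knots=cfg.n_knots,
                                    min_group_obs=cfg.min_group_obs)
        groups = list(zip(sub["plot"], sub["tree"]))
        sm.fit({c: sub[c].to_numpy(dtype=float) for c in cov},
               sub["ratio"].to_numpy(), groups=groups,
               fallback=sub["species"].to_numpy())
        sl = slots[sl_mask]
        pred = sm.predict({c: sl[c].to_numpy(dtype=float) for c in cov},
                          groups=list(zip(sl["plot"], sl["tree"])),
                          fallback=sl["species"].to_numpy())
        slots.loc[sl_mask, "ratio_pred"] = pred
        smoothers["spruce" if is_spruce else "other"] = sm

    slots["ratio_pred"] = slots["ratio_pred"].clip(lower=0.05)
    slots["hSmooth"] = slots["ratio_pred"] * model.predict(
        slots["age"].to_numpy())

    # per-tree: monotonise the smooth, anchor, finalise
    out_rows = []
    hmon_key = {(p, tr): g.sort_values("t")
                for (p, tr), g in hmon.groupby(["plot", "tree"])}
    for (p, tr), grp in slots.groupby(["plot", "tree"]):
        grp = grp.sort_values("t")
        t = grp["t"].to_numpy()
        btimes = breaks.get((p, tr), ())
        hs = segment_isotonic(t, grp["hSmooth"].to_numpy(), btimes)
        hs = np.maximum(hs, 1e-3)
        anchors = hmon_key.get((p, tr))
        if anchors is not None:
            ta = anchors["t"].to_numpy()
            ha = anchors["hMon"].to_numpy()
        else:
            ta = np.array([])
            ha = np.array([])
        h_all = anchor_to_observations(t, hs, ta, ha)
        h_all = finalize_heights(t, h_all, btimes)
        if btimes:
            first = min(btimes)
            m = ta < first - 1e-6
            ta_nb, ha_nb = ta[m], ha[m]
        else:
            ta_nb, ha_nb = ta, ha
        hs_nb = isotonic_fit(t, grp["hSmooth"].to_numpy())
        hs_nb = np.maximum(hs_nb, 1e-3)
        h_nb = anchor_to_observations(t, hs_nb, ta_nb, ha_nb)
        h_nb = finalize_heights(t, h_nb)
        for row, hv, hn in zip(grp.itertuples(), h_all, h_nb):
            out_rows.append({"plot": int(p), "tree": int(tr),
                             "year": int(row.year), "obs": int(row.obs),
                             "t": float(row.t), "h_all": float(hv),
                             "h_nobreak": float(hn)})
    records = pd.DataFrame(out_rows)
    aux = {"model": model, "factors": factors, "smoothers": smoothers,
           "breaks": breaks, "hmon": hmon}
    return records, aux
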