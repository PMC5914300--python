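"""Crown-base curation: monotone, height-bounded crown-base series.

Spruce self-prunes: the live crown base only moves upward, and it can never
sit above the tree top. Observed crown-base heights (direct readings, or
angles converted by triangulation) are clipped to the concurrent tree height
and projected onto non-decreasing values. Two cross-tree estimates — an
additive-spline model of the crown base itself and one of the crown ratio
(crown base / height) scaled by the no-break height — are averaged, made
monotone, anchored back onto the monotone observations, and finally bounded
by the tree height.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import decimal_year
from .heights import anchor_to_observations
from .hypsometry import height_slope_distance, DEFAULT_MARK_HEIGHT_DM
from .monotone import isotonic_fit, mean_date_flat_runs
from .smoothing import AdditiveSplineSmoother

__all__ = [
    "CrownConfig",
    "monotone_crown_base",
    "estimate_crown_base",
    "finalize_crown_base",
    "run_crown_pipeline",
]


@dataclass
class CrownConfig:
    min_group_obs: int = 3
    n_knots: int = 8
    spruce_covariates: tuple = ("age", "d", "h_nobreak", "x", "y")
    other_covariates: tuple = ("age", "d", "h_nobreak")


def monotone_crown_base(t, hcr, h_concurrent=None):
    """Clip crown-base observations to tree height, then isotonic-project.

    Returns ``(hCr_mon, clipped flags)``.
    """
    t = np.asarray(t, dtype=float)
    hcr = np.asarray(hcr, dtype=float)
    clipped = np.zeros(hcr.size, dtype=bool)
    if h_concurrent is not None:
        h = np.asarray(h_concurrent, dtype=float)
        clipped = hcr > h
        hcr = np.minimum(hcr, h)
    return isotonic_fit(t, hcr), clipped


def estimate_crown_base(train: pd.DataFrame, slots: pd.DataFrame,
                        cfg: CrownConfig | None = None):
    """Cross-tree crown-base estimates at every calendar slot.

    ``train`` rows carry observed ``hCr`` (dm) plus the covariates; ``slots``
    is the prediction grid with the same covariates and the no-break height.
    Returns ``slots`` with ``hCr_direct`` and ``hCr_ratio`` columns (the
    ratio estimate is the predicted crown ratio, clipped to [0, 1], times the
    no-break height).
    """
    cfg = cfg or CrownConfig()
    slots = slots.copy()
    slots["hCr_direct"] = np.nan
    slots["hCr_ratio"] = np.nan
    for is_spruce, cov in ((True, cfg.spruce_covariates),
                           (False, cfg.other_covariates)):
        tr_mask = (train["species"] == "PCAB") == is_spruce
        sl_mask = (slots["species"] == "PCAB") == is_spruce
        if not sl_mask.any():
            continue
        sub = train[tr_mask]
        sl = slots[sl_mask]
        if len(sub) < 10:
            ratio = float((sub["hCr"] / sub["h_nobreak"]).mean()) if len(sub) \
                else 0.5
            ratio = min(max(ratio, 0.0), 1.0)
            slots.loc[sl_mask, "hCr_direct"] = ratio * sl["h_nobreak"]
            slots.loc[sl_mask, "hCr_ratio"] = ratio * sl["h_nobreak"]
            continue
        X_tr = {c: sub[c].to_numpy(dtype=float) for c in cov}
        X_sl = {c: sl[c].to_numpy(dtype=float) for c in cov}
        g_tr = list(zip(sub["plot"], sub["tree"]))
        g_sl = list(zip(sl["plot"], sl["tree"]))
        direct = AdditiveSplineSmoother(cov, n_knots=cfg.n_knots,
                                        min_group_obs=cfg.min_group_obs)
        direct.fit(X_tr, sub["hCr"].to_numpy(), groups=g_tr,
                   fallback=sub["species"].to_numpy())
        slots.loc[sl_mask, "hCr_direct"] = direct.predict(
            X_sl, groups=g_sl, fallback=sl["species"].to_numpy())
        ratio_model = AdditiveSplineSmoother(cov, n_knots=cfg.n_knots,
                                             min_group_obs=cfg.min_group_obs)
        ratio_model.fit(X_tr,
                        (sub["hCr"] / sub["h_nobreak"]).to_numpy(),
                        groups=g_tr, fallback=sub["species"].to_numpy())
        pred_ratio = np.clip(ratio_model.predict(
            X_sl, groups=g_sl, fallback=sl["species"].to_numpy()), 0.0, 1.0)
        slots.loc[sl_mask, "hCr_ratio"] = pred_ratio * sl["h_nobreak"]
    slots["hCr_direct"] = slots["hCr_direct"].clip(lower=0.0)
    return slots


def finalize_crown_base(t, hcr_direct, hcr_ratio, t_anchor, hcr_anchor,
                        h_final):
    """Average the two estimates, monotonise, anchor, and bound by height."""
    t = np.asarray(t, dtype=float)
    avg = (np.asarray(hcr_direct, dtype=float)
           + np.asarray(hcr_ratio, dtype=float)) / 2.0
    avg = isotonic_fit(t, avg)
    avg = np.maximum(avg, 1e-3)
    out = anchor_to_observations(t, avg, np.asarray(t_anchor, dtype=float),
                                 np.asarray(hcr_anchor, dtype=float))
    out = isotonic_fit(t, out)
    out = mean_date_flat_runs(t, out)
    h_final = np.asarray(h_final, dtype=float)
    out = np.minimum(out, h_final)
    out = isotonic_fit(t, out)
    bad = out > h_final + 1e-6
    if bad.any():
        raise ValueError(
            f"crown base above tree height at {int(bad.sum())} dates after "
            "all adjustments")
    return out


# ---------------------------------------------------------------------------
# whole-dataset driver

def build_crown_observations(tables: dict) -> pd.DataFrame:
    """Observed crown-base heights (dm) per (plot, tree, year, obs).

    Direct readings come from ``ka`` when ``kh = 0``; angle campaigns
    (``kh = 1``) store the crown-base angle in ``wka`` (1/10 degree) and the
    slope distance in ``ho``, converted by triangulation.
    """
    dates = tables["date"].copy()
    dates["t"] = dates["date"].map(decimal_year)
    obs = tables["dbhObs"].merge(dates[["plot", "year", "obs", "t"]],
                                 on=["plot", "year", "obs"], how="inner")
    kh = obs["kh"].to_numpy(dtype=float, na_value=np.nan)
    ka = obs["ka"].to_numpy(dtype=float, na_value=np.nan)
    ho = obs["ho"].to_numpy(dtype=float, na_value=np.nan)
    kb = obs["kb"].to_numpy(dtype=float, na_value=np.nan)
    wka = obs["wka"].to_numpy(dtype=float, na_value=np.nan)
    hcr = np.full(len(obs), np.nan)
    for i in range(len(obs)):
        if np.isnan(kh[i]):
            continue
        if kh[i] == 0 and not np.isnan(ka[i]):
            hcr[i] = ka[i]
        elif kh[i] == 1 and not (np.isnan(wka[i]) or np.isnan(ho[i])
                                 or np.isnan(kb[i])):
            try:
                hcr[i] = height_slope_distance(ho[i], wka[i] / 10.0,
                                               kb[i] / 10.0,
                                               K=DEFAULT_MARK_HEIGHT_DM)
            except ValueError:
                pass
    out = pd.DataFrame({
        "plot": obs["plot"].astype(int), "tree": obs["tree"].astype(int),
        "year": obs["year"].astype(int), "obs": obs["obs"].astype(int),
        "t": obs["t"].astype(float), "hCr": hcr})
    return out[np.isfinite(hcr)].reset_index(drop=True)


def run_crown_pipeline(tables: dict, height_records: pd.DataFrame,
                       diameter_records: pd.DataFrame,
                       cfg: CrownConfig | None = None):
    """Full crown-base stage.

    ``height_records`` must carry ``h_all``/``h_nobreak`` per slot (from the
    height stage). Returns per-slot ``hCr`` (dm) bounded by ``h_all``.
    """
    cfg = cfg or CrownConfig()
    pos = tables["pos"]
    germination = {(int(p), int(tr)): int(g) for p, tr, g in zip(
        pos["plot"], pos["tree"], pos["germinationYear"])}
    species = {(int(p), int(tr)): s for p, tr, s in zip(
        pos["plot"], pos["tree"], pos["species"])}
    xy = {(int(p), int(tr)): (float(x), float(y)) for p, tr, x, y in zip(
        pos["plot"], pos["tree"], pos["x"], pos["y"])}

    slots = height_records.merge(
        diameter_records[["plot", "tree", "year", "obs", "d"]],
        on=["plot", "tree", "year", "obs"], how="inner")
    slots["species"] = [species[(p, tr)] for p, tr in zip(slots["plot"],
                                                          slots["tree"])]
    slots["age"] = slots["t"] - np.array(
        [germination[(p, tr)] for p, tr in zip(slots["plot"], slots["tree"])])
    slots["x"] = [xy[(p, tr)][0] for p, tr in zip(slots["plot"],
                                                  slots["tree"])]
    slots["y"] = [xy[(p, tr)][1] for p, tr in zip(slots["plot"],
                                                  slots["tree"])]

    cobs = build_crown_observations(tables)
    hkey = {(p, tr, y, o): (h, hn) for p, tr, y, o, h, hn in zip(
        slots["plot"], slots["tree"], slots["year"], slots["obs"],
        slots["h_all"], slots["h_nobreak"])}

    # clip to concurrent height, monotonise per tree
    mon_frames = []
    for (p, tr), grp in cobs.groupby(["plot", "tree"]):
        grp = grp.sort_values("t").copy()
        conc = np.array([hkey.get((p, tr, y, o), (np.inf, np.inf))[0]
                         for y, o in zip(grp["year"], grp["obs"])])
        mon, _ = monotone_crown_base(grp["t"].to_numpy(),
                                     grp["hCr"].to_numpy(), conc)
        grp["hCr_mon"] = mon
        mon_frames.append(grp)
    cmon = (pd.concat(mon_frames, ignore_index=True) if mon_frames
            else cobs.assign(hCr_mon=[]))

    # training rows need covariates from the slot grid
    train = cmon.merge(
        slots[["plot", "tree", "year", "obs", "d", "h_nobreak", "age",
               "x", "y", "species"]],
        on=["plot", "tree", "year", "obs"], how="inner")
    train = train.rename(columns={"hCr_mon": "hCr_obs"})
    train["hCr"] = train["hCr_obs"]

    est = estimate_crown_base(train, slots, cfg)

    out_rows = []
    anchors = {(p, tr): g.sort_values("t")
               for (p, tr), g in cmon.groupby(["plot", "tree"])}
    for (p, tr), grp in est.groupby(["plot", "tree"]):
        grp = grp.sort_values("t")
        anc = anchors.get((p, tr))
        ta = anc["t"].to_numpy() if anc is not None else np.array([])
        ha = anc["hCr_mon"].to_numpy() if anc is not None else np.array([])
        hcr = finalize_crown_base(
            grp["t"].to_numpy(), grp["hCr_direct"].to_numpy(),
            grp["hCr_ratio"].to_numpy(), ta, ha,
            grp["h_all"].to_numpy())
        for row, v in zip(grp.itertuples(), hcr):
            out_rows.append({"plot": int(p), "tree": int(tr),
                             "year": int(row.year), "obs": int(row.obs),
                             "t": float(row.t), "hCr": float(v)})
    return pd.DataFrame(out_rows)
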