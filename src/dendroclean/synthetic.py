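"""Ground-truthed synthetic spacing-trial generator.

Emits a complete dataset in the published CSV schemas — tree register,
campaign calendar, repeated measurements, stem-analysis ring series, plot
geometry — together with the latent truth it was sampled from, so every
curation stage can be validated by parameter/curve recovery without any
external data.

What is emulated
----------------
* trees on exact rectangular planting rasters, numbered along serpentine
  rows, with plot spacings mirroring the trial (1x1, 1.5x1.5, 1x2, 2x2 m);
* monotone height growth ``h = m_i * c0*log(1+exp(c2)*age^c3)^c1`` with a
  lognormal tree effect and a mild spatial gradient; diameter tied to height
  by an allometric power law with its own tree effect; diameter accrues
  linearly within the May–August growing season;
* era-specific measurement error: crosswise calliper readings (with digit
  heaping on 0/5 mm) until the tape era, girth-tape readings afterwards
  (reading a factor ``tape_extra`` above the calliper convention, as
  non-circular stems make tape diameters run high); height instruments with
  their own bias/noise, heights on subsamples only, one era recorded as raw
  angle/distance triangulation fields;
* thinning campaigns with coded removals, crown breaks (a lasting height
  loss, recorded as a crown code at the next campaign), missing
  observations;
* stem discs on trees felled at the final survey whose ring-width series
  accumulate exactly to the inside-bark radius truth
  (outside-bark diameter / bark factor) year by year.

Not emulated: competition dynamics, spatially correlated growth shocks,
species-specific allometry (non-spruce admixture trees share the spruce
growth law scaled down).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data_model import decimal_year, SPECIES_CODES
from .diameter import season_fraction
from .heights import HeightAgeModel
from .spatial import SerpentineNumbering

__all__ = [
    "PlotSpec",
    "CampaignSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_stand",
    "score_recovery",
]


@dataclass(frozen=True)
class PlotSpec:
    plot: int
    spacing: tuple[float, float]  # m
    n_i: int = 12
    n_j: int = 12
    origin: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class CampaignSpec:
    year: int
    d_instrument: str = "calliper"  # calliper | tape
    d_bias: float = 0.0             # relative, on outside-bark truth
    d_sd: float = 0.01
    round_probs: tuple = (0.6, 0.2, 0.2)  # round to 1 / 5 / 10 mm
    h_instrument: str = "pole"
    h_bias: float = 0.0
    h_sd: float = 0.02
    h_sample: float = 0.3           # fraction of trees with height measured
    angle_records: bool = False     # store raw triangulation fields (kh=1)
    thin_frac: float = 0.0
    month: int = 10
    day: int = 1
    obs: int = 1

    @property
    def date(self) -> _dt.date:
        return _dt.date(self.year, self.month, self.day)


def _default_campaigns() -> tuple:
    years = [1923, 1929, 1936, 1942, 1947, 1952, 1960, 1965, 1970, 1973,
             1978, 1983, 1989, 1993, 1997]
    # small, fixed era biases: different observers, different instruments
    d_biases = [0.02, -0.01, 0.015, 0.0, -0.02, 0.01, -0.015, 0.02, 0.0,
                -0.01, 0.012, -0.008, 0.01, 0.0, 0.005]
    h_biases = [0.03, 0.02, -0.02, 0.01, -0.03, 0.02, -0.01, 0.015, -0.02,
                0.01, -0.015, 0.01, 0.0, -0.01, 0.0]
    out = []
    for k, y in enumerate(years):
        tape = y >= 1978
        out.append(CampaignSpec(
            year=y,
            d_instrument="tape" if tape else "calliper",
            d_bias=d_biases[k], d_sd=0.015 if not tape else 0.008,
            round_probs=(0.5, 0.25, 0.25) if not tape else (1.0, 0.0, 0.0),
            h_instrument=("pole" if y < 1940 else
                          "blume-leiss" if y < 1990 else "vertex"),
            h_bias=h_biases[k], h_sd=0.03 if y < 1990 else 0.015,
            h_sample=0.3 if y < 1993 else 1.0,
            angle_records=(y in (1983, 1989, 1993)),
            thin_frac=0.12 if 0 < k < len(years) - 1 else 0.0))
    return tuple(out)


@dataclass(frozen=True)
class SimulationConfig:
    plots: tuple = (
        PlotSpec(1, (1.0, 1.0), origin=(0.0, 0.0)),
        PlotSpec(2, (1.5, 1.5), origin=(40.0, 0.0)),
        PlotSpec(3, (1.0, 2.0), origin=(0.0, 40.0)),
        PlotSpec(4, (2.0, 2.0), origin=(40.0, 40.0)),
    )
    campaigns: tuple = field(default_factory=_default_campaigns)
    # height-age truth (dm, years): ~31 m dominant height at age 109
    c0: float = 75.0
    c1: float = 1.2
    c2: float = -6.0
    c3: float = 2.0
    tree_sd: float = 0.08          # lognormal sd of the height multiplier
    spatial_gradient: float = 0.03  # relative height trend across the stand
    allometry_b: float = 1.2
    allometry_coef: float = 0.3615  # mm per dm^b: ~35 cm dbh at age 109
    diameter_sd: float = 0.10      # lognormal sd of the diameter multiplier
    bark_factor: float = 1.070     # outside-bark unshrunk / inside-bark disc
    tape_extra: float = 1.082 / 1.070  # tape reads high on non-circular stems
    crown_ratio_limits: tuple = (0.2, 0.7)
    crown_ratio_tau: float = 40.0
    crown_break_hazard: float = 0.002  # per tree-year
    break_drop_dm: tuple = (10.0, 25.0)
    missing_d_rate: float = 0.02
    spruce_fraction: float = 0.97
    germination: dict = field(default_factory=lambda: {
        "PCAB": 1888, "LADC": 1892, "PNSY": 1892, "FASY": 1892,
        "QCPE": 1892, "BTPE": 1892})
    n_disc_trees: int = 4          # per plot, felled at the final survey
    disc_step_m: float = 5.0
    map_year: int = 1989           # campaign whose positions count as mapped
    altitude_m: float = 400.0

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# truth container

class SyntheticTruth:
    """Latent growth curves and event log of one simulated stand."""

    def __init__(self, config: SimulationConfig, seed: int):
        self.config = config
        self.seed = seed
        self.trees: pd.DataFrame | None = None
        self._curves: dict = {}
        self.events: list = []

    def _register(self, key, years, d_end, h_fn, breaks, germ):
        self._curves[key] = (years, d_end, h_fn, tuple(breaks), germ)

    def d_at(self, plot, tree, t) -> float:
        """Outside-bark, unshrunk diameter truth (mm) at decimal year."""
        years, d_end, _, _, _ = self._curves[(plot, tree)]
        t = float(t)
        year = int(np.floor(t))
        if year < years[0]:
            return 0.0
        k = min(year, years[-1]) - years[0]
        prev = d_end[k - 1] if k > 0 else 0.0
        frac = season_fraction(t) if year <= years[-1] else 1.0
        return prev + frac * (d_end[k] - prev)

    def h_base_at(self, plot, tree, t) -> float:
        """Break-free height truth (dm)."""
        _, _, h_fn, _, germ = self._curves[(plot, tree)]
        return float(h_fn(float(t) - germ))

    def h_at(self, plot, tree, t) -> float:
        """Height truth (dm), reduced by accumulated crown-break losses."""
        _, _, h_fn, breaks, germ = self._curves[(plot, tree)]
        h = float(h_fn(float(t) - germ))
        for tb, drop in breaks:
            if t >= tb:
                h -= drop
        return max(h, 1.0)

    def hcr_at(self, plot, tree, t) -> float:
        """Crown-base truth (dm): ratio curve times height, never above the
        (possibly broken) top, never descending."""
        _, _, h_fn, breaks, germ = self._curves[(plot, tree)]
        lo, hi = self.config.crown_ratio_limits
        tau = self.config.crown_ratio_tau

        def raw(u):
            age = u - germ
            r = hi - (hi - lo) * np.exp(-age / tau)
            return min(r * float(h_fn(age)), self.h_at(plot, tree, u))

        # running max over breaks before t keeps the crown base monotone
        cand = [raw(t)] + [raw(tb) for tb, _ in breaks if tb <= t]
        return max(cand)


# ---------------------------------------------------------------------------
# helpers

def _lonlat_stub(x, y):
    # fixed affine placeholder for the projected->geographic seam
    return 16.0 + x * 1e-5, 48.0 + y * 1e-5


def _heap_round(rng, v: float, probs) -> float:
    u = rng.random()
    if u < probs[0]:
        unit = 1.0
    elif u < probs[0] + probs[1]:
        unit = 5.0
    else:
        unit = 10.0
    return float(np.round(v / unit) * unit)


def _triangulation_fields(rng, h_dm: float, dist_dm: float = 200.0,
                          K: float = 13.0):
    wu = rng.uniform(-5.0, 5.0)
    tan_wo = (h_dm - K) / (dist_dm * np.cos(np.radians(wu))) - np.tan(
        np.radians(wu))
    wo = np.degrees(np.arctan(tan_wo))
    return dist_dm, round(wo * 10), round(wu * 10)


# ---------------------------------------------------------------------------
# the generator

def simulate_stand(config: SimulationConfig, seed: int):
    """Simulate one stand; returns ``(SyntheticTruth, tables dict)``.

    The same ``(config, seed)`` pair reproduces the dataset exactly.
    """
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(config, seed)
    model = HeightAgeModel(config.c0, config.c1, config.c2, config.c3)
    campaigns = sorted(config.campaigns, key=lambda c: c.year)
    final_year = campaigns[-1].year
    t_camps = [decimal_year(c.date) for c in campaigns]

    pos_rows, date_rows, obs_rows, crown_rows = [], [], [], []
    corner_rows, area_rows = [], []
    sa_tree_rows, sa_ir_rows, sa_disc_rows, sec_rows = [], [], [], []
    tree_rows = []

    for pspec in config.plots:
        sx, sy = pspec.spacing
        x0, y0 = pspec.origin
        numbering = SerpentineNumbering(pspec.n_i, pspec.n_j)
        # corners exactly mid-row around the raster
        local_corners = [(-sx / 2, -sy / 2),
                         ((pspec.n_i - 0.5) * sx, -sy / 2),
                         ((pspec.n_i - 0.5) * sx, (pspec.n_j - 0.5) * sy),
                         (-sx / 2, (pspec.n_j - 0.5) * sy)]
        for ci, (cx, cy) in enumerate(local_corners, start=1):
            lon, lat = _lonlat_stub(x0 + cx, y0 + cy)
            corner_rows.append({"plot": pspec.plot, "corner": ci,
                                "cor": False, "x": x0 + cx, "y": y0 + cy,
                                "lon": lon, "lat": lat})
        area_rows.append({"plot": pspec.plot,
                          "area": pspec.n_i * sx * pspec.n_j * sy})
        for c, tc in zip(campaigns, t_camps):
            date_rows.append({"plot": pspec.plot, "year": c.year,
                              "obs": c.obs, "date": c.date})

        extent = max(pspec.n_i * sx, pspec.n_j * sy)
        trees = []
        for i in range(pspec.n_i):
            for j in range(pspec.n_j):
                num = numbering.number_of(i, j)
                x = x0 + i * sx
                y = y0 + j * sy
                spruce = rng.random() < config.spruce_fraction
                sp = "PCAB" if spruce else str(
                    rng.choice([s for s in SPECIES_CODES if s != "PCAB"]))
                germ = config.germination[sp]
                m = float(np.exp(rng.normal(0.0, config.tree_sd)))
                grad = 1.0 + config.spatial_gradient * (
                    (x - x0) / max(extent, 1e-9) - 0.5)
                scale = m * grad * (1.0 if sp == "PCAB" else 0.85)
                s_d = float(np.exp(rng.normal(0.0, config.diameter_sd)))
                trees.append({"plot": pspec.plot, "tree": num, "node": (i, j),
                              "x": x, "y": y, "species": sp, "germ": germ,
                              "h_scale": scale, "d_scale": s_d})
        trees.sort(key=lambda r: r["tree"])

        # latent curves
        for tr in trees:
            germ = tr["germ"]
            years = np.arange(germ + 1, final_year + 1)
            ages = years - germ

            def h_fn(age, s=tr["h_scale"]):
                return s * model.curve(np.maximum(age, 1e-6), config.c0,
                                       config.c1, config.c2, config.c3)

            h_end = h_fn(ages)
            d_end = (config.allometry_coef * tr["d_scale"]
                     * np.asarray(h_end) ** config.allometry_b)
            # crown breaks over the campaign span
            breaks = []
            t_prev = t_camps[0]
            for tc in t_camps[1:]:
                lam = config.crown_break_hazard * (tc - t_prev)
                if rng.random() < lam:
                    tb = rng.uniform(t_prev + 0.1, tc - 0.1)
                    drop = rng.uniform(*config.break_drop_dm)
                    breaks.append((tb, drop))
                t_prev = tc
            truth._register((pspec.plot, tr["tree"]), years, d_end, h_fn,
                            breaks, germ)
            tr["breaks"] = breaks
            for tb, drop in breaks:
                truth.events.append({"plot": pspec.plot, "tree": tr["tree"],
                                     "kind": "crown_break", "t": tb,
                                     "drop_dm": drop})

        # observation campaigns + thinning
        removed: dict[int, tuple] = {}  # tree -> (removeDate, code)
        standing = {tr["tree"] for tr in trees}
        by_num = {tr["tree"]: tr for tr in trees}
        for c, tc in zip(campaigns, t_camps):
            for num in sorted(standing):
                tr = by_num[num]
                key = (pspec.plot, num)
                d_true = truth.d_at(*key, tc)
                h_true = truth.h_at(*key, tc)
                hcr_true = truth.hcr_at(*key, tc)
                row = {"plot": pspec.plot, "tree": num, "year": c.year,
                       "obs": c.obs, "dbh": None, "dbh2": None, "hmk": None,
                       "kh": None, "ho": None, "ka": None, "kb": None,
                       "wka": None, "kraft": None, "crown": 0, "stem": 0,
                       "defoliation": None}
                # crown code: break since previous campaign
                n_breaks_before = sum(1 for tb, _ in tr["breaks"] if tb <= tc)
                if n_breaks_before:
                    last_tb = max(tb for tb, _ in tr["breaks"] if tb <= tc)
                    prev_t = t_camps[t_camps.index(tc) - 1] \
                        if t_camps.index(tc) > 0 else -np.inf
                    if last_tb > prev_t:
                        row["crown"] = 1 if n_breaks_before == 1 else 6
                # diameter
                if rng.random() >= config.missing_d_rate:
                    mult = (1.0 + c.d_bias) * (1.0 + rng.normal(0, c.d_sd))
                    if c.d_instrument == "tape":
                        mult *= config.tape_extra
                    d_obs = d_true * mult
                    if c.d_instrument == "calliper":
                        asym = rng.normal(0, 0.02)
                        row["dbh"] = _heap_round(rng, d_obs * (1 + asym),
                                                 c.round_probs)
                        row["dbh2"] = _heap_round(rng, d_obs * (1 - asym),
                                                  c.round_probs)
                    else:
                        row["dbh"] = _heap_round(rng, d_obs, c.round_probs)
                # height subsample
                if rng.random() < c.h_sample:
                    h_obs = h_true * (1.0 + c.h_bias) \
                        * (1.0 + rng.normal(0, c.h_sd))
                    hcr_obs = hcr_true * (1.0 + rng.normal(0, c.h_sd))
                    hcr_obs = min(hcr_obs, h_obs)
                    row["hmk"] = 1
                    if c.angle_records:
                        row["kh"] = 1
                        dist, ka, kb = _triangulation_fields(rng, h_obs)
                        row["ho"], row["ka"], row["kb"] = dist, ka, kb
                        row["wka"] = round(np.degrees(np.arctan(
                            (hcr_obs - 13.0) / (dist * np.cos(np.radians(
                                kb / 10.0))) - np.tan(np.radians(kb / 10.0))))
                            * 10)
                    else:
                        row["kh"] = 0
                        row["ho"] = float(np.round(h_obs))
                        row["ka"] = float(np.round(hcr_obs))
                obs_rows.append(row)
            # thinning after the survey
            if c.thin_frac > 0:
                candidates = sorted(standing)
                for num in candidates:
                    if len(standing) <= 4:
                        break
                    if rng.random() < c.thin_frac:
                        code = int(rng.choice([1, 1, 1, 2, 9]))
                        removed[num] = (c.date, code)
                        standing.discard(num)

        # crown radii at the mapping campaign
        map_camp = next((c for c in campaigns if c.year == config.map_year),
                        campaigns[-1])
        tmap = decimal_year(map_camp.date)
        for num in sorted(standing):
            d_true = truth.d_at(pspec.plot, num, tmap)
            radii = {f"d{b}": round(max(
                0.012 * d_true * (1 + rng.normal(0, 0.1)), 0.1), 2)
                for b in (17, 62, 107, 152, 197, 242, 287, 332)}
            crown_rows.append({"plot": pspec.plot, "tree": num,
                               "year": map_camp.year, "obs": map_camp.obs,
                               **radii})

        # stem discs: survivors felled at the final survey
        survivors = sorted(standing)
        n_disc = min(config.n_disc_trees, len(survivors))
        disc_trees = list(rng.choice(survivors, size=n_disc, replace=False))
        t_final = t_camps[-1]
        for num in disc_trees:
            tr = by_num[num]
            key = (pspec.plot, num)
            germ = tr["germ"]
            h_final_dm = truth.h_base_at(*key, t_final)
            heights_m = [1.3]
            z = config.disc_step_m
            while z * 10 < 0.7 * h_final_dm:
                heights_m.append(z)
                z += config.disc_step_m
            sa_tree_rows.append({
                "plot": pspec.plot, "tree": num, "species": tr["species"],
                "dbh": round(truth.d_at(*key, t_final) / 10.0, 1),
                "height": round(h_final_dm / 10.0, 1),
                "hKrown": round(truth.hcr_at(*key, t_final) / 10.0, 1)})
            years, d_end, h_fn, _, _ = truth._curves[key]
            for disc_id, z_m in enumerate(heights_m, start=1):
                sa_disc_rows.append({"plot": pspec.plot, "tree": num,
                                     "disc": disc_id, "h": z_m})
                # age when the top passed this height
                z_dm = z_m * 10.0
                if h_fn(years[-1] - germ) <= z_dm:
                    continue
                if h_fn(0.5) >= z_dm:
                    age_z = 0.5
                else:
                    age_z = brentq(lambda a: h_fn(a) - z_dm, 0.5,
                                   years[-1] - germ)
                first_year = germ + int(np.ceil(age_z + 0.5))
                ring_years = [y for y in years if y >= first_year]
                prev = {d: 0.0 for d in "NESW"}
                for y in ring_years:
                    k = y - years[0]
                    h_now = h_fn(y - germ)
                    taper = np.sqrt(max((h_now - z_dm) / max(
                        h_now - 13.0, 1e-6), 0.0)) if z_m > 1.3 else 1.0
                    r_in = (d_end[k] / config.bark_factor) / 2.0 * taper
                    r_units = round(r_in * 100.0)  # 1/100 mm
                    for dname in "NESW":
                        ir = max(r_units - prev[dname], 0.0)
                        sa_ir_rows.append({
                            "plot": pspec.plot, "tree": num, "disc": disc_id,
                            "dir": dname, "year": y, "ir": ir})
                        prev[dname] = prev[dname] + ir
            # trunk profile at felling
            sec = {"plot": pspec.plot, "tree": num, "year": final_year,
                   "species": tr["species"],
                   "length": round(h_final_dm / 10.0, 1),
                   "dbh": round(truth.d_at(*key, t_final) / 10.0, 1),
                   "crownLength": round((h_final_dm - truth.hcr_at(
                       *key, t_final)) / 10.0, 1),
                   "crownWidth": round(0.0024 * truth.d_at(*key, t_final), 1)}
            for mi in range(1, 28):
                z_dm = mi * 10.0
                if z_dm >= h_final_dm:
                    sec[f"m{mi}"] = None
                else:
                    taper = np.sqrt(max((h_final_dm - z_dm)
                                        / max(h_final_dm - 13.0, 1e-6), 0.0))
                    sec[f"m{mi}"] = round(
                        truth.d_at(*key, t_final) * taper / 10.0, 1)
            sec_rows.append(sec)

        # register
        for tr in trees:
            num = tr["tree"]
            rd = removed.get(num)
            lon, lat = _lonlat_stub(tr["x"], tr["y"])
            pos_rows.append({
                "plot": pspec.plot, "tree": num, "x": tr["x"], "y": tr["y"],
                "z": config.altitude_m + 0.01 * tr["x"],
                "species": tr["species"],
                "posObs": rd is None or rd[0].year >= config.map_year,
                "germinationYear": tr["germ"], "core": True,
                "removeDate": rd[0] if rd else None,
                "removeal": rd[1] if rd else None,
                "lon": lon, "lat": lat})
            tree_rows.append({**{k: tr[k] for k in
                                 ("plot", "tree", "x", "y", "species",
                                  "germ", "node")},
                              "removed": removed.get(num)})

    def _frame(rows, schema_name):
        from .data_model import SCHEMAS
        cols = SCHEMAS[schema_name].column_names
        df = pd.DataFrame(rows, columns=cols)
        for c in SCHEMAS[schema_name].columns:
            if c.kind == "int":
                df[c.name] = pd.array(
                    [None if v is None or (isinstance(v, float)
                                           and np.isnan(v)) else int(v)
                     for v in df[c.name]], dtype="Int64")
            elif c.kind == "float":
                df[c.name] = pd.to_numeric(df[c.name]).astype(float)
            elif c.kind == "bool":
                df[c.name] = pd.array(df[c.name], dtype="boolean")
            elif c.kind == "date":
                df[c.name] = pd.to_datetime(df[c.name])
            else:
                df[c.name] = df[c.name].astype("string")
        return df

    tables = {
        "corner": _frame(corner_rows, "corner"),
        "area": _frame(area_rows, "area"),
        "pos": _frame(pos_rows, "pos"),
        "date": _frame(date_rows, "date"),
        "dbhObs": _frame(obs_rows, "dbhObs"),
        "crown": _frame(crown_rows, "crown"),
        "secDiam": _frame(sec_rows, "secDiam"),
        "saTree": _frame(sa_tree_rows, "saTree"),
        "saIr": _frame(sa_ir_rows, "saIr"),
        "saDisc": _frame(sa_disc_rows, "saDisc"),
    }
    truth.trees = pd.DataFrame(tree_rows)
    return truth, tables


# ---------------------------------------------------------------------------
# recovery scoring

def score_recovery(truth: SyntheticTruth, output: pd.DataFrame,
                   *, tol: float = 1e-6) -> dict:
    """Compare a processed dhc-style frame against the generator truth.

    ``output`` needs plot, tree, year, obs, t and any of d (mm), h (dm),
    hCr (dm). Returns per-variable RMSE/bias at the campaign dates plus
    invariant-violation counts (monotonicity, crown base above height,
    coverage of the calendar between each tree's first and last record).
    """
    report: dict = {"n_rows": int(len(output))}
    known = set(truth._curves)
    keys = set(zip(output["plot"], output["tree"]))
    if not keys <= known:
        raise ValueError("output contains trees unknown to the truth")
    for var, getter in (("d", truth.d_at), ("h", truth.h_at),
                        ("hCr", truth.hcr_at)):
        if var not in output.columns:
            continue
        sub = output[output[var].notna()]
        err = np.array([float(row[var]) - getter(row["plot"], row["tree"],
                                                 row["t"])
                        for _, row in sub.iterrows()])
        if err.size:
            report[f"{var}_rmse"] = float(np.sqrt(np.mean(err ** 2)))
            report[f"{var}_bias"] = float(np.mean(err))
    # invariants
    breaks = {}
    for e in truth.events:
        if e["kind"] == "crown_break":
            breaks.setdefault((e["plot"], e["tree"]), []).append(e["t"])
    d_viol = h_viol = hcr_viol = bound_viol = gaps = 0
    for (p, tr), grp in output.groupby(["plot", "tree"]):
        grp = grp.sort_values("t")
        t = grp["t"].to_numpy()
        if "d" in grp and np.any(np.diff(grp["d"].to_numpy()) < -tol):
            d_viol += 1
        if "h" in grp:
            h = grp["h"].to_numpy()
            btimes = breaks.get((p, tr), [])
            for a in range(1, len(h)):
                if h[a] < h[a - 1] - tol:
                    crossed = any(t[a - 1] < tb <= t[a] for tb in btimes)
                    if not crossed:
                        h_viol += 1
        if "hCr" in grp:
            if np.any(np.diff(grp["hCr"].to_numpy()) < -tol):
                hcr_viol += 1
            if "h" in grp and np.any(grp["hCr"].to_numpy()
                                     > grp["h"].to_numpy() + tol):
                bound_viol += 1
        if "d" in grp:
            gaps += int(grp["d"].isna().sum())
    report.update({
        "d_monotone_violations": d_viol,
        "h_monotone_violations": h_viol,
        "hCr_monotone_violations": hcr_viol,
        "hCr_above_h_violations": bound_viol,
        "missing_values": gaps,
    })
    return report
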