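"""Generator: determinism, schema validity, truth consistency, scoring."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import dendroclean as dc
from dendroclean.diameter import StemDiscGrowth
from dendroclean.synthetic import simulate_stand


def test_same_seed_reproduces_identical_tables(small_stand):
    cfg, _, tables = small_stand
    _, again = simulate_stand(cfg, seed=42)
    for name in tables:
        pd.testing.assert_frame_equal(tables[name], again[name])


def test_different_seed_changes_observations(small_stand):
    cfg, _, tables = small_stand
    _, other = simulate_stand(cfg, seed=43)
    assert not tables["dbhObs"]["dbh"].equals(other["dbhObs"]["dbh"])


def test_generated_dataset_passes_validation(small_stand):
    _, _, tables = small_stand
    assert dc.validate_dataset(tables) == []


def test_disc_ring_sums_match_inside_bark_truth(small_stand):
    cfg, truth, tables = small_stand
    keys = tables["saDisc"][["plot", "tree"]].drop_duplicates()
    for _, row in keys.iterrows():
        p, tr = int(row["plot"]), int(row["tree"])
        g = StemDiscGrowth.from_tables(tables["saIr"], tables["saDisc"],
                                       p, tr)
        disc = g.breast_height_disc()
        years = g.discs[disc]["years"]
        for year in (years[0] + 2, years[-1] // 2 * 2, years[-1]):
            if year < years[0]:
                continue
            d_inside = g.inside_diameter_at(year + 0.999, disc)
            d_truth = truth.d_at(p, tr, year + 0.999) / cfg.bark_factor
            assert d_inside == pytest.approx(d_truth, abs=0.02)


def test_zero_noise_zero_bias_observations_equal_truth():
    cfg = dc.SimulationConfig().with_(plots=(dc.PlotSpec(1, (2.0, 2.0), 5, 5),))
    camps = tuple(dataclasses.replace(
        c, d_bias=0.0, d_sd=0.0, round_probs=(1.0, 0.0, 0.0),
        h_bias=0.0, h_sd=0.0, h_sample=1.0, angle_records=False,
        thin_frac=0.0) for c in cfg.campaigns)
    cfg = cfg.with_(campaigns=camps, missing_d_rate=0.0, tape_extra=1.0,
                    crown_break_hazard=0.0)
    truth, tables = simulate_stand(cfg, seed=7)
    dates = tables["date"].copy()
    dates["t"] = dates["date"].map(dc.decimal_year)
    obs = tables["dbhObs"].merge(dates[["plot", "year", "obs", "t"]],
                                 on=["plot", "year", "obs"])
    for _, r in obs.iterrows():
        d_true = truth.d_at(int(r["plot"]), int(r["tree"]), float(r["t"]))
        d_obs = (float(r["dbh"]) + float(r["dbh2"])) / 2 \
            if pd.notna(r["dbh2"]) else float(r["dbh"])
        assert d_obs == pytest.approx(d_true, abs=0.51)  # 1 mm rounding
        h_true = truth.h_at(int(r["plot"]), int(r["tree"]), float(r["t"]))
        assert float(r["ho"]) == pytest.approx(h_true, abs=0.51)


def test_truth_curves_monotone_except_breaks(small_stand):
    _, truth, tables = small_stand
    dates = tables["date"]
    ts = sorted(dc.decimal_year(d) for d in dates["date"].unique())
    breaks = {}
    for e in truth.events:
        breaks.setdefault((e["plot"], e["tree"]), []).append(e["t"])
    for key in list(truth._curves)[:20]:
        d = [truth.d_at(*key, t) for t in ts]
        assert np.all(np.diff(d) >= -1e-9)
        h = [truth.h_at(*key, t) for t in ts]
        for a in range(1, len(h)):
            if h[a] < h[a - 1] - 1e-9:
                assert any(ts[a - 1] < tb <= ts[a]
                           for tb in breaks.get(key, []))
        hcr = [truth.hcr_at(*key, t) for t in ts]
        assert np.all(np.diff(hcr) >= -1e-9)
        assert np.all(np.array(hcr) <= np.array(h) + 1e-9)


def test_calliper_era_diameters_exceed_inside_bark_truth(small_stand):
    """Observed calliper diameters should run ~7% above the inside-bark
    truth on average (the configured bark/shrinkage factor)."""
    cfg, truth, tables = small_stand
    dates = tables["date"].copy()
    dates["t"] = dates["date"].map(dc.decimal_year)
    obs = tables["dbhObs"].merge(dates[["plot", "year", "obs", "t"]],
                                 on=["plot", "year", "obs"])
    obs = obs[(obs["year"] < 1978) & obs["dbh"].notna()]
    rel = []
    for _, r in obs.iterrows():
        d_in = truth.d_at(int(r["plot"]), int(r["tree"]),
                          float(r["t"])) / cfg.bark_factor
        d_obs = (float(r["dbh"]) + float(r["dbh2"])) / 2 \
            if pd.notna(r["dbh2"]) else float(r["dbh"])
        if d_in > 0:
            rel.append(d_obs / d_in - 1)
    assert np.mean(rel) == pytest.approx(0.07, abs=0.03)


class TestScoreRecovery:
    def _truth_frame(self, truth, tables):
        dates = tables["date"].copy()
        dates["t"] = dates["date"].map(dc.decimal_year)
        rows = []
        for (p, tr) in list(truth._curves)[:10]:
            for _, drow in dates.iterrows():
                t = float(drow["t"])
                rows.append({"plot": p, "tree": tr, "year": int(drow["year"]),
                             "obs": int(drow["obs"]), "t": t,
                             "d": truth.d_at(p, tr, t),
                             "h": truth.h_at(p, tr, t),
                             "hCr": truth.hcr_at(p, tr, t)})
        return pd.DataFrame(rows)

    def test_perfect_output_scores_zero(self, small_stand):
        _, truth, tables = small_stand
        out = self._truth_frame(truth, tables)
        rep = dc.score_recovery(truth, out)
        assert rep["d_rmse"] == pytest.approx(0.0, abs=1e-9)
        assert rep["h_monotone_violations"] == 0
        assert rep["hCr_above_h_violations"] == 0

    def test_constant_offset_scores_as_bias(self, small_stand):
        _, truth, tables = small_stand
        out = self._truth_frame(truth, tables)
        out["d"] = out["d"] + 1.0
        rep = dc.score_recovery(truth, out)
        assert rep["d_bias"] == pytest.approx(1.0, abs=1e-9)
        assert rep["d_rmse"] == pytest.approx(1.0, abs=1e-9)

    def test_unknown_tree_rejected(self, small_stand):
        _, truth, tables = small_stand
        out = self._truth_frame(truth, tables)
        out.loc[out.index[0], "tree"] = 424242
        with pytest.raises(ValueError):
            dc.score_recovery(truth, out)
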