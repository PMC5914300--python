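"""Diameter stage: disc references, levelling, filters, completion."""

import numpy as np
import pandas as pd
import pytest

import dendroclean as dc
from dendroclean.diameter import (StemDiscGrowth,
                                  build_disc_references,
                                  build_observation_frame,
                                  calibration_factors, complete_series,
                                  disc_equivalent_diameter, enforce_monotone,
                                  fill_gaps, filter_diameter_outliers,
                                  level_systematic_bias, observed_diameter,
                                  season_fraction)


def test_observed_diameter_rules():
    assert observed_diameter(100, 110) == 105.0
    assert observed_diameter(100) == 100.0
    with pytest.raises(ValueError):
        observed_diameter(np.nan, 110.0)


def test_disc_equivalent_diameter_examples():
    assert disc_equivalent_diameter([7, 7, 7, 7]) == pytest.approx(14.0)
    assert disc_equivalent_diameter([10, 10, 20, 20]) == pytest.approx(
        2 * np.sqrt(250), rel=1e-12)
    r = 9.0
    assert disc_equivalent_diameter([0, r, r, r]) == pytest.approx(
        r * np.sqrt(3), rel=1e-12)


def test_season_fraction_boundaries():
    assert season_fraction(1950.999) == pytest.approx(1.0)  # Dec 31
    assert season_fraction(1950 + 121 / 365.25) == pytest.approx(0.0,
                                                                 abs=0.01)
    # Jul 1 is 61 days into the 123-day season
    jul1 = 1950 + 182 / 365.25
    assert season_fraction(jul1) == pytest.approx(61 / 123, abs=0.01)
    assert season_fraction(1950.05) == 0.0  # winter


def make_disc_growth(years, ring_mm, h=1.3):
    """One disc, four equal directions with the given ring widths (mm)."""
    rows = []
    for d in "NESW":
        for y, ir in zip(years, ring_mm):
            rows.append({"plot": 1, "tree": 1, "disc": 1, "dir": d,
                         "year": y, "ir": ir * 100})
    sa_ir = pd.DataFrame(rows)
    sa_disc = pd.DataFrame([{"plot": 1, "tree": 1, "disc": 1, "h": h}])
    return StemDiscGrowth.from_tables(sa_ir, sa_disc, 1, 1)


def test_disc_diameter_season_accrual_and_bark_factor():
    g = make_disc_growth([1950, 1951], [5.0, 2.0])
    # end of 1951: radius 7 mm -> diameter 14 mm inside bark
    assert g.diameter_at(1951.99) == pytest.approx(14.0 * 1.070)
    # May 1 of 1951: only the 1950 ring
    may1 = 1951 + 121 / 365.25
    assert g.diameter_at(may1) == pytest.approx(10.0 * 1.070, rel=1e-3)
    # Jul 1: 61/123 of the 1951 ring accrued
    jul1 = 1951 + 182 / 365.25
    expect = (10.0 + 4.0 * 61 / 123) * 1.070
    assert g.diameter_at(jul1) == pytest.approx(expect, rel=1e-2)
    with pytest.raises(ValueError):
        g.diameter_at(1949.5)


def test_levelling_removes_uniform_inflation_exactly():
    g = make_disc_growth([1950, 1951], [5.0, 2.0])
    refs = {(1, 1): g}
    t = 1951.999
    d_ref = g.diameter_at(t)
    obs = pd.DataFrame({
        "plot": [1, 1, 1], "tree": [1, 2, 3], "year": [1951] * 3,
        "obs": [1] * 3, "t": [t] * 3,
        "d": [d_ref * 1.1, 200 * 1.1, 150 * 1.1]})  # all BAs +21% (d +10%)
    lev, fac = level_systematic_bias(obs, refs)
    assert fac.loc[0, "ba_factor"] == pytest.approx(1.1 ** 2)
    assert lev["d_lev"].to_numpy() == pytest.approx([d_ref, 200.0, 150.0])


def test_levelling_without_references_flags_factor_one():
    obs = pd.DataFrame({"plot": [1], "tree": [5], "year": [1950],
                        "obs": [1], "t": [1950.9], "d": [123.0]})
    lev, fac = level_systematic_bias(obs, {})
    assert fac.loc[0, "no_reference"]
    assert lev.loc[0, "d_lev"] == 123.0


def test_outlier_filter_examples():
    t = np.arange(10, dtype=float)
    d = 100 + 8 * t  # 8 mm/yr: plausible
    keep, flagged = filter_diameter_outliers(t, d)
    assert keep.all() and not flagged.any()

    d2 = d.copy()
    d2[5] = d2[4] - 12  # -12 mm drop
    keep, flagged = filter_diameter_outliers(t, d2)
    assert not keep[5] and flagged[5]
    assert keep.sum() == 9

    # two-point series: flagged but retained
    keep, flagged = filter_diameter_outliers([0.0, 1.0], [100.0, 80.0])
    assert keep.all() and flagged[1]


def test_outlier_filter_rate_thresholds():
    # -4 mm over 0.5 yr = -8 mm/yr < -5.4 mm/yr: violates the rate rule
    t = np.array([0.0, 1.0, 1.5, 2.5, 3.5])
    d = np.array([100.0, 108.0, 104.0, 112.0, 120.0])
    keep, flagged = filter_diameter_outliers(t, d)
    assert not keep[2]
    # +9 mm over 1 yr: fine
    keep, _ = filter_diameter_outliers([0.0, 1.0, 2.0, 3.0],
                                       [100.0, 109.0, 118.0, 127.0])
    assert keep.all()


def test_fill_gaps_passes_through_knots_and_stays_monotone():
    t = np.array([0.0, 2.0, 5.0, 9.0])
    d = np.array([100.0, 130.0, 135.0, 180.0])
    grid = np.linspace(0, 9, 500)
    out = fill_gaps(t, d, grid)
    knots = fill_gaps(t, d, t)
    assert knots == pytest.approx(d, rel=1e-12)
    assert np.all(np.diff(out) >= -1e-9)
    with pytest.raises(ValueError):
        fill_gaps(t, d, np.array([-1.0]))


def test_fill_gap_midway_between_equal_values_is_constant():
    out = fill_gaps([0.0, 2.0], [150.0, 150.0], [1.0])
    assert out[0] == pytest.approx(150.0)


def test_enforce_monotone_pava_then_linearised_flat_run():
    t = np.arange(4, dtype=float)
    out = enforce_monotone(t, [10.0, 12.0, 11.0, 13.0])
    # PAVA pools (12, 11) -> 11.5, then the flat pair is linearised
    assert out == pytest.approx([10.0, 11.0, 12.0, 13.0])
    inc = [10.0, 11.0, 14.0]
    assert enforce_monotone(np.arange(3.0), inc) == pytest.approx(inc)
    same = [5.0, 5.0, 5.0]
    assert enforce_monotone(np.arange(3.0), same) == pytest.approx(same)


def test_complete_series_covers_all_interior_calendar_dates():
    t_obs = [1923.7, 1936.7, 1947.7, 1960.7]
    d_obs = [100.0, 160.0, 200.0, 260.0]
    cal = [1923.7, 1929.7, 1936.7, 1942.7, 1947.7, 1952.7, 1960.7, 1970.7]
    t_all, d_all, filled = complete_series(t_obs, d_obs, cal)
    assert set(np.round(t_all, 6)) == set(np.round(cal[:-1], 6))
    assert np.all(np.diff(d_all) >= -1e-9)
    assert filled.sum() == 3  # 1929.7, 1942.7, 1952.7


def test_calibration_factor_recovered_from_biased_synthetic_stand():
    """Calliper readings generated 7% above the inside-bark disc truth must
    reproduce a ~0.07 median relative difference (and ~0.082 for tape)."""
    cfg = dc.SimulationConfig().with_(
        plots=(dc.PlotSpec(1, (1.5, 1.5), 7, 7),),
        missing_d_rate=0.0, n_disc_trees=6)
    _, tables = dc.simulate_stand(cfg, seed=5)
    obs = build_observation_frame(tables)
    refs = build_disc_references(tables)
    fac = calibration_factors(obs, refs)
    assert fac["calliper"] == pytest.approx(0.070, abs=0.02)
    assert fac["tape"] == pytest.approx(0.082, abs=0.02)


def test_pipeline_beats_raw_on_biased_stand():
    from conftest import calliper_bias_config
    cfg = calliper_bias_config(bias=0.07, noise=0.02)
    truth, tables = dc.simulate_stand(cfg, seed=11)
    rec, factors = dc.run_diameter_pipeline(tables)
    obs = build_observation_frame(tables)
    clean = np.array([r.d - truth.d_at(r.plot, r.tree, r.t)
                      for r in rec.itertuples()])
    raw = np.array([r.d - truth.d_at(r.plot, r.tree, r.t)
                    for r in obs.itertuples()])
    assert np.sqrt(np.mean(clean ** 2)) < np.sqrt(np.mean(raw ** 2))
    # groups with references are levelled close to truth
    with_ref = factors[~factors["no_reference"]]
    assert (with_ref["ba_factor"] - 1.07 ** 2).abs().median() < 0.05
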