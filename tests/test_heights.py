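"""Height stage: filters, disc references, height-age model, anchoring."""

import numpy as np
import pandas as pd
import pytest

from dendroclean.heights import (HeightAgeModel, anchor_to_observations,
                                 disc_height_age, filter_height_outliers,
                                 finalize_heights, level_height_bias,
                                 segment_isotonic)
from dendroclean.diameter import StemDiscGrowth

TRUE_PARAMS = (75.0, 1.2, -6.0, 2.0)


class TestHeightAgeModel:
    def test_noiseless_parameters_recovered_to_4_significant_digits(self):
        ages = np.linspace(10, 109, 40)
        h = HeightAgeModel.curve(ages, *TRUE_PARAMS)
        m = HeightAgeModel().fit(ages, h)
        assert m.params_ == pytest.approx(TRUE_PARAMS, rel=1e-4)

    def test_h100_within_3pct_under_noise(self):
        rng = np.random.default_rng(21)
        ages = rng.uniform(15, 109, 200)
        h = HeightAgeModel.curve(ages, *TRUE_PARAMS) * (
            1 + rng.normal(0, 0.02, 200))
        m = HeightAgeModel().fit(ages, h)
        for age in (20, 50, 100, 109):
            truth = HeightAgeModel.curve(age, *TRUE_PARAMS)
            assert m.predict(age) == pytest.approx(truth, rel=0.03)

    def test_constant_heights_raise(self):
        with pytest.raises(RuntimeError):
            HeightAgeModel().fit([10, 20, 30, 40], [100.0] * 4)

    def test_too_few_ages_raise(self):
        with pytest.raises(ValueError):
            HeightAgeModel().fit([10, 10, 20, 20], [50, 51, 80, 81])

    def test_fitted_curve_monotone_on_data_range(self):
        rng = np.random.default_rng(2)
        ages = rng.uniform(20, 100, 80)
        h = HeightAgeModel.curve(ages, *TRUE_PARAMS) + rng.normal(0, 5, 80)
        m = HeightAgeModel().fit(ages, h)
        grid = np.linspace(20, 100, 300)
        assert np.all(np.diff(m.predict(grid)) >= -1e-9)


class TestOutlierFilter:
    def test_large_drop_with_recorded_break_retained(self):
        t = np.array([0.0, 5.0, 10.0])
        h = np.array([200.0, 188.0, 195.0])
        keep = filter_height_outliers(t, h, [False, True, False])
        assert keep.all()

    def test_large_drop_without_break_removes_later_point(self):
        t = np.array([0.0, 5.0, 10.0])
        h = np.array([200.0, 188.0, 205.0])
        keep = filter_height_outliers(t, h, [False, False, False])
        assert list(keep) == [True, False, True]

    def test_subthreshold_rise_retained(self):
        keep = filter_height_outliers([0.0, 1.0], [200.0, 209.0])
        assert keep.all()

    def test_superthreshold_rise_removed(self):
        keep = filter_height_outliers([0.0, 1.0, 2.0],
                                      [200.0, 215.0, 216.0])
        assert list(keep) == [True, False, True]


def make_two_disc_tree(first_years=(1900, 1910), heights=(0.5, 5.0)):
    rows = []
    for disc, (y0, h) in enumerate(zip(first_years, heights), start=1):
        for d in "NESW":
            for y in range(y0, 1931):
                rows.append({"plot": 1, "tree": 1, "disc": disc, "dir": d,
                             "year": y, "ir": 100})
    sa_ir = pd.DataFrame(rows)
    sa_disc = pd.DataFrame([{"plot": 1, "tree": 1, "disc": d, "h": h}
                            for d, h in zip((1, 2), heights)])
    return StemDiscGrowth.from_tables(sa_ir, sa_disc, 1, 1)


class TestDiscHeightAge:
    def test_knots_and_half_year_offset(self):
        g = make_two_disc_tree()
        fn, (lo, hi) = disc_height_age(g, germination_year=1890)
        # disc 1: first ring 1900 -> age 9.5 at 5 dm; disc 2: 19.5 at 50 dm
        assert (lo, hi) == (9.5, 19.5)
        assert fn(9.5) == pytest.approx(5.0)
        assert fn(19.5) == pytest.approx(50.0)
        mid = fn(14.5)
        assert 5.0 < mid < 50.0

    def test_single_disc_insufficient(self):
        g = make_two_disc_tree()
        g.discs.pop(2)
        with pytest.raises(ValueError):
            disc_height_age(g, 1890)

    def test_inconsistent_ring_counts_rejected(self):
        # the higher disc starts EARLIER than the lower one: impossible
        g = make_two_disc_tree(first_years=(1910, 1900))
        with pytest.raises(ValueError):
            disc_height_age(g, 1890)


def test_level_height_bias_recovers_uniform_deficit():
    fn = lambda age: 10.0 * age  # reference: dm
    refs = {(1, 1): (fn, (0.0, 100.0))}
    germ = {(1, 1): 1900, (1, 2): 1900}
    t = 1950.0
    obs = pd.DataFrame({
        "plot": [1, 1], "tree": [1, 2], "year": [1950, 1950],
        "obs": [1, 1], "t": [t, t],
        "h": [500.0 * 0.95, 300.0]})  # tree 1 measured 5% low
    lev, fac = level_height_bias(obs, refs, germ)
    assert fac.loc[0, "h_factor"] == pytest.approx(1 / 0.95, rel=1e-9)
    assert lev.loc[0, "h_lev"] == pytest.approx(500.0)
    assert lev.loc[1, "h_lev"] == pytest.approx(300.0 / 0.95)


def test_segment_isotonic_respects_breaks():
    t = np.arange(6, dtype=float)
    h = np.array([100.0, 110.0, 108.0, 80.0, 85.0, 83.0])
    out = segment_isotonic(t, h, break_times=[2.5])
    assert out[:3] == pytest.approx([100.0, 109.0, 109.0])
    assert out[3] == pytest.approx(80.0)
    assert np.all(np.diff(out[3:]) >= 0)
    assert out[3] < out[2]  # the break-induced decrease survives


class TestAnchoring:
    def test_identity_when_smooth_equals_observations(self):
        t = np.linspace(0, 10, 11)
        h = 100 + 5 * t
        out = anchor_to_observations(t, h, t[::2], h[::2])
        assert out == pytest.approx(h)

    def test_single_anchor_gives_constant_multiplier(self):
        t = np.linspace(0, 10, 11)
        h = 100 + 5 * t
        out = anchor_to_observations(t, h, [4.0], [h[4] * 1.1])
        assert out == pytest.approx(h * 1.1)

    def test_multiplier_interpolates_linearly_between_anchors(self):
        t = np.array([0.0, 5.0, 10.0])
        h = np.array([100.0, 100.0, 100.0])
        out = anchor_to_observations(t, h, [0.0, 10.0], [95.0, 105.0])
        assert out[1] == pytest.approx(100.0)  # m = 1.00 at the midpoint

    def test_anchored_curve_reproduces_every_anchor_exactly(self):
        rng = np.random.default_rng(8)
        t = np.linspace(0, 20, 21)
        h = 50 + 10 * np.sqrt(t + 1)
        ta = np.array([2.0, 9.0, 17.0])
        ha = np.interp(ta, t, h) * rng.uniform(0.9, 1.1, 3)
        out = anchor_to_observations(t, h, ta, ha)
        assert np.interp(ta, t, out) == pytest.approx(ha, rel=1e-9)

    def test_no_anchors_is_identity(self):
        t = np.arange(5.0)
        h = np.array([10.0, 11, 12, 13, 14.0])
        assert anchor_to_observations(t, h, [], []) == pytest.approx(h)


class TestFinalize:
    def test_strictly_increasing_input_unchanged(self):
        t = np.arange(5.0)
        h = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert finalize_heights(t, h) == pytest.approx(h)

    def test_flat_triple_redistributed_through_mean_date(self):
        t = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        v = np.array([99.0, 100.0, 100.0, 100.0, 101.0])
        out = finalize_heights(t, v)
        assert out[2] == pytest.approx(100.0)  # run mean date is t=2
        assert np.all(np.diff(out) >= 0)
        assert out[1] < 100.0 < out[3]

    def test_decrease_across_recorded_break_preserved(self):
        t = np.arange(4.0)
        h = np.array([100.0, 110.0, 70.0, 80.0])
        out = finalize_heights(t, h, break_times=[1.5])
        assert out[2] < out[1]
        assert np.all(np.diff(out[:2]) >= 0)
        assert np.all(np.diff(out[2:]) >= 0)
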