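"""Raster reconstruction, serpentine placement, corner correction."""

import numpy as np
import pytest

from dendroclean.spatial import (RasterFit, SerpentineNumbering,
                                 correct_corners, estimate_removed_positions,
                                 fit_raster)


def grid_points(n=10, sx=1.5, sy=1.5, origin=(0.0, 0.0), noise=0.0, rng=None):
    ii, jj = np.meshgrid(np.arange(n), np.arange(n))
    pts = np.column_stack([origin[0] + ii.ravel() * sx,
                           origin[1] + jj.ravel() * sy])
    if noise and rng is not None:
        pts = pts + rng.normal(0, noise, pts.shape)
    return pts


def test_exact_grid_recovered_perfectly():
    fit = fit_raster(grid_points(), (1.5, 1.5))
    assert fit.spacing_x == pytest.approx(1.5, abs=1e-9)
    assert fit.spacing_y == pytest.approx(1.5, abs=1e-9)
    assert fit.rms_residual == pytest.approx(0.0, abs=1e-9)


def test_fit_is_translation_invariant():
    rng = np.random.default_rng(5)
    a = fit_raster(grid_points(noise=0.03, rng=np.random.default_rng(5)),
                   (1.5, 1.5))
    b = fit_raster(grid_points(origin=(503.7, -211.9), noise=0.03,
                               rng=np.random.default_rng(5)), (1.5, 1.5))
    assert a.spacing_x == pytest.approx(b.spacing_x, abs=1e-6)
    assert a.spacing_y == pytest.approx(b.spacing_y, abs=1e-6)
    assert a.rms_residual == pytest.approx(b.rms_residual, abs=1e-6)


def test_spacing_converges_to_truth_as_noise_vanishes():
    errs = []
    for sigma in (0.1, 0.05, 0.01, 0.0):
        rng = np.random.default_rng(17)
        fit = fit_raster(grid_points(noise=sigma, rng=rng), (1.5, 1.5))
        errs.append(abs(fit.spacing_x - 1.5) + abs(fit.spacing_y - 1.5))
    assert errs == sorted(errs, reverse=True) or errs[-1] < 1e-9
    assert errs[-1] < 1e-9


def test_anisotropic_spacing_recovered():
    fit = fit_raster(grid_points(sx=1.0, sy=2.0), (1.0, 2.0))
    assert fit.spacing_x == pytest.approx(1.0, abs=1e-9)
    assert fit.spacing_y == pytest.approx(2.0, abs=1e-9)


def test_degenerate_inputs_rejected():
    with pytest.raises(ValueError):
        fit_raster([[0, 0], [1, 0], [2, 0]], (1, 1))
    collinear = np.column_stack([np.arange(6.0), np.zeros(6)])
    with pytest.raises(ValueError):
        fit_raster(collinear, (1, 1))


# ---------------------------------------------------------------------------
# serpentine numbering

def test_numbering_round_trips_over_all_variants():
    for transpose in (False, True):
        for flip_rows in (False, True):
            for flip_start in (False, True):
                num = SerpentineNumbering(5, 4, transpose, flip_rows,
                                          flip_start, offset=10)
                seen = set()
                for i in range(5):
                    for j in range(4):
                        n = num.number_of(i, j)
                        assert num.node_of(n) == (i, j)
                        seen.add(n)
                assert seen == set(range(11, 31))


def test_missing_number_placed_at_its_skipped_node():
    num = SerpentineNumbering(4, 4)
    raster = RasterFit((0.0, 0.0), 1.0, 1.0, 0.0, 0.0)
    missing = 7
    node = num.node_of(missing)
    placed = estimate_removed_positions([missing], raster, num, [node],
                                        seed=0)
    assert placed[0]["node"] == node
    assert placed[0]["on_pattern"]


def test_no_vacant_nodes_is_an_error():
    num = SerpentineNumbering(2, 2)
    raster = RasterFit((0.0, 0.0), 1.0, 1.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        estimate_removed_positions([1], raster, num, [], seed=0)


def test_serpentine_recovery_with_20pct_removals():
    rng = np.random.default_rng(3)
    num = SerpentineNumbering(10, 10)
    raster = RasterFit((0.0, 0.0), 1.5, 1.5, 0.0, 0.0)
    removed = set(rng.choice(100, 20, replace=False) + 1)
    vacant = [num.node_of(n) for n in sorted(removed)]
    placed = estimate_removed_positions(sorted(removed), raster, num, vacant,
                                        seed=1)
    correct = sum(num.number_of(*p["node"]) == p["tree"] for p in placed)
    assert correct / len(placed) >= 0.95


def test_placement_reproducible_under_fixed_seed():
    num = SerpentineNumbering(6, 6)
    raster = RasterFit((0.0, 0.0), 1.0, 1.0, 0.0, 0.0)
    vacant = [(i, j) for i in range(6) for j in range(3)]
    trees = [100, 101, 102, 103]  # all off-pattern
    a = estimate_removed_positions(trees, raster, num, vacant, seed=9)
    b = estimate_removed_positions(trees, raster, num, vacant, seed=9)
    assert a == b


def test_numbering_inferred_from_measured_trees():
    true = SerpentineNumbering(8, 8, transpose=False, flip_rows=True,
                               flip_start=False, offset=3)
    nodes = [(i, j) for i in range(8) for j in range(8)]
    numbers = [true.number_of(i, j) for i, j in nodes]
    got = SerpentineNumbering.infer(numbers[::2], nodes[::2], 8, 8)
    assert all(got.number_of(i, j) == true.number_of(i, j)
               for i, j in nodes)


# ---------------------------------------------------------------------------
# corners

def test_midrow_corners_left_unchanged_and_unit_square_area():
    raster = RasterFit((0.0, 0.0), 1.0, 1.0, 0.0, 0.0)
    corners = np.array([[-0.5, -0.5], [0.5, -0.5], [0.5, 0.5], [-0.5, 0.5]])
    out, changed, area = correct_corners(corners, raster)
    assert not changed.any()
    assert np.allclose(out, corners)
    assert area == pytest.approx(1.0)


def test_offset_corner_snapped_to_midrow_line():
    raster = RasterFit((0.0, 0.0), 1.0, 1.0, 0.0, 0.0)
    corners = np.array([[-0.5, -0.5], [3.5, -0.5], [3.5, 3.5],
                        [-0.3, 3.5]])  # last corner 0.2 m off the mid-row
    out, changed, area = correct_corners(corners, raster)
    assert changed[3] and not changed[:3].any()
    assert np.allclose(out[3], [-0.5, 3.5])
    assert area == pytest.approx(16.0)


def test_degenerate_polygon_rejected():
    raster = RasterFit((0.0, 0.0), 1.0, 1.0, 0.0, 0.0)
    corners = np.array([[-0.5, -0.5], [0.5, 0.5], [0.5, -0.5], [-0.5, 0.5]])
    with pytest.raises(ValueError):
        correct_corners(corners, raster)
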