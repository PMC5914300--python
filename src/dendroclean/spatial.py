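"""Planting-raster reconstruction and tree-position estimation.

The trial was planted on rectangular rasters (one spacing per plot), but only
the trees still standing at the 1988 mapping have measured coordinates. This
module recovers the raster (origin, two spacings, a small orientation angle)
from the mapped positions, snaps plot corners onto the mid-row lines, and
places trees removed before mapping on vacant raster nodes — on the node
implied by the 1923/25 serpentine numbering scheme when the tree number fits
that pattern, otherwise uniformly at random on the remaining vacancies.

The raster fit is an alternating (grid-constrained ICP) scheme: assign each
mapped tree to its nearest raster node, least-squares update the raster
parameters for that assignment, repeat until the assignment is stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from shapely.geometry import Polygon

__all__ = [
    "RasterFit",
    "SerpentineNumbering",
    "fit_raster",
    "estimate_removed_positions",
    "correct_corners",
]

MAX_ORIENTATION_RAD = np.deg2rad(5.0)


@dataclass(frozen=True)
class RasterFit:
    origin: tuple[float, float]
    spacing_x: float
    spacing_y: float
    orientation: float  # radians
    rms_residual: float
    n_iterations: int = 0

    def __post_init__(self):
        if self.spacing_x <= 0 or self.spacing_y <= 0:
            raise ValueError("spacings must be positive")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be non-negative")

    def _rotation(self) -> np.ndarray:
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        return np.array([[c, -s], [s, c]])

    def node_xy(self, i, j) -> np.ndarray:
        """Projected coordinates of raster node (i, j)."""
        local = np.column_stack([np.asarray(i, dtype=float) * self.spacing_x,
                                 np.asarray(j, dtype=float) * self.spacing_y])
        return local @ self._rotation().T + np.asarray(self.origin)

    def nearest_node(self, points) -> np.ndarray:
        """Integer (i, j) of the nearest raster node for each point."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        local = (p - np.asarray(self.origin)) @ self._rotation()
        return np.column_stack([
            np.round(local[:, 0] / self.spacing_x).astype(int),
            np.round(local[:, 1] / self.spacing_y).astype(int)])


def _residuals(params, points, idx):
    x0, y0, theta, sx, sy = params
    c, s = np.cos(theta), np.sin(theta)
    lx = idx[:, 0] * sx
    ly = idx[:, 1] * sy
    px = x0 + c * lx - s * ly
    py = y0 + s * lx + c * ly
    return np.concatenate([px - points[:, 0], py - points[:, 1]])


def fit_raster(points, initial_spacing, *, max_iter: int = 100) -> RasterFit:
    """Fit origin, spacings and a small orientation to mapped positions.

    Alternates nearest-node assignment with a least-squares parameter update
    until the assignment stops changing. The orientation is bounded to |5°|;
    mapped coordinates are in a projected national system, so the planting
    rows are nearly axis-parallel but not exactly.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or len(points) < 4:
        raise ValueError("need at least 4 (x, y) positions")
    centred = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-8) < 2:
        raise ValueError("positions are collinear; raster is unidentifiable")
    sx0, sy0 = float(initial_spacing[0]), float(initial_spacing[1])
    if sx0 <= 0 or sy0 <= 0:
        raise ValueError("initial spacings must be positive")

    params = np.array([points[:, 0].min(), points[:, 1].min(), 0.0, sx0, sy0])
    lo = [-np.inf, -np.inf, -MAX_ORIENTATION_RAD, sx0 * 0.5, sy0 * 0.5]
    hi = [np.inf, np.inf, MAX_ORIENTATION_RAD, sx0 * 1.5, sy0 * 1.5]
    prev_idx = None
    for it in range(1, max_iter + 1):
        fit = RasterFit(origin=(params[0], params[1]), spacing_x=params[3],
                        spacing_y=params[4], orientation=params[2],
                        rms_residual=0.0)
        idx = fit.nearest_node(points)
        if prev_idx is not None and np.array_equal(idx, prev_idx):
            break
        prev_idx = idx
        sol = least_squares(_residuals, params, args=(points, idx),
                            bounds=(lo, hi))
        if not sol.success:
            raise RuntimeError(
                f"raster least-squares update failed at iteration {it}: "
                f"{sol.message}")
        params = sol.x
    else:
        raise RuntimeError(
            f"raster fit did not stabilise within {max_iter} iterations")
    res = _residuals(params, points, prev_idx)
    dx, dy = np.split(res, 2)
    rms = float(np.sqrt(np.mean(dx ** 2 + dy ** 2)))  # point-to-node distance
    # re-base so the smallest assigned index is (0, 0)
    imin, jmin = prev_idx.min(axis=0)
    base = RasterFit(origin=(params[0], params[1]), spacing_x=params[3],
                     spacing_y=params[4], orientation=params[2],
                     rms_residual=0.0)
    new_origin = base.node_xy([imin], [jmin])[0]
    return RasterFit(origin=(float(new_origin[0]), float(new_origin[1])),
                     spacing_x=float(params[3]), spacing_y=float(params[4]),
                     orientation=float(params[2]),
                     rms_residual=rms, n_iterations=it)


# ---------------------------------------------------------------------------
# serpentine (boustrophedon) numbering

@dataclass(frozen=True)
class SerpentineNumbering:
    """Tree numbering along planting rows with alternating direction.

    Rows (constant j) are walked in order; every other row is traversed
    backwards. ``transpose`` walks columns instead, ``flip_rows`` reverses
    the row order, ``flip_start`` reverses the direction of the first row.
    ``offset`` is added to the 1-based path position to give the tree number.
    """

    n_i: int
    n_j: int
    transpose: bool = False
    flip_rows: bool = False
    flip_start: bool = False
    offset: int = 0

    def number_of(self, i: int, j: int) -> int:
        if self.transpose:
            major, minor, n_minor = i, j, self.n_j
            n_major = self.n_i
        else:
            major, minor, n_minor = j, i, self.n_i
            n_major = self.n_j
        if self.flip_rows:
            major = n_major - 1 - major
        forward = (major % 2 == 0) != self.flip_start
        pos_in_row = minor if forward else n_minor - 1 - minor
        return self.offset + major * n_minor + pos_in_row + 1

    def node_of(self, number: int) -> tuple[int, int] | None:
        k = number - 1 - self.offset
        n_minor = self.n_i if not self.transpose else self.n_j
        n_major = self.n_j if not self.transpose else self.n_i
        if not 0 <= k < n_minor * n_major:
            return None
        major, pos = divmod(k, n_minor)
        forward = (major % 2 == 0) != self.flip_start
        minor = pos if forward else n_minor - 1 - pos
        if self.flip_rows:
            major = n_major - 1 - major
        return (minor, major) if not self.transpose else (major, minor)

    @classmethod
    def infer(cls, numbers, nodes, n_i: int, n_j: int) -> "SerpentineNumbering":
        """Pick the path variant that best explains measured tree numbers.

        ``nodes`` are the (i, j) raster indices of trees whose numbers are
        known. For each of the eight traversal variants the offset is taken
        as the most common difference between tree number and path position;
        the variant with the most exact matches wins.
        """
        numbers = np.asarray(numbers, dtype=int)
        best, best_score = None, -1
        for transpose in (False, True):
            for flip_rows in (False, True):
                for flip_start in (False, True):
                    cand = cls(n_i, n_j, transpose, flip_rows, flip_start, 0)
                    implied = np.array([cand.number_of(i, j)
                                        for i, j in nodes])
                    diffs, counts = np.unique(numbers - implied,
                                              return_counts=True)
                    off = int(diffs[np.argmax(counts)])
                    score = int(counts.max())
                    if score > best_score:
                        best_score = score
                        best = cls(n_i, n_j, transpose, flip_rows,
                                   flip_start, off)
        return best


def estimate_removed_positions(tree_numbers, raster: RasterFit,
                               numbering: SerpentineNumbering,
                               vacant_nodes, seed: int):
    """Place unmapped trees on vacant raster nodes.

    Trees whose number maps to a vacant node under the serpentine model go
    there; the rest are placed uniformly at random (seeded) on the remaining
    vacancies. Returns a list of dicts with tree, node, x, y and an
    ``on_pattern`` flag. No node is used twice.
    """
    vacant = {tuple(n) for n in vacant_nodes}
    tree_numbers = list(tree_numbers)
    if len(tree_numbers) > len(vacant):
        raise ValueError(
            f"{len(tree_numbers)} trees to place but only {len(vacant)} "
            "vacant nodes")
    placements, leftover = [], []
    for num in tree_numbers:
        node = numbering.node_of(int(num))
        if node is not None and node in vacant:
            vacant.discard(node)
            placements.append((num, node, True))
        else:
            leftover.append(num)
    rng = np.random.default_rng(seed)
    pool = sorted(vacant)
    rng.shuffle(pool)
    for num, node in zip(leftover, pool):
        placements.append((num, tuple(node), False))
    out = []
    for num, node, pattern in placements:
        xy = raster.node_xy([node[0]], [node[1]])[0]
        out.append({"tree": int(num), "node": node, "x": float(xy[0]),
                    "y": float(xy[1]), "on_pattern": pattern,
                    "posObs": False})
    return out


def correct_corners(corners, raster: RasterFit, *, tol: float = 1e-6):
    """Snap plot corners onto the mid-row lines of the raster.

    A plot border should run exactly between adjacent planting rows in both
    raster directions, i.e. at local coordinates (i+1/2)*spacing. Corners
    already there are kept (flagged unchanged); others are replaced by the
    nearest mid-row point. Returns (adjusted corners (4, 2), changed flags,
    polygon area in m²).
    """
    corners = np.asarray(corners, dtype=float)
    if corners.shape != (4, 2):
        raise ValueError("expected exactly 4 corners")
    R = raster._rotation()
    local = (corners - np.asarray(raster.origin)) @ R
    sx, sy = raster.spacing_x, raster.spacing_y
    snapped = np.column_stack([
        (np.round(local[:, 0] / sx - 0.5) + 0.5) * sx,
        (np.round(local[:, 1] / sy - 0.5) + 0.5) * sy])
    adjusted = snapped @ R.T + np.asarray(raster.origin)
    changed = np.linalg.norm(adjusted - corners, axis=1) > tol
    out = np.where(changed[:, None], adjusted, corners)
    poly = Polygon(out)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("adjusted corners form a degenerate polygon")
    return out, changed, float(poly.area)
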