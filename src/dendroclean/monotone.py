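"""Monotone-series primitives shared by the diameter, height and crown stages.

Three operations recur throughout the curation pipeline:

* isotonic least-squares projection (PAVA) of a series onto non-decreasing
  values, used to remove negative increments;
* monotone cubic Hermite interpolation through observed knots, used to fill
  observation gaps without overshooting;
* replacement of zero-increment runs left behind by the isotonic projection,
  either by straight linear interpolation between the strictly smaller /
  strictly larger neighbours, or by re-anchoring the run's value at its mean
  date first (the variant used for heights).
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import PchipInterpolator
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "isotonic_fit",
    "monotone_interpolator",
    "linearize_flat_runs",
    "mean_date_flat_runs",
    "flat_runs",
]


def isotonic_fit(t, y, weights=None) -> np.ndarray:
    """Non-decreasing least-squares projection of ``y`` ordered by ``t``.

    Ties in ``t`` are averaged (secondary ordering is irrelevant for the
    projection). Returns fitted values aligned with the input order.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("t and y must be 1-d arrays of equal length")
    if y.size <= 1:
        return y.copy()
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    return iso.fit_transform(t, y, sample_weight=weights)


def monotone_interpolator(t, y) -> PchipInterpolator:
    """Monotone cubic Hermite interpolant through ``(t, y)``.

    The interpolant passes exactly through every knot and preserves
    monotonicity of the data (Fritsch–Carlson conditions). ``t`` must be
    strictly increasing.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two knots to interpolate")
    if np.any(np.diff(t) <= 0):
        raise ValueError("knot times must be strictly increasing")
    return PchipInterpolator(t, y, extrapolate=False)


def flat_runs(values, atol: float = 0.0):
    """Yield ``(i, j)`` index ranges (inclusive) of maximal constant runs
    of length >= 2 in ``values``."""
    v = np.asarray(values, dtype=float)
    n = v.size
    i = 0
    while i < n - 1:
        j = i
        while j + 1 < n and abs(v[j + 1] - v[i]) <= atol:
            j += 1
        if j > i:
            yield i, j
        i = j + 1 if j > i else i + 1


def linearize_flat_runs(t, y, atol: float = 0.0) -> np.ndarray:
    """Replace interior constant runs by linear interpolation in time.

    A maximal run of equal values is replaced only when it has a strictly
    smaller predecessor and a strictly larger successor; the run's values are
    linearly interpolated between those two neighbours. Runs touching either
    end of the series are left alone, so the output stays non-decreasing if
    the input was.
    """
    t = np.asarray(t, dtype=float)
    out = np.asarray(y, dtype=float).copy()
    for i, j in flat_runs(out, atol):
        if i == 0 or j == out.size - 1:
            continue
        lo_t, lo_v = t[i - 1], out[i - 1]
        hi_t, hi_v = t[j + 1], out[j + 1]
        if lo_v < out[i] < hi_v:
            out[i : j + 1] = np.interp(t[i : j + 1], [lo_t, hi_t], [lo_v, hi_v])
    return out


def mean_date_flat_runs(t, y, atol: float = 0.0) -> np.ndarray:
    """Flat-run removal that honours the run's average date.

    The run's constant value is treated as true at the run's mean date; the
    run entries are then linearly interpolated through the three points
    (previous neighbour, mean date, next neighbour). Used for height series,
    where a constant stretch is read as "the tree had this height around the
    middle of the stretch".
    """
    t = np.asarray(t, dtype=float)
    out = np.asarray(y, dtype=float).copy()
    for i, j in flat_runs(out, atol):
        if i == 0 or j == out.size - 1:
            continue
        lo_t, lo_v = t[i - 1], out[i - 1]
        hi_t, hi_v = t[j + 1], out[j + 1]
        if not (lo_v < out[i] < hi_v):
            continue
        tm = t[i : j + 1].mean()
        v = out[i]
        xp = [lo_t, tm, hi_t]
        fp = [lo_v, v, hi_v]
        out[i : j + 1] = np.interp(t[i : j + 1], xp, fp)
    return out
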