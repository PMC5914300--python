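"""Tree-height triangulation from recorded angles and distances.

For campaigns where heights were not read off the instrument directly, the
field crews recorded angles (to the tree top and to a mark on the stem) and a
distance, and heights were computed afterwards. Two instrument set-ups occur:

* base-bar mode: a bar of known length ``A`` (cm) held against the stem,
  with a device constant ``C`` (default 1/0.3),
  ``H = A * C * cos^2(WU) * (tan WO + tan WU) + K``;
* slope-distance mode: slope distance ``D`` (dm) from observer to the stem
  mark, ``H = D * cos(WU) * (tan WO + tan WU) + K``.

``WO`` is the angle to the tree top, ``WU`` the angle to the measurement mark
(both degrees, downslope negative), ``K`` the mark height in dm (typically
13 dm). Both formulas reduce to plain horizontal-distance triangulation
``D * tan(WO) + K`` when ``WU = 0``.

Legacy punch-card angle records are fixed 3-character strings holding the
angle in tenths of a degree; a leading ``9`` flags a negative (downslope)
angle, with the remaining two digits the magnitude in tenths.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "decode_angle",
    "height_base_bar",
    "height_slope_distance",
    "heights_from_observations",
    "DEFAULT_BASE_BAR_CONSTANT",
    "DEFAULT_MARK_HEIGHT_DM",
]

DEFAULT_BASE_BAR_CONSTANT = 1 / 0.3
DEFAULT_MARK_HEIGHT_DM = 13.0


def decode_angle(raw: str) -> float:
    """Decode a 3-character punch-card angle field to signed degrees."""
    if len(raw) != 3 or not raw.isdigit():
        raise ValueError(f"angle field must be 3 digits, got {raw!r}")
    if raw[0] == "9":
        return -int(raw[1:]) / 10.0
    return int(raw) / 10.0


def _check_angles(*angles_deg: float) -> None:
    for a in angles_deg:
        if not -90.0 < a < 90.0:
            raise ValueError(f"angle {a} deg outside the open interval "
                             "(-90, 90)")


def height_base_bar(A: float, WO: float, WU: float,
                    C: float = DEFAULT_BASE_BAR_CONSTANT,
                    K: float = DEFAULT_MARK_HEIGHT_DM) -> float:
    """Height (dm) from base-bar length ``A`` (cm) and angles (degrees)."""
    if A <= 0:
        raise ValueError("base-bar length must be positive")
    _check_angles(WO, WU)
    wo, wu = math.radians(WO), math.radians(WU)
    return A * C * math.cos(wu) ** 2 * (math.tan(wo) + math.tan(wu)) + K


def height_slope_distance(D: float, WO: float, WU: float,
                          K: float = DEFAULT_MARK_HEIGHT_DM) -> float:
    """Height (dm) from slope distance ``D`` (dm) and angles (degrees)."""
    if D <= 0:
        raise ValueError("slope distance must be positive")
    _check_angles(WO, WU)
    wo, wu = math.radians(WO), math.radians(WU)
    return D * math.cos(wu) * (math.tan(wo) + math.tan(wu)) + K


def heights_from_observations(obs: pd.DataFrame, *, base_bar_years=(1978,),
                              C: float = DEFAULT_BASE_BAR_CONSTANT,
                              K: float = DEFAULT_MARK_HEIGHT_DM
                              ) -> pd.Series:
    """Tree height in dm for every row of a ``dbhObs`` table.

    Rows with ``kh == 0`` already carry the height in ``ho``; rows with
    ``kh == 1`` carry raw triangulation fields (``ho`` the distance — base-bar
    length in cm for the base-bar campaigns, otherwise slope distance in
    dm — and ``ka``/``kb`` the angles to top and stem mark in 1/10 degree).
    Rows with no usable height yield NaN.
    """
    out = np.full(len(obs), np.nan)
    kh = obs["kh"].to_numpy(dtype=float, na_value=np.nan)
    ho = obs["ho"].to_numpy(dtype=float, na_value=np.nan)
    ka = obs["ka"].to_numpy(dtype=float, na_value=np.nan)
    kb = obs["kb"].to_numpy(dtype=float, na_value=np.nan)
    years = obs["year"].to_numpy(dtype=float, na_value=np.nan)
    for i in range(len(obs)):
        if np.isnan(kh[i]) or np.isnan(ho[i]):
            continue
        if kh[i] == 0:
            out[i] = ho[i]
            continue
        if np.isnan(ka[i]) or np.isnan(kb[i]):
            continue
        wo, wu = ka[i] / 10.0, kb[i] / 10.0
        try:
            if years[i] in base_bar_years:
                out[i] = height_base_bar(ho[i], wo, wu, C=C, K=K)
            else:
                out[i] = height_slope_distance(ho[i], wo, wu, K=K)
        except ValueError:
            out[i] = np.nan
    return pd.Series(out, index=obs.index, name="h_dm")
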