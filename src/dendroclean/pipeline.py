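"""End-to-end curation: raw tables in, completed monotone dhc table out."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crown import CrownConfig, run_crown_pipeline
from .diameter import DiameterConfig, run_diameter_pipeline
from .heights import HeightConfig, run_height_pipeline

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    diameter: DiameterConfig = field(default_factory=DiameterConfig)
    height: HeightConfig = field(default_factory=HeightConfig)
    crown: CrownConfig = field(default_factory=CrownConfig)


def run_pipeline(tables: dict, cfg: PipelineConfig | None = None):
    """Run diameter, height and crown-base stages on a raw dataset.

    Returns ``(dhc, aux)``: a dhcComplSmooth-style frame — one row per
    (plot, tree, year, obs) between each tree's first and last diameter
    observation, with complete monotone ``d`` (mm), ``h`` and ``hCr`` (dm) —
    and a dict of stage by-products (levelling factor tables, the fitted
    height-age model, break events).
    """
    cfg = cfg or PipelineConfig()
    d_rec, d_factors = run_diameter_pipeline(tables, cfg.diameter)
    h_rec, h_aux = run_height_pipeline(tables, d_rec, cfg.height)
    c_rec = run_crown_pipeline(tables, h_rec, d_rec, cfg.crown)
    keys = ["plot", "tree", "year", "obs"]
    dhc = (d_rec[keys + ["t", "d", "gap_filled"]]
           .merge(h_rec[keys + ["h_all", "h_nobreak"]], on=keys, how="left")
           .merge(c_rec[keys + ["hCr"]], on=keys, how="left"))
    dhc = dhc.rename(columns={"h_all": "h"})
    dhc["hCr"] = np.minimum(dhc["hCr"].to_numpy(dtype=float),
                            dhc["h"].to_numpy(dtype=float))
    dhc = dhc.sort_values(keys).reset_index(drop=True)
    aux = {"diameter_factors": d_factors,
           "height": h_aux,
           "h_nobreak": h_rec}
    return dhc, aux


def to_published_schema(dhc: pd.DataFrame) -> pd.DataFrame:
    """Project a pipeline result onto the published dhcComplSmooth columns."""
    out = dhc[["plot", "tree", "year", "obs", "d", "h", "hCr"]].copy()
    for c in ("plot", "tree", "year", "obs"):
        out[c] = pd.array(out[c].astype(int), dtype="Int64")
    return out
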