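import dataclasses

import pytest

import dendroclean as dc


@pytest.fixture(scope="session")
def small_stand():
    """One 8x8 plot at 1.5 m spacing with the default era table."""
    cfg = dc.SimulationConfig().with_(
        plots=(dc.PlotSpec(1, (1.5, 1.5), 8, 8),))
    truth, tables = dc.simulate_stand(cfg, seed=42)
    return cfg, truth, tables


@pytest.fixture(scope="session")
def small_pipeline(small_stand):
    cfg, truth, tables = small_stand
    dhc, aux = dc.run_pipeline(tables)
    return truth, tables, dhc, aux


def calliper_bias_config(bias=0.07, noise=0.02, rows=6):
    """Every campaign a calliper survey with the given relative bias."""
    cfg = dc.SimulationConfig()
    camps = tuple(dataclasses.replace(
        c, d_instrument="calliper", d_bias=bias, d_sd=noise,
        round_probs=(1.0, 0.0, 0.0)) for c in cfg.campaigns)
    return cfg.with_(plots=(dc.PlotSpec(1, (1.5, 1.5), rows, rows),),
                     campaigns=camps, missing_d_rate=0.0)
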