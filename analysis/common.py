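"""Shared settings for the numbered analysis drivers.

One synthetic surveillance area (subtropical climate, 650,000 residents,
15% aged 65+) observed for 6 years of mortality, with a 45-year weather
record for hazard fitting. Every driver is deterministic given SEED.
"""

from pathlib import Path

import numpy as np

import heatrisk as hr

SEED = 16
RESULTS = Path(__file__).resolve().parent.parent / "results"
SPEC = hr.CrossBasisSpec()  # df_var=2, df_lag=3, max_lag=3
CLIMATE_YEARS = 45


def surveillance_dataset() -> hr.SyntheticDataset:
    return hr.generate_dataset(hr.demo_config(seed=SEED))


def climate_record():
    """Weather-only record covering the 45 years ending with the
    surveillance window."""
    import dataclasses

    cfg = hr.demo_config(seed=SEED)
    clim_cfg = dataclasses.replace(
        cfg, n_years=CLIMATE_YEARS,
        start_year=cfg.start_year + cfg.n_years - CLIMATE_YEARS,
        seed=SEED + 3_000_003)
    frame, _ = hr.generate_temperature(clim_cfg,
                                       np.random.default_rng(clim_cfg.seed))
    return frame
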