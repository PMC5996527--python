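import numpy as np
import pandas as pd
import pytest

import heatrisk as hr


def temp_frame(values, start="2010-06-01", column="tmax", spread=2.0):
    """A weather frame with consecutive dates; tmean/tmax/tmin derived from
    one metric so every definition is applicable."""
    values = np.asarray(values, dtype=float)
    idx = pd.date_range(start, periods=len(values), freq="D")
    if column == "tmax":
        tmax = values
        tmean = values - spread
    elif column == "tmean":
        tmean = values
        tmax = values + spread
    else:
        tmean = values + spread
        tmax = tmean + spread
    tmin = tmean - spread
    if column == "tmin":
        tmin = values
    return pd.DataFrame({"tmax": tmax, "tmean": tmean, "tmin": tmin}, index=idx)


@pytest.fixture(scope="session")
def demo_dataset():
    """One demo synthetic area, shared read-only across tests."""
    return hr.generate_dataset(hr.demo_config(seed=16))


@pytest.fixture(scope="session")
def demo_fit(demo_dataset):
    """Selected definition, events and elder vulnerability fit on the demo."""
    records = demo_dataset.records
    defn = hr.HWDefinition(id="hw11", metric="max",
                           threshold_kind="absolute_celsius",
                           threshold_value=35.0, min_duration=3)
    thr = hr.resolve_threshold(records, defn)
    events = hr.detect_events(records, defn, threshold=thr)
    spec = hr.CrossBasisSpec()
    fit, curve = hr.fit_vulnerability(records, events, spec, age_group="65plus")
    return {"records": records, "definition": defn, "threshold": thr,
            "events": events, "spec": spec, "fit": fit, "curve": curve}
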