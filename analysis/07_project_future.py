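"""Project heat-wave mortality risk under warming and population aging.

A future 45-year weather scenario (annual mean +2.5 C, doubled hot-spell
rate) is generated; events are re-detected with the *historical* threshold,
the hazard is refitted, the vulnerability curves are held at their baseline
estimates, and losses are converted with the future age structure (31.53%
aged 65+). Writes results/risk_future.json and prints the future-to-
baseline AAL ratios.
"""

import dataclasses
import json

import numpy as np

import heatrisk as hr
from common import CLIMATE_YEARS, RESULTS, SEED, SPEC, surveillance_dataset

T_INCREASE = 2.5  # deg C added to the annual mean temperature
SPELL_RATE_MULT = 2.0
ELDER_SHARE_FUTURE = 0.3153


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    ds = surveillance_dataset()
    records = ds.records
    best, _ = hr.select_definition(records, hr.default_catalogue(), SPEC)
    thr = hr.resolve_threshold(records, best)
    events = hr.detect_events(records, best, threshold=thr)
    curves = {g: hr.fit_vulnerability(records, events, SPEC, age_group=g)[1]
              for g in ("0_64", "65plus")}

    cfg = hr.demo_config(seed=SEED)
    fut_cfg = dataclasses.replace(
        cfg, n_years=CLIMATE_YEARS, start_year=cfg.start_year + 44,
        t_mean_annual=cfg.t_mean_annual + T_INCREASE,
        spell_rate=cfg.spell_rate * SPELL_RATE_MULT, seed=SEED + 2_000_003)
    future_series, _ = hr.generate_temperature(
        fut_cfg, np.random.default_rng(fut_cfg.seed))

    structure = hr.AgeStructure(
        shares={"0_64": 1 - ELDER_SHARE_FUTURE, "65plus": ELDER_SHARE_FUTURE},
        source="future aging scenario")
    out = hr.project_future(curves, structure, n_years=10_000,
                            seed=SEED + 1_000_003,
                            future_series=future_series, definition=best,
                            historical_threshold=thr)

    # baseline ASMR for the ratio, from the stored risk table if present
    baseline_path = RESULTS / "risk.json"
    baseline = (json.loads(baseline_path.read_text())
                if baseline_path.exists() else None)

    summary = {"t_increase": T_INCREASE, "spell_rate_mult": SPELL_RATE_MULT,
               "elder_share": ELDER_SHARE_FUTURE, "groups": {}}
    for g in ("0_64", "65plus"):
        res = out["asmr"][g]
        summary["groups"][g] = {"aal": res.aal,
                                "pml": {str(T): v for T, v in res.pml.items()}}
        line = (f"  [{g}] future ASMR AAL {res.aal['central']:.1f} "
                f"({res.aal['lower']:.1f}-{res.aal['upper']:.1f}) per million/yr")
        if baseline:
            base_aal = baseline[f"asmr_{g}"]["aal"]["central"]
            if base_aal > 0:
                line += f"; {res.aal['central'] / base_aal:.1f}x baseline"
        print(line)
    (RESULTS / "risk_future.json").write_text(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
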