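"""Generate the synthetic surveillance area and summarise what it contains.

Writes results/data.csv (daily weather, confounders, deaths by age group)
and results/truth.json (the generating parameters and the realised hot
spell calendar, for downstream recovery checks).
"""

import json

import heatrisk as hr
from common import RESULTS, SEED, surveillance_dataset


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    ds = surveillance_dataset()
    hr.write_dataset(ds, RESULTS / "data.csv", RESULTS / "truth.json")

    rec = ds.records
    print(f"simulated {len(rec)} days "
          f"({rec.index[0].date()} .. {rec.index[-1].date()}), seed {SEED}")
    print(f"  summer peak tmax: {rec['tmax'].max():.1f} C; "
          f"annual mean tmean: {rec['tmean'].mean():.1f} C")
    for g in ("0_64", "65plus"):
        print(f"  mean daily deaths [{g}]: {rec[f'deaths_{g}'].mean():.2f}")
    print(f"  injected hot spells: {len(ds.truth['spells'])}; "
          f"truth events (tmax > 35 C, >= 3 d): {len(ds.truth['truth_events'])}")


if __name__ == "__main__":
    main()
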