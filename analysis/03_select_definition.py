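"""Select the area's local heat-wave definition by minimum AIC.

One DLNM per catalogued definition is fitted to the elder crude mortality
rate on identical observations; the definition with the lowest AIC is the
local definition used by every later stage. Writes results/aic_table.csv.
"""

import heatrisk as hr
from common import RESULTS, SPEC, surveillance_dataset


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    records = surveillance_dataset().records
    best, table = hr.select_definition(records, hr.default_catalogue(), SPEC)
    table.to_csv(RESULTS / "aic_table.csv", index=False)

    fittable = table.dropna(subset=["aic"]).sort_values("aic")
    print(fittable.to_string(index=False))
    print(f"\nselected: {best.id} ({best.metric} temperature > "
          f"{best.threshold_value}"
          f"{'th percentile' if best.threshold_kind == 'percentile' else ' C'}"
          f" for >= {best.min_duration} consecutive days)")
    runner_up = fittable.iloc[1]
    print(f"AIC margin over runner-up ({runner_up['id']}): "
          f"{runner_up['aic'] - fittable.iloc[0]['aic']:.2f}")


if __name__ == "__main__":
    main()
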