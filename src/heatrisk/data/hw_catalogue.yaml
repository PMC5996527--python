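# Catalogue of sixteen heat-wave definitions drawn from the epidemiological
# literature: a temperature metric (daily mean / maximum / minimum), a
# threshold (absolute Celsius or an empirical percentile of the reference
# record) and a minimum consecutive-day duration. "Duration >= N" semantics;
# exceedance is strict (>).
- {id: hw01, metric: mean, threshold_kind: percentile, threshold_value: 97.0, min_duration: 2}
- {id: hw02, metric: mean, threshold_kind: percentile, threshold_value: 98.0, min_duration: 2}
- {id: hw03, metric: mean, threshold_kind: percentile, threshold_value: 99.0, min_duration: 2}
- {id: hw04, metric: mean, threshold_kind: percentile, threshold_value: 98.0, min_duration: 3}
- {id: hw05, metric: mean, threshold_kind: percentile, threshold_value: 99.0, min_duration: 3}
- {id: hw06, metric: max, threshold_kind: percentile, threshold_value: 95.0, min_duration: 2}
- {id: hw07, metric: max, threshold_kind: percentile, threshold_value: 97.0, min_duration: 2}
- {id: hw08, metric: max, threshold_kind: percentile, threshold_value: 98.0, min_duration: 2}
- {id: hw09, metric: max, threshold_kind: percentile, threshold_value: 99.0, min_duration: 2}
- {id: hw10, metric: max, threshold_kind: absolute_celsius, threshold_value: 35.0, min_duration: 2}
- {id: hw11, metric: max, threshold_kind: absolute_celsius, threshold_value: 35.0, min_duration: 3}
- {id: hw12, metric: max, threshold_kind: absolute_celsius, threshold_value: 37.0, min_duration: 3}
- {id: hw13, metric: min, threshold_kind: percentile, threshold_value: 95.0, min_duration: 2}
- {id: hw14, metric: min, threshold_kind: percentile, threshold_value: 97.0, min_duration: 2}
- {id: hw15, metric: min, threshold_kind: percentile, threshold_value: 98.0, min_duration: 3}
- {id: hw16, metric: min, threshold_kind: percentile, threshold_value: 99.0, min_duration: 2}
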