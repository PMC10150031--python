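"""Summarise the bundled reference evaluation tables.

The package ships the 24-sample two-shred overlap benchmark (per-sample
AAR/CAR), the 20 constituent shred areas, and the per-class recognition
confidences grouped by overlap type.
"""

from shredcot import group_mean, summarize
from shredcot.data import benchmark_records, load_recognition_confidence

s = summarize(benchmark_records())
print(f"overlap benchmark (n={s.n})")
print(f"  average AAR      : {s.avg_aar:.3f}")
print(f"  average CAR      : {s.avg_car:.2f}")
print(f"  increase range   : {100 * s.min_increase:.1f}% .. {100 * s.max_increase:.1f}%")
print(f"  negative optim.  : {s.negative_optimization_count}")

conf = load_recognition_confidence()
for group, values in conf.items():
    print(f"recognition confidence, {group:16s}: {group_mean(list(values.values()))}%")
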