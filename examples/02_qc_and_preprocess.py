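"""Quality control and signal conditioning of one recording.

Applies fellow-eye substitution, the file rejection rules, gap
interpolation, zero-phase low-pass filtering, and segmentation into
baseline-aligned 5 s movement traces.
"""

from accomstep import (SimConfig, apply_rejection, interpolate_short_gaps,
                       segment_movements, simulate_cohort, substitute_eye)

rec = simulate_cohort(SimConfig(n_participants=1, seed=11, gap_rate=0.2))[0]

repaired, counts = substitute_eye(rec)
print(f"fellow-eye substitution: {counts['od']} right-eye and {counts['os']} "
      "left-eye samples repaired")

report = apply_rejection(repaired, substitute=False)
print(f"QC: {100 * report.missing_fraction_combined:.2f}% missing, "
      f"longest gap {report.longest_missing_run} samples, "
      f"{report.n_valid_samples} valid samples "
      f"-> {'ACCEPTED' if report.accepted else 'REJECTED ' + str(report.reasons)}")
# rejection thresholds: >=25% missing, <750 valid samples (15 s), >=225-sample gap

filled = interpolate_short_gaps(repaired)
traces, dropped = segment_movements(filled)
print(f"\nsegmented {len(traces)} movements ({dropped} dropped at end of file)")
tr = traces[0]
print(f"first movement: {tr.direction}, {tr.t.size} samples, "
      f"refraction change {tr.refraction[0]:.2f} -> {tr.refraction[-1]:.2f} D, "
      f"peak |velocity| {abs(tr.velocity).max():.2f} D/s")
# traces are filtered (5th-order Butterworth, 20 Hz, zero-phase), baseline-
# aligned to their first sample, and differentiated by central differences
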