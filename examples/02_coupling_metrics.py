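"""From one raw logger series to ΔT, β and a thermoregulatory class.

Preprocessing clips to the 12:30–15:00 equilibrated window and trims
cooler-cycle minutes (T_air ≤ 16 °C benign / 31 °C high). ΔT is the mean
leaf−air offset over the retained minutes; β is the mean of 30-min-window
OLS slopes of T_leaf on T_air.
"""

from thermoreg import (
    Treatment,
    coupling_metrics,
    generate_experiment,
    preprocess_series,
)

exp = generate_experiment(seed=42)
pid = exp.meta[0].plant_id
series = exp.series[(pid, Treatment.BENIGN)]

clean, report = preprocess_series(series)
print(
    f"{pid}: {report.n_input} logged minutes -> {report.n_after_window} in window "
    f"-> {report.n_after_threshold} above threshold "
    f"({100 * report.fraction_trimmed_by_threshold:.1f} % trimmed)"
)

cm = coupling_metrics(clean)
print(f"ΔT mean = {cm.delta_t_mean:+.2f} °C  (leaf warmer than air if positive)")
for w in cm.window_slopes:
    status = f"slope {w.slope:.3f} (r² {w.r2:.3f})" if w.retained else f"skipped: {w.note}"
    print(f"  window {int(w.start_minute) // 60:02d}:{int(w.start_minute) % 60:02d}  n={w.n_points:3d}  {status}")
print(f"β = {cm.beta:.3f} -> {cm.thermo_class.value}")
print("β < 1 means the leaf damps air-temperature swings (limited homeothermy).")
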