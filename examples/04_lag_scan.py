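"""Detect a delayed discontinuity by scanning shifted cutoffs.

An award's effect need not appear in the award month itself. The scan re-fits
the RDD with the cutoff shifted by 0..max_lag months and reports the shift
with the largest |estimate|/SE; here the generator delays the treated jump by
2 months, and the scan finds it.
"""

from rddmatch import SynthConfig, generate_panel, scan_lag

config = SynthConfig(n_treated=346, n_control_pool=346, lag_months=2, seed=5)
panel = generate_panel(config)
series = panel.outcome_series("views", panel.treated_ids())

fits, best = scan_lag(series, panel.cutoff_index, max_lag=3)
print("lag profile (treated arm, monthly views; true delay = 2 months):")
for lag, f in enumerate(fits):
    z = abs(f.estimate) / f.std_error
    print(f"  lag {lag}: jump = {f.estimate:10.1f}  SE = {f.std_error:9.1f}  |z| = {z:6.2f}")
print(f"\nbest lag = {best} month(s): the discontinuity is sharpest when the "
      "cutoff is shifted to the month the effect actually materialized.")
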