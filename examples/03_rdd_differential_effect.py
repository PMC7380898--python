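"""Estimate the outcome jump at the award month and the differential effect.

Each group's monthly outcome series is fitted with two sharp-RDD estimators:
a global linear fit with separate slopes and a jump term at the cutoff
(parametric), and a triangular-kernel local-linear fit within a 3-month
bandwidth (nonparametric). The differential treatment effect subtracts the
matched control group's jump from the treated group's jump, removing shocks
common to both arms.
"""

from rddmatch import PipelineConfig, SynthConfig, run_pipeline

report = run_pipeline(PipelineConfig(
    synth=SynthConfig(seed=7),  # study scale: 346 treated, pool of 3000
    log_level="WARNING",
))

print("group-wise jumps at the cutoff (true simulated jumps: views +80000, "
      "patients +20 in the treated arm, none in controls):")
for f in report.fits:
    print(f"  {f.outcome:8s} {f.group:8s} {f.method:13s} "
          f"jump = {f.estimate:12.1f}  SE = {f.std_error:10.1f}  p = {f.p_value:.3g}")

print("\ndifferential (treated minus control) effects:")
for d in report.differentials:
    print(f"  {d.outcome:8s} {d.method:13s} "
          f"estimate = {d.estimate:12.1f}  SE = {d.std_error:10.1f}  p = {d.p_value:.3g}")
print("\nthe view effect is large and significant; the consultation effect is "
      "an order of magnitude smaller relative to its noise -- the qualitative "
      "pattern an attention-driven incentive produces.")
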