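"""Generate a synthetic physician-month panel and inspect its structure.

The generator mimics a 12-month observation window around an incentive award:
month 0 holds each physician's cumulative profile state (rating score,
thank-you letters, virtual gifts, contribution score, articles), months 1-11
hold marginal changes, and treated physicians' monthly outcomes jump at the
award cutoff (month 6).
"""

from rddmatch import SynthConfig, generate_panel

config = SynthConfig(n_treated=100, n_control_pool=600, seed=42)
panel = generate_panel(config)

m0 = panel.month0()
print(f"panel: {panel.n_physicians} physicians x 12 months, cutoff at month "
      f"{panel.cutoff_index}")
print(f"treated: {int(m0['treated'].sum())}, controls: "
      f"{int((1 - m0['treated']).sum())}")
print("\nmonth-0 covariate means by arm (treated physicians are busier "
      "-- selection on observables):")
print(m0.groupby("treated")[["prs", "thank", "gift", "contr", "article"]]
      .mean().round(1))

monthly = panel.monthly()
views = monthly[monthly["treated"] == 1].groupby("month_index")["views"].mean()
print("\ntreated-arm mean monthly views (note the ~80k step at month 6, "
      "the award month):")
print(views.round(0).to_string())
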