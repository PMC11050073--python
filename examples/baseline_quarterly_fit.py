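"""Simulate the calibrated baseline and print its quarterly death series.

The model starts in January 2016 from published compartment sizes and steps
monthly; overdose deaths are summed to calendar quarters, matching the
cadence of national surveillance releases.
"""

import opiflow as of

config = of.default_config()
traj = of.run(
    config.initial_state(),
    config.parameter_set("optimized"),
    config.schedule_set(),
    48,
)
series = of.quarterly_deaths(traj)

print("quarter   deaths")
for period, deaths in series.items():
    print(f"{period}    {deaths:7.1f}")
print(f"\ncumulative 2016-2019: {traj.cumulative_od_deaths:.0f} overdose deaths")
print()
print("Deaths climb with the fentanyl proxy (0.25 in 2016 to 0.80 in 2019)")
print("while the intervention ramp (0% to 60% of deaths prevented) holds the")
print("rise in check; within each year the quarterly seasonality multipliers")
print("(1.02, 1.01, 0.95, 0.99) shape the profile.")
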