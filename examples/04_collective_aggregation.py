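"""Collective aggregation of cardiomyocytes over 250 h (fibered matrix).

Runs the fibered-matrix scenario: 60 differentiated cardiac cells
migrate, proliferate, form stable junctions and coalesce into one main
group.  Prints the population growth and the main-group trajectory.
"""

from cardiomech.engine import ScenarioConfig, run_scenario

cfg = ScenarioConfig.preset("F-ECM")
result = run_scenario(cfg, seed=1)

m = result.metrics
for t in (0, 50, 100, 150, 200, 250):
    row = m[m.time == t].iloc[0]
    print(f"t = {t:3.0f} h: {int(row.n_cells):4d} cells, "
          f"{int(row.n_groups):3d} groups, "
          f"main group {int(row.main_group_size):4d}, "
          f"AR = {row.main_group_ar:4.2f}")
arr = result.manifest["arrivals"]
print(f"\ncells that reached the fiber: {arr['n_arrived']} "
      f"(mean first-touch {arr['mean_time_to_fiber']:.0f} h); "
      f"{arr['n_censored']} never arrived")
print("Small groups nucleate everywhere, merge on collision and are held "
      "together\nby persistent junctions; by 250 h most cells sit in one "
      "large aggregate.")
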