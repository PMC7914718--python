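"""Stem-cell differentiation in the fibered hydrogel (75 h).

Runs the differentiation scenario: 60 mesenchymal stem cells seeded at
random in the 20 kPa matrix with a 25 kPa central fiber, no load, no
field.  Cells accumulate the stiffness stimulus, complete their first
cycle and adopt the cardiac phenotype.
"""

from cardiomech.engine import ScenarioConfig, run_scenario

cfg = ScenarioConfig.preset("DIFF")
result = run_scenario(cfg, seed=1)

m, ev = result.metrics, result.events
d = ev[ev.event == "differentiate"]
print(f"calibrated substrate constant c_sub = {result.manifest['c_sub']:.4g}")
print(f"first differentiation at {d.time.min():.0f} h")
all_done = m[m.n_msc == 0]
print(f"all {cfg.params.n_cells} stem cells differentiated by "
      f"{all_done.time.min():.0f} h")
grp = m[m.main_group_size >= 2]
print(f"first stable cardiomyocyte group at {grp.time.min():.0f} h")
print(f"population after 75 h: {int(m.iloc[-1].n_cells)} cells "
      f"({int(m.iloc[-1].n_cm_late)} arrested in groups)")
print("\nDifferentiation starts once the fastest cells complete the "
      "~18 h cycle the\nsubstrate constant is calibrated to; junctions and "
      "stable groups follow as\nthe new cardiomyocytes touch and align.")
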