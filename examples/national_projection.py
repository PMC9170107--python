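"""Project a single national screen of everyone aged 65-80.

Uses a synthetic age/sex population table shaped like a national Vital
Statistics release (examples/data/population_synthetic.csv) together with
the campaign's detected prevalence of anticoagulation-eligible untreated
AF (12/1607) and the Markov model's 10-year stroke-risk reduction per
treated person.  Substitute a real population CSV to reproduce the
published national totals.
"""

from pathlib import Path

import afscreen as af

here = Path(__file__).parent
pop = af.load_population(here / "data" / "population_synthetic.csv")
tables = {sex: af.default_transitions(sex) for sex in ("men", "women")}
config = af.calibrate_conventions(tables["men"], af.default_qol())

prevalence = af.detected_prevalence({0: 3, 1: 8, 2: 2, 3: 2}, 1607, min_score=1)
res = af.project(pop, prevalence, tables, horizon=10, config=config)

print(f"detected prevalence applied: {prevalence:.4%} (12/1607)")
print(f"population aged 65-80: {res.cells['population'].sum():,.0f}")
print(f"untreated AF identified: {res.total_identified:,.0f}")
print(f"strokes prevented over {res.horizon} years of DOAC: "
      f"{res.total_strokes_prevented:,.0f}")
mean_arr = res.total_strokes_prevented / res.total_identified
print(f"\nPer identified case the 10-year absolute stroke-risk reduction "
      f"averages {mean_arr:.1%} (a number needed to treat of "
      f"{1 / mean_arr:.0f}).")
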