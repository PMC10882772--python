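"""Morris elementary-effects screening of the discounted-emissions objective.

The objective is the signed sum of discounted emission pulses (negative =
emission), so a positive mu means that increasing the parameter yields
fewer emissions. A reduced design (8 trajectories) keeps this example
quick; the conventional full design uses 10 levels and 30 trajectories.
"""

import hwpflow as hf

params = hf.generate_fixture_set(seed=1)
harvest = hf.HarvestInput(0, "log_type", hf.bau_harvest())

names = ("doc_f_paper_msw", "ch4_recovery_r", "ch4_oxidation_ox",
         "half_life_paper", "lifespans.corrugated_boxes.mode")
design, result = hf.run_morris(params, harvest, names=names,
                               p=10, r_traj=8, seed=1)

print("parameter ranking by mu* (tCO2e per unit-scaled step):")
print(result.ranked().round(0).to_string())
print("\npositive mu -> raising the parameter avoids emissions (e.g. more")
print("landfill methane recovery); negative mu -> raising it adds emissions")
print("(e.g. a larger decayable fraction of landfilled paper).")
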