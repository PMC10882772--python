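"""Compare wood-usage scenario overlays against business as usual.

Each overlay adjusts the harvest mix and/or parameters; the delta table
shows discounted 120-year storage (tC) and emission (tCO2e, negative)
sums and their change relative to BAU.
"""

import hwpflow as hf

params = hf.generate_fixture_set(seed=1)
bau_q = hf.bau_harvest()
bau = hf.simulate(hf.HarvestInput(0, "log_type", bau_q), params)

for name, overlay in hf.stock_overlays(params).items():
    q, p = hf.apply_scenario(bau_q, params, overlay)
    traj = hf.simulate(hf.HarvestInput(0, "log_type", q), p)
    delta = hf.compare(bau, traj)["delta"] / 1e6
    print(f"\n{name}: {overlay.notes}")
    print(delta.round(2).to_string())

print("\nPositive storage deltas mean the scenario holds more carbon;")
print("positive emission deltas mean it emits less (rows are negatives).")
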