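"""The full synthetic study: four 12-h windows plus the two ablations.

Runs the complete pipeline (synthesize specimens -> links -> growth maps ->
average -> FE growth -> scoring) over the 3.5-5.5 dpf windows at the
measured window growth rates, then repeats one window with the isotropised
field to show that growth orientation, not heterogeneity, carries the
shape prediction.
"""

from jointmorph.pipeline import RunConfig, run_all, run_window

config = RunConfig(seed=1)
summary = run_all(config)

print("recovered growth rates (x 1e-2 per hour):")
t = summary.rates_table
t = t[t["direction"] == "main"]
for _, row in t.iterrows():
    print(f"  {row['window']:9s} {row['region']}: "
          f"{100 * row['mean_rate_per_h']:+.2f} +/- {100 * row['sd_rate_per_h']:.2f}")

print("\nprediction quality (feature x window):")
print(summary.score_table.to_string())

iso = run_window(RunConfig(seed=1, ablation="heterogeneous_isotropic"), 1)
print("\nisotropised 4-4.5 dpf window:")
print(iso.scores[["feature", "percentage_match", "category"]].to_string(index=False))
# The full simulation predicts lengths and depths accurately; removing
# orientation (isotropic spheres) undergrows the dominant length features,
# while the near-zero-change MC width stays hard to predict in all runs.
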