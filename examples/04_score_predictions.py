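"""Score a predicted shape against initial and target measurements.

The percentage match of change, 100 x (pred - init) / (target - init), is
computed per shape feature and binned: <10 % no growth predicted, 10-70 %
undergrowth, 70-130 % accurate, >130 % overgrowth.
"""

from jointmorph.scoring import ShapeFeatures, score_features, scores_frame

initial = ShapeFeatures(MC_length=70.0, MC_depth=20.0, MC_width=20.0,
                        PQ_length=80.0, PQ_depth=20.0)
target = ShapeFeatures(MC_length=83.0, MC_depth=22.0, MC_width=19.5,
                       PQ_length=96.0, PQ_depth=21.0)
predicted = ShapeFeatures(MC_length=82.5, MC_depth=21.0, MC_width=20.3,
                          PQ_length=97.0, PQ_depth=22.5)

results = score_features(initial, target, predicted)
print(scores_frame(results).to_string(index=False))
# MC_length 96 % -> accurate; MC_depth 50 % -> undergrowth; MC_width -160 %
# (the feature should have shrunk but grew) -> no growth predicted;
# PQ_length 106 % -> accurate; PQ_depth 250 % -> overgrowth.
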