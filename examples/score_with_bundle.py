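"""Package a trained model as a portable bundle and score new DNA.

A bundle (``*.imseeker``) freezes detection parameters, the ordered feature
names, the fitted normalizer and the model itself; anyone can load it and
go from raw sequence to predicted transition pH and a 0-1 stability score
(the prediction min-max calibrated against the training-label range).
"""

from imseeker import (DetectionParams, build_bundle, load_bundle, run_automl,
                      save_bundle, score_sequence)
from imseeker.automl import AutoMLBudget, SearchSpace
from imseeker.synthetic import labelled_dataset

df, _ = labelled_dataset(200, seed=11)
run = run_automl(df, space=SearchSpace(("NONE", "GUS"), ("RIDGE", "HGBR")),
                 budget=AutoMLBudget(2, 8), seed=11)
bundle = build_bundle(run, DetectionParams(scan_reverse_complement=False),
                      label_kind="transition pH")
import os
os.makedirs("scratch", exist_ok=True)
save_bundle(bundle, "scratch/example_model.imseeker")
loaded = load_bundle("scratch/example_model.imseeker")

for dna in ("CCCTAACCCTAACCCTAACCC",        # short loops, strong candidate
            "CCCTTAGTTACCCTTAGTTACCCTTAGTTACCC",  # long loops
            "ATATATATAT"):                  # no candidate at all
    hits = score_sequence(loaded, dna)
    if not hits:
        print(f"{dna}: no i-motif candidate")
    for m in hits:
        print(f"{dna}: predicted {loaded.label_kind} = "
              f"{m.predicted_label:.3f}, stability score = "
              f"{m.stability_score:.3f}")

# Higher stability scores mean the model places the motif nearer the top of
# the training-label range; 0 and 1 mark the range endpoints (clamped).
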