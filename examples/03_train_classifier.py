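"""Train the person-dependent LDA attention classifier and calibrate it.

Cross-validated calibration accuracy is the quality gate used before a
person goes 'online'; the discriminant's largest weight should fall on
the TP10 alpha feature, where the internal-attention effect is largest.
"""

import numpy as np

import attngate as ag

plan = ag.make_session_plan(4, 50.0, 50.0, seed=3)
stream = ag.synthesize_bandpower(plan)

cal = ag.cross_validate(stream, k=5, scheme="shuffled")
print(f"5-fold calibration accuracy: {100 * cal.mean_accuracy:.2f}% "
      f"(folds: {', '.join(f'{100*a:.1f}' for a in cal.fold_accuracies)})")

blocked = ag.cross_validate(stream, k=5, scheme="contiguous")
print(f"leakage-safe contiguous folds: {100 * blocked.mean_accuracy:.2f}%")

model = ag.train(stream)
model.calibration = cal
top = int(np.argmax(np.abs(model.weights)))
print(f"largest |weight|: {ag.FEATURE_COLUMNS[top]}")
model.save("model.json")
print("model saved to model.json")
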