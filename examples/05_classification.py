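"""3-category classification: absolute vs relative confidence.

Three fixed random templates; jittered instances form train/test sets; one
neuron per category learns to fire the shared target train for its own
category only. Decisions compare each neuron's output distance to its
target.
"""

from psdlearn.experiments import run_classification

res = run_classification(seed=1)

print("per-category accuracies")
print("  absolute confidence: train", res.train_absolute.tolist(),
      " test", res.test_absolute.tolist())
print("  relative confidence: train", res.train_relative.tolist(),
      " test", res.test_relative.tolist())
print(f"means: absolute test {res.mean_test_absolute:.3f}, "
      f"relative test {res.mean_test_relative:.3f}")
print("Meaning: the absolute criterion demands a close match to the target")
print("train; the relative (winner-take-all) criterion only needs the right")
print("neuron to be closest, and is consistently the stronger decision rule.")
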