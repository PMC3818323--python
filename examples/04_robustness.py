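"""Noisy training buys robustness: jittered-stimulus generalization.

Trains one neuron on 5 template patterns either on the clean templates
(deterministic) or on freshly jittered copies each epoch (noisy, sd 2 ms),
then tests on jittered patterns at several noise levels.
"""

from psdlearn.experiments import run_robustness

levels = (0.0, 1.0, 2.0, 4.0)
det = run_robustness("jitter", "deterministic", test_levels=levels,
                     n_templates=5, seed=3)
noi = run_robustness("jitter", "noisy", test_levels=levels, train_level=2.0,
                     n_templates=5, seed=3)

print("test jitter sd (ms):        ", list(levels))
print("deterministic training acc: ", det.accuracy.tolist())
print("noisy training acc:         ", noi.accuracy.tolist())
print("Meaning: the deterministically trained neuron is exact on clean input")
print("but brittle; training under jitter keeps accuracy high up to the")
print("training noise level.")
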