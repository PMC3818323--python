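"""Memory capacity at desk scale: load factors of a 200-synapse neuron.

Sweeps the number of stored patterns per synapse on a coarse grid (a small
neuron and few runs keep this quick; the full protocol uses N=500, step
0.008, 10 runs).
"""

from psdlearn.experiments import run_capacity

res = run_capacity(n_synapses=200, load_grid=(0.05, 0.10, 0.15, 0.20, 0.25),
                   runs=3, seed=1)

print(f"{'load P/N':>9} {'mean epochs':>12} {'failure rate':>13}")
for a, m, f in zip(res.load_grid, res.mean_epochs, res.failure_rate):
    print(f"{a:9.3f} {m:12.1f} {f:13.2f}")
print(f"alpha_max = {res.max_load:.3f}  (largest load with >=50% of runs "
      f"memorizing all patterns)")
print(f"alpha_eff = {res.efficient_load:.3f}  (largest load learned within "
      f"100 epochs on average)")
print("Meaning: training effort rises slowly with load, then diverges at the")
print("capacity limit; the efficient load marks the knee of that curve.")
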