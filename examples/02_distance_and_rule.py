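"""The van Rossum distance and the sign structure of the PSD update.

Hand-built spike trains show how the metric scores timing errors and how
missed/spurious output spikes translate into potentiation/depression.
"""

import numpy as np

from psdlearn import (KernelParams, SpikePattern, SpikeTrain, psd_delta,
                      van_rossum_distance)

window = 200.0
target = SpikeTrain([40.0, 80.0, 120.0, 160.0], window)

for desc, times in [("exact match", [40.0, 80.0, 120.0, 160.0]),
                    ("1 ms late everywhere", [41.0, 81.0, 121.0, 161.0]),
                    ("one spike missing", [40.0, 80.0, 120.0]),
                    ("silent", [])]:
    d = van_rossum_distance(SpikeTrain(times, window), target)
    print(f"D({desc:22s}) = {d:6.3f}")
print("Meaning: D < 0.2 demands near-exact timing; a single missing spike")
print("already costs ~1.0.")

kernel = KernelParams()
pattern = SpikePattern([SpikeTrain([35.0], window), SpikeTrain([150.0], window)],
                       window)
miss = psd_delta(pattern, SpikeTrain([40.0], window), SpikeTrain([], window),
                 kernel, eta=0.02)
false_alarm = psd_delta(pattern, SpikeTrain([], window),
                        SpikeTrain([155.0], window), kernel, eta=0.02)
print("\ndelta-w after a missed desired spike at 40 ms: ", np.round(miss, 4))
print("delta-w after a spurious output spike at 155 ms:", np.round(false_alarm, 4))
print("Meaning: only the afferent spiking shortly before the event moves —")
print("potentiated for a miss, depressed for a false alarm.")
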