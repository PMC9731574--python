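"""Spike-field coupling and the hit/miss peak-frequency shift.

Builds 12 synthetic spike-LFP pairs whose units lock to 70 Hz gamma on
hit trials and 62 Hz on miss trials, screens them with the Rayleigh+FDR
test, and runs the peak-frequency contrast.  The paired t-test should
recover a positive shift (hits faster) of ~8 Hz.
"""

import spikefield as sf
from spikefield import sfc

pairs = [sf.synth.gen_pair_phase_data(
    "high", {"hit": 70.0, "miss": 62.0}, kappa=2.0, rate=20.0,
    noise_sd=1.0, seed=100 + k) for k in range(12)]

n_sig = sum(sfc.screen_pair(p).significant for p in pairs)
print(f"{n_sig}/{len(pairs)} pairs pass the Rayleigh+FDR screen")

res = sfc.peak_frequency_shift(pairs, band=(45.0, 75.0))
t = res["table"]
print(t.to_string(index=False))
print(f"\nmean gamma peak: hits {t['peak_hit'].mean():.1f} Hz, "
      f"misses {t['peak_miss'].mean():.1f} Hz")
print(f"paired t = {res['t']:.2f}, p = {res['p']:.2g} over "
      f"{res['n_pairs']} pairs")
print("a positive shift means spikes couple to faster gamma on "
      "later-remembered trials")
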