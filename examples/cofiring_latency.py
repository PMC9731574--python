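"""Co-firing latency: shuffle-normalized cross-correlograms of
sender/receiver spike trains with condition-dependent lags.

Hit trials echo sender spikes 20 ms later, miss trials 60 ms later; the
z peak of the cross-correlogram recovers both lags, and the paired
contrast shows the hit lag is shorter.
"""

import numpy as np

import spikefield as sf
from spikefield import cofire

rng = np.random.default_rng(5)
results = []
for _ in range(6):  # six sender/receiver pairs
    res = {}
    for cond, lag in ((sf.HIT, 20.0), (sf.MISS, 60.0)):
        spec = sf.CofireSpec(lag_ms=lag, jitter_sd_ms=2.0, copy_prob=0.6,
                             background_rate=3.0)
        senders, receivers = [], []
        for _ in range(14):
            s = np.sort(rng.uniform(0, 1.0, rng.poisson(15)))
            senders.append(s if s.size else np.array([0.5]))
            receivers.append(sf.gen_cofiring_pair(senders[-1], spec, 1.0,
                                                  rng.integers(2**31)))
        res[cond] = cofire.cofiring_xcorr(senders, receivers, 1.0,
                                          n_shuffles=300,
                                          seed=rng.integers(2**31))
    results.append(res)

retained = [r for r in results if cofire.coincidence_filter(r)]
print(f"{len(retained)}/{len(results)} pairs pass the coincidence filter")
out = cofire.peak_lag_contrast(retained)
print(out["table"].to_string(index=False))
print(f"\nmean peak lag: hits {out['table']['lag_hit_ms'].mean():.1f} ms, "
      f"misses {out['table']['lag_miss_ms'].mean():.1f} ms")
print(f"paired t = {out['t']:.2f}, p = {out['p']:.2g}")
print("shorter hit lags sit inside the classic window where "
      "spike-timing-dependent plasticity strengthens the connection")
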