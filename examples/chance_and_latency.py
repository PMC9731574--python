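"""Task chance levels and the oscillation-frequency -> co-firing-latency
arithmetic.

Selecting two targets among four candidates in sequence gives a chance
level of 1/6 for recalling both (not 50%), and a constant quarter-cycle
phase lag between two coupled neurons translates into a firing latency
that shrinks as the coupling frequency rises.
"""

import numpy as np

import spikefield as sf

p = sf.chance_probabilities()
print("chance of both selections correct:  "
      f"{100 * p['p_both']:.2f}%  (the 'hit' chance level)")
print(f"chance of exactly one correct:      {100 * p['p_one']:.2f}%")
print(f"chance of a miss (anything less):   {100 * p['p_miss']:.2f}%")

quarter = np.pi / 2
for f in (8.0, 4.0):
    ms = sf.phase_lag_to_latency(quarter, f) * 1e3
    print(f"quarter-cycle lag at {f:.0f} Hz -> downstream neuron fires "
          f"{ms:.2f} ms later")
print("faster oscillations pack co-firing into shorter windows, the "
      "regime where spike-timing-dependent plasticity strengthens synapses")
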