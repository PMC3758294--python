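"""Anatomy of the Bayesian-Hebbian weight structure.

Presents two non-overlapping patterns to a small noiseless network and
prints the resulting weight statistics: units co-active during a
presentation end up coupled by positive log-odds weights, units active
in different patterns by negative ones (the lateral inhibition that
makes the patterns compete), and the bias tracks each unit's activation
history.
"""

import numpy as np

from latchnet import ModelParams, init_state, step

params = ModelParams(H=4, M=4)
pat_a = np.zeros(16); pat_a[[0, 4, 8, 12]] = 1.0
pat_b = np.zeros(16); pat_b[[1, 5, 9, 13]] = 1.0

state = init_state(params)
rng = np.random.default_rng(0)
for pat in (pat_a, pat_b):
    for _ in range(1000):  # 1 s presentation each
        step(state, params, rng, kappa=params.kappa_encode,
             g_w=params.g_w_encode, clamp_o=pat)

ia, ib = np.flatnonzero(pat_a), np.flatnonzero(pat_b)
within_a = state.w[np.ix_(ia, ia)]
within_b = state.w[np.ix_(ib, ib)]
between = state.w[np.ix_(ia, ib)]
print("mean weight within pattern A: %+.3f" % within_a.mean())
print("mean weight within pattern B: %+.3f" % within_b.mean())
print("mean weight between patterns: %+.3f" % between.mean())
print("bias of A units: %.2f   B units: %.2f   silent units: %.2f"
      % (state.beta[ia].mean(), state.beta[ib].mean(),
         np.delete(state.beta, np.r_[ia, ib]).mean()))
print("\nPositive within / negative between weights store each pattern "
      "as an attractor, mutually inhibitory with the other; units never "
      "stimulated keep the lowest bias.")
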