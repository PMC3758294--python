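# latchnet

A modular attractor-network model of working memory and immediate free
recall of word lists.

Classical network models hold items in working memory as persistent
activity.  `latchnet` implements the alternative: items are stored in
*fast, volatile Bayesian-Hebbian synaptic plasticity* (the BCPNN rule)
together with modulated intrinsic excitability, while spike-frequency
adaptation keeps terminating whatever is currently active.  The result
is latching dynamics — activity spontaneously hops between the stored
attractors — which doubles as the model's account of rehearsal during
list presentation and of retrieval during free recall.  The package
contains the network, the single-trial free-recall experiment protocol
(stimulus clamping, print-now gating, overlap-threshold recall
detection, trial batching, a divided-attention variant), and the
behavioral statistics used in the free-recall literature: serial
position curve, recall-length distribution, lag-CRP, and reactivation
analyses.

The model in brief (per unit `j`, forward Euler at 1 ms):

    τ_m ds_j/dt = β_j + Σ_i w_ij o_i + g_I log I_j − g_a a_j − s_j + noise
    o_j  = softmax of s within each hypercolumn
    τ_a da_j/dt = o_j − a_j

    weights and bias from running co-activation estimates, gated by the
    print-now parameter κ:
    w_ij = g_w log( p_ij / (p_i p_j) ),   β_j = g_b log p_j

See `docs/methods.md` for the full model description, parameter table,
and numerical choices.

## Worked example

```python
from latchnet import ModelParams, run_trial

params = ModelParams(recall_s=48.0)
log = run_trial(params, seed=42, n_items=3)
for e in log.first_recalls:
    print(f"t = {e.time_s:.2f} s  item {e.item}  dwell {e.dwell_s:.2f} s")
print("recall events per item:",
      [sum(e.item == k and e.phase == "recall" for e in log.events)
       for k in range(3)])
```

prints

```
t = 6.01 s  item 0  dwell 0.79 s
t = 7.20 s  item 1  dwell 0.67 s
t = 8.49 s  item 2  dwell 0.83 s
recall events per item: [12, 12, 11]
```

Three items are presented for one second each (two-second stimulus
cycle, so recall starts at t = 6 s); during the 48-second recall period
the network spontaneously reactivates every stored item about a dozen
times, dwelling ~0.7–0.8 s on each visit before adaptation ends it —
the latching that stands in for rehearsal and recall.  The `examples/`
scripts walk through the other capabilities one at a time:

- `examples/latching_dynamics.py` — the reactivation sequence above in
  full detail;
- `examples/free_recall_batch.py` — 12-item lists in batch: serial
  position curve, recall length, lag-CRP, reactivation gradient;
- `examples/divided_attention.py` — blocked reactivation during
  encoding versus focused encoding;
- `examples/learning_rule.py` — the sign structure of the learned
  weight matrix.

A thin CLI wraps the same library calls for batch use:

```bash
latchnet simulate --trials 64 --seed 7 --out events.csv
latchnet stats --events events.csv --n-items 12 --out curves.csv
latchnet sweep --param g_w_recall --values 1.6,1.7,1.8 \
    --trials 64 --seed 7 --target target_curves.csv --out sweep.csv
```

Every output CSV carries the resolved configuration hash and base seed;
identical configuration and seed reproduce outputs byte for byte.

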