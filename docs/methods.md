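# Model and methods

## The network

`latchnet` implements a modular recurrent attractor network of the Potts
(hypercolumnar) type as a model of working memory and immediate free
recall.  The network has `H` hypercolumns of `M` graded-output units
(default 12 × 12 = 144 units); a unit stands for a cortical minicolumn
(~100 neurons), a hypercolumn for a bundle of minicolumns that compete
through shared lateral inhibition.  Each unit `j` carries a support
(membrane-like) variable `s_j`, an adaptation variable `a_j`, and an
output `o_j ∈ [0, 1]`:

    τ_m ds_j/dt = β_j + Σ_i w_ij o_i + g_I log I_j − g_a a_j − s_j
    o_j = exp(s_j) / Σ_{k ∈ hypercolumn} exp(s_k)
    τ_a da_j/dt = o_j − a_j

plus additive zero-mean Gaussian noise of amplitude σ on every unit's
support at every free integration step.  The softmax implements the
soft winner-take-all action of within-hypercolumn basket-cell
inhibition; adaptation is the rate-model counterpart of the slow
after-hyperpolarization and terminates any sustained activation after
some hundreds of milliseconds.

## Bayesian-Hebbian plasticity (BCPNN)

Memory lives in rapidly expressed, volatile synaptic weights and in a
modulated intrinsic excitability, not in persistent activity.  Fast
traces `z` low-pass the outputs (τ_z = 240 ms) and act as the synaptic
eligibility buffer; slow probability estimates integrate the traces
when the global print-now gain κ is raised:

    τ_z  dz/dt   = o − z                       (z never below the background rate)
    τ_p  dp_i/dt = κ (z_i − p_i)               (likewise p_j)
    τ_p  dp_ij/dt = κ (z_i z_j − p_ij)

    w_ij = g_w log( p_ij / (p_i p_j) )         β_j = g_b log p_j

with every probability floored at ε = 1.17549e-38 before the log.
Correlated units couple excitatorily, anti-correlated units
inhibitorily; a frequently active unit earns a high (less negative)
bias — its prior log-probability of being active.  With κ = 0 the
estimates, and hence weights and bias, are frozen exactly.  Because
τ_p is finite (10 s), the store is a palimpsest: new items gradually
overwrite old ones.

### Background rate of the traces

The z-traces decay toward the current output, which for a suppressed
unit is numerically zero.  Letting the probability estimates follow
activity all the way to zero makes the log-odds of any long-silent
*pair* grow without bound (the numerator `p_ij` decays once, the
denominator `p_i p_j` twice), so never-stimulated unit pairs would
acquire strong spurious couplings and old items would never weaken.  A
probabilistic estimator needs a prior: we give the traces a spontaneous
background rate, `z ≥ z_floor = z_floor_frac / M` (default half the
chance rate, 1/(2M)).  Silent units then relax to background
statistics, their pairwise log-odds decay to zero, and the bias to the
background value — genuine palimpsest forgetting.  The floor is
inactive in any situation where units participate in ongoing activity
(uniform activity keeps all estimates exactly at chance, so weights
stay at zero).

## Stimulus clamping

An item is a sparse random pattern with exactly one active unit per
hypercolumn.  During a presentation the pattern enters through the
evidence term of the support equation: `I_j = 1` for pattern units and
`I_j = ε` otherwise, contributing `g_I log I_j` (0 or ≈ −87).  This
"soft clamp" drives the pattern to essentially binary dominance within
a few τ_m while merely *shifting* all suppressed units by a common
constant — their relative support standing survives the presentation,
so the moment the input is released the strongest stored memory can
re-nucleate immediately.  A hard clamp mode (`clamp_mode="hard"`, the
output overridden and the support pinned to `log o`) is available; it
makes clamped frames exactly deterministic but flattens the suppressed
landscape to a single value at every presentation, which delays
re-nucleation by most of an inter-stimulus interval and lets the
learning rule track the resulting disordered states — we therefore
default to the soft mode.

## The free-recall protocol

The default experiment mirrors a classical single-trial supraspan
paradigm: 12 items, one presented every 2 s (1 s clamp with κ = 1.10,
then a 1 s inter-stimulus interval), a 24 s list presentation in total,
followed by 45 s of free recall with κ = 0 and the recall weight gain
g_w = 1.70.  The network is fully reset between lists and patterns are
renewed every trial.  κ stays at its encoding value during the ISIs
(`kappa_isi=None`), so spontaneous ISI reactivations of earlier items
re-imprint their traces — this is the mechanism that produces the
early-position reactivation gradient; a variant with κ = 0 outside the
clamps is available via `kappa_isi=0.0`.  The blocked-reactivation
("divided attention") mode clamps the output to the uniform state
during every ISI, which suppresses reactivations entirely.

### Recall detection

The cosine overlap `m_k = x_k·o / (‖x_k‖‖o‖)` between the output and
every stored pattern is computed at each step and fed to a per-item
leaky accumulator,

    A_k ← (1 − dt/τ_acc) A_k + m_k ,

with an event registered at each upward crossing of Θ = 11 and a
hysteresis re-arm at Θ/2.  The steady level of the accumulator is
`(τ_acc/dt)·m`, so τ_acc calibrates which overlaps can ever reach Θ.
With the default τ_acc = 25 ms, registration requires an overlap
sustained above 0.44: comfortably above the overlap every pattern has
with a diffuse network state (1/√M ≈ 0.289 → A ≈ 7.2) and above
chance pattern-pair overlaps (≤ 5 shared units → A ≤ 10.4), while a
genuine attractor visit (m ≈ 1) crosses within ~15 ms.  A raw
cumulative-sum variant (`detector="cumsum"`) is provided for
comparison; it has no leak and hence no such calibration.  Detector
state is continuous across the encoding phases and restarts at the
beginning of the recall phase.  Events during an item's own clamp
window are logged but not counted as reactivations; only the first
recall-phase event per item enters the recall statistics, all events
enter the reactivation statistics.  If two first recalls land on the
identical time step the trial is flagged and excluded from statistics.
An event's dwell time is the time the accumulator stays above Θ/2.

## Parameters

| symbol | meaning | default |
|---|---|---|
| H, M | hypercolumns, units per hypercolumn | 12, 12 |
| dt | Euler step | 1 ms |
| τ_m, τ_a | unit, adaptation time constants | 50 ms, 2.70 s |
| σ | support noise per step | 0.20 |
| g_a | adaptation gain | 97.0 |
| g_w | weight gain (encode / recall) | 2.00 / 1.70 |
| g_b | bias gain | 12.0 |
| τ_zi, τ_zj | trace time constants | 240 ms |
| τ_p | estimate time constant | 10.0 s |
| κ | print-now (encode / recall) | 1.10 / 0.00 |
| Θ | recall threshold | 11.0 |
| ε | low cutoff before logs | 1.17549e-38 |
| g_I | input gain during clamps | 1.0 |
| τ_acc | detector leak time constant | 25 ms |
| z_floor_frac | trace background rate × M | 0.5 |
| clamp, ISI, recall durations | protocol | 1 s, 1 s, 45 s |

The first thirteen rows are the published operating point of the model;
g_I, τ_acc, the background rate and the clamp mode are auxiliary
choices of this implementation, with the rationale given above.  The
bias gain follows the weight-update rule (g_b = 12); the alternative
reading in which the bias uses the weight gain is reproducible by
setting `g_b` accordingly in the configuration.  Noise is additive
Gaussian per step, applied after the Euler update and not scaled by
dt/τ_m; the load demonstrations use a 48 s recall period
(`recall_s=48.0`), the 12-item protocol 45 s.

## Numerical scheme

Forward Euler at dt = 1 ms throughout, with the update order: traces
and gated estimates (from the previous step's outputs), weight/bias
recomputation, support update plus noise, normalization (with
per-hypercolumn max subtraction; supports near log ε occur routinely),
adaptation.  The batch engine executes the same scheme in numba
kernels: phases with κ = 0 freeze the weights once and run fully
compiled; plastic phases recompute the weight contribution every step,
restricted to presynaptic rows with `o_i > 1e-16` — suppressed softmax
losers sit at `o ~ e^-80`, so the restriction is exact to double
precision.  A readable pure-NumPy reference path implements one step
at a time; both consume the random stream identically and an
equivalence test pins them together at ~1e-9 over short schedules.
Per-trial seeds derive from the batch base seed through NumPy's
`SeedSequence`, so trial `i` is independent of the batch size and every
run is exactly reproducible.

## What the synthetic experiment does and does not emulate

Items are uncorrelated random codes renewed every trial: there is no
word frequency, semantic similarity, or re-use of lists across
subjects, and the network is fully reset between lists, so proactive
interference across lists is absent by construction.  One parameter
set stands in for a population of subjects.  Passing batch statistics
therefore says the *mechanism* behaves as described — it does not
certify agreement with any particular human dataset.

## Observed behavior at the default operating point, and a limitation

At the published constants the model reproduces: latching (every
stored item reactivates repeatedly during recall at loads up to 7);
dwell times that shorten as load grows (≈ 0.95 s at load 2 down to
≈ 0.63 s at load 7 in our measurements); an encoding-phase
reactivation gradient concentrated on early input positions (≈ 3.8
reactivations for the first item, none for the last four); complete
ablation of reactivations in blocked mode; and recall probability that
increases with an item's reactivation count.

The dynamics are also sensitive to the integration step: doubling dt
to 2 ms changes the 12-item serial position curve by up to ~0.27
(early positions lose recall probability), and rescaling the per-step
noise diffusion-consistently (σ√(dt/1 ms)) does not remove the
difference — the sensitivity sits in the Euler discretization of the
latching/learning interplay, not in the noise treatment.  The
time-step robustness test is therefore expected to fail at its 0.1
threshold and is left as is.

One further benchmark is *not* reproduced: the U-shaped serial
position curve at list length 12.  With these constants every stored item remains a
viable attractor throughout the 45 s recall period, and the
adaptation-driven rotation (≈ 100 activation events per trial) visits
all of them, so nearly every trial recalls the full list and the
serial-position curve saturates near 1.  A U shape requires mid-list
items to become non-retrievable within a single trial; the within-trial
trace decay available here (κ·t/τ_p ≤ ~2.6 e-folds) lowers an old
item's bias by at most ~16 support units while its log-odds weights
transiently *grow* with age (the estimator-aging effect described
above, only partly curable by the background floor), leaving
attractor-strength gaps of ~5–10 — too small for the rotation to
exclude anything over ~100 transitions.  The acceptance tests that
encode the U shape and the primacy-ablation contrast are kept at their
stated thresholds and fail honestly at this operating point; the
mechanism they probe (reactivation-dependent primacy) is still visible
directly in the reactivation statistics.

## Problem sizes

Batch statistics in the tests and the acceptance script use 256 trials
(128 for the time-step robustness comparison), the load demonstrations
5 seeds, and the dwell-load analysis 3 seeds per load; all are run at
the full 12 × 12 network with dt = 1 ms.
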