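"""Single-trial free-recall protocol and batch runner.

A trial presents ``n_items`` sparse random patterns to a freshly
initialized network — each clamped for ``item_clamp_s`` seconds with
plasticity gated on, followed by an inter-stimulus interval — and then
lets the network run freely for ``recall_s`` seconds with plasticity off
(``kappa = 0``) and the recall weight gain.  Throughout, the cosine
overlap ``m_k`` between the output and every stored pattern feeds a
per-item leaky accumulator; upward crossings of the threshold ``theta``
register activation events.  Events during the recall phase define the
recall sequence (first event per item); events during encoding outside an
item's own clamp window are its reactivations, the mechanism behind the
primacy effect.

The "blocked" variant clamps the output to the uniform state during every
inter-stimulus interval, suppressing reactivations — the model's analogue
of encoding under divided attention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _fastpath, plasticity
from .dynamics import NetworkState, init_state, step
from .params import ModelParams
from .patterns import PatternList, generate_list, overlap_all

__all__ = [
    "Phase",
    "Schedule",
    "build_schedule",
    "detect_recalls",
    "RecallEvent",
    "RecallEventLog",
    "run_trial",
    "run_batch",
    "events_frame",
    "derive_trial_seeds",
]

# generous bound on events per trial: one event needs a crossing plus a
# drop below theta/2, which takes tens of steps at minimum
_EVENT_CAP_DIVISOR = 8


@dataclass(frozen=True)
class Phase:
    """One schedule segment with its phase-dependent parameters."""

    kind: str               # "clamp" | "isi" | "recall" | "reset"
    duration_s: float
    n_steps: int
    kappa: float
    g_w: float
    g_I: float
    clamp_target: str       # "pattern" | "uniform" | "none"
    item: int | None = None


@dataclass(frozen=True)
class Schedule:
    phases: tuple[Phase, ...]
    n_items: int

    @property
    def encoding_span_s(self) -> float:
        return sum(p.duration_s for p in self.phases
                   if p.kind in ("clamp", "isi"))

    @property
    def total_steps(self) -> int:
        return sum(p.n_steps for p in self.phases)


def _steps(duration_s: float, dt: float) -> int:
    n = round(duration_s / dt)
    if not math.isclose(n * dt, duration_s, rel_tol=0.0, abs_tol=1e-9):
        raise ValueError(
            f"phase duration {duration_s} s is not a multiple of dt={dt}")
    return n


def build_schedule(n_items: int, params: ModelParams,
                   blocked: bool = False) -> Schedule:
    """Standard list schedule: per item a clamp plus an ISI, then the
    free-recall phase.

    Clamps carry ``kappa_encode``/``g_w_encode`` with input gain 1; ISIs
    have no input (clamped to uniform in blocked mode) and the ISI
    plasticity gate; the recall phase runs ``kappa_recall`` (0 by
    default) at ``g_w_recall``.
    """
    if n_items < 1:
        raise ValueError(f"n_items must be >= 1, got {n_items}")
    phases: list[Phase] = []
    for k in range(n_items):
        phases.append(Phase(
            kind="clamp", duration_s=params.item_clamp_s,
            n_steps=_steps(params.item_clamp_s, params.dt),
            kappa=params.kappa_encode, g_w=params.g_w_encode, g_I=params.g_I,
            clamp_target="pattern", item=k))
        phases.append(Phase(
            kind="isi", duration_s=params.isi_s,
            n_steps=_steps(params.isi_s, params.dt),
            kappa=params.kappa_isi_effective, g_w=params.g_w_encode,
            g_I=0.0, clamp_target="uniform" if blocked else "none"))
    phases.append(Phase(
        kind="recall", duration_s=params.recall_s,
        n_steps=_steps(params.recall_s, params.dt),
        kappa=params.kappa_recall, g_w=params.g_w_recall, g_I=0.0,
        clamp_target="none"))
    return Schedule(phases=tuple(phases), n_items=n_items)


def _leak(params: ModelParams) -> float:
    """Per-step leak of the detector accumulator (0 for the literal
    cumulative-sum variant)."""
    if params.detector == "cumsum":
        return 0.0
    return params.dt / params.tau_acc


def detect_recalls(m_timeseries: np.ndarray, params: ModelParams,
                   t0_step: int = 0) -> pd.DataFrame:
    """Run the recall detector over an overlap time series.

    Per item ``k`` a leaky accumulator ``A_k <- (1 - dt/tau_acc) A_k +
    m_k`` is advanced each step; an event is registered at each upward
    crossing of ``theta``, and a new event for the same item requires the
    accumulator to first fall below ``theta/2`` (hysteresis).  Events
    whose accumulator has not dropped below ``theta/2`` by the end of the
    series are closed there.

    Returns a DataFrame with columns ``step``, ``item``, ``end_step``,
    ``dwell_steps`` sorted by ``step``.
    """
    m = np.ascontiguousarray(m_timeseries, dtype=np.float64)
    if m.ndim != 2:
        raise ValueError("m_timeseries must be (n_steps, n_items)")
    T, K = m.shape
    cap = max(T // _EVENT_CAP_DIVISOR, 64)
    A = np.zeros(K)
    open_ev = np.full(K, -1, dtype=np.int64)
    ev_step = np.zeros(cap, dtype=np.int64)
    ev_item = np.zeros(cap, dtype=np.int64)
    ev_end = np.zeros(cap, dtype=np.int64)
    n_ev = _fastpath.detect_events_jit(m, _leak(params), params.theta,
                                       t0_step, A, open_ev,
                                       ev_step, ev_item, ev_end, 0)
    if n_ev > cap:
        raise RuntimeError(f"event buffer overflow ({n_ev} > {cap})")
    end_step = ev_end[:n_ev].copy()
    end_step[end_step < 0] = t0_step + T
    return pd.DataFrame({
        "step": ev_step[:n_ev], "item": ev_item[:n_ev],
        "end_step": end_step,
        "dwell_steps": end_step - ev_step[:n_ev],
    })


@dataclass(frozen=True)
class RecallEvent:
    """One registered activation of a stored item."""

    time_s: float
    step: int
    item: int
    phase: str          # "clamp" | "isi" | "recall"
    own_clamp: bool     # event fired during this item's own presentation
    ordinal: int        # 1-based event count for this item within the trial
    dwell_s: float      # time the accumulator stayed above theta/2
    first_recall: bool  # first recall-phase event of this item


@dataclass
class RecallEventLog:
    """Complete timestamped record of one trial."""

    trial: int
    seed: int
    n_items: int
    blocked: bool
    patterns: PatternList
    events: list[RecallEvent]
    excluded: bool = False
    exclusion_reason: str | None = None
    overlaps: np.ndarray | None = None   # (total_steps, n_items) if recorded

    @property
    def first_recalls(self) -> list[RecallEvent]:
        """Recall-phase first events, in registration order."""
        return [e for e in self.events if e.first_recall]

    @property
    def recalled_positions(self) -> list[int]:
        """Input positions (0-based) in order of first recall."""
        return [e.item for e in self.first_recalls]

    def reactivation_counts(self) -> np.ndarray:
        """Encoding-phase reactivations per item (events outside the
        item's own clamp window)."""
        counts = np.zeros(self.n_items, dtype=np.int64)
        for e in self.events:
            if e.phase != "recall" and not e.own_clamp:
                counts[e.item] += 1
        return counts


def _phase_lookup(schedule: Schedule) -> list[tuple[int, int, Phase]]:
    out, t = [], 0
    for ph in schedule.phases:
        out.append((t, t + ph.n_steps, ph))
        t += ph.n_steps
    return out


def _finalize_events(schedule: Schedule, params: ModelParams,
                     ev_step: np.ndarray, ev_item: np.ndarray,
                     ev_end: np.ndarray, n_ev: int,
                     recall_start: int, total_steps: int,
                     ) -> tuple[list[RecallEvent], bool, str | None]:
    """Assign phases/ordinals/dwells and apply the simultaneous-recall
    exclusion rule to raw kernel event arrays."""
    lookup = _phase_lookup(schedule)
    order = np.argsort(ev_step[:n_ev], kind="stable")
    per_item_count: dict[int, int] = {}
    first_seen: set[int] = set()
    events: list[RecallEvent] = []
    first_steps: list[int] = []
    for idx in order:
        t = int(ev_step[idx])
        k = int(ev_item[idx])
        end = int(ev_end[idx])
        if end < 0:
            end = recall_start if t < recall_start else total_steps
        phase = None
        own = False
        for lo, hi, ph in lookup:
            if lo <= t < hi:
                phase = ph.kind
                own = ph.kind == "clamp" and ph.item == k
                break
        assert phase is not None
        per_item_count[k] = per_item_count.get(k, 0) + 1
        is_first = phase == "recall" and k not in first_seen
        if is_first:
            first_seen.add(k)
            first_steps.append(t)
        events.append(RecallEvent(
            time_s=t * params.dt, step=t, item=k, phase=phase,
            own_clamp=own, ordinal=per_item_count[k],
            dwell_s=(end - t) * params.dt, first_recall=is_first))
    excluded = False
    reason = None
    if len(first_steps) != len(set(first_steps)):
        excluded = True
        reason = "simultaneous-recall"
    return events, excluded, reason


def run_trial(
    params: ModelParams,
    seed: int | np.random.Generator,
    n_items: int = 12,
    blocked: bool = False,
    patterns: PatternList | None = None,
    backend: str = "fast",
    record_overlaps: bool = False,
    trial: int = 0,
    return_state: bool = False,
):
    """Run one full free-recall trial from a fresh network.

    The RNG stream is consumed identically by both backends (pattern
    draw, then one ``standard_normal(n)`` per free step in step order), so
    a given seed produces one answer.  ``backend="numpy"`` runs the
    readable reference step loop; ``backend="fast"`` runs the numba
    kernels.  With ``record_overlaps`` the full ``m_k`` time series is
    kept on the log (for dynamics figures and the detector oracle).
    """
    if isinstance(seed, np.random.Generator):
        rng, seed_val = seed, -1
    else:
        rng, seed_val = np.random.default_rng(seed), int(seed)
    if patterns is None:
        patterns = generate_list(n_items, params, rng)
    if patterns.n_items != n_items:
        raise ValueError("pattern list size does not match n_items")
    schedule = build_schedule(n_items, params, blocked)
    state = init_state(params)
    total_steps = schedule.total_steps
    cap = max(total_steps // _EVENT_CAP_DIVISOR, 64)
    ev_step = np.zeros(cap, dtype=np.int64)
    ev_item = np.zeros(cap, dtype=np.int64)
    ev_end = np.zeros(cap, dtype=np.int64)
    A = np.zeros(n_items)
    open_ev = np.full(n_items, -1, dtype=np.int64)
    n_ev = 0
    leak = _leak(params)
    m_rec = np.zeros((total_steps, n_items)) if record_overlaps \
        else np.zeros((1, 1))
    record = 1 if record_overlaps else 0

    cols = np.ascontiguousarray(
        (np.arange(params.H) * params.M)[None, :] + patterns.active)
    dense = patterns.dense()
    sqrtH = float(np.sqrt(params.H))
    n = params.n_units
    c_a = params.dt / params.tau_a
    c_zi = params.dt / params.tau_zi
    c_zj = params.dt / params.tau_zj
    dt_tau_m = params.dt / params.tau_m
    recall_start = sum(ph.n_steps for ph in schedule.phases
                       if ph.kind != "recall")

    if backend == "numpy":
        n_ev = _run_reference(params, schedule, state, rng, dense, cols,
                              patterns, A, open_ev, ev_step, ev_item,
                              ev_end, leak, m_rec, record, recall_start)
    elif backend == "fast":
        n_ev = _run_fast(params, schedule, state, rng, dense, cols, sqrtH,
                         A, open_ev, ev_step, ev_item, ev_end, leak,
                         m_rec, record, recall_start,
                         c_a, c_zi, c_zj, dt_tau_m)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    if n_ev > cap:
        raise RuntimeError(f"event buffer overflow ({n_ev} > {cap})")

    events, excluded, reason = _finalize_events(
        schedule, params, ev_step, ev_item, ev_end, n_ev,
        recall_start, total_steps)
    log = RecallEventLog(
        trial=trial, seed=seed_val, n_items=n_items, blocked=blocked,
        patterns=patterns, events=events, excluded=excluded,
        exclusion_reason=reason,
        overlaps=m_rec if record_overlaps else None)
    if return_state:
        return log, state
    return log


def _clamp_vectors(params: ModelParams, target: str, dense: np.ndarray,
                   item: int | None) -> tuple[np.ndarray, np.ndarray]:
    if target == "pattern":
        o_c = dense[item].astype(np.float64)
    elif target == "uniform":
        o_c = np.full(params.n_units, 1.0 / params.M)
    else:
        raise ValueError(f"bad clamp target {target!r}")
    return o_c, np.log(np.maximum(o_c, params.epsilon))


def _run_fast(params, schedule, state, rng, dense, cols, sqrtH,
              A, open_ev, ev_step, ev_item, ev_end, leak,
              m_rec, record, recall_start, c_a, c_zi, c_zj, dt_tau_m):
    """Phase-by-phase execution through the numba kernels."""
    n = params.n_units
    n_ev = 0
    t = 0
    hard = params.clamp_mode == "hard"
    for ph in schedule.phases:
        if ph.kind == "reset":
            fresh = init_state(params)
            for name in ("s", "a", "o", "z_i", "z_j", "p_i", "p_j",
                         "p_ij", "w", "beta"):
                getattr(state, name)[...] = getattr(fresh, name)
            t += ph.n_steps
            continue
        if ph.kind == "recall":
            # close encoding events still above theta/2, then restart the
            # detector for clean recall registration
            for k in range(open_ev.size):
                if open_ev[k] >= 0:
                    ev_end[open_ev[k]] = t
                    open_ev[k] = -1
            A[:] = 0.0
        c_p = ph.kappa * params.dt / params.tau_p
        is_clamped = (hard and ph.clamp_target == "pattern") or \
            ph.clamp_target == "uniform"
        if is_clamped:
            o_c, log_o_c = _clamp_vectors(params, ph.clamp_target, dense,
                                          ph.item)
            n_ev = _fastpath.run_clamp_phase(
                ph.n_steps, t, o_c, log_o_c,
                state.s, state.a, state.o, state.z_i, state.z_j,
                state.p_i, state.p_j, state.p_ij,
                c_zi, c_zj, c_p, params.z_floor, c_a, cols, sqrtH,
                A, open_ev, leak,
                params.theta, ev_step, ev_item, ev_end, n_ev,
                record, m_rec[t:t + ph.n_steps] if record else m_rec)
        elif c_p == 0.0 and ph.clamp_target == "none":
            # frozen plasticity, no input: weights and bias constant
            w = plasticity.compute_weights(state.p_i, state.p_j,
                                           state.p_ij, ph.g_w,
                                           params.epsilon)
            beta = plasticity.compute_bias(state.p_j, params.g_b,
                                           params.epsilon)
            state.w, state.beta = w, beta
            done = 0
            while done < ph.n_steps:
                chunk = min(5000, ph.n_steps - done)
                noise = params.sigma * rng.standard_normal((chunk, n)) \
                    if params.sigma > 0 else np.zeros((chunk, n))
                rc = _fastpath.run_recall_chunk(
                    chunk, t + done, state.s, state.a, state.o,
                    state.z_i, state.z_j, c_zi, c_zj, params.z_floor,
                    w, beta, params.g_a, dt_tau_m, noise,
                    params.H, params.M, c_a, cols, sqrtH, A, open_ev,
                    leak, params.theta, ev_step, ev_item, ev_end, n_ev,
                    record, m_rec, t + done if record else 0)
                if rc < 0:
                    raise FloatingPointError(
                        f"non-finite support at unit {-1 - rc} "
                        f"(step {t + done})")
                n_ev = rc
                done += chunk
        else:
            # plastic free phase: trace, estimate and weight
            # recomputation every step, run fully jitted
            if ph.g_I != 0.0 and ph.clamp_target == "pattern":
                ext = ph.g_I * np.log(np.maximum(dense[ph.item],
                                                 params.epsilon))
            else:
                ext = np.zeros(n)
            done = 0
            while done < ph.n_steps:
                chunk = min(5000, ph.n_steps - done)
                noise = params.sigma * rng.standard_normal((chunk, n)) \
                    if params.sigma > 0 else np.zeros((chunk, n))
                rc = _fastpath.run_plastic_chunk(
                    chunk, t + done, state.s, state.a, state.o,
                    state.z_i, state.z_j, state.p_i, state.p_j,
                    state.p_ij, c_zi, c_zj, c_p, params.z_floor, ext,
                    ph.g_w, params.g_b, params.epsilon, params.g_a,
                    dt_tau_m, noise, params.H, params.M, c_a, cols,
                    sqrtH, A, open_ev, leak, params.theta,
                    ev_step, ev_item, ev_end, n_ev,
                    record, m_rec, t + done if record else 0)
                if rc < 0:
                    raise FloatingPointError(
                        f"non-finite support at unit {-1 - rc} "
                        f"(step {t + done})")
                n_ev = rc
                done += chunk
            state.w = plasticity.compute_weights(
                state.p_i, state.p_j, state.p_ij, ph.g_w, params.epsilon)
            state.beta = plasticity.compute_bias(state.p_j, params.g_b,
                                                 params.epsilon)
        t += ph.n_steps
        state.n_steps = t
        state.t = t * params.dt
    # close any events still open at the end of the trial
    for k in range(open_ev.size):
        if open_ev[k] >= 0:
            ev_end[open_ev[k]] = t
            open_ev[k] = -1
    # keep the exported state's w/beta consistent with the last phase
    last = schedule.phases[-1]
    state.w = plasticity.compute_weights(state.p_i, state.p_j, state.p_ij,
                                         last.g_w, params.epsilon)
    state.beta = plasticity.compute_bias(state.p_j, params.g_b,
                                         params.epsilon)
    return n_ev


def _run_reference(params, schedule, state, rng, dense, cols, patterns,
                   A, open_ev, ev_step, ev_item, ev_end, leak,
                   m_rec, record, recall_start):
    """Reference execution: the readable step function plus the
    stand-alone detector, phase by phase (detector state restarts at the
    recall phase exactly as in the fast path)."""
    total = schedule.total_steps
    m_all = np.zeros((total, schedule.n_items))
    t = 0
    hard = params.clamp_mode == "hard"
    for ph in schedule.phases:
        if ph.kind == "reset":
            fresh = init_state(params)
            for name in ("s", "a", "o", "z_i", "z_j", "p_i", "p_j",
                         "p_ij", "w", "beta"):
                getattr(state, name)[...] = getattr(fresh, name)
            t += ph.n_steps
            continue
        clamp_o = None
        input_I = None
        if ph.clamp_target == "pattern":
            if hard:
                clamp_o = dense[ph.item]
            else:
                input_I = np.maximum(dense[ph.item], params.epsilon)
        elif ph.clamp_target == "uniform":
            clamp_o = np.full(params.n_units, 1.0 / params.M)
        for i in range(ph.n_steps):
            step(state, params, rng, kappa=ph.kappa, g_w=ph.g_w,
                 g_I=ph.g_I if input_I is not None else 0.0,
                 input_I=input_I, clamp_o=clamp_o)
            m_all[t + i] = overlap_all(patterns, state.o)
        t += ph.n_steps
    if record:
        m_rec[...] = m_all
    n_ev = _fastpath.detect_events_jit(
        np.ascontiguousarray(m_all[:recall_start]), leak, params.theta,
        0, A, open_ev, ev_step, ev_item, ev_end, 0)
    # close encoding events and restart detection for the recall phase
    for k in range(open_ev.size):
        if open_ev[k] >= 0:
            ev_end[open_ev[k]] = recall_start
            open_ev[k] = -1
    A[:] = 0.0
    n_ev = _fastpath.detect_events_jit(
        np.ascontiguousarray(m_all[recall_start:]), leak, params.theta,
        recall_start, A, open_ev, ev_step, ev_item, ev_end, n_ev)
    for k in range(open_ev.size):
        if open_ev[k] >= 0:
            ev_end[open_ev[k]] = total
            open_ev[k] = -1
    return n_ev


def derive_trial_seeds(base_seed: int, n_trials: int) -> np.ndarray:
    """Reproducible per-trial seeds from one base seed (stable across
    batch sizes: trial i's seed does not depend on n_trials)."""
    ss = np.random.SeedSequence(base_seed)
    return ss.generate_state(n_trials, dtype=np.uint64) >> np.uint64(1)


def run_batch(
    n_trials: int,
    params: ModelParams,
    base_seed: int,
    n_items: int = 12,
    blocked: bool = False,
    backend: str = "fast",
    progress: bool = False,
) -> list[RecallEventLog]:
    """Run ``n_trials`` independent trials with derived per-trial seeds.

    Patterns are renewed on every trial and the network is fully reset;
    excluded trials are kept in the output, flagged.
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    seeds = derive_trial_seeds(base_seed, n_trials)
    logs = []
    for i in range(n_trials):
        logs.append(run_trial(params, int(seeds[i]), n_items=n_items,
                              blocked=blocked, backend=backend, trial=i))
        if progress and (i + 1) % 16 == 0:
            print(f"  trial {i + 1}/{n_trials}", flush=True)
    return logs


def events_frame(logs: list[RecallEventLog]) -> pd.DataFrame:
    """Flatten logs into the tidy event table used by the CSV interface."""
    rows = []
    for log in logs:
        if not log.events:
            rows.append({
                "trial": log.trial, "seed": log.seed, "time_s": np.nan,
                "item": -1, "phase": "", "own_clamp": False, "ordinal": 0,
                "dwell_s": np.nan, "first_recall": False,
                "excluded": log.excluded})
        for e in log.events:
            rows.append({
                "trial": log.trial, "seed": log.seed, "time_s": e.time_s,
                "item": e.item, "phase": e.phase, "own_clamp": e.own_clamp,
                "ordinal": e.ordinal, "dwell_s": e.dwell_s,
                "first_recall": e.first_recall, "excluded": log.excluded})
    return pd.DataFrame(rows)
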