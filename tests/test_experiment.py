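"""Free-recall protocol: schedule construction, recall detection,
trial/batch execution, determinism, and fast-vs-reference agreement."""

import numpy as np
import pandas as pd
import pytest

from latchnet import (ModelParams, build_schedule, detect_recalls,
                      events_frame, run_batch, run_trial)
from latchnet.experiment import _finalize_events, derive_trial_seeds


class TestSchedule:
    def test_twelve_item_encoding_spans_24s(self, params):
        sched = build_schedule(12, params)
        assert sched.encoding_span_s == pytest.approx(24.0)
        assert sched.phases[-1].kind == "recall"
        assert sched.phases[-1].duration_s == pytest.approx(45.0)

    def test_phase_parameters(self, params):
        sched = build_schedule(2, params)
        clamp, isi = sched.phases[0], sched.phases[1]
        assert clamp.kind == "clamp"
        assert clamp.kappa == params.kappa_encode == 1.10
        assert clamp.g_w == params.g_w_encode == 2.00
        assert clamp.g_I == 1.0 and clamp.clamp_target == "pattern"
        assert isi.g_I == 0.0 and isi.clamp_target == "none"
        rec = sched.phases[-1]
        assert rec.kappa == params.kappa_recall == 0.0
        assert rec.g_w == params.g_w_recall == 1.70

    def test_blocked_isis_clamp_to_uniform(self, params):
        sched = build_schedule(3, params, blocked=True)
        for ph in sched.phases:
            if ph.kind == "isi":
                assert ph.clamp_target == "uniform"

    def test_duration_not_multiple_of_dt_rejected(self, params):
        bad = params.replace(item_clamp_s=0.0015, dt=0.002)
        with pytest.raises(ValueError, match="multiple"):
            build_schedule(2, bad)


class TestDetector:
    def test_sustained_full_overlap_crosses_at_step_13(self, params):
        """m=1 with tau_acc=50 ms and theta=11: the accumulator
        A_t = (1 - 0.98^t)/0.02 first reaches 11 at step 13."""
        p = params.replace(tau_acc=0.050)
        m = np.ones((100, 1))
        ev = detect_recalls(m, p)
        assert len(ev) == 1
        assert ev.step.iloc[0] == 12  # 13th step, 0-based

    def test_chance_overlap_never_registers(self, params):
        """m = 1/12 saturates the accumulator at m*tau_acc/dt < theta."""
        for tau in (0.025, 0.050):
            p = params.replace(tau_acc=tau)
            ev = detect_recalls(np.full((20000, 2), 1 / 12), p)
            assert len(ev) == 0

    def test_zero_overlap_no_events(self, params):
        assert len(detect_recalls(np.zeros((5000, 3)), params)) == 0

    def test_hysteresis_requires_drop_below_half_theta(self, params):
        """A second event needs the accumulator to fall below theta/2
        first; a shallow dip does not re-arm the detector."""
        p = params.replace(tau_acc=0.025)
        on, off = np.ones((600, 1)), np.zeros((100, 1))
        shallow = np.full((25, 1), 0.35)  # A stays above theta/2
        m = np.vstack([on, shallow, on, off, on])
        ev = detect_recalls(m, p)
        assert len(ev) == 2
        assert ev.dwell_steps.iloc[0] > 600

    def test_cumsum_variant_has_no_leak(self, params):
        p = params.replace(detector="cumsum")
        ev = detect_recalls(np.full((100, 1), 1.0), p)
        assert len(ev) == 1
        assert ev.step.iloc[0] == 10  # sum reaches 11 at the 11th step


class TestTrial:
    def test_identical_seeds_identical_logs(self, small_params):
        a = run_trial(small_params, seed=5, n_items=2)
        b = run_trial(small_params, seed=5, n_items=2)
        assert [(e.step, e.item, e.phase) for e in a.events] == \
               [(e.step, e.item, e.phase) for e in b.events]
        pd.testing.assert_frame_equal(events_frame([a]), events_frame([b]))

    def test_fast_and_reference_backends_agree(self, small_params):
        lf, sf = run_trial(small_params, seed=11, n_items=3,
                           return_state=True)
        lr, sr = run_trial(small_params, seed=11, n_items=3,
                           backend="numpy", return_state=True)
        for name in ("s", "a", "o", "z_i", "z_j", "p_i", "p_j", "p_ij"):
            assert np.allclose(getattr(sf, name), getattr(sr, name),
                               atol=1e-9), name
        assert [(e.step, e.item) for e in lf.events] == \
               [(e.step, e.item) for e in lr.events]

    def test_backends_agree_in_hard_clamp_and_blocked_modes(self):
        p = ModelParams(H=4, M=4, item_clamp_s=0.2, isi_s=0.2,
                        recall_s=0.5, clamp_mode="hard")
        for blocked in (False, True):
            lf, sf = run_trial(p, seed=3, n_items=2, blocked=blocked,
                               return_state=True)
            lr, sr = run_trial(p, seed=3, n_items=2, blocked=blocked,
                               backend="numpy", return_state=True)
            assert np.allclose(sf.s, sr.s, atol=1e-9)
            assert np.allclose(sf.p_ij, sr.p_ij, atol=1e-12)
            assert [(e.step, e.item) for e in lf.events] == \
                   [(e.step, e.item) for e in lr.events]

    def test_own_clamp_events_not_counted_as_reactivations(self, params):
        log = run_trial(params, seed=3, n_items=3)
        own = [e for e in log.events if e.own_clamp]
        assert own, "stimulus presentations should register events"
        counts = log.reactivation_counts()
        non_own = [e for e in log.events
                   if e.phase != "recall" and not e.own_clamp]
        assert counts.sum() == len(non_own)

    def test_detector_restarts_at_recall_phase(self, params):
        """Recall-phase first events are fresh crossings, not carryover:
        every first recall's step lies inside the recall phase."""
        log = run_trial(params, seed=9, n_items=3)
        rs = round(3 * 2 / params.dt)
        for e in log.first_recalls:
            assert e.step >= rs

    def test_overlap_recording_matches_detector(self, small_params):
        """The stand-alone detector applied to the recorded overlap
        series reproduces the trial's event log (encoding phases and the
        recall phase are separate detector segments)."""
        p = small_params
        log = run_trial(p, seed=21, n_items=2, record_overlaps=True)
        rs = round(2 * 0.4 / p.dt)
        enc = detect_recalls(log.overlaps[:rs], p)
        rec = detect_recalls(log.overlaps[rs:], p, t0_step=rs)
        got = [(e.step, e.item) for e in log.events]
        expect = [(int(r.step), int(r.item)) for r in enc.itertuples()]
        expect += [(int(r.step), int(r.item)) for r in rec.itertuples()]
        assert sorted(got) == sorted(expect)


class TestBatch:
    def test_trial_seeds_stable_under_batch_size(self):
        assert np.array_equal(derive_trial_seeds(7, 4),
                              derive_trial_seeds(7, 16)[:4])

    def test_batch_runs_independent_flagged_trials(self, small_params):
        logs = run_batch(3, small_params, base_seed=1, n_items=2)
        assert [lg.trial for lg in logs] == [0, 1, 2]
        assert len({lg.seed for lg in logs}) == 3
        # a batch trial equals the same trial run stand-alone
        solo = run_trial(small_params, seed=logs[1].seed, n_items=2,
                         trial=1)
        assert [(e.step, e.item) for e in solo.events] == \
               [(e.step, e.item) for e in logs[1].events]

    def test_invalid_trial_count(self, small_params):
        with pytest.raises(ValueError):
            run_batch(0, small_params, base_seed=1)


class TestExclusion:
    def test_simultaneous_first_recalls_flag_trial(self, params):
        """Two items whose first recall-phase crossing lands on the same
        step mark the trial excluded."""
        sched = build_schedule(2, params)
        rs = sum(ph.n_steps for ph in sched.phases[:-1])
        ev_step = np.array([rs + 50, rs + 50, rs + 90])
        ev_item = np.array([0, 1, 0])
        ev_end = np.array([rs + 60, rs + 60, rs + 95])
        events, excluded, reason = _finalize_events(
            sched, params, ev_step, ev_item, ev_end, 3, rs,
            sched.total_steps)
        assert excluded and reason == "simultaneous-recall"
        assert len(events) == 3

    def test_distinct_steps_not_flagged(self, params):
        sched = build_schedule(2, params)
        rs = sum(ph.n_steps for ph in sched.phases[:-1])
        events, excluded, _ = _finalize_events(
            sched, params, np.array([rs + 50, rs + 51]),
            np.array([0, 1]), np.array([rs + 60, rs + 61]), 2, rs,
            sched.total_steps)
        assert not excluded
        assert [e.first_recall for e in events] == [True, True]
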