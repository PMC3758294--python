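"""Model parameters for the modular attractor working-memory network.

The network is a Potts-style architecture: ``H`` hypercolumns of ``M``
graded-output units each, with soft winner-take-all normalization inside
every hypercolumn, all-to-all plastic connectivity between units, and slow
spike-frequency-like adaptation.  :class:`ModelParams` collects every
constant of the model together with the free-recall schedule durations and
the recall-detector settings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

__all__ = ["ModelParams"]


@dataclass(frozen=True)
class ModelParams:
    """All constants of the network model and the free-recall protocol.

    Defaults are the published operating point of the model: a 12x12
    network stepped at 1 ms, with fast z-traces (240 ms), slow probability
    estimates (10 s), strong adaptation (g_a = 97, tau_a = 2.7 s) and the
    encode/recall switching of the print-now gain ``kappa`` and the weight
    gain ``g_w``.

    Parameters
    ----------
    H, M
        Number of hypercolumns and units per hypercolumn.
    dt
        Forward-Euler step size in seconds.
    tau_m, tau_a
        Unit (membrane-like) and adaptation time constants, seconds.
    sigma
        Amplitude of the zero-mean Gaussian noise added to each unit's
        support after every free (non-clamped) integration step.
    g_a
        Adaptation gain (drive is ``-g_a * a_j``).
    g_w_encode, g_w_recall
        Weight gain applied to the log-odds weights during encoding and
        recall phases respectively.
    g_b
        Gain of the intrinsic-excitability bias ``beta_j = g_b log p_j``.
    tau_zi, tau_zj
        Pre- and post-synaptic trace time constants, seconds.
    tau_p
        Time constant of the slow probability estimates, seconds; sets the
        palimpsest forgetting horizon.
    kappa_encode, kappa_recall
        Print-now (plasticity gate) values for encoding and recall.
    kappa_isi
        Print-now value during inter-stimulus intervals.  ``None`` (the
        default) means "same as encoding": plasticity stays on throughout
        the list presentation, so ISI reactivations strengthen the
        reactivated item and the store forgets with a horizon of roughly
        ``tau_p`` of elapsed time.  Set 0.0 for the variant with
        plasticity strictly confined to clamped presentations.
    theta
        Recall-detector threshold on the leaky-accumulated overlap.
    epsilon
        Low cutoff applied to probabilities before logs (single-precision
        tiny).
    z_floor_frac
        Spontaneous background rate of the plasticity traces, as a
        fraction of the chance rate ``1/M``: the z-traces never decay
        below ``z_floor_frac / M``.  This is the pseudocount prior of a
        Bayesian estimator — silent units are treated as having a small
        spontaneous rate — and it is what makes the store a genuine
        palimpsest: an unrehearsed item's estimates relax toward
        background statistics, so its log-odds weights decay to zero and
        its bias to the background value, instead of the odds ratio
        growing without bound as numerator and denominator both decay to
        zero.  0 disables the floor.
    g_I
        Gain of the external evidence term ``g_I * log I_j`` used by the
        soft-clamp input mode.
    tau_acc
        Leak time constant (s) of the recall detector's per-item
        accumulator.  The steady-state accumulator level for a sustained
        overlap ``m`` is ``(tau_acc/dt) * m``, so with the default 25 ms
        and ``theta = 11`` an item registers only when its overlap is
        sustained above 0.44 — safely over the ``1/sqrt(M)`` (~0.29)
        overlap every pattern has with a diffuse network state, and over
        chance pattern-pair overlaps, while a genuine attractor visit
        (``m ~ 1``) crosses within ~15 ms.
    item_clamp_s, isi_s, recall_s
        Schedule durations: stimulus clamp, inter-stimulus interval, and
        free-recall period, seconds.
    clamp_mode
        "soft" (default): the stimulus enters as the evidence term
        ``g_I log I_j`` of the support equation, which suppresses
        non-stimulus units by a uniform ~log(epsilon) shift while
        preserving their relative standing — the stored landscape
        re-emerges the moment the input is released.  "hard": the output
        is overridden by the stimulus pattern and the support pinned to
        ``log o`` (fully deterministic clamped frames, but the landscape
        is flattened at every presentation).
    detector
        "leaky" (default) or "cumsum" (no leak; the raw running sum).
    """

    H: int = 12
    M: int = 12
    dt: float = 0.001
    tau_m: float = 0.050
    tau_a: float = 2.70
    sigma: float = 0.20
    g_a: float = 97.0
    g_w_encode: float = 2.00
    g_w_recall: float = 1.70
    g_b: float = 12.0
    tau_zi: float = 0.240
    tau_zj: float = 0.240
    tau_p: float = 10.0
    kappa_encode: float = 1.10
    kappa_recall: float = 0.00
    kappa_isi: float | None = None
    theta: float = 11.0
    epsilon: float = 1.17549e-38
    z_floor_frac: float = 0.5
    g_I: float = 1.0
    tau_acc: float = 0.025
    item_clamp_s: float = 1.0
    isi_s: float = 1.0
    recall_s: float = 45.0
    clamp_mode: str = "soft"
    detector: str = "leaky"

    @property
    def n_units(self) -> int:
        return self.H * self.M

    @property
    def z_floor(self) -> float:
        """Background rate of the plasticity traces."""
        return self.z_floor_frac / self.M

    @property
    def kappa_isi_effective(self) -> float:
        return self.kappa_encode if self.kappa_isi is None else self.kappa_isi

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise ``ValueError`` naming the offending field if invalid."""
        if self.H < 1:
            raise ValueError(f"H must be >= 1, got {self.H}")
        if self.M < 2:
            raise ValueError(f"M must be >= 2, got {self.M}")
        for name in ("dt", "tau_m", "tau_a", "tau_zi", "tau_zj", "tau_p",
                     "tau_acc", "item_clamp_s", "isi_s", "recall_s"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if not self.dt < min(self.tau_m, self.tau_zi, self.tau_zj):
            raise ValueError("dt must be smaller than the fastest time "
                             f"constant, got dt={self.dt}")
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if not 0 <= self.z_floor_frac < 1:
            raise ValueError(f"z_floor_frac must be in [0, 1), got "
                             f"{self.z_floor_frac}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.clamp_mode not in ("hard", "soft"):
            raise ValueError(f"clamp_mode must be 'hard' or 'soft', got "
                             f"{self.clamp_mode!r}")
        if self.detector not in ("leaky", "cumsum"):
            raise ValueError(f"detector must be 'leaky' or 'cumsum', got "
                             f"{self.detector!r}")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields changed (re-validated)."""
        return dataclasses.replace(self, **changes)
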