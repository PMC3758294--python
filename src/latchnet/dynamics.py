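"""Unit-level network dynamics: support integration, soft winner-take-all
normalization within hypercolumns, and slow adaptation.

This is the readable reference implementation of one network time step.
The batch experiment runner uses numba kernels (:mod:`latchnet._fastpath`)
that are pinned to this module by an equivalence test; both consume the
same random-number stream, so short runs agree to floating-point
round-off.

State evolution (forward Euler, step ``dt``):

* support:     ``tau_m ds_j/dt = beta_j + sum_i w_ij o_i + g_I log I_j
  - g_a a_j - s_j``, followed by additive per-step noise ``sigma eta_j``;
* output:      ``o_j = exp(s_j) / sum_{k in hypercolumn} exp(s_k)``;
* adaptation:  ``tau_a da_j/dt = o_j - a_j``.

During hard-clamp phases the support/noise update is skipped entirely:
``o`` is overridden by the stimulus pattern and ``s`` pinned to
``log(max(o, eps))``, so clamped frames are deterministic and draw no
random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ModelParams
from . import plasticity

__all__ = [
    "NetworkState",
    "init_state",
    "update_support",
    "normalize_activity",
    "update_adaptation",
    "step",
]


@dataclass
class NetworkState:
    """Full mutable state of the network (one trial's worth).

    Arrays are flat over units (length ``H*M``); ``p_ij`` and ``w`` are
    ``(H*M, H*M)`` with entry ``[i, j]`` describing the connection from
    unit ``i`` to unit ``j``.
    """

    s: np.ndarray        # support
    a: np.ndarray        # adaptation
    o: np.ndarray        # output in [0, 1], sums to 1 per hypercolumn
    z_i: np.ndarray      # presynaptic trace
    z_j: np.ndarray      # postsynaptic trace
    p_i: np.ndarray      # presynaptic activation estimate
    p_j: np.ndarray      # postsynaptic activation estimate
    p_ij: np.ndarray     # co-activation estimate, (n, n)
    w: np.ndarray        # connection weights, (n, n)
    beta: np.ndarray     # unit bias
    t: float = 0.0       # simulated time, seconds
    n_steps: int = field(default=0)

    def copy(self) -> "NetworkState":
        return NetworkState(
            s=self.s.copy(), a=self.a.copy(), o=self.o.copy(),
            z_i=self.z_i.copy(), z_j=self.z_j.copy(),
            p_i=self.p_i.copy(), p_j=self.p_j.copy(),
            p_ij=self.p_ij.copy(), w=self.w.copy(), beta=self.beta.copy(),
            t=self.t, n_steps=self.n_steps,
        )

    def unit_frame(self) -> pd.DataFrame:
        """Per-unit state snapshot as a tidy DataFrame (debug export)."""
        n = self.s.size
        return pd.DataFrame({
            "unit": np.arange(n), "s": self.s, "a": self.a, "o": self.o,
            "z_i": self.z_i, "z_j": self.z_j, "p_i": self.p_i,
            "p_j": self.p_j, "beta": self.beta,
        })

    def connection_frame(self) -> pd.DataFrame:
        """Weight and co-activation snapshot as a tidy (pre, post, w,
        p_ij) table, stamped with the simulated time."""
        n = self.s.size
        pre, post = np.divmod(np.arange(n * n), n)
        return pd.DataFrame({
            "time_s": self.t, "pre": pre, "post": post,
            "w": self.w.ravel(), "p_ij": self.p_ij.ravel(),
        })


def init_state(params: ModelParams) -> NetworkState:
    """Fresh network state at the model's documented initial values.

    ``a = 0``, ``s = log(1/M)``, ``o = 1/M`` (the uniform soft-WTA fixed
    point), traces at ``1/M``, pair estimates at ``1/M**2`` (independence),
    hence ``w = 0`` and a uniform bias ``g_b log(1/M)``.
    """
    params.validate()
    n = params.n_units
    M = params.M
    s = np.full(n, np.log(1.0 / M))
    a = np.zeros(n)
    o = np.full(n, 1.0 / M)
    z = np.full(n, 1.0 / M)
    p = np.full(n, 1.0 / M)
    p_ij = np.full((n, n), 1.0 / M**2)
    w = plasticity.compute_weights(p, p, p_ij, params.g_w_encode,
                                   params.epsilon)
    beta = plasticity.compute_bias(p, params.g_b, params.epsilon)
    return NetworkState(s=s, a=a, o=o, z_i=z.copy(), z_j=z.copy(),
                        p_i=p.copy(), p_j=p.copy(), p_ij=p_ij, w=w,
                        beta=beta)


def update_support(
    s: np.ndarray,
    o: np.ndarray,
    a: np.ndarray,
    w: np.ndarray,
    beta: np.ndarray,
    params: ModelParams,
    rng: np.random.Generator,
    input_I: np.ndarray | None = None,
    g_I: float = 0.0,
    sigma: float | None = None,
) -> np.ndarray:
    """One Euler step of the support equation plus per-step noise.

    ``input_I`` is the external evidence in ``[epsilon, 1]`` entering as
    ``g_I * log I_j`` (used by the soft-clamp input mode); omit it or set
    ``g_I = 0`` for input-free evolution.  The noise draw
    (``sigma * standard_normal``) is made whenever ``sigma > 0`` so the
    random stream advances deterministically.
    """
    if sigma is None:
        sigma = params.sigma
    drive = beta + o @ w - params.g_a * a - s
    if g_I != 0.0 and input_I is not None:
        drive = drive + g_I * np.log(np.maximum(input_I, params.epsilon))
    s_new = s + (params.dt / params.tau_m) * drive
    if sigma > 0.0:
        s_new = s_new + sigma * rng.standard_normal(s.size)
    if not np.all(np.isfinite(s_new)):
        bad = int(np.flatnonzero(~np.isfinite(s_new))[0])
        raise FloatingPointError(
            f"non-finite support at unit {bad} (t-step produced "
            f"{s_new[bad]!r})")
    return s_new


def normalize_activity(s: np.ndarray, H: int, M: int) -> np.ndarray:
    """Divisive (softmax) normalization within each hypercolumn.

    ``o_j = exp(s_j) / sum_{k in h} exp(s_k)`` computed with per-
    hypercolumn max subtraction, so supports as low as ``log(eps)`` (which
    occur during clamping) are safe.
    """
    sh = s.reshape(H, M)
    mx = sh.max(axis=1, keepdims=True)
    if not np.all(np.isfinite(mx)):
        bad = int(np.flatnonzero(~np.isfinite(mx.ravel()))[0])
        raise FloatingPointError(
            f"hypercolumn {bad} has no finite support; cannot normalize")
    e = np.exp(sh - mx)
    return (e / e.sum(axis=1, keepdims=True)).ravel()


def update_adaptation(a: np.ndarray, o: np.ndarray,
                      params: ModelParams) -> np.ndarray:
    """One Euler step of ``tau_a da/dt = o - a`` (relaxation toward the
    current output with the slow adaptation time constant)."""
    return a + (params.dt / params.tau_a) * (o - a)


def step(
    state: NetworkState,
    params: ModelParams,
    rng: np.random.Generator,
    *,
    kappa: float,
    g_w: float,
    g_I: float = 0.0,
    input_I: np.ndarray | None = None,
    clamp_o: np.ndarray | None = None,
) -> NetworkState:
    """Advance the full network state by one time step, in place.

    Fixed update order: (1) z-traces and kappa-gated p-estimates from the
    previous step's outputs, (2) recompute ``w`` and ``beta``, (3) support
    update with noise, (4) normalization, (5) hard-clamp override if
    ``clamp_o`` is given (steps 3-4 are then skipped and no noise is
    drawn), (6) adaptation update.
    """
    state.z_i = plasticity.update_z_traces(state.z_i, state.o,
                                           params.tau_zi, params.dt,
                                           z_floor=params.z_floor)
    state.z_j = plasticity.update_z_traces(state.z_j, state.o,
                                           params.tau_zj, params.dt,
                                           z_floor=params.z_floor)
    state.p_i, state.p_j, state.p_ij = plasticity.update_p_estimates(
        state.p_i, state.p_j, state.p_ij, state.z_i, state.z_j,
        kappa, params.tau_p, params.dt)
    state.w = plasticity.compute_weights(state.p_i, state.p_j, state.p_ij,
                                         g_w, params.epsilon)
    state.beta = plasticity.compute_bias(state.p_j, params.g_b,
                                         params.epsilon)
    if clamp_o is None:
        state.s = update_support(state.s, state.o, state.a, state.w,
                                 state.beta, params, rng,
                                 input_I=input_I, g_I=g_I)
        state.o = normalize_activity(state.s, params.H, params.M)
    else:
        state.o = clamp_o.astype(float, copy=True)
        state.s = np.log(np.maximum(state.o, params.epsilon))
    state.a = update_adaptation(state.a, state.o, params)
    state.n_steps += 1
    state.t = state.n_steps * params.dt
    return state
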