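"""Incremental Bayesian-Hebbian (BCPNN) learning rule.

Connection weights are log odds-ratios of slowly estimated activation
probabilities, and unit biases are log prior probabilities scaled by an
intrinsic-excitability gain.  Learning proceeds in two stages with
separate time scales:

* fast pre-/post-synaptic traces ``z`` (hundreds of ms) low-pass filter the
  unit outputs and act as the eligibility buffer that binds consecutively
  active items;
* slow probability estimates ``p_i``, ``p_j``, ``p_ij`` (seconds) integrate
  the z-traces, gated by the global print-now parameter ``kappa``; with
  ``kappa = 0`` they are frozen exactly.

Weights and biases are pure functions of the ``p`` estimates::

    w_ij   = g_w * log( p_ij / (p_i * p_j) )
    beta_j = g_b * log( p_j )

with every probability floored at ``epsilon`` before the log.  Correlated
units therefore end up with excitatory weights, anti-correlated units with
inhibitory ones, and the finite ``tau_p`` makes the store a palimpsest:
new items gradually overwrite old ones.

All functions are pure and operate on plain numpy arrays; pre- and
post-synaptic traces share one updater since they obey the same equation.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "update_z_traces",
    "update_p_estimates",
    "compute_weights",
    "compute_bias",
]


def update_z_traces(z: np.ndarray, o: np.ndarray, tau_z: float,
                    dt: float, z_floor: float = 0.0) -> np.ndarray:
    """One forward-Euler step of ``tau_z dz/dt = o - z``.

    Used for both the presynaptic (``tau_zi``) and postsynaptic
    (``tau_zj``) trace with the appropriate time constant.  ``z_floor``
    is the spontaneous background rate: the trace of a silent unit decays
    to the floor, not to zero, which keeps the downstream probability
    estimates anchored at background statistics.
    """
    z_new = z + (dt / tau_z) * (o - z)
    if z_floor > 0.0:
        np.maximum(z_new, z_floor, out=z_new)
    return z_new


def update_p_estimates(
    p_i: np.ndarray,
    p_j: np.ndarray,
    p_ij: np.ndarray,
    z_i: np.ndarray,
    z_j: np.ndarray,
    kappa: float,
    tau_p: float,
    dt: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One kappa-gated Euler step of the slow probability estimates.

    ``tau_p dp/dt = kappa (target - p)`` with targets ``z_i``, ``z_j`` and
    the co-activation product ``z_i z_j`` for the pair estimate.  With
    ``kappa = 0`` the inputs are returned unchanged (bit-identical), which
    is what freezes the memory trace during recall.
    """
    if kappa == 0.0:
        return p_i, p_j, p_ij
    c = kappa * dt / tau_p
    new_pi = p_i + c * (z_i - p_i)
    new_pj = p_j + c * (z_j - p_j)
    new_pij = p_ij + c * (np.outer(z_i, z_j) - p_ij)
    return new_pi, new_pj, new_pij


def compute_weights(p_i: np.ndarray, p_j: np.ndarray, p_ij: np.ndarray,
                    g_w: float, epsilon: float) -> np.ndarray:
    """Log odds-ratio weights ``w_ij = g_w log(p_ij / (p_i p_j))``.

    Every probability is floored at ``epsilon`` so the log is always
    finite; self-connections (i == j) are treated like any other pair.
    """
    pi = np.maximum(p_i, epsilon)[:, None]
    pj = np.maximum(p_j, epsilon)[None, :]
    pij = np.maximum(p_ij, epsilon)
    return g_w * (np.log(pij) - np.log(pi) - np.log(pj))


def compute_bias(p_j: np.ndarray, g_b: float, epsilon: float) -> np.ndarray:
    """Intrinsic-excitability bias ``beta_j = g_b log(p_j)``.

    A unit that has often been active carries a higher (less negative)
    bias — the a-priori log-probability of activation given experience.
    """
    return g_b * np.log(np.maximum(p_j, epsilon))
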