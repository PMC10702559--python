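"""Weight-convergent STDP on feed-forward weights and homeostatic inhibition.

The plasticity rule has two cases, both local in space (one synapse) and in
time (gated by exponentially decaying traces):

* **Causal (LTP), on a postsynaptic spike.**  For every presynaptic neuron
  whose trace ``x_i`` still exceeds the eligibility threshold ``epsilon``:

      dw = alpha_plus * (1 - x_i - w + w_offset)

  This drives ``w`` toward the attractive fixed point
  ``1 - exp(-dt_pre_post / tau_x) + w_offset`` (see
  :func:`equilibrium_weight`): *earlier* presynaptic spikes — which carry
  the most information under a latency code — converge to *larger*
  weights, so the spike-timing distribution is stored in the weight
  distribution rather than saturating at the bounds.

* **Anti-causal (LTD), on a presynaptic spike.**  For every postsynaptic
  neuron whose trace ``y_j`` exceeds ``epsilon``:

      dw = -alpha_minus * (1 - y_j)

  Late presynaptic spikes (small ``y_j``) are depressed hardest; a
  simultaneous pair (``y_j = 1``) is not depressed at all.

Weights are clipped to [0, 1] after every update (hard bounds).

The representation layer's all-to-all lateral inhibitory weights start at
``-c_min`` and relax toward ``-c_max`` with time constant ``tau_w``
(homeostasis), moving the circuit from k-winners-take-all early in training
to strict winner-take-all at the end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dynamics import Clock, TraceState

__all__ = [
    "STDPParams",
    "HomeostasisParams",
    "PlasticState",
    "stdp_on_post",
    "stdp_on_pre",
    "equilibrium_weight",
    "init_lateral_weights",
    "homeostasis_step",
]


@dataclass(frozen=True)
class STDPParams:
    """Learning rule hyperparameters (defaults: values used in all experiments)."""

    alpha_plus: float = 0.004
    alpha_minus: float = 0.024
    w_offset: float = 0.2
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        for name in ("alpha_plus", "alpha_minus", "w_offset", "epsilon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.epsilon >= 1:
            raise ValueError("epsilon must be < 1")


@dataclass(frozen=True)
class HomeostasisParams:
    """Lateral-inhibition ramp: magnitude grows from c_min to c_max over tau_w ms."""

    c_min: float
    c_max: float
    tau_w: float

    def __post_init__(self) -> None:
        if not (0 < self.c_min < self.c_max):
            raise ValueError("need 0 < c_min < c_max")
        if self.tau_w <= 0:
            raise ValueError("tau_w must be > 0")


@dataclass
class PlasticState:
    """Feed-forward weight matrix (post x pre) with its traces."""

    W: np.ndarray
    traces: TraceState
    enabled: bool = True

    @property
    def m(self) -> int:
        return self.W.shape[0]

    @property
    def n(self) -> int:
        return self.W.shape[1]


def stdp_on_post(
    state: PlasticState, params: STDPParams, post_spikes: np.ndarray
) -> PlasticState:
    """Causal update: triggered by this step's postsynaptic spikes.

    Rows of eligible (``x_i > epsilon``) synapses of every spiking
    postsynaptic neuron move toward their timing-dependent fixed point;
    the result is clipped to [0, 1].
    """
    if not state.enabled:
        return state
    post_idx = np.flatnonzero(post_spikes)
    if post_idx.size == 0:
        return state
    x = state.traces.x
    elig = x > params.epsilon
    if not elig.any():
        return state
    cols = np.flatnonzero(elig)
    target = 1.0 - x[cols] + params.w_offset
    for j in post_idx:
        w = state.W[j, cols]
        state.W[j, cols] = np.clip(w + params.alpha_plus * (target - w), 0.0, 1.0)
    return state


def stdp_on_pre(
    state: PlasticState, params: STDPParams, pre_spikes: np.ndarray
) -> PlasticState:
    """Anti-causal update: triggered by this step's presynaptic spikes.

    Every synapse from a spiking presynaptic neuron to a postsynaptic
    neuron with ``y_j > epsilon`` is depressed by
    ``alpha_minus * (1 - y_j)`` and clipped to [0, 1].
    """
    if not state.enabled:
        return state
    pre_idx = np.flatnonzero(pre_spikes)
    if pre_idx.size == 0:
        return state
    y = state.traces.y
    rows = np.flatnonzero(y > params.epsilon)
    if rows.size == 0:
        return state
    dw = params.alpha_minus * (1.0 - y[rows])
    block = state.W[np.ix_(rows, pre_idx)]
    state.W[np.ix_(rows, pre_idx)] = np.clip(block - dw[:, None], 0.0, 1.0)
    return state


def equilibrium_weight(delta_t, tau_x: float = 1.3, w_offset: float = 0.2):
    """Analytic fixed point of the causal case for a pre→post lag ``delta_t`` ms.

        w* = min(1, 1 - exp(-delta_t / tau_x) + w_offset)

    Used as an independent oracle by the tests and by the decoder
    round-trip checks; ``delta_t`` must be >= 0 (causal pairings only).
    """
    delta_t = np.asarray(delta_t, dtype=float)
    if np.any(delta_t < 0):
        raise ValueError("delta_t must be >= 0 for the causal fixed point")
    w = 1.0 - np.exp(-delta_t / tau_x) + w_offset
    w = np.minimum(w, 1.0)
    return float(w) if w.ndim == 0 else w


def init_lateral_weights(m: int, params: HomeostasisParams) -> np.ndarray:
    """All-to-all inhibitory weights at -c_min, zero diagonal (no self-inhibition)."""
    L = np.full((m, m), -params.c_min)
    np.fill_diagonal(L, 0.0)
    return L


def homeostasis_step(
    lateral_W: np.ndarray, params: HomeostasisParams, clock: Clock
) -> np.ndarray:
    """One Euler step of the inhibition ramp: tau_w * dw/dt = -c_max - w.

    Off-diagonal (signed, negative) entries relax toward -c_max; the
    diagonal stays 0.  ``tau_w`` is normally one third of the total
    training duration T*P, so dt/tau_w is tiny and the Euler step is
    effectively exact.
    """
    diag = np.diag_indices_from(lateral_W)
    saved = lateral_W[diag].copy()
    lateral_W += (clock.dt / params.tau_w) * (-params.c_max - lateral_W)
    lateral_W[diag] = saved
    return lateral_W
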