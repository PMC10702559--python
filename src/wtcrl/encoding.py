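"""Population latency coding of real-valued inputs into spike patterns.

Each scalar coordinate of an input vector in [0, 1]^k is represented by a
population of ``l`` LIF neurons with circular Gaussian tuning curves.  The
tuning centers (preferential values) are uniformly spread between 0.05 and
0.95 and the input space wraps around: 1.0 is identified with 0.0.  Each
neuron receives its activation level as a constant input current for
``t_active`` ms followed by ``t_quiet`` ms of quiescence and, with the
default parameters (sigma = 0.6, V_theta = 0.5, tau_m = 10 ms), fires
exactly one spike per presentation window.  The input value is thereby
encoded in the *relative* latencies of the population's spikes: the neuron
whose center is closest to the value fires first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dynamics import Clock, LayerState, NeuronParams, fire_and_reset, step_membrane

__all__ = [
    "EncoderSpec",
    "SpikePattern",
    "make_centers",
    "circular_distance",
    "activation",
    "activation_vector",
    "EncoderLayer",
    "encode",
]

#: Neuron parameters of the encoding layer used in all experiments.
DEFAULT_ENCODER_NEURON = NeuronParams(tau_m=10.0, v_theta=0.5, t_refrac=6.0, g=0.0)


def make_centers(l: int) -> np.ndarray:
    """Tuning-curve centers: ``l`` values uniformly spread from 0.05 to 0.95."""
    if l < 2:
        raise ValueError(f"need at least 2 neurons per dimension, got l={l}")
    return np.linspace(0.05, 0.95, l)


def circular_distance(a, b):
    """Distance on a circle of circumference 1: min(|a-b|, 1-|a-b|)."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
    return np.minimum(d, 1.0 - d)


def activation(a, center, sigma: float):
    """Circular Gaussian receptive field: exp(-d^2 / (2 sigma^2)).

    ``d`` is the circular distance between input value and tuning center,
    so a center at 0.95 responds almost maximally to an input of 0.05.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    d = circular_distance(a, center)
    return np.exp(-(d**2) / (2.0 * sigma**2))


@dataclass(frozen=True)
class EncoderSpec:
    """Geometry and timing of the encoding layer.

    Parameters
    ----------
    l : int
        Neurons per input dimension.
    sigma : float
        Tuning-curve width in input-space units.  The default 0.6 is broad
        enough that the minimum activation (0.707 at circular distance 0.5)
        exceeds the encoder threshold 0.5, so no neuron is ever silent.
    t_active, t_quiet : float
        Stimulus-on and quiescent durations in ms.  The window length is
        ``T = t_active + t_quiet``; the quiescent half lets membrane
        potentials, currents and traces decay between presentations instead
        of a hard state reset.
    """

    l: int = 10
    sigma: float = 0.6
    t_active: float = 12.5
    t_quiet: float = 12.5
    centers: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.t_active <= 0:
            raise ValueError("t_active must be > 0")
        if self.t_quiet < 0:
            raise ValueError("t_quiet must be >= 0")
        if self.centers is None:
            object.__setattr__(self, "centers", make_centers(self.l))
        else:
            centers = np.asarray(self.centers, dtype=float)
            if centers.shape != (self.l,) or np.any(np.diff(centers) <= 0):
                raise ValueError("centers must be l strictly increasing values")
            object.__setattr__(self, "centers", centers)

    @property
    def T(self) -> float:
        """Presentation window length in ms."""
        return self.t_active + self.t_quiet


@dataclass
class SpikePattern:
    """Spike events of one layer within one presentation window.

    ``neurons`` and ``times`` are parallel arrays; times are in ms relative
    to window onset and lie in [0, T).  For the encoding layer there is at
    most one event per neuron per window.
    """

    neurons: np.ndarray
    times: np.ndarray
    window_id: int = 0

    @property
    def n_spikes(self) -> int:
        return int(self.neurons.shape[0])

    def latency_of(self, neuron: int) -> float:
        """Spike time of ``neuron`` in this window (raises if it did not fire)."""
        hits = np.flatnonzero(self.neurons == neuron)
        if hits.size == 0:
            raise KeyError(f"neuron {neuron} did not spike in this window")
        return float(self.times[hits[0]])

    def to_text(self) -> str:
        """Two-column serialization: neuron_index time_ms, one event per line."""
        return "\n".join(f"{n} {t:.4f}" for n, t in zip(self.neurons, self.times))


def _validate_input(a_vec: np.ndarray) -> np.ndarray:
    a_vec = np.atleast_1d(np.asarray(a_vec, dtype=float))
    if np.any(a_vec < 0.05 - 1e-12) or np.any(a_vec > 0.95 + 1e-12):
        raise ValueError(
            "input values must lie within the normalization margins [0.05, 0.95]; "
            f"got range [{a_vec.min():.4f}, {a_vec.max():.4f}]"
        )
    return a_vec


def activation_vector(a_vec: np.ndarray, spec: EncoderSpec) -> np.ndarray:
    """Activation levels A in [0,1]^(k*l), dimension-major.

    Neuron ``(i-1)*l + z`` (0-based: ``i*l + z``) encodes dimension ``i``
    with center ``centers[z]``; this storage order is the contract the
    decoder's block indexing relies on.
    """
    a_vec = _validate_input(a_vec)
    return activation(a_vec[:, None], spec.centers[None, :], spec.sigma).ravel()


class EncoderLayer:
    """Stateful encoding layer stepped in lockstep with the rest of the network."""

    def __init__(
        self,
        k: int,
        spec: EncoderSpec,
        neuron_params: NeuronParams = DEFAULT_ENCODER_NEURON,
    ) -> None:
        self.k = k
        self.spec = spec
        self.params = neuron_params
        self.state = LayerState.zeros(k * spec.l)

    @property
    def n(self) -> int:
        return self.state.n

    def set_input(self, a_vec: np.ndarray) -> None:
        """Compute and store the activation vector for the coming window."""
        self._A = activation_vector(a_vec, self.spec)
        if self.params.g == 0 and np.any(self._A <= self.params.v_theta):
            warnings.warn(
                "some activation levels do not exceed the encoder threshold; "
                "the corresponding neurons will stay silent",
                stacklevel=2,
            )

    def step(self, clock: Clock, stimulus_on: bool, rng: np.random.Generator | None):
        """Advance one dt; returns the boolean spike mask for this step."""
        st = self.state
        st.I = self._A if stimulus_on else np.zeros(self.n)
        draw = None
        if self.params.g > 0:
            assert rng is not None
            draw = rng.standard_normal(self.n)
        step_membrane(st, self.params, clock, draw)
        fire_and_reset(st, self.params, clock)
        return st.s


def encode(
    a_vec: np.ndarray,
    spec: EncoderSpec | None = None,
    neuron_params: NeuronParams = DEFAULT_ENCODER_NEURON,
    dt: float = 0.1,
    rng: np.random.Generator | None = None,
    window_id: int = 0,
) -> SpikePattern:
    """Encode one input vector into a spatio-temporal spike pattern.

    Simulates the k*l encoder neurons over one full presentation window
    (``t_active`` ms of constant drive then ``t_quiet`` ms of quiescence)
    and collects every emitted spike.  With the default parameters and
    ``g = 0`` each neuron spikes exactly once, at latency
    ``-tau_m * ln(1 - V_theta / A)`` up to the Euler discretization.
    """
    if spec is None:
        spec = EncoderSpec()
    a_vec = np.atleast_1d(np.asarray(a_vec, dtype=float))
    layer = EncoderLayer(a_vec.shape[0], spec, neuron_params)
    layer.set_input(a_vec)
    if neuron_params.g > 0 and rng is None:
        rng = np.random.default_rng()
    clock = Clock(dt=dt)
    n_active = clock.steps_for(spec.t_active)
    n_total = clock.steps_for(spec.T)
    neurons: list[np.ndarray] = []
    times: list[np.ndarray] = []
    for step in range(n_total):
        clock.tick()
        fired = layer.step(clock, stimulus_on=step < n_active, rng=rng)
        if fired.any():
            idx = np.flatnonzero(fired)
            neurons.append(idx)
            times.append(np.full(idx.shape, clock.t))
    if neurons:
        return SpikePattern(
            neurons=np.concatenate(neurons),
            times=np.concatenate(times),
            window_id=window_id,
        )
    return SpikePattern(
        neurons=np.empty(0, dtype=int), times=np.empty(0), window_id=window_id
    )
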