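"""Two-layer network assembly, training/testing protocols, SBMU detection.

The architecture couples an encoding layer ``u`` of ``n = k*l`` latency
coding neurons to a representation layer ``v`` of ``m`` LIF neurons through
a plastic feed-forward weight matrix ``W`` (m x n, entries in [0, 1]).
Layer ``v`` carries all-to-all lateral inhibitory weights whose magnitude
ramps from ``c_min`` to ``c_max`` over the training phase (homeostasis),
moving the circuit from k-WTA to strict WTA.  The first ``v`` neuron to
cross threshold within a presentation window is the spiking best matching
unit (SBMU) — the self-organized analogue of a self-organizing map's BMU.

Only three parameters depend on the input dimensionality, all linear in
``k * l``:

    V_theta_v = 0.25 * k * l      c_min = 9 * V_theta_v      c_max = 91 * V_theta_v
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from . import codec
from .dynamics import (
    Clock,
    LayerState,
    NeuronParams,
    SynapseParams,
    TraceState,
    fire_and_reset,
    step_membrane,
    update_traces,
)
from .encoding import EncoderLayer, EncoderSpec, SpikePattern
from .plasticity import (
    HomeostasisParams,
    PlasticState,
    STDPParams,
    homeostasis_step,
    init_lateral_weights,
    stdp_on_post,
    stdp_on_pre,
)

__all__ = [
    "derive_dimension_params",
    "NetworkConfig",
    "PresentationResult",
    "Network",
]


def derive_dimension_params(k: int, l: int) -> tuple[float, float, float]:
    """Dimension-dependent parameters (V_theta_v, c_min, c_max).

    The representation threshold scales linearly with the number of
    afferent spikes ``k*l`` (one spike per encoder neuron, weights in
    [0, 1]); the inhibition levels scale with the threshold so the WTA
    behavior is preserved across input dimensionalities.
    """
    if k < 1 or l < 1:
        raise ValueError("k and l must be >= 1")
    v_theta_v = 0.25 * k * l
    return v_theta_v, 9.0 * v_theta_v, 91.0 * v_theta_v


@dataclass
class NetworkConfig:
    """Complete parameterization of the two-layer network.

    All defaults reproduce the reference parameter table; the three
    dimension-dependent values (``v_theta_v``, ``c_min``, ``c_max``) are
    derived from ``k`` and ``l`` when left unset, and ``tau_w`` — the
    homeostasis time constant — defaults to one third of the planned
    training duration ``T * P`` and is resolved when training starts.
    """

    k: int = 25
    m: int = 64
    l: int = 10
    dt: float = 0.1
    # encoding layer u
    tau_m_u: float = 10.0
    v_theta_u: float = 0.5
    t_refrac_u: float = 6.0
    # representation layer v
    tau_m_v: float = 1.4
    v_theta_v: float | None = None
    t_refrac_v: float = 6.0
    # synapses and traces
    tau_f_ff: float = 2.8  # u -> v
    tau_f_lat: float = 0.3  # v -> v
    tau_x: float = 1.3
    tau_y: float = 4.3
    # STDP
    alpha_plus: float = 0.004
    alpha_minus: float = 0.024
    w_offset: float = 0.2
    epsilon: float = 0.1
    # homeostasis
    c_min: float | None = None
    c_max: float | None = None
    tau_w: float | None = None
    # encoder geometry / timing
    sigma: float = 0.6
    t_active: float = 12.5
    t_quiet: float = 12.5
    # noise
    g: float = 0.0
    noise_on_representation: bool = False
    # initialization
    w_init_low: float = 0.6
    w_init_high: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        v_theta_v, c_min, c_max = derive_dimension_params(self.k, self.l)
        if self.v_theta_v is None:
            self.v_theta_v = v_theta_v
        if self.c_min is None:
            self.c_min = 9.0 * self.v_theta_v
        if self.c_max is None:
            self.c_max = 91.0 * self.v_theta_v
        if not (0 <= self.w_init_low <= self.w_init_high <= 1):
            raise ValueError("w_init range must satisfy 0 <= low <= high <= 1")

    @property
    def n(self) -> int:
        return self.k * self.l

    @property
    def T(self) -> float:
        return self.t_active + self.t_quiet

    def encoder_spec(self) -> EncoderSpec:
        return EncoderSpec(
            l=self.l, sigma=self.sigma, t_active=self.t_active, t_quiet=self.t_quiet
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


@dataclass
class PresentationResult:
    """Outcome of one presentation window."""

    sbmu: int | None
    rep_spikes: SpikePattern
    input_vec: np.ndarray

    @property
    def n_spikes(self) -> int:
        return self.rep_spikes.n_spikes


class Network:
    """The assembled two-layer network with its training and test protocols."""

    def __init__(self, config: NetworkConfig) -> None:
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        c = config
        self.spec = c.encoder_spec()
        self.encoder = EncoderLayer(
            c.k,
            self.spec,
            NeuronParams(tau_m=c.tau_m_u, v_theta=c.v_theta_u, t_refrac=c.t_refrac_u, g=c.g),
        )
        g_v = c.g if c.noise_on_representation else 0.0
        self.params_v = NeuronParams(
            tau_m=c.tau_m_v, v_theta=c.v_theta_v, t_refrac=c.t_refrac_v, g=g_v
        )
        self.syn = SynapseParams(tau_f=c.tau_f_ff, tau_x=c.tau_x, tau_y=c.tau_y)
        self.homeo = HomeostasisParams(
            c_min=c.c_min, c_max=c.c_max, tau_w=c.tau_w if c.tau_w else 1.0
        )
        self.stdp = STDPParams(
            alpha_plus=c.alpha_plus,
            alpha_minus=c.alpha_minus,
            w_offset=c.w_offset,
            epsilon=c.epsilon,
        )
        W = self.rng.uniform(c.w_init_low, c.w_init_high, size=(c.m, c.n))
        self.plastic = PlasticState(W=W, traces=TraceState.zeros(c.n, c.m))
        self.lateral = init_lateral_weights(c.m, self.homeo)
        self.v_state = LayerState.zeros(c.m)
        self.I_ff = np.zeros(c.m)
        self.I_lat = np.zeros(c.m)
        self.clock = Clock(dt=c.dt)
        self._decay_ff = np.exp(-c.dt / c.tau_f_ff)
        self._decay_lat = np.exp(-c.dt / c.tau_f_lat)
        self.presentations_seen = 0
        self.metrics_log: list[dict] = []

    # -- single presentation ------------------------------------------------

    def present(self, a_vec: np.ndarray, training: bool = False) -> PresentationResult:
        """Simulate one full presentation window of ``T`` ms.

        Encodes ``a_vec`` into the u layer, propagates spikes through ``W``
        into the v layer, delivers lateral inhibition on every v spike and
        — iff ``training`` — applies both STDP cases and one homeostasis
        step per dt.  Returns the SBMU (earliest v spike; ties broken by
        lowest index) and all v spikes with times relative to window onset.
        A window with no v spike yields ``sbmu = None``.
        """
        c = self.config
        a_vec = np.atleast_1d(np.asarray(a_vec, dtype=float))
        if a_vec.shape != (c.k,):
            raise ValueError(f"expected input of shape ({c.k},), got {a_vec.shape}")
        self.encoder.set_input(a_vec)
        clock = self.clock
        n_active = clock.steps_for(c.t_active)
        n_total = clock.steps_for(self.spec.T)
        t0 = clock.t
        v = self.v_state
        W = self.plastic.W
        sbmu: int | None = None
        spike_neurons: list[int] = []
        spike_times: list[float] = []
        noise_v = self.params_v.g > 0
        for step in range(n_total):
            clock.tick()
            pre = self.encoder.step(clock, stimulus_on=step < n_active, rng=self.rng)
            # v-layer currents: decay, then instantaneous feed-forward delivery
            self.I_ff *= self._decay_ff
            self.I_lat *= self._decay_lat
            pre_idx = np.flatnonzero(pre)
            if pre_idx.size:
                self.I_ff += W[:, pre_idx].sum(axis=1)
            v.I = self.I_ff + self.I_lat
            draw = self.rng.standard_normal(c.m) if noise_v else None
            step_membrane(v, self.params_v, clock, draw)
            fire_and_reset(v, self.params_v, clock)
            post = v.s
            if post.any():
                post_idx = np.flatnonzero(post)
                if sbmu is None:
                    sbmu = int(post_idx[0])
                spike_neurons.extend(int(j) for j in post_idx)
                spike_times.extend([clock.t - t0] * post_idx.size)
                # lateral inhibition; zero diagonal => no self-inhibition
                self.I_lat += self.lateral[:, post_idx].sum(axis=1)
            update_traces(self.plastic.traces, self.syn, pre, post, clock)
            if training and self.plastic.enabled:
                stdp_on_post(self.plastic, self.stdp, post)
                stdp_on_pre(self.plastic, self.stdp, pre)
                homeostasis_step(self.lateral, self.homeo, clock)
        self.presentations_seen += 1
        pattern = SpikePattern(
            neurons=np.asarray(spike_neurons, dtype=int),
            times=np.asarray(spike_times),
            window_id=self.presentations_seen - 1,
        )
        return PresentationResult(sbmu=sbmu, rep_spikes=pattern, input_vec=a_vec)

    # -- training protocol --------------------------------------------------

    def train(
        self,
        patch_stream: Iterable[np.ndarray],
        P: int,
        log_every: int | None = None,
    ) -> list[dict]:
        """Run ``P`` training presentations; returns the metrics log.

        The homeostasis time constant is resolved to ``T * P / 3`` (unless
        fixed in the config) so the lateral inhibition reaches ~c_max by
        the end of the phase.  Metrics are aggregated over consecutive
        chunks of ``log_every`` presentations (default: P/8, at least 1):
        per-chunk RMS uses the reconstruction from the SBMU's weight row at
        presentation time; incoherence decodes all code vectors at the log
        point.
        """
        if P == 0:
            return []
        if P < 0:
            raise ValueError("P must be >= 0")
        if self.config.tau_w is None:
            tau_w = self.spec.T * P / 3.0
            self.homeo = HomeostasisParams(
                c_min=self.homeo.c_min, c_max=self.homeo.c_max, tau_w=tau_w
            )
        if log_every is None:
            log_every = max(1, P // 8)
        stream: Iterator[np.ndarray] = iter(patch_stream)
        c = self.config
        chunk_orig: list[np.ndarray] = []
        chunk_recon: list[np.ndarray] = []
        chunk_sbmu: list[int] = []
        chunk_counts: list[int] = []
        silent = 0
        for p in range(1, P + 1):
            try:
                a_vec = next(stream)
            except StopIteration:
                raise ValueError(
                    f"patch stream exhausted after {p - 1} of {P} presentations"
                ) from None
            res = self.present(a_vec, training=True)
            chunk_counts.append(res.n_spikes)
            if res.sbmu is None:
                silent += 1
            else:
                code = codec.reconstruct_patch(
                    self.plastic.W[res.sbmu], c.k, c.l, self.spec.centers, strict=False
                )
                chunk_orig.append(res.input_vec)
                chunk_recon.append(code.values)
                chunk_sbmu.append(res.sbmu)
            if p % log_every == 0 or p == P:
                record = self._log_record(
                    p, chunk_orig, chunk_recon, chunk_sbmu, chunk_counts, silent
                )
                self.metrics_log.append(record)
                chunk_orig, chunk_recon, chunk_sbmu = [], [], []
                chunk_counts, silent = [], 0
        return self.metrics_log

    def _log_record(self, p, orig, recon, sbmus, counts, silent) -> dict:
        c = self.config
        record: dict = {
            "iter": self.presentations_seen,
            "chunk": len(counts),
            "sparsity": codec.sparsity(counts, c.m) if counts else float("nan"),
            "silent_rate": silent / len(counts) if counts else float("nan"),
        }
        if orig:
            record["rms"] = codec.rms_error(np.stack(orig), np.stack(recon))
            code_vectors = codec.decode_all(self.plastic.W, c.k, c.l, self.spec.centers)
            record["incoherence_5"] = codec.incoherence(
                sbmus, np.stack(orig), code_vectors, 0.05
            )
            record["incoherence_10"] = codec.incoherence(
                sbmus, np.stack(orig), code_vectors, 0.10
            )
        else:
            record["rms"] = float("nan")
            record["incoherence_5"] = float("nan")
            record["incoherence_10"] = float("nan")
        return record

    # -- testing protocol ---------------------------------------------------

    def evaluate(self, patch_stream: Iterable[np.ndarray]) -> codec.MetricsReport:
        """Test-phase evaluation over a finite stream of patches.

        Plasticity is disabled, homeostasis is frozen and the lateral
        weights are pinned at ``-c_max`` (strict WTA) for the duration of
        the evaluation; the network's training state is restored on exit.
        Windows without any v spike are counted in ``silent_rate`` and in
        sparsity, but excluded from RMS and incoherence.
        """
        c = self.config
        saved_lateral = self.lateral
        saved_enabled = self.plastic.enabled
        pinned = np.full((c.m, c.m), -self.homeo.c_max)
        np.fill_diagonal(pinned, 0.0)
        self.lateral = pinned
        self.plastic.enabled = False
        try:
            code_vectors = codec.decode_all(self.plastic.W, c.k, c.l, self.spec.centers)
            originals: list[np.ndarray] = []
            recons: list[np.ndarray] = []
            sbmus: list[int] = []
            counts: list[int] = []
            silent = 0
            for a_vec in patch_stream:
                res = self.present(a_vec, training=False)
                counts.append(res.n_spikes)
                if res.sbmu is None:
                    silent += 1
                    continue
                originals.append(res.input_vec)
                recons.append(code_vectors[res.sbmu])
                sbmus.append(res.sbmu)
            if not counts:
                raise ValueError("evaluation stream was empty")
            rms = codec.rms_error(np.stack(originals), np.stack(recons)) if originals else float("nan")
            inc5 = (
                codec.incoherence(sbmus, np.stack(originals), code_vectors, 0.05)
                if originals
                else float("nan")
            )
            inc10 = (
                codec.incoherence(sbmus, np.stack(originals), code_vectors, 0.10)
                if originals
                else float("nan")
            )
            return codec.MetricsReport(
                rms=rms,
                sparsity=codec.sparsity(counts, c.m),
                incoherence_5=inc5,
                incoherence_10=inc10,
                silent_rate=silent / len(counts),
                n_presentations=len(counts),
            )
        finally:
            self.lateral = saved_lateral
            self.plastic.enabled = saved_enabled

    def set_noise(self, g: float) -> None:
        """Change the white-noise scale without touching learned state.

        The robustness protocol trains with noise and then evaluates the
        learned representation noise-free; this switches ``g`` for both
        layers (the representation layer only receives noise when
        ``noise_on_representation`` is set).  Note this mutates the held
        config, so the change survives ``save``/``load``.
        """
        c = self.config
        c.g = g
        self.encoder.params = NeuronParams(
            tau_m=c.tau_m_u, v_theta=c.v_theta_u, t_refrac=c.t_refrac_u, g=g
        )
        g_v = g if c.noise_on_representation else 0.0
        self.params_v = NeuronParams(
            tau_m=c.tau_m_v, v_theta=c.v_theta_v, t_refrac=c.t_refrac_v, g=g_v
        )

    def code_vectors(self) -> np.ndarray:
        """Decoded code vector of every representation neuron, shape (m, k)."""
        c = self.config
        return codec.decode_all(self.plastic.W, c.k, c.l, self.spec.centers)

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write weights (HDF5), a config snapshot (JSON) and the metrics log."""
        import h5py

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with h5py.File(directory / "model.h5", "w") as f:
            f.create_dataset("W", data=self.plastic.W)
            f.create_dataset("lateral", data=self.lateral)
            f.create_dataset("centers", data=self.spec.centers)
            f.attrs["k"] = self.config.k
            f.attrs["l"] = self.config.l
            f.attrs["m"] = self.config.m
            f.attrs["presentations_seen"] = self.presentations_seen
        (directory / "config.json").write_text(json.dumps(self.config.to_dict(), indent=2))
        with (directory / "metrics.jsonl").open("w") as fh:
            for record in self.metrics_log:
                fh.write(json.dumps(record) + "\n")

    @classmethod
    def load(cls, directory: str | Path) -> "Network":
        import h5py

        directory = Path(directory)
        config = NetworkConfig.from_dict(
            json.loads((directory / "config.json").read_text())
        )
        net = cls(config)
        with h5py.File(directory / "model.h5", "r") as f:
            net.plastic.W = f["W"][...]
            net.lateral = f["lateral"][...]
            net.presentations_seen = int(f.attrs["presentations_seen"])
        log_path = directory / "metrics.jsonl"
        if log_path.exists():
            net.metrics_log = [
                json.loads(line) for line in log_path.read_text().splitlines() if line
            ]
        return net
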