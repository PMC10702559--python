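# Methods

`wtcrl` implements a two-layer spiking neural network that learns
vector-quantization-style representations of real-valued inputs from a
*temporal* spike code, together with the encoder, decoder and evaluation
metrics needed to measure reconstruction quality. This note records the
model, the numerical choices, and what the shipped tests do and do not
establish.

## Model

### Neurons and synapses

All neurons are leaky integrate-and-fire (LIF) with current-based (CuBa)
exponential synapses:

    tau_m dV/dt = -V + I + g·eta(t)
    I_j <- I_j + sum_i w_ji s_i(t)        (on presynaptic spikes)
    tau_f dI_j/dt = -I_j                  (otherwise)

On crossing the threshold `V_theta`, a neuron emits a spike, resets to 0
and is clamped at 0 for `T_refrac = 6 ms`. Each synapse sees two local
state variables — a presynaptic trace `x_i` and a postsynaptic trace `y_j`
— which jump to 1 on the corresponding spike and decay exponentially
(`tau_x = 1.3 ms`, `tau_y = 4.3 ms`).

### Latency population code

A scalar `a ∈ [0,1]` is distributed over `l = 10` encoder neurons with
circular Gaussian tuning curves `A_z = exp(-d(a, mu_z)^2 / (2 sigma^2))`,
where `d` is arc distance on a circle of circumference 1, the centers
`mu_z` are uniform on [0.05, 0.95] and `sigma = 0.6`. The activation is
injected as a constant current for `t_active = 12.5 ms`, followed by
`t_quiet = 12.5 ms` of silence (window `T = 25 ms`). Because the minimum
possible activation (circular distance 0.5) is `exp(-0.25/0.72) ≈ 0.707 >
V_theta_u = 0.5`, every neuron fires exactly once per window at latency
`-tau_m ln(1 - V_theta/A)`: the input value lives in the *relative*
latencies of the population. State is not hard-reset between windows; the
quiescent half-window lets potentials, currents and traces decay
naturally (all relevant time constants are ≤ 10 ms).

### Plasticity

Feed-forward weights `w_ji ∈ [0,1]` follow a two-case rule gated by the
traces (eligibility threshold `epsilon = 0.1`):

* post spike, `x_i > eps`:  `dw = alpha_plus · (1 - x_i - w + w_offset)`
* pre spike,  `y_j > eps`:  `dw = -alpha_minus · (1 - y_j)`

with hard clipping to [0,1] after every update. The causal case has the
attractive fixed point `w* = 1 - exp(-lag/tau_x) + w_offset`: *early*
presynaptic spikes (large lag to the postsynaptic spike) converge to
*large* weights, so the latency structure of the input is stored directly
in the weight profile instead of saturating at the bounds. The causal
case is only eligible for lags up to `tau_x·ln(1/eps) ≈ 2.99 ms`, the
anti-causal case up to `tau_y·ln(1/eps) ≈ 9.90 ms`; at a lag of exactly
3.0 ms the presynaptic trace (0.0995) sits marginally below the
threshold and the causal case does not trigger — a boundary worth knowing
when probing the rule with clamped pairings.

### Competition and homeostasis

Representation-layer neurons (`tau_m_v = 1.4 ms`) receive the encoder
spikes through the plastic weights (`tau_f = 2.8 ms`) and inhibit each
other all-to-all (`tau_f = 0.3 ms`, no self-inhibition). The first neuron
to cross threshold in a window is the spiking best matching unit (SBMU).
Inhibitory magnitudes ramp from `c_min` to `c_max` with time constant
`tau_w = T·P/3` over a training phase of `P` presentations, moving the
circuit from k-winners-take-all (fast early learning by several neurons)
to strict winner-take-all (specialization). During testing, plasticity is
off, homeostasis is frozen and inhibition is pinned at `-c_max`.

Only three parameters depend on the input dimensionality `k`:

    V_theta_v = 0.25·k·l       c_min = 9·V_theta_v       c_max = 91·V_theta_v

### Decoding and metrics

Each dimension's `l`-block of a neuron's weight row is decoded by a
weighted circular mean of the centers' preferred directions
(`theta_z = 2·pi·mu_z`), the population-vector construction used for
motor-cortex direction decoding. Metrics: RMS reconstruction error with
the root taken per patch before averaging; sparsity = spikes per window /
m; incoherence = fraction of presentations whose SBMU is outside the top
`ceil(m·x)` neurons by Euclidean distance between input and code vectors.

## Numerical choices

* Forward Euler, `dt = 0.1 ms`; currents and traces use the exact
  one-step decay factor `exp(-dt/tau)`. Time is an integer step count, so
  refractory windows are exact.
* Per-step order: encoder layer integrates and fires; representation
  currents decay, then receive this step's presynaptic spikes
  (instantaneous, no delays); membranes integrate; threshold/reset;
  lateral inhibition is delivered from this step's spikes (affecting the
  next step); traces decay then jump; STDP case 1 then case 2; one
  homeostasis Euler step (training only). A presynaptic spike therefore
  influences the postsynaptic potential within the same step, and a
  same-step pre/post pair reads `x = 1` (zero lag), matching the
  fixed-point derivation.
* **Noise.** The membrane noise `g·eta(t)` is discretized by sampling
  `eta ~ N(0,1)` once per step and treating `g·eta` as an input current
  held constant over the step (increment `g·eta·dt/tau_m`). This gives a
  stationary membrane noise s.d. of ≈ 0.07·g and a first-spike jitter
  that grows monotonically with g, reaching ~5 ms for the slowest encoder
  neurons at g = 1.5. The textbook Euler–Maruyama scaling
  `g·sqrt(dt/tau_m)` was rejected after measurement: it produces noise so
  large that the temporal code is destroyed already at g = 0.5, and its
  first-spike jitter is non-monotone in g. Noise applies to the encoding
  layer; a config flag (`noise_on_representation`) extends it to the
  representation layer, default off.
* The robustness protocol trains with noise and evaluates noise-free:
  the sweep measures the network's ability to *learn* under noise, not
  the stochasticity of a noisy read-out.
* SBMU ties (two neurons crossing in the same dt step) break to the
  lowest index. Under strict WTA, simultaneous same-step crossings are
  possible (inhibition cannot act within a step); later spikes in the
  window are fully suppressed.
* Degenerate circular means (all-zero or perfectly symmetric weight
  blocks) raise an error in strict mode; inside full-patch
  reconstruction they decode to 0.5 with a warning so evaluation can
  proceed on pathological untrained neurons while the degeneracy stays
  visible.
* Windows with no representation spike yield no SBMU; they count toward
  sparsity and a reported `silent_rate` but are excluded from RMS and
  incoherence, which are undefined for a silent network.
* Inputs outside the normalization margins [0.05, 0.95] are rejected:
  the circular encoding space identifies 1.0 with 0.0, so the margins are
  part of the code's correctness, not a convenience.

## Synthetic world

The generator emits a mixture of `n_prototypes` fixed prototype patches
with i.i.d. Gaussian jitter (`jitter_sd`), clipped to the margins, with
ground-truth labels. The benchmark configuration used throughout the
tests: 4 prototypes drawn uniformly in [0.15, 0.85]^9 with rejection at
normalized separation ≥ 0.25, jitter s.d. 0.03, m = 8, P = 2000 training
presentations, 200 held-out evaluation patches.

What it emulates: a low-dimensional clustered input distribution where
the correct representation (the prototypes) is known exactly, enabling
parameter-recovery tests with hard error bounds. What it does not
emulate: the heavy-tailed, spatially correlated statistics of image
patches, near-constant (blank) inputs, high dimensionality (k = 25 or
256), or large representation layers — so a green synthetic suite
establishes that the mechanism (encoding → competitive STDP → decoding)
works and is stable, not that image-dataset error levels are reproduced.
The MNIST protocol is implemented and runs when the IDX files are placed
under `data/mnist/`; it is an optional download and not part of the
default test run.

Two benchmark measurements are worth flagging. First, at m = 8 both
incoherence thresholds (5% and 10%) reduce to top-1 of 8, and with 8
neurons coding 4 prototypes each prototype acquires near-duplicate
coders; which duplicate fires first is decided by sub-millisecond latency
differences while the distance rank is decided by sub-0.02 code-vector
differences, so election and ranking can disagree with zero
reconstruction cost. Incoherence on this benchmark is therefore a noisy,
structurally inflatable quantity (seed-to-seed s.d. ~0.035 around a ~0
mean), unlike at the m ≥ 64 / top-k regimes. Second, the training-phase
sparsity log aggregates 8 chunks of P/8 windows; chunk means carry
sampling noise of order 0.001, and the monotonicity check allows 0.01
absolute slack.

## Known limitations

* Clock-driven only; no event-driven path, conductance synapses,
  delays, or adaptive thresholds.
* The noise discretization is a documented choice, not the model's
  unique stochastic interpretation; jitter magnitudes are calibrated,
  not derived.
* Silent windows have no defined reconstruction; heavy-noise regimes
  are summarized by `silent_rate` rather than by imputed errors.
* Training throughput is ~80 presentations/s (pure numpy, k = 9); full
  60,000-presentation image protocols are supported but take tens of
  minutes.
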