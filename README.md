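# wtcrl — temporally coded representation learning in spiking networks

`wtcrl` is a spiking-neural-network package for learning low-error,
highly sparse representations of real-valued data from a **temporal**
spike code. Rate-coded spiking models transmit a pixel intensity with up
to hundreds of spikes; here each input coordinate is encoded by a
population of `l = 10` leaky integrate-and-fire neurons that fire **once
each**, with the value carried by their *relative spike latencies*. A
competitive representation layer then learns those latencies directly in
its synaptic weights with a weight-convergent STDP rule, and the learned
weights decode back to input space through a weighted circular mean.

It is aimed at computational-neuroscience and neuromorphic-computing work
where one wants a local, event-driven, low-spike-count learning rule that
still supports a quantitative reconstruction-error evaluation.

## The model in brief

* **Encoding** — each scalar `a ∈ [0,1]` drives `l` LIF neurons
  (`tau_m = 10 ms`, `V_theta = 0.5`) through circular Gaussian tuning
  curves (centers uniform on [0.05, 0.95], `sigma = 0.6`) for 12.5 ms,
  then 12.5 ms of quiescence. The nearest-center neuron fires first, at
  latency `-tau_m·ln(1 - V_theta/A)`.
* **Plasticity** — on a postsynaptic spike, eligible weights move toward
  the attractive fixed point

      w* = 1 - exp(-Δt/tau_x) + w_offset,     Δt = t_post - t_pre

  so *earlier* presynaptic spikes converge to *larger* weights; on a
  presynaptic spike, weights of recently fired postsynaptic neurons are
  depressed by `alpha_minus·(1 - y_j)`. Hard bounds keep `w ∈ [0,1]`.
* **Competition** — the first representation neuron to fire (the spiking
  best matching unit, SBMU) inhibits the rest; a homeostatic ramp of the
  inhibitory weights from `9·V_theta_v` to `91·V_theta_v` moves the layer
  from k-WTA to strict WTA over training. `V_theta_v = 0.25·k·l` scales
  the model to any input dimensionality `k`.
* **Decoding & metrics** — code vectors are read out per dimension as the
  circular mean of tuning centers weighted by the learned weights; quality
  is measured by RMS reconstruction error, sparsity (spikes per window /
  m) and incoherence of the SBMU election.

See `docs/methods.md` for the full account.

## Worked example

Train an 8-neuron representation layer on a stream of noisy 9-dimensional
prototype patches and evaluate it on held-out patches:

```python
import numpy as np
from wtcrl import Network, NetworkConfig, SyntheticSpec, generate_synthetic

spec = SyntheticSpec(n_prototypes=4, k=9, jitter_sd=0.03, seed=42)
patches, labels, prototypes = generate_synthetic(spec, 2200)

net = Network(NetworkConfig(k=9, m=8, seed=1))
net.train(iter(patches[:2000]), 2000)
report = net.evaluate(iter(patches[2000:]))
print(report.as_dict())

code_vectors = net.code_vectors()
for i, proto in enumerate(prototypes):
    err = np.abs(code_vectors - proto).max(axis=1).min()
    print(f"prototype {i}: best per-coordinate error {err:.4f}")
```

Output:

```
{'rms': 0.029090088317586586, 'sparsity': 0.125, 'incoherence_5': 0.0,
 'incoherence_10': 0.0, 'silent_rate': 0.0, 'n_presentations': 200}
prototype 0: best per-coordinate error 0.0084
prototype 1: best per-coordinate error 0.0085
prototype 2: best per-coordinate error 0.0081
prototype 3: best per-coordinate error 0.0091
```

Reading it: the trained network reconstructs held-out patches with RMS
error 0.029 (the jitter floor of the data is 0.03, so the prototypes are
essentially perfectly recovered — each within 0.01 per coordinate);
sparsity 0.125 means exactly one of the 8 neurons fires per 25 ms window
(a single spike per presentation); zero incoherence means the firing
neuron is always the one whose code vector is closest to the input.

The same protocols are available from the shell:

```
wtcrl synth --prototypes 4 --k 9 --n 1000 --noise 0.03 --out patches.csv
wtcrl train --dataset synth --k 9 --m 8 --iters 2000 --seed 1 --out run/
wtcrl eval  --model run/ --dataset synth --count 200 --report json
```

## Acceptance script

`scripts/acceptance.py` recomputes the package's headline quantity from
scratch by running the simulator — it encodes a randomly drawn scalar with
the reference parameters and counts the spikes the 10-neuron encoding
population emits in one presentation window:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The JSON maps each quantity's id to the value measured in that run.
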