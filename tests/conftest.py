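"""Shared fixtures: the synthetic benchmark world and cached training runs.

The synthetic benchmark is the package's stated test world: 4 well-separated
prototypes in k = 9 dimensions, Gaussian jitter sd 0.03, an m = 8
representation layer trained for P = 2000 presentations and evaluated on
200 held-out patches.  Training runs are expensive (~half a minute each),
so they are cached per (seed, noise) at session scope and shared between
the unit and acceptance suites.
"""

from dataclasses import dataclass

import numpy as np
import pytest

from wtcrl import Network, NetworkConfig, SyntheticSpec, generate_synthetic
from wtcrl.codec import MetricsReport

# the stated synthetic world
BENCH_PROTOTYPES = 4
BENCH_K = 9
BENCH_JITTER = 0.03
BENCH_M = 8
BENCH_P = 2000
BENCH_EVAL = 200
BENCH_DATA_SEED = 42


@dataclass
class BenchRun:
    net: Network
    report: MetricsReport
    untrained_report: MetricsReport
    log: list
    prototypes: np.ndarray
    code_vectors: np.ndarray


@pytest.fixture(scope="session")
def bench_world():
    """Synthetic patches, labels and ground-truth prototypes."""
    spec = SyntheticSpec(
        n_prototypes=BENCH_PROTOTYPES,
        k=BENCH_K,
        jitter_sd=BENCH_JITTER,
        seed=BENCH_DATA_SEED,
    )
    patches, labels, protos = generate_synthetic(spec, BENCH_P + BENCH_EVAL)
    return patches, labels, protos


@pytest.fixture(scope="session")
def bench_run(bench_world):
    """Factory returning a cached trained-and-evaluated benchmark run.

    ``run(seed, g)`` trains with noise scale ``g`` and evaluates the learned
    representation noise-free (the robustness protocol perturbs learning,
    not the read-out).
    """
    patches, labels, protos = bench_world
    train_patches = patches[:BENCH_P]
    eval_patches = patches[BENCH_P:]
    cache: dict = {}

    def run(seed: int, g: float = 0.0) -> BenchRun:
        key = (seed, g)
        if key not in cache:
            # fresh config per network: set_noise mutates the config it holds
            untrained = Network(NetworkConfig(k=BENCH_K, m=BENCH_M, seed=seed, g=g))
            untrained.set_noise(0.0)
            untrained_report = untrained.evaluate(iter(eval_patches))
            net = Network(NetworkConfig(k=BENCH_K, m=BENCH_M, seed=seed, g=g))
            log = net.train(iter(train_patches), BENCH_P)
            net.set_noise(0.0)
            report = net.evaluate(iter(eval_patches))
            cache[key] = BenchRun(
                net=net,
                report=report,
                untrained_report=untrained_report,
                log=list(log),
                prototypes=protos,
                code_vectors=net.code_vectors(),
            )
        return cache[key]

    return run
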