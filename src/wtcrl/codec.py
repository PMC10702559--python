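"""Decoding learned weights back to input space, and evaluation metrics.

A representation neuron's afferent weight row stores, per input dimension,
a unimodal profile over the ``l`` tuning centers.  Decoding maps each
``l``-block back to a scalar with a weighted *circular* mean of the
centers' preferred directions (angles ``theta_z = 2 pi mu_z``), the same
population-vector construction used to decode movement direction from
motor-cortex activity:

    xbar = sum_z w_z cos(theta_z) / sum_z w_z
    ybar = sum_z w_z sin(theta_z) / sum_z w_z
    a_hat = (atan2(-ybar, -xbar) + pi) / (2 pi)

Three metrics summarize an evaluation run:

* RMS reconstruction error: mean over patches of the per-patch root mean
  squared pixel error (the root is taken inside the patch average).
* Sparsity: spikes emitted by the representation layer per window divided
  by the number of neurons ``m``.
* Incoherence: fraction of presentations whose first-spiking neuron (SBMU)
  is *not* among the ``ceil(m*x)`` neurons whose code vectors are closest
  (Euclidean) to the input.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "UndefinedCircularMeanError",
    "CodeVector",
    "MetricsReport",
    "decode_coordinate",
    "reconstruct_patch",
    "decode_all",
    "rms_error",
    "sparsity",
    "incoherence",
    "spike_economy_ratio",
]


class UndefinedCircularMeanError(ValueError):
    """Raised when a weight block has zero mass or a vanishing resultant."""


#: Resultant lengths below this are treated as the degenerate symmetric case.
_RESULTANT_TOL = 1e-9


def decode_coordinate(
    weights: np.ndarray,
    centers: np.ndarray,
    strict: bool = True,
) -> float:
    """Weighted circular mean of the tuning centers; inverse of the encoder.

    Parameters
    ----------
    weights : (l,) array
        Non-negative weights of one dimension's block.
    centers : (l,) array
        The tuning centers mu_z in [0, 1].
    strict : bool
        If True, a zero weight sum or a near-zero resultant (perfectly
        symmetric weights) raises :class:`UndefinedCircularMeanError`;
        if False, the coordinate falls back to 0.5 with a warning so a
        full-patch reconstruction can proceed on pathological neurons.
    """
    weights = np.asarray(weights, dtype=float)
    centers = np.asarray(centers, dtype=float)
    if weights.shape != centers.shape:
        raise ValueError("weights and centers must have the same length")
    total = weights.sum()
    theta = 2.0 * math.pi * centers
    if total > 0:
        xbar = (weights * np.cos(theta)).sum() / total
        ybar = (weights * np.sin(theta)).sum() / total
    else:
        xbar = ybar = 0.0
    if total <= 0 or math.hypot(xbar, ybar) < _RESULTANT_TOL:
        if strict:
            raise UndefinedCircularMeanError(
                "circular mean undefined: "
                + ("all-zero weights" if total <= 0 else "vanishing resultant")
            )
        warnings.warn(
            "undefined circular mean; decoding coordinate as 0.5", stacklevel=2
        )
        return 0.5
    theta_bar = math.atan2(-ybar, -xbar) + math.pi  # in [0, 2 pi)
    return theta_bar / (2.0 * math.pi)


@dataclass
class CodeVector:
    """Input-space vector decoded from one neuron's afferent weights."""

    values: np.ndarray
    neuron: int = -1


def reconstruct_patch(
    w_row: np.ndarray,
    k: int,
    l: int,
    centers: np.ndarray,
    strict: bool = False,
    neuron: int = -1,
) -> CodeVector:
    """Decode a neuron's full weight row into a k-dimensional code vector.

    The row is split into ``k`` consecutive ``l``-blocks (dimension-major
    layout, matching the encoder) and each block is decoded independently.
    With ``strict=False`` degenerate blocks decode to 0.5 with a warning.
    """
    w_row = np.asarray(w_row, dtype=float)
    if w_row.shape != (k * l,):
        raise ValueError(f"expected weight row of length k*l={k * l}, got {w_row.shape}")
    values = np.array(
        [
            decode_coordinate(w_row[i * l : (i + 1) * l], centers, strict=strict)
            for i in range(k)
        ]
    )
    return CodeVector(values=values, neuron=neuron)


def decode_all(W: np.ndarray, k: int, l: int, centers: np.ndarray) -> np.ndarray:
    """Code vectors of every representation neuron, as an (m, k) array."""
    return np.stack(
        [reconstruct_patch(row, k, l, centers, strict=False).values for row in W]
    )


def rms_error(
    originals: np.ndarray, reconstructions: np.ndarray, pooled: bool = False
) -> float:
    """Reconstruction error between P original and P reconstructed patches.

    Default: mean over patches of sqrt(mean over pixels of squared error),
    i.e. the root is taken per patch before averaging.  ``pooled=True``
    instead takes a single root over the pooled mean squared error (a
    sensitivity-check variant, not the reported metric).
    """
    a = np.atleast_2d(np.asarray(originals, dtype=float))
    ahat = np.atleast_2d(np.asarray(reconstructions, dtype=float))
    if a.shape != ahat.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {ahat.shape}")
    if a.shape[0] == 0:
        raise ValueError("need at least one patch")
    sq = (a - ahat) ** 2
    if pooled:
        return float(np.sqrt(sq.mean()))
    return float(np.sqrt(sq.mean(axis=1)).mean())


def sparsity(spike_counts, m: int) -> float:
    """Mean spikes per presentation window divided by the layer size m."""
    if m <= 0:
        raise ValueError("m must be > 0")
    counts = np.atleast_1d(np.asarray(spike_counts, dtype=float))
    if np.any(counts < 0):
        raise ValueError("spike counts must be >= 0")
    return float(counts.mean() / m)


def _distance_ranks(inputs: np.ndarray, code_vectors: np.ndarray) -> np.ndarray:
    """Per-presentation neuron orderings by normalized Euclidean distance.

    Distances are divided by sqrt(k) so they live in [0, 1] for coordinates
    in [0, 1]; the normalization does not change the ordering.  Ties are
    broken by neuron index (stable sort).
    """
    k = inputs.shape[1]
    d = np.linalg.norm(
        inputs[:, None, :] - code_vectors[None, :, :], axis=2
    ) / math.sqrt(k)
    return np.argsort(d, axis=1, kind="stable")


def incoherence(
    sbmu_indices,
    inputs: np.ndarray,
    code_vectors: np.ndarray,
    x: float,
) -> float:
    """Fraction of presentations whose SBMU is outside the top ceil(m*x) ranks.

    For each presentation the ``m`` code vectors are ranked by distance to
    the input; the SBMU counts as *coherent* if its rank is within the top
    ``ceil(m*x)`` and *paradoxical* otherwise.  Returns
    ``1 - sc / (sc + sp)``.
    """
    if not (0 < x <= 1):
        raise ValueError("decision threshold x must be in (0, 1]")
    sbmu_indices = np.atleast_1d(np.asarray(sbmu_indices, dtype=int))
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    if sbmu_indices.shape[0] != inputs.shape[0]:
        raise ValueError("one SBMU index per presentation required")
    if sbmu_indices.shape[0] == 0:
        raise ValueError("incoherence undefined: no presentations with an SBMU")
    m = code_vectors.shape[0]
    top = math.ceil(m * x)
    order = _distance_ranks(inputs, code_vectors)
    coherent = (order[:, :top] == sbmu_indices[:, None]).any(axis=1)
    sc = int(coherent.sum())
    sp = coherent.shape[0] - sc
    return 1.0 - sc / (sc + sp)


def spike_economy_ratio(
    baseline_sparsity: float,
    baseline_window_steps: int,
    model_sparsity: float,
) -> float:
    """Per-neuron spike-count ratio of a rate-coded baseline to this model.

    A rate-coded network with per-step sparsity ``baseline_sparsity``
    integrated over ``baseline_window_steps`` steps emits
    ``baseline_sparsity * baseline_window_steps`` spikes per neuron per
    window; this model emits ``model_sparsity`` (single-spike code).
    """
    if model_sparsity <= 0:
        raise ValueError("model sparsity must be > 0")
    return baseline_sparsity * baseline_window_steps / model_sparsity


@dataclass
class MetricsReport:
    """Aggregate evaluation metrics over a presentation set."""

    rms: float
    sparsity: float
    incoherence_5: float
    incoherence_10: float
    silent_rate: float
    n_presentations: int = 0

    def as_dict(self) -> dict:
        return asdict(self)
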