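"""Dataset ingestion, patch extraction/normalization, synthetic patch streams.

Supports the two image sources the experiments use — MNIST digits stored in
IDX containers and 512x512 natural images stored as portable grayscale or
raw-float files — plus a synthetic prototype-mixture generator so the whole
package can be exercised without any download.  Patches are flattened
row-major and affinely normalized into a margin interval strictly inside
[0, 1] ([0.15, 0.85] for MNIST, [0.05, 0.95] for natural images): the
margin keeps extreme pixel values apart on the circular encoding space,
where 1.0 wraps onto 0.0.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = [
    "PatchSpec",
    "SyntheticSpec",
    "read_idx",
    "write_idx",
    "load_mnist_images",
    "normalize",
    "extract_patches",
    "make_prototypes",
    "generate_synthetic",
    "synthetic_stream",
]

_IDX_DTYPES = {
    0x08: np.uint8,
    0x09: np.int8,
    0x0B: ">i2",
    0x0C: ">i4",
    0x0D: ">f4",
    0x0E: ">f8",
}


def read_idx(path: str | Path) -> np.ndarray:
    """Read an IDX container (the MNIST file format) into an ndarray.

    The header is big-endian: two zero bytes, a type code, the number of
    dimensions, then one 4-byte size per dimension.  Raises a format error
    with the offending byte offset on bad magic or truncation.
    """
    data = Path(path).read_bytes()
    if len(data) < 4:
        raise ValueError(f"{path}: truncated IDX header (file has {len(data)} bytes)")
    zero1, zero2, type_code, ndim = struct.unpack(">BBBB", data[:4])
    if zero1 != 0 or zero2 != 0 or type_code not in _IDX_DTYPES:
        raise ValueError(f"{path}: bad IDX magic {data[:4]!r} at byte offset 0")
    header_end = 4 + 4 * ndim
    if len(data) < header_end:
        raise ValueError(f"{path}: truncated IDX dimension list at byte offset {len(data)}")
    shape = struct.unpack(f">{ndim}I", data[4:header_end])
    dtype = np.dtype(_IDX_DTYPES[type_code])
    expected = header_end + int(np.prod(shape)) * dtype.itemsize
    if len(data) < expected:
        raise ValueError(
            f"{path}: truncated IDX payload at byte offset {len(data)} "
            f"(expected {expected} bytes)"
        )
    return np.frombuffer(data[header_end:expected], dtype=dtype).reshape(shape)


def write_idx(path: str | Path, array: np.ndarray) -> None:
    """Write an ndarray as an IDX container (round-trip counterpart of read_idx)."""
    array = np.ascontiguousarray(array)
    code = None
    for c, dt in _IDX_DTYPES.items():
        if np.dtype(dt) == array.dtype:
            code = c
            break
    if code is None:
        raise ValueError(f"dtype {array.dtype} has no IDX type code")
    with open(path, "wb") as fh:
        fh.write(struct.pack(">BBBB", 0, 0, code, array.ndim))
        fh.write(struct.pack(f">{array.ndim}I", *array.shape))
        fh.write(array.tobytes())


def load_mnist_images(path: str | Path) -> np.ndarray:
    """Read an MNIST image file and check it holds a stack of 2-D images."""
    images = read_idx(path)
    if images.ndim != 3:
        raise ValueError(f"{path}: expected images with 3 dimensions, got {images.ndim}")
    return images


@dataclass(frozen=True)
class PatchSpec:
    """Patch extraction and normalization settings.

    ``source_range`` fixes the affine normalization's source interval (e.g.
    (0, 255) for MNIST so patch intensities keep their global meaning);
    when None the observed dataset min/max is used.
    """

    side: int = 5
    margin_low: float = 0.15
    margin_high: float = 0.85
    count: int = 1000
    seed: int = 0
    source_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.margin_low < self.margin_high <= 1):
            raise ValueError("need 0 <= margin_low < margin_high <= 1")
        if self.side < 1:
            raise ValueError("patch side must be >= 1")

    @property
    def k(self) -> int:
        return self.side**2


def normalize(
    values: np.ndarray,
    low: float,
    high: float,
    source_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Affine map of ``values`` from ``source_range`` onto [low, high].

    The source interval defaults to the observed min/max; a constant input
    (degenerate range) maps to ``high``.
    """
    values = np.asarray(values, dtype=float)
    if source_range is None:
        lo, hi = float(values.min()), float(values.max())
    else:
        lo, hi = source_range
    if hi <= lo:
        return np.full_like(values, high)
    return low + (values - lo) * (high - low) / (hi - lo)


def extract_patches(images: np.ndarray, spec: PatchSpec) -> np.ndarray:
    """Draw patches at uniformly random positions from randomly chosen images.

    Returns an array of shape (count, side**2); each patch is flattened
    row-major and normalized into [margin_low, margin_high].  Blank
    (constant) regions are kept, not filtered.  The same seed yields the
    identical patch sequence (integer RNG, fixed draw order).
    """
    if spec.count <= 0:
        raise ValueError("patch count must be > 0")
    images = np.asarray(images)
    if images.ndim != 3:
        raise ValueError("images must have shape (n_images, height, width)")
    n_img, h, w = images.shape
    if spec.side > h or spec.side > w:
        raise ValueError(f"patch side {spec.side} exceeds image size {h}x{w}")
    rng = np.random.default_rng(spec.seed)
    img_idx = rng.integers(0, n_img, size=spec.count)
    rows = rng.integers(0, h - spec.side + 1, size=spec.count)
    cols = rng.integers(0, w - spec.side + 1, size=spec.count)
    source = spec.source_range
    if source is None:
        source = (float(images.min()), float(images.max()))
    patches = np.empty((spec.count, spec.k))
    for p in range(spec.count):
        window = images[img_idx[p], rows[p] : rows[p] + spec.side, cols[p] : cols[p] + spec.side]
        patches[p] = normalize(
            window.astype(float).ravel(), spec.margin_low, spec.margin_high, source
        )
    return patches


# -- synthetic prototype mixtures ------------------------------------------


@dataclass(frozen=True)
class SyntheticSpec:
    """A synthetic world: a mixture of fixed prototype patches plus jitter.

    Each emitted patch is a prototype drawn according to ``mix_weights``
    with i.i.d. Gaussian jitter of standard deviation ``jitter_sd`` added
    per coordinate, clipped back into the normalization margins.  The true
    prototype index accompanies every patch, enabling parameter-recovery
    tests against ground truth.
    """

    n_prototypes: int = 4
    k: int = 9
    jitter_sd: float = 0.03
    margin_low: float = 0.15
    margin_high: float = 0.85
    mix_weights: tuple[float, ...] | None = None
    seed: int = 0
    prototypes: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.mix_weights is not None:
            w = np.asarray(self.mix_weights, dtype=float)
            if w.shape != (self.n_prototypes,) or np.any(w < 0):
                raise ValueError("mix_weights must be n_prototypes nonnegative values")
            if not np.isclose(w.sum(), 1.0):
                raise ValueError("mix_weights must sum to 1")
        if self.prototypes is not None:
            protos = np.asarray(self.prototypes, dtype=float)
            if protos.shape != (self.n_prototypes, self.k):
                raise ValueError("prototypes must have shape (n_prototypes, k)")
            if protos.min() < self.margin_low or protos.max() > self.margin_high:
                raise ValueError("prototypes must lie within the margins")


def make_prototypes(
    n: int,
    k: int,
    rng: np.random.Generator,
    margin_low: float = 0.15,
    margin_high: float = 0.85,
    min_separation: float = 0.25,
    max_tries: int = 10000,
) -> np.ndarray:
    """Draw ``n`` well-separated prototypes uniformly within the margins.

    Separation is measured as Euclidean distance normalized by sqrt(k);
    candidates closer than ``min_separation`` to an accepted prototype are
    rejected and redrawn.
    """
    protos: list[np.ndarray] = []
    for _ in range(max_tries):
        cand = rng.uniform(margin_low, margin_high, size=k)
        if all(
            np.linalg.norm(cand - p) / np.sqrt(k) >= min_separation for p in protos
        ):
            protos.append(cand)
            if len(protos) == n:
                return np.stack(protos)
    raise RuntimeError(
        f"could not place {n} prototypes at separation {min_separation} "
        f"in {max_tries} draws"
    )


def generate_synthetic(
    spec: SyntheticSpec, count: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate ``count`` synthetic patches.

    Returns ``(patches, labels, prototypes)`` where ``labels[p]`` is the
    index of the prototype patch ``p`` was jittered from.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.prototypes is not None:
        protos = np.asarray(spec.prototypes, dtype=float)
    else:
        protos = make_prototypes(
            spec.n_prototypes, spec.k, rng, spec.margin_low, spec.margin_high
        )
    if spec.mix_weights is None:
        p = np.full(spec.n_prototypes, 1.0 / spec.n_prototypes)
    else:
        p = np.asarray(spec.mix_weights, dtype=float)
    labels = rng.choice(spec.n_prototypes, size=count, p=p)
    patches = protos[labels] + rng.normal(0.0, spec.jitter_sd, size=(count, spec.k))
    np.clip(patches, spec.margin_low, spec.margin_high, out=patches)
    return patches, labels, protos


def synthetic_stream(spec: SyntheticSpec, count: int) -> Iterator[np.ndarray]:
    """Iterator over synthetic patches only (labels discarded)."""
    patches, _, _ = generate_synthetic(spec, count)
    return iter(patches)
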