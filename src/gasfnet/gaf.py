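"""Gramian angular summation field (GASF) encoding of ECG segments.

A 1-D segment is min--max rescaled to [-1, 1], optionally shortened by
piecewise aggregate approximation (PAA), mapped to polar angles
``phi = arccos(x)`` and encoded as the matrix of pairwise angle-sum
cosines ``G[i, j] = cos(phi_i + phi_j)``.  The encoding preserves temporal
order (time runs along the main diagonal) and the diagonal itself stores
``2*x^2 - 1``, so the rescaled series is recoverable up to sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .signal_io import Segment

__all__ = [
    "GAFImage",
    "rescale_unit",
    "paa",
    "to_polar",
    "gasf",
    "encode_segment",
    "encode_dataset",
    "save_images",
    "load_images",
    "to_png",
]

log = logging.getLogger(__name__)

#: Inputs this far outside [-1, 1] are clamped rather than rejected.
CLAMP_TOL = 1e-12


@dataclass
class GAFImage:
    """A GASF matrix with its provenance.

    ``matrix`` is S x S, symmetric, with entries in [-1, 1]; ``encoding``
    is always ``"GASF"`` (the difference field is deliberately not
    implemented).
    """

    matrix: np.ndarray
    source: dict = field(default_factory=dict)
    encoding: str = "GASF"

    @property
    def size(self) -> int:
        return self.matrix.shape[0]


def rescale_unit(values: Sequence[float]) -> np.ndarray:
    """Affinely map a series onto [-1, 1] (min -> -1, max -> +1).

    A constant series has no span; by convention it maps to all zeros
    (logged as a warning) so that downstream arccos stays defined.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot rescale an empty series")
    lo, hi = x.min(), x.max()
    if hi == lo:
        log.warning("rescale_unit: constant series of length %d mapped to zeros", x.size)
        return np.zeros_like(x)
    return (2.0 * x - hi - lo) / (hi - lo)


def paa(values: Sequence[float], m: int) -> np.ndarray:
    """Piecewise aggregate approximation: frame means at target length ``m``.

    The series is split into ``m`` contiguous frames whose lengths differ
    by at most one (the remainder goes to the leading frames); each output
    value is the mean of its frame.  ``m == len(values)`` is the identity.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if not 1 <= m <= n:
        raise ValueError(f"PAA target length must be in [1, {n}], got {m}")
    if m == n:
        return x.copy()
    base, rem = divmod(n, m)
    bounds = np.cumsum([0] + [base + 1] * rem + [base] * (m - rem))
    return np.add.reduceat(x, bounds[:-1]) / np.diff(bounds)


def to_polar(x: Sequence[float]) -> np.ndarray:
    """Map a rescaled series to polar angles ``arccos(x)`` in [0, pi]."""
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > 1.0 + CLAMP_TOL):
        bad = float(np.abs(x).max())
        raise ValueError(f"polar encoding needs values in [-1, 1]; max |x| = {bad}")
    return np.arccos(np.clip(x, -1.0, 1.0))


def gasf(phi: Sequence[float]) -> GAFImage:
    """Gramian angular summation field ``G[i, j] = cos(phi_i + phi_j)``."""
    phi = np.asarray(phi, dtype=float)
    if phi.size == 0:
        raise ValueError("cannot encode an empty angle sequence")
    matrix = np.cos(phi[:, None] + phi[None, :])
    return GAFImage(matrix)


def encode_segment(segment: Segment | Sequence[float], size: int | None = 224) -> GAFImage:
    """Encode one segment: rescale -> PAA(size) -> polar -> GASF.

    ``size`` is the output image side; ``None`` (or the segment length)
    skips PAA.  Rescaling is per-segment.
    """
    if isinstance(segment, Segment):
        values, source = segment.values, {
            "record": segment.source_record,
            "start": segment.start_index,
            "label": segment.label,
            "length": len(segment),
        }
    else:
        values, source = np.asarray(segment, dtype=float), {"length": int(np.size(segment))}
    x = rescale_unit(values)
    if size is not None and size != x.size:
        x = paa(x, size)
    img = gasf(to_polar(x))
    img.source = source
    return img


def encode_dataset(segments: Sequence[Segment], size: int = 224) -> tuple[np.ndarray, list[str | None]]:
    """Encode many segments into an (N, S, S) float array plus labels."""
    imgs = np.empty((len(segments), size, size), dtype=float)
    labels: list[str | None] = []
    for i, seg in enumerate(segments):
        imgs[i] = encode_segment(seg, size).matrix
        labels.append(seg.label if isinstance(seg, Segment) else None)
    return imgs, labels


def save_images(path: str | Path, images: np.ndarray, labels: Sequence[str | None]) -> None:
    """Store an image stack and labels in a portable NPZ archive."""
    np.savez_compressed(
        Path(path),
        images=np.asarray(images, dtype=np.float32),
        labels=np.asarray(["" if l is None else l for l in labels]),
    )


def load_images(path: str | Path) -> tuple[np.ndarray, list[str | None]]:
    with np.load(Path(path)) as npz:
        images = npz["images"].astype(float)
        labels = [l or None for l in npz["labels"].tolist()]
    return images, labels


def to_png(image: GAFImage | np.ndarray, path: str | Path) -> None:
    """Export an image for visualization, mapping [-1, 1] -> [0, 255].

    Lossy 8-bit quantization: training always consumes the float matrices.
    """
    from PIL import Image

    m = image.matrix if isinstance(image, GAFImage) else np.asarray(image)
    u8 = np.round((np.clip(m, -1.0, 1.0) + 1.0) * 127.5).astype(np.uint8)
    Image.fromarray(u8, mode="L").save(Path(path))
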