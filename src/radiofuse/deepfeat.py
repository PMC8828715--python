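"""Deep feature block over the 2.5D views.

The pipeline only requires a deterministic mapping from each 224x224 view
to a fixed-width feature vector (default 2048 per view, 6144 per patient
over the three views).  A pretrained CNN adapter can implement the same
``ViewExtractor`` contract; the built-in extractor is a seeded bank of
small convolution kernels (oriented edges, blobs, and random projections)
with rectification and global average pooling — fully deterministic and
sensitive to both intensity level and texture amplitude, which is what the
downstream supervised selection needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core import FeatureVector
from .imaging import MultiplanarViews

DEFAULT_WIDTH = 2048
VIEW_ORDER = ("axial", "sagittal", "coronal")


@dataclass
class ViewExtractor:
    """Contract: a named, deterministic map view -> ``width`` real numbers."""

    name: str
    width: int
    apply: Callable[[np.ndarray], np.ndarray]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("width must be >= 1")


def extract_deep(views: MultiplanarViews, extractor: ViewExtractor,
                 block: str = "TL") -> FeatureVector:
    """Concatenate extractor output over (axial, sagittal, coronal)."""
    values: list[np.ndarray] = []
    names: list[str] = []
    for view_name, view in zip(VIEW_ORDER, views.as_tuple()):
        out = np.asarray(extractor.apply(view), dtype=float).ravel()
        if out.size != extractor.width:
            raise ValueError(
                f"extractor {extractor.name!r} returned {out.size} values "
                f"for the {view_name} view, expected {extractor.width}"
            )
        values.append(out)
        names += [f"{extractor.name}.{view_name}.{i:04d}"
                  for i in range(extractor.width)]
    return FeatureVector(values=np.concatenate(values), names=names,
                         block=block)


def _fixed_kernels(ksize: int) -> np.ndarray:
    """A few oriented edge/blob kernels, flattened (each ksize*ksize)."""
    k = ksize
    y, x = np.mgrid[:k, :k] - (k - 1) / 2
    r2 = x ** 2 + y ** 2
    gauss = np.exp(-r2 / (0.5 * k))
    kernels = [
        x * gauss,                     # vertical edge
        y * gauss,                     # horizontal edge
        (x + y) * gauss,               # diagonal edge
        (x - y) * gauss,               # anti-diagonal edge
        (1 - r2 / r2.max()) * gauss,   # centre blob
        (r2 / r2.max() - 0.5) * gauss, # ring / surround
    ]
    return np.stack([kk.ravel() / (np.abs(kk).sum() + 1e-12) for kk in kernels])


def _pool(view: np.ndarray, factor: int) -> np.ndarray:
    h = (view.shape[0] // factor) * factor
    w = (view.shape[1] // factor) * factor
    v = view[:h, :w].reshape(h // factor, factor, w // factor, factor)
    return v.mean(axis=(1, 3))


def filterbank_standin(seed: int, width: int = DEFAULT_WIDTH,
                       ksize: int = 5, pool_factor: int = 8) -> ViewExtractor:
    """Deterministic convolutional filter-bank extractor.

    Each view is average-pooled by ``pool_factor``, all ``ksize x ksize``
    patches are extracted, and each of ``width`` kernels (the fixed
    oriented set plus seeded random projections, each with a seeded bias)
    is applied to every patch; responses are rectified (ReLU) and globally
    average-pooled to one number per kernel.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    rng = np.random.default_rng(seed)
    fixed = _fixed_kernels(ksize)
    n_random = max(0, width - len(fixed))
    random_k = rng.normal(size=(n_random, ksize * ksize))
    random_k /= np.linalg.norm(random_k, axis=1, keepdims=True)
    kernels = np.concatenate([fixed, random_k])[:width]  # (width, k*k)
    biases = rng.normal(0.0, 0.1, size=width)

    def apply(view: np.ndarray) -> np.ndarray:
        v = _pool(np.asarray(view, dtype=float), pool_factor)
        # patch matrix: (n_patches, k*k)
        wins = np.lib.stride_tricks.sliding_window_view(v, (ksize, ksize))
        patches = wins.reshape(-1, ksize * ksize)
        resp = patches @ kernels.T + biases  # (n_patches, width)
        return np.maximum(resp, 0.0).mean(axis=0)

    return ViewExtractor(name=f"standin{seed}", width=width, apply=apply,
                         seed=seed)
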