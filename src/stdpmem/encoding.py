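"""Tensor-product encoding of data vectors with orthonormal tag vectors.

A raw datum ``f`` (an image flattened to brightness deviations, or a word
embedding) is bound to a low-dimensional *tag* vector ``r`` by the outer
product ``m = f r^T``, flattened to a single state vector of length
``D * K``.  When the tags are orthonormal, right-contraction with a tag
recovers the corresponding datum exactly, and a superposition of encoded
memories decodes selectively: ``decode(sum_j c_j m_j, r_i) = c_i f_i``.

Layout convention: element ``(d, k)`` of the ``D x K`` outer product sits at
flat position ``d * K + k`` (data index varies slowest).  ``encode`` and
``decode`` share this convention; nothing else in the package depends on it.

Also provides the image <-> vector translation (pixel brightness mapped
affinely to ``[-sigma, sigma]``) and a seeded generator of synthetic
"dark object on a light background" fixture images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TagSet",
    "ImageSpec",
    "make_tag_set",
    "encode",
    "decode",
    "image_to_vector",
    "vector_to_image",
    "synth_image",
    "load_image",
    "save_image",
]

ORTHO_TOL = 1e-12


@dataclass
class TagSet:
    """An ordered set of ``m`` orthonormal tag vectors in ``R^K``.

    ``vectors`` has shape ``(m, K)``; ``labels`` are free-form identifiers
    (slot indices, or grammatical roles such as ``"S"``, ``"P"``).
    """

    vectors: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if not self.labels:
            self.labels = [str(i) for i in range(len(self.vectors))]
        if len(self.labels) != len(self.vectors):
            raise ValueError("labels and vectors length mismatch")

    @property
    def m(self) -> int:
        return self.vectors.shape[0]

    @property
    def K(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return self.m

    def __getitem__(self, key) -> np.ndarray:
        if isinstance(key, str):
            key = self.labels.index(key)
        return self.vectors[key]

    def gram(self) -> np.ndarray:
        return self.vectors @ self.vectors.T

    def max_orthonormality_defect(self) -> float:
        return float(np.max(np.abs(self.gram() - np.eye(self.m))))


@dataclass
class ImageSpec:
    """A grayscale image: ``pixels`` in ``[0, 1]`` plus the brightness
    half-range ``sigma`` used when mapping to a data vector."""

    pixels: np.ndarray
    sigma: float = 0.02

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


def make_tag_set(m: int, K: int, seed: int, labels: list | None = None) -> TagSet:
    """Draw ``m`` orthonormal tag vectors in ``R^K`` (seeded Gaussian + QR).

    Signs are fixed so the result is a deterministic function of the seed.
    """
    if not 1 <= m <= K:
        raise ValueError(f"need 1 <= m <= K, got m={m}, K={K}")
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((K, m))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    return TagSet(vectors=Q.T.copy(), labels=list(labels) if labels else [])


def encode(f: np.ndarray, r: np.ndarray, check: bool = True) -> np.ndarray:
    """Bind datum ``f`` (length D) to tag ``r`` (length K): flattened ``f r^T``."""
    f = np.asarray(f, dtype=float).ravel()
    r = np.asarray(r, dtype=float).ravel()
    nr = np.linalg.norm(r)
    if nr == 0.0:
        raise ValueError("tag vector must be nonzero")
    if check and abs(nr - 1.0) > 1e-9:
        warnings.warn(
            f"tag vector is not unit length (|r|={nr:.6g}); decoding will "
            "not be exact",
            stacklevel=2,
        )
    return np.outer(f, r).ravel()


def decode(x: np.ndarray, r: np.ndarray, D: int | None = None,
           K: int | None = None) -> np.ndarray:
    """Right-contract a state with a tag: ``reshape(x, (D, K)) @ r``.

    For a retrievable state ``x = sum_j c_j encode(f_j, r_j)`` with
    orthonormal tags this returns ``c_i f_i`` when called with ``r_i``.
    """
    x = np.asarray(x, dtype=float).ravel()
    r = np.asarray(r, dtype=float).ravel()
    if K is None:
        K = r.size
    elif K != r.size:
        raise ValueError(f"K={K} does not match tag length {r.size}")
    if x.size % K != 0:
        raise ValueError(f"state length {x.size} not divisible by K={K}")
    if D is None:
        D = x.size // K
    elif D * K != x.size:
        raise ValueError(f"D*K={D * K} does not match state length {x.size}")
    return x.reshape(D, K) @ r


def decode_trajectory(states: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Decode every row of an ``(M, D*K)`` state array at once -> ``(M, D)``."""
    states = np.asarray(states, dtype=float)
    r = np.asarray(r, dtype=float).ravel()
    M, N = states.shape
    K = r.size
    if N % K != 0:
        raise ValueError("state length not divisible by tag length")
    return states.reshape(M, N // K, K) @ r


def image_to_vector(img: ImageSpec) -> np.ndarray:
    """Map brightness ``b`` in [0,1] to ``sigma * (2b - 1)`` and flatten.

    Pure black maps to ``-sigma``, pure white to ``+sigma``.  Out-of-range
    pixels are clipped with a warning.
    """
    pix = img.pixels
    if pix.min() < 0.0 or pix.max() > 1.0:
        warnings.warn("pixel brightness outside [0,1]; clipping", stacklevel=2)
        pix = np.clip(pix, 0.0, 1.0)
    return (img.sigma * (2.0 * pix - 1.0)).ravel()


def vector_to_image(g: np.ndarray, H: int, W: int,
                    sigma_display: float = 0.002) -> ImageSpec:
    """Inverse brightness map with clipping.

    Values at or below ``-sigma_display`` become pure black, at or above
    ``+sigma_display`` pure white, linear in between.  Retrieved vectors
    routinely exceed the display range, hence the clip rather than a
    strict inverse.
    """
    g = np.asarray(g, dtype=float).ravel()
    if g.size != H * W:
        raise ValueError(f"vector length {g.size} != H*W = {H * W}")
    if sigma_display <= 0:
        raise ValueError("sigma_display must be positive")
    b = np.clip((g / sigma_display + 1.0) / 2.0, 0.0, 1.0)
    return ImageSpec(pixels=b.reshape(H, W), sigma=sigma_display)


_STYLES = ("blobs", "shapes", "noise")


def synth_image(seed: int, H: int = 64, W: int = 64,
                style: str = "blobs", sigma: float = 0.02) -> ImageSpec:
    """Seeded synthetic grayscale fixture image.

    ``blobs`` and ``shapes`` emulate a photographed silhouette: a dark
    object (brightness < 0.5) on a lighter background (> 0.5).  Background
    level and shading gradient, object position, size and darkness are all
    drawn from the seed, so that distinct seeds give images with near-zero
    mean brightness deviation and modest pairwise correlation.  ``noise``
    is i.i.d. uniform brightness.
    """
    if H < 4 or W < 4:
        raise ValueError("image must be at least 4x4")
    if style not in _STYLES:
        raise ValueError(f"unknown style {style!r}; choose from {_STYLES}")
    rng = np.random.default_rng(seed)
    if style == "noise":
        return ImageSpec(pixels=rng.uniform(0.0, 1.0, (H, W)), sigma=sigma)

    yy, xx = np.mgrid[0:H, 0:W]
    yy = yy / max(H - 1, 1)
    xx = xx / max(W - 1, 1)
    base = rng.uniform(0.58, 0.72)
    g1, g2 = rng.uniform(-0.12, 0.12, 2)
    background = np.clip(base + g1 * (yy - 0.5) + g2 * (xx - 0.5), 0.52, 0.95)

    # object support built from overlapping primitives; target ~20-40% cover
    mask = np.zeros((H, W), dtype=bool)
    strength = np.zeros((H, W))
    n_prim = int(rng.integers(2, 5))
    for _ in range(n_prim):
        cy, cx = rng.uniform(0.2, 0.8, 2)
        if style == "blobs":
            ry = rng.uniform(0.10, 0.28)
            rx = rng.uniform(0.10, 0.28)
            d2 = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
            m = d2 < 1.0
            s = np.exp(-d2)
        else:  # shapes: axis-aligned rectangles and bars
            hy = rng.uniform(0.06, 0.25)
            hx = rng.uniform(0.06, 0.25)
            m = (np.abs(yy - cy) < hy) & (np.abs(xx - cx) < hx)
            s = m.astype(float)
        mask |= m
        strength = np.maximum(strength, s)

    dark = rng.uniform(0.08, 0.32)
    obj = np.clip(dark + 0.1 * (1.0 - strength), 0.05, 0.45)
    pixels = np.where(mask, obj, background)
    return ImageSpec(pixels=pixels, sigma=sigma)


def load_image(path, sigma: float = 0.02) -> ImageSpec:
    """Read a raster image as grayscale brightness in [0, 1].

    Multi-channel inputs are converted by luminance average (PIL "L" mode).
    """
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=float) / 255.0
    return ImageSpec(pixels=arr, sigma=sigma)


def save_image(img: ImageSpec, path) -> None:
    """Write an 8-bit single-channel PNG."""
    from PIL import Image

    arr = np.clip(np.round(img.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)
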