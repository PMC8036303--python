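"""Texture feature extraction: GLCM/Haralick descriptor bags from images.

An image is quantized to G gray levels over its observed range, tiled into
patches, and each patch is described by the 13 classical Haralick statistics
of its gray-level co-occurrence matrix (averaged over a set of offsets).
Descriptors are mapped onto the simplex so they can be modeled by SSD
mixtures.  Keypoint descriptors (ORB, library-backed) are available as an
alternative bag type.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ssd import FeatureBag, project_to_simplex

__all__ = [
    "GLCM",
    "quantize",
    "glcm",
    "haralick_features",
    "image_to_bag",
    "load_image",
    "DEFAULT_OFFSETS",
]

#: horizontal, vertical and the two diagonal unit offsets
DEFAULT_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass(frozen=True)
class GLCM:
    """Normalized gray-level co-occurrence matrix at one pixel offset."""

    matrix: np.ndarray
    levels: int
    offset: tuple[int, int]
    symmetric: bool


def quantize(image: np.ndarray, levels: int) -> np.ndarray:
    """Linear binning of an image onto ``levels`` gray levels over its range."""
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    if hi - lo < 1e-12:
        return np.zeros(image.shape, dtype=np.intp)
    q = np.floor((image - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def glcm(
    image: np.ndarray,
    levels: int = 8,
    offset: tuple[int, int] = (0, 1),
    symmetric: bool = True,
) -> GLCM:
    """Co-occurrence probabilities of level pairs at ``offset`` = (dy, dx)."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    q = quantize(image, levels)
    dy, dx = int(offset[0]), int(offset[1])
    h, w = q.shape
    if h <= abs(dy) or w <= abs(dx):
        raise ValueError("image smaller than the offset traversal")
    ys = slice(max(0, -dy), h - max(0, dy))
    xs = slice(max(0, -dx), w - max(0, dx))
    src = q[ys, xs]
    dst = q[max(0, dy) : h - max(0, -dy), max(0, dx) : w - max(0, -dx)]
    counts = np.bincount(
        (src * levels + dst).ravel(), minlength=levels * levels
    ).reshape(levels, levels).astype(float)
    if symmetric:
        counts = counts + counts.T
    return GLCM(counts / counts.sum(), levels, (dy, dx), symmetric)


def _xlog2(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with the 0 log 0 := 0 convention."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def haralick_features(g: GLCM) -> np.ndarray:
    """The 13 classical Haralick texture statistics of one GLCM.

    Order: energy (angular second moment), contrast, correlation, variance,
    inverse difference moment, sum average, sum variance, sum entropy,
    entropy, difference variance, difference entropy, and the two
    information measures of correlation.  Entropies are in bits.
    """
    p = g.matrix
    n = g.levels
    i = np.arange(n)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    sd_x = float(np.sqrt(((i - mu_x) ** 2) @ px))
    sd_y = float(np.sqrt(((i - mu_y) ** 2) @ py))

    energy = float((p**2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if sd_x > 1e-12 and sd_y > 1e-12:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 0.0
    variance = float((((ii - mu_x) ** 2) * p).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())

    # distributions of i+j (range 0..2n-2) and |i-j| (range 0..n-1)
    p_sum = np.bincount((ii + jj).ravel(), weights=p.ravel(), minlength=2 * n - 1)
    p_diff = np.bincount(np.abs(ii - jj).ravel(), weights=p.ravel(), minlength=n)
    ks = np.arange(2 * n - 1)
    kd = np.arange(n)
    sum_avg = float(ks @ p_sum)
    sum_var = float(((ks - sum_avg) ** 2) @ p_sum)
    sum_ent = float(-_xlog2(p_sum).sum())
    entropy = float(-_xlog2(p).sum())
    diff_avg = float(kd @ p_diff)
    diff_var = float(((kd - diff_avg) ** 2) @ p_diff)
    diff_ent = float(-_xlog2(p_diff).sum())

    # information measures of correlation
    pxpy = np.outer(px, py)
    mask = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[mask] * np.log2(pxpy[mask])).sum())
    hxy2 = float(-_xlog2(pxpy).sum())
    hx = float(-_xlog2(px).sum())
    hy = float(-_xlog2(py).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 1e-12 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return np.array(
        [
            energy, contrast, correlation, variance, idm, sum_avg, sum_var,
            sum_ent, entropy, diff_var, diff_ent, imc1, imc2,
        ]
    )


def _haralick_patch(patch: np.ndarray, levels: int, offsets) -> np.ndarray:
    feats = [haralick_features(glcm(patch, levels, off)) for off in offsets]
    return np.mean(feats, axis=0)


def image_to_bag(
    image: np.ndarray,
    image_id: str = "image",
    *,
    patch_size: int = 16,
    stride: int | None = None,
    levels: int = 8,
    offsets=DEFAULT_OFFSETS,
    descriptor: str = "haralick",
    epsilon: float = 1e-6,
) -> FeatureBag:
    """Represent one grayscale image as a bag of simplex descriptors.

    ``descriptor="haralick"`` slides ``patch_size`` patches with ``stride``
    (default non-overlapping), computes offset-averaged 13-vectors and
    projects each onto the simplex (D = 13).  ``descriptor="keypoint"``
    delegates to the ORB detector of scikit-image and simplex-projects the
    binary descriptors.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    stride = stride or patch_size
    if descriptor == "haralick":
        h, w = image.shape
        if h < patch_size or w < patch_size:
            raise ValueError(f"image {image_id}: smaller than one patch")
        rows = []
        for y in range(0, h - patch_size + 1, stride):
            for x in range(0, w - patch_size + 1, stride):
                rows.append(
                    _haralick_patch(image[y : y + patch_size, x : x + patch_size], levels, offsets)
                )
        raw = np.vstack(rows)
    elif descriptor == "keypoint":
        from skimage.feature import ORB

        orb = ORB(n_keypoints=200)
        orb.detect_and_extract(image / max(image.max(), 1e-12))
        raw = orb.descriptors.astype(float)
        if raw is None or raw.shape[0] == 0:
            raise ValueError(f"image {image_id}: no keypoint descriptors extracted")
    else:
        raise ValueError("descriptor must be 'haralick' or 'keypoint'")
    if raw.shape[0] == 0:
        raise ValueError(f"image {image_id}: no descriptors extracted")
    return FeatureBag(image_id, project_to_simplex(raw, epsilon))


def load_image(path: str | Path) -> np.ndarray:
    """Read PNG/TIFF/JPEG as a 2-D grayscale float array (luminance for color)."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path), dtype=float)
    if img.ndim == 3:
        img = img[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
    return img
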