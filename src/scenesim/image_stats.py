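"""Form and color feature spaces for scene images, and set-level variance.

Two 64-dimensional global descriptors summarize each image:

* **form** — mean magnitude response of a bank of 64 Gabor filters
  (8 orientations x 8 spatial frequencies, 8x8-pixel kernels) applied to the
  grayscale image at the analysis resolution of 600x450 pixels.
* **color** — joint hue x saturation histogram with 8 uniform bins per
  dimension, normalized to proportions.

The variance of an exemplar set in either space is the sum of the eigenvalues
of the (population, 1/n) covariance matrix of its feature vectors, which
equals the mean squared Euclidean distance of the vectors from their mean.
"""

from __future__ import annotations

from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from PIL import Image
from skimage.color import rgb2hsv
from skimage.transform import resize

#: (rows, cols) every image is brought to before feature extraction.
ANALYSIS_SHAPE = (450, 600)

KERNEL_SIZE = 8
N_ORIENTATIONS = 8
N_FREQUENCIES = 8
#: Wavelengths in pixels, geometrically spaced so every cycle fits the kernel.
WAVELENGTHS = tuple(float(w) for w in np.geomspace(2.0, 8.0, N_FREQUENCIES))
ORIENTATIONS = tuple(k * np.pi / N_ORIENTATIONS for k in range(N_ORIENTATIONS))

# Grayscale luminance weights, fixed for bit-reproducibility.
_LUMA = np.array([0.299, 0.587, 0.114])


def _as_float_rgb(image) -> np.ndarray:
    """Coerce a PIL image / array to float64 RGB in [0, 1]."""
    if isinstance(image, Image.Image):
        image = np.asarray(image.convert("RGB"))
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[-1] not in (3, 4):
        raise ValueError(f"expected an RGB image, got array of shape {arr.shape}")
    arr = arr[..., :3]
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    arr = arr.astype(float)
    if arr.max() > 1.0 + 1e-9:
        arr = arr / 255.0
    return np.clip(arr, 0.0, 1.0)


def _to_analysis_gray(image) -> np.ndarray:
    rgb = _as_float_rgb(image)
    gray = rgb @ _LUMA
    if gray.shape != ANALYSIS_SHAPE:
        gray = resize(gray, ANALYSIS_SHAPE, anti_aliasing=True, preserve_range=True)
    return gray


@lru_cache(maxsize=1)
def gabor_bank() -> np.ndarray:
    """The 64 Gabor kernels as an array of shape (64, 8, 8).

    Kernels are even-symmetric (cosine phase) Gaussian-windowed gratings at 8
    orientations (k*pi/8) and 8 wavelengths (geometric from 2 to 8 px), mean
    subtracted so they are DC-free, then L2-normalized.  Ordering is
    orientation-major: index = orientation * 8 + frequency.
    """
    half = (KERNEL_SIZE - 1) / 2.0
    coords = np.arange(KERNEL_SIZE) - half
    y, x = np.meshgrid(coords, coords, indexing="ij")
    sigma = KERNEL_SIZE / 4.0
    envelope = np.exp(-(x**2 + y**2) / (2.0 * sigma**2))
    kernels = np.empty((N_ORIENTATIONS * N_FREQUENCIES, KERNEL_SIZE, KERNEL_SIZE))
    for oi, theta in enumerate(ORIENTATIONS):
        u = x * np.cos(theta) + y * np.sin(theta)
        for fi, lam in enumerate(WAVELENGTHS):
            k = envelope * np.cos(2.0 * np.pi * u / lam)
            k = k - k.mean()  # DC-free: constant input -> zero response
            k = k / np.linalg.norm(k)
            kernels[oi * N_FREQUENCIES + fi] = k
    return kernels


def gabor_form_features(image) -> np.ndarray:
    """64-element form descriptor: per-pixel Gabor magnitudes averaged over space.

    The image is converted to grayscale, resized to 600x450, and correlated
    with each kernel at every pixel location (edge-replicated borders, so a
    constant image yields an exactly zero vector).  The per-pixel absolute
    responses are averaged over all 600x450 locations.
    """
    gray = _to_analysis_gray(image)
    pad_before = (KERNEL_SIZE - 1) // 2
    pad_after = KERNEL_SIZE - 1 - pad_before
    padded = np.pad(gray, ((pad_before, pad_after), (pad_before, pad_after)), mode="edge")
    # kernels are DC-free, so removing the global mean changes nothing analytically
    # but keeps the float32 matmul exact on constant images
    padded = padded - padded.mean()
    patches = sliding_window_view(padded, (KERNEL_SIZE, KERNEL_SIZE))
    flat = patches.reshape(-1, KERNEL_SIZE * KERNEL_SIZE).astype(np.float32)
    kernels = gabor_bank().reshape(len(gabor_bank()), -1).astype(np.float32).T
    responses = np.abs(flat @ kernels)  # (n_pixels, 64)
    return responses.mean(axis=0).astype(float)


def color_histogram(image) -> np.ndarray:
    """64-element color descriptor: 8x8 hue x saturation histogram, sum 1.

    Hue and saturation each lie in [0, 1] and are binned uniformly into 8
    bins; achromatic pixels (saturation 0) land in hue bin 0 by the hexcone
    convention.  The flattened ordering is hue-major.
    """
    rgb = _as_float_rgb(image)
    if rgb.shape[:2] != ANALYSIS_SHAPE:
        rgb = np.clip(resize(rgb, ANALYSIS_SHAPE + (3,), anti_aliasing=True, preserve_range=True), 0.0, 1.0)
    hsv = rgb2hsv(rgb)
    hue = hsv[..., 0].ravel()
    sat = hsv[..., 1].ravel()
    counts, _, _ = np.histogram2d(hue, sat, bins=8, range=[[0.0, 1.0], [0.0, 1.0]])
    return (counts / counts.sum()).ravel()


def feature_matrix(images: Iterable, space: str = "form") -> np.ndarray:
    """Stack per-image feature vectors into an (n_images, 64) matrix."""
    if space == "form":
        fn = gabor_form_features
    elif space == "color":
        fn = color_histogram
    else:
        raise ValueError(f"space must be 'form' or 'color', got {space!r}")
    rows = [fn(img) for img in images]
    if not rows:
        raise ValueError("empty image set")
    return np.vstack(rows)


def feature_variance(features: np.ndarray) -> float:
    """Total variance of a feature-vector set: eigenvalue sum of its covariance.

    Computed by eigendecomposition of the 1/n (population) covariance matrix of
    the rows; by the trace identity this equals the mean squared Euclidean
    distance of the rows from their mean vector.
    """
    F = np.asarray(features, dtype=float)
    if F.ndim != 2:
        raise ValueError("features must be a 2-D (n_images, n_features) matrix")
    if F.shape[0] < 2:
        raise ValueError("need at least 2 images to define a variance")
    cov = np.cov(F, rowvar=False, bias=True)
    cov = np.atleast_2d(cov)
    eigvals = np.linalg.eigvalsh(cov)
    return float(eigvals.sum())


def average_image(images: Sequence) -> np.ndarray:
    """Pixel-wise arithmetic mean of a set of same-sized RGB images (float64)."""
    arrays = [np.asarray(img, dtype=float) for img in images]
    if not arrays:
        raise ValueError("empty image set")
    shape = arrays[0].shape
    for i, a in enumerate(arrays):
        if a.shape != shape:
            raise ValueError(f"image {i} has shape {a.shape}, expected {shape}")
    return np.mean(arrays, axis=0)


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG file as a uint8 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))
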