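"""Patch features used by the classical nucleus-probability classifier.

The classifier must answer one question per 80x80 tile: is there a nucleus
at the tile centre?  The informative evidence is local colour (hematoxylin
vs DAB optical density), darkness, and edge structure near the centre, so a
tile is summarised by windowed moments of four per-pixel channels —
hematoxylin OD, DAB OD, brightness and Sobel gradient magnitude — over a
small (20 px) and a large (40 px) centre-anchored window.

Two equivalent evaluation paths are provided: per-patch (for training on
sampled tiles) and whole-image (separable uniform filters sampled at grid
anchors, for fast probability maps).  They agree to floating precision
because both windows sit strictly inside an 80 px tile, where the Sobel
operator and the box filters see identical neighbourhoods.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.filters import sobel

from ..stains import brightness, stain_concentrations

__all__ = [
    "N_FEATURES",
    "channel_maps",
    "feature_maps",
    "features_at",
    "featurize_patches",
]

SMALL_WINDOW = 20
LARGE_WINDOW = 40
_N_CHANNELS = 4
#: per channel: small-window mean, large-window mean, small-window std
N_FEATURES = _N_CHANNELS * 3


def channel_maps(image: np.ndarray) -> np.ndarray:
    """Stack of per-pixel channels: (hema OD, DAB OD, brightness/255, |grad|)."""
    conc = stain_concentrations(image)
    bright = brightness(image) / 255.0
    grad = sobel(bright)
    return np.stack([conc[..., 0], conc[..., 1], bright, grad], axis=-1)


def _box(x: np.ndarray, size: int) -> np.ndarray:
    return uniform_filter(x, size=size, mode="reflect")


def feature_maps(image: np.ndarray) -> np.ndarray:
    """(H, W, 12) feature image; position (r, c) describes the tile centred there."""
    channels = channel_maps(image)
    feats = []
    for k in range(_N_CHANNELS):
        x = channels[..., k]
        m_small = _box(x, SMALL_WINDOW)
        m_large = _box(x, LARGE_WINDOW)
        m2_small = _box(x * x, SMALL_WINDOW)
        sd_small = np.sqrt(np.clip(m2_small - m_small**2, 0.0, None))
        feats.extend([m_small, m_large, sd_small])
    return np.stack(feats, axis=-1)


def features_at(image: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Feature vectors for tiles centred at integer pixel ``centers`` (n, 2)."""
    fmaps = feature_maps(image)
    centers = np.asarray(centers, dtype=int)
    return fmaps[centers[:, 0], centers[:, 1], :]


def featurize_patches(patches: np.ndarray) -> np.ndarray:
    """Feature vectors for a batch of (n, w, w, 3) RGB patches.

    Windows are anchored at the patch centre ``w // 2`` and match the
    whole-image path exactly for ``w >= 2 * LARGE_WINDOW``.
    """
    patches = np.asarray(patches)
    if patches.ndim == 3:
        patches = patches[None]
    w = patches.shape[1]
    if w < 2 * LARGE_WINDOW:
        raise ValueError(f"patch side {w} too small; need >= {2 * LARGE_WINDOW}")
    center = w // 2

    def _sl(size: int) -> slice:
        return slice(center - size // 2, center + size - size // 2)

    out = np.empty((patches.shape[0], N_FEATURES), dtype=np.float64)
    for i, patch in enumerate(patches):
        channels = channel_maps(patch)
        cols = []
        for k in range(_N_CHANNELS):
            x = channels[..., k]
            small = x[_sl(SMALL_WINDOW), _sl(SMALL_WINDOW)]
            large = x[_sl(LARGE_WINDOW), _sl(LARGE_WINDOW)]
            cols.extend([small.mean(), large.mean(), small.std()])
        out[i] = cols
    return out
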