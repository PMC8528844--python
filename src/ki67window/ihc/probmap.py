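"""Nucleus probability map at stride resolution, and its Gaussian smoothing.

One probability per grid anchor: "is there a nucleus at this window's
centre?".  Smoothing the map with a small Gaussian turns isolated
high-probability cells into blob-shaped modes (the *nucleus map*) from
which peaks and contours are extracted downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .classifier import PatchClassifier
from .features import features_at
from .patches import PatchGrid

__all__ = ["ProbabilityMap", "compute_probability_map", "smooth_to_nucleus_map"]


@dataclass
class ProbabilityMap:
    """Grid of per-anchor probabilities plus the geometry to map them back."""

    values: np.ndarray
    grid: PatchGrid
    image_shape: tuple[int, int]
    #: image-pixel coordinate of grid cell (0, 0)'s window centre
    origin_px: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.origin_px is None:
            c = self.grid.window_px // 2
            self.origin_px = (float(c), float(c))

    def grid_to_image(self, points: np.ndarray) -> np.ndarray:
        """Map (row, col) grid coordinates to image-pixel coordinates."""
        pts = np.asarray(points, dtype=np.float64)
        return pts * self.grid.stride_px + np.asarray(self.origin_px)


def compute_probability_map(
    image: np.ndarray, classifier: PatchClassifier, grid: PatchGrid | None = None
) -> ProbabilityMap:
    """Classify every grid tile of ``image`` into a probability map.

    Map dimensions follow ``floor((dim - window) / stride) + 1`` per axis.
    Uses the whole-image feature path, which matches per-patch featurisation
    to floating precision.
    """
    grid = grid or PatchGrid()
    nr, nc = grid.n_anchors(image.shape[:2])
    centers = grid.centers(image.shape[:2])
    probs = classifier.predict_probability_features(features_at(image, centers))
    return ProbabilityMap(values=probs.reshape(nr, nc), grid=grid, image_shape=image.shape[:2])


def smooth_to_nucleus_map(pmap: ProbabilityMap, sigma: float) -> ProbabilityMap:
    """Gaussian-filter the probability map (grid units, reflect boundary)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    smoothed = gaussian_filter(pmap.values, sigma=sigma, mode="reflect")
    return replace(pmap, values=smoothed)
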