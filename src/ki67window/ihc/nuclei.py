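"""Nucleus calls: peak extraction from the nucleus map and positivity calling.

Detection finds local maxima of the smoothed nucleus map above a
probability threshold, non-maximum-suppressed at a minimum separation.
Each peak is expanded to a contour by tracing, along radial rays, where the
map falls to a fixed fraction of the peak value (clipped to a maximum
radius) — a radial half-peak level set.  Positivity is then decided inside
the contour from colour-deconvolved DAB optical density and brightness:
a nucleus is Ki67-positive when it carries enough DAB chromogen *and* is
dark enough not to be unstained bright debris.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.draw import polygon as draw_polygon
from skimage.feature import peak_local_max

from ..stains import brightness, stain_concentrations
from .probmap import ProbabilityMap

__all__ = ["NucleusCall", "extract_nuclei", "classify_positivity"]

_N_RAYS = 16
_RAY_STEP_GRID = 0.25
_MIN_CONTOUR_AREA_PX = 3


@dataclass
class NucleusCall:
    """One detected nucleus in image-pixel coordinates."""

    center_row: float
    center_col: float
    contour: np.ndarray  # (m, 2) closed polygon, image px
    peak_value: float
    mean_dab_od: float | None = None
    mean_brightness: float | None = None
    positive: bool | None = None
    valid: bool = True


def _radial_radius_grid(
    values: np.ndarray, peak: tuple[int, int], level: float, max_radius_grid: float
) -> float:
    """Mean radius (grid units) where the map drops below ``level``."""
    angles = np.linspace(0.0, 2 * np.pi, _N_RAYS, endpoint=False)
    steps = np.arange(_RAY_STEP_GRID, max_radius_grid + _RAY_STEP_GRID, _RAY_STEP_GRID)
    rr = peak[0] + np.outer(steps, np.sin(angles))
    cc = peak[1] + np.outer(steps, np.cos(angles))
    sampled = map_coordinates(values, [rr, cc], order=1, mode="nearest")
    below = sampled < level
    first = np.argmax(below, axis=0).astype(float) * _RAY_STEP_GRID
    first[~below.any(axis=0)] = max_radius_grid
    # argmax returns 0 both for "below at first step" and "never below";
    # the latter was fixed above, the former means a sub-step radius
    first[first == 0.0] = _RAY_STEP_GRID / 2
    return float(first.mean())


def _circle_polygon(center: tuple[float, float], radius: float, n: int = 24) -> np.ndarray:
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.stack(
        [center[0] + radius * np.sin(t), center[1] + radius * np.cos(t)], axis=1
    )


def extract_nuclei(
    nucleus_map: ProbabilityMap,
    detection_threshold: float = 0.5,
    min_separation_px: float = 14.0,
    contour_level: float = 0.5,
    max_radius_px: float = 14.0,
) -> list[NucleusCall]:
    """Detect nuclei on a smoothed map; contours but no positivity yet.

    Returns calls sorted by (row, col); an empty list is a valid outcome.
    """
    if detection_threshold <= 0 or min_separation_px <= 0:
        raise ValueError("thresholds must be positive")
    stride = nucleus_map.grid.stride_px
    min_dist_grid = max(1, int(round(min_separation_px / stride)))
    peaks = peak_local_max(
        nucleus_map.values,
        min_distance=min_dist_grid,
        threshold_abs=detection_threshold,
        exclude_border=False,
    )
    calls: list[NucleusCall] = []
    for pr, pc in peaks:
        peak_val = float(nucleus_map.values[pr, pc])
        radius_grid = _radial_radius_grid(
            nucleus_map.values,
            (pr, pc),
            contour_level * peak_val,
            max_radius_px / stride,
        )
        center = nucleus_map.grid_to_image(np.array([pr, pc], dtype=float))
        radius_px = min(radius_grid * stride, max_radius_px)
        contour = _circle_polygon((center[0], center[1]), radius_px)
        calls.append(
            NucleusCall(
                center_row=float(center[0]),
                center_col=float(center[1]),
                contour=contour,
                peak_value=peak_val,
            )
        )
    calls.sort(key=lambda c: (c.center_row, c.center_col))
    return calls


def classify_positivity(
    image: np.ndarray,
    call: NucleusCall,
    dab_od_threshold: float = 0.15,
    brightness_threshold: float = 230.0,
    stain_maps: np.ndarray | None = None,
    brightness_map: np.ndarray | None = None,
) -> NucleusCall:
    """Set the positivity label of one nucleus call in place (and return it).

    ``stain_maps``/``brightness_map`` may be passed pre-computed when calling
    on many nuclei of one image.  Contours with fewer than 3 in-image pixels
    are flagged invalid and excluded from counting.
    """
    if stain_maps is None:
        stain_maps = stain_concentrations(image)
    if brightness_map is None:
        brightness_map = brightness(image)
    shape = image.shape[:2]
    rr, cc = draw_polygon(call.contour[:, 0], call.contour[:, 1], shape=shape)
    if len(rr) < _MIN_CONTOUR_AREA_PX:
        call.valid = False
        call.positive = None
        return call
    call.mean_dab_od = float(stain_maps[rr, cc, 1].mean())
    call.mean_brightness = float(brightness_map[rr, cc].mean())
    call.positive = bool(
        call.mean_dab_od > dab_od_threshold
        and call.mean_brightness < brightness_threshold
    )
    return call
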