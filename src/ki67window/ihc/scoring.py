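"""ROI-level Ki67 scoring: the full chain from pixels to a proliferation index.

``score_roi`` runs classification -> probability map -> Gaussian nucleus map
-> peak/contour extraction -> per-nucleus positivity, restricted to a
half-open ROI rectangle, and reports (total nuclei, positive nuclei,
index %).  ``find_hotspot`` slides a fixed-area ROI over the slide and picks
the one with the highest index among ROIs holding at least ``min_cells``
nuclei, emulating a pathologist's 1 mm^2 hotspot protocol.

Images are reflect-padded by half a window before tiling so that grid
centres cover the full ROI; probability-map dimensions for an *unpadded*
image still follow the stated floor formula.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ..stains import brightness, stain_concentrations
from .classifier import PatchClassifier
from .nuclei import NucleusCall, classify_positivity, extract_nuclei
from .patches import PatchGrid
from .probmap import ProbabilityMap, compute_probability_map, smooth_to_nucleus_map

__all__ = ["PipelineParams", "Ki67Score", "detect_and_classify", "score_roi", "find_hotspot"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineParams:
    """All tunables of the scoring chain (0-based px coordinates throughout).

    ``sigma_grid`` defaults to ``nucleus_radius_px / (2 * stride_px)`` —
    roughly half the expected blob width on the stride grid.  The positivity
    thresholds were calibrated once on a held-out synthetic calibration
    slide and frozen here.
    """

    window_px: int = 80
    stride_px: int = 10
    nucleus_radius_px: float = 8.0
    sigma_grid: float | None = None
    detection_threshold: float = 0.3
    min_separation_px: float = 14.0
    contour_level: float = 0.5
    max_radius_px: float = 14.0
    dab_od_threshold: float = 0.15
    brightness_threshold: float = 230.0
    microns_per_pixel: float = 0.5
    min_cells: int = 1000

    @property
    def grid(self) -> PatchGrid:
        return PatchGrid(window_px=self.window_px, stride_px=self.stride_px)

    @property
    def sigma(self) -> float:
        if self.sigma_grid is not None:
            return self.sigma_grid
        return self.nucleus_radius_px / (2.0 * self.stride_px)

    def validate(self) -> list[str]:
        problems = []
        if self.stride_px > self.window_px:
            problems.append(
                "stride_px > window_px leaves pixels unexamined (warning)"
            )
        if not 0 < self.detection_threshold < 1:
            problems.append("detection_threshold must lie in (0, 1)")
        if self.contour_level <= 0 or self.contour_level >= 1:
            problems.append("contour_level must lie in (0, 1)")
        if self.microns_per_pixel <= 0:
            problems.append("microns_per_pixel must be positive")
        if self.min_cells < 1:
            problems.append("min_cells must be >= 1")
        return problems


@dataclass
class Ki67Score:
    """Ki67 proliferation index for one ROI."""

    area_mm2: float
    n_total: int
    n_positive: int
    defined: bool = True

    @property
    def n_negative(self) -> int:
        return self.n_total - self.n_positive

    @property
    def index(self) -> float:
        if not self.defined or self.n_total == 0:
            return float("nan")
        return 100.0 * self.n_positive / self.n_total

    def as_dict(self) -> dict:
        return {
            "area_mm2": self.area_mm2,
            "n_total": self.n_total,
            "n_positive": self.n_positive,
            "index": self.index,
            "defined": self.defined,
        }


def detect_and_classify(
    image: np.ndarray, classifier: PatchClassifier, params: PipelineParams
) -> list[NucleusCall]:
    """Run the full chain over an image; calls are in image-pixel coordinates.

    The image is reflect-padded by ``window // 2`` so windows centred near
    the borders exist; phantom reflections resolve to the same in-image
    nucleus within the matching tolerance of the stride.
    """
    pad = params.window_px // 2
    padded = np.pad(image, ((pad, pad), (pad, pad), (0, 0)), mode="reflect")
    pmap = compute_probability_map(padded, classifier, params.grid)
    # window centres of the padded image, expressed in original coordinates
    pmap = ProbabilityMap(
        values=pmap.values,
        grid=pmap.grid,
        image_shape=image.shape[:2],
        origin_px=(0.0, 0.0),
    )
    nmap = smooth_to_nucleus_map(pmap, params.sigma)
    calls = extract_nuclei(
        nmap,
        detection_threshold=params.detection_threshold,
        min_separation_px=params.min_separation_px,
        contour_level=params.contour_level,
        max_radius_px=params.max_radius_px,
    )
    h, w = image.shape[:2]
    calls = [c for c in calls if 0 <= c.center_row < h and 0 <= c.center_col < w]
    stains = stain_concentrations(image)
    bright = brightness(image)
    for call in calls:
        classify_positivity(
            image,
            call,
            dab_od_threshold=params.dab_od_threshold,
            brightness_threshold=params.brightness_threshold,
            stain_maps=stains,
            brightness_map=bright,
        )
    return calls


def _roi_area_mm2(roi: tuple[int, int, int, int], mpp: float) -> float:
    r0, c0, r1, c1 = roi
    return max(r1 - r0, 0) * max(c1 - c0, 0) * (mpp / 1000.0) ** 2


def _count_in_roi(
    calls: list[NucleusCall], roi: tuple[int, int, int, int]
) -> tuple[int, int]:
    r0, c0, r1, c1 = roi
    total = pos = 0
    for c in calls:
        if c.valid and r0 <= c.center_row < r1 and c0 <= c.center_col < c1:
            total += 1
            pos += int(bool(c.positive))
    return total, pos


def score_roi(
    slide,
    roi: tuple[int, int, int, int],
    classifier: PatchClassifier,
    params: PipelineParams,
    calls: list[NucleusCall] | None = None,
) -> Ki67Score:
    """Score a half-open ROI rectangle ``(r0, c0, r1, c1)`` of a slide.

    Only calls whose centres lie inside the ROI are counted.  An ROI with no
    detected nuclei yields a score flagged undefined, never 0.  Pre-computed
    whole-image ``calls`` may be passed to amortise detection.
    """
    image = slide.image
    h, w = image.shape[:2]
    r0, c0, r1, c1 = roi
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"ROI {roi} not inside image of shape {(h, w)}")
    if calls is None:
        margin = params.window_px
        cr0, cc0 = max(r0 - margin, 0), max(c0 - margin, 0)
        cr1, cc1 = min(r1 + margin, h), min(c1 + margin, w)
        crop = image[cr0:cr1, cc0:cc1]
        crop_calls = detect_and_classify(crop, classifier, params)
        for c in crop_calls:
            c.center_row += cr0
            c.center_col += cc0
        calls = crop_calls
    n_total, n_positive = _count_in_roi(calls, roi)
    area = _roi_area_mm2(roi, params.microns_per_pixel)
    if n_total == 0:
        logger.info("ROI %s contains no detected nuclei; score undefined", roi)
        return Ki67Score(area_mm2=area, n_total=0, n_positive=0, defined=False)
    logger.info("ROI %s: %d nuclei counted, %d positive", roi, n_total, n_positive)
    return Ki67Score(area_mm2=area, n_total=n_total, n_positive=n_positive)


def find_hotspot(
    slide,
    classifier: PatchClassifier,
    params: PipelineParams,
    roi_area_mm2: float = 1.0,
    coarse_stride_px: int | None = None,
    calls: list[NucleusCall] | None = None,
) -> tuple[int, int, int, int]:
    """Locate the square ROI of the given area with the highest Ki67 index.

    Candidate ROIs slide at a coarse stride; only ROIs with at least
    ``params.min_cells`` counted nuclei qualify.  Ties prefer more nuclei,
    then the top-left position.
    """
    image = slide.image
    h, w = image.shape[:2]
    side = int(round(np.sqrt(roi_area_mm2) * 1000.0 / params.microns_per_pixel))
    if side > h or side > w:
        raise ValueError(
            f"ROI side {side} px exceeds image {h}x{w}; reduce roi_area_mm2"
        )
    if calls is None:
        calls = detect_and_classify(image, classifier, params)
    stride = coarse_stride_px or max(side // 8, 1)
    best = None
    for r0 in list(range(0, h - side, stride)) + [h - side]:
        for c0 in list(range(0, w - side, stride)) + [w - side]:
            roi = (r0, c0, r0 + side, c0 + side)
            n_total, n_pos = _count_in_roi(calls, roi)
            if n_total < params.min_cells:
                continue
            index = 100.0 * n_pos / n_total
            key = (index, n_total, -r0, -c0)
            if best is None or key > best[0]:
                best = (key, roi)
    if best is None:
        raise ValueError(
            f"no ROI of {roi_area_mm2} mm^2 reaches min_cells={params.min_cells}; "
            "consider lowering min_cells"
        )
    return best[1]
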