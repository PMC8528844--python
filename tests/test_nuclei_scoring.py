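"""Nucleus detection, positivity calling, and ROI scoring properties."""

import dataclasses

import numpy as np
import pytest

from ki67window.evaluation import detection_metrics
from ki67window.ihc.nuclei import classify_positivity, extract_nuclei
from ki67window.ihc.probmap import ProbabilityMap
from ki67window.ihc.patches import PatchGrid
from ki67window.ihc.scoring import (
    PipelineParams,
    detect_and_classify,
    find_hotspot,
    score_roi,
)
from ki67window.simulate.slides import SlideSpec, generate_slide
from ki67window.stains import render_rgb


def _map_from(values):
    return ProbabilityMap(
        values=np.asarray(values, dtype=float),
        grid=PatchGrid(),
        image_shape=(480, 480),
        origin_px=(0.0, 0.0),
    )


class TestExtractNuclei:
    def test_blank_map_yields_no_calls(self):
        calls = extract_nuclei(_map_from(np.zeros((30, 30))))
        assert calls == []

    def test_two_blobs_closer_than_min_separation_give_one_call(self):
        values = np.zeros((30, 30))
        values[10, 10] = 0.9
        values[10, 11] = 0.8  # 10 px apart, below the 14 px separation
        calls = extract_nuclei(_map_from(values), min_separation_px=14)
        assert len(calls) == 1
        assert calls[0].center_col == pytest.approx(100.0)  # the higher peak

    def test_two_distant_blobs_give_two_calls(self):
        values = np.zeros((30, 30))
        values[10, 10] = 0.9
        values[10, 15] = 0.8
        calls = extract_nuclei(_map_from(values), min_separation_px=14)
        assert len(calls) == 2

    def test_center_inside_contour_and_contour_closed_polygon(self):
        values = np.zeros((30, 30))
        values[12, 12] = 1.0
        (call,) = extract_nuclei(_map_from(values))
        assert call.contour.shape[1] == 2
        radii = np.linalg.norm(
            call.contour - [call.center_row, call.center_col], axis=1
        )
        assert (radii > 0).all()  # centre strictly inside


class TestPositivity:
    def _nucleus_image(self, dab: float, hema: float):
        conc = np.zeros((60, 60, 3))
        rr, cc = np.mgrid[0:60, 0:60]
        blob = np.clip(1 - (((rr - 30) ** 2 + (cc - 30) ** 2) / 12**2), 0, None)
        conc[..., 0] = hema * blob
        conc[..., 1] = dab * blob
        return np.clip(
            np.rint(render_rgb(conc, (242.0, 241.0, 238.0))), 0, 255
        ).astype(np.uint8)

    def _call_at_center(self):
        values = np.zeros((6, 6))
        values[3, 3] = 1.0
        (call,) = extract_nuclei(
            ProbabilityMap(
                values=values, grid=PatchGrid(), image_shape=(60, 60),
                origin_px=(0.0, 0.0),
            )
        )
        return call

    def test_pure_dab_nucleus_positive(self):
        image = self._nucleus_image(dab=0.8, hema=0.0)
        call = classify_positivity(image, self._call_at_center())
        assert call.positive is True

    def test_pure_hematoxylin_nucleus_negative(self):
        image = self._nucleus_image(dab=0.0, hema=0.9)
        call = classify_positivity(image, self._call_at_center())
        assert call.positive is False
        assert call.mean_dab_od < 0.15

    def test_degenerate_contour_flagged_invalid(self):
        image = self._nucleus_image(dab=0.8, hema=0.0)
        call = self._call_at_center()
        call.contour = call.contour * 0.0  # collapses to a point
        call = classify_positivity(image, call)
        assert call.valid is False and call.positive is None


class TestDetectionQuality:
    def test_well_separated_nuclei_recall_precision_and_positivity(self, classifier):
        spec = SlideSpec(
            width_px=640, height_px=640, n_tumor_nuclei=200, n_stromal_nuclei=0,
            positive_fraction=0.3, seed=13,
        )
        m = detection_metrics(classifier, spec)
        assert m["recall"] >= 0.95
        assert m["precision"] >= 0.95
        assert m["positivity_accuracy"] >= 0.95


class TestScoreRoi:
    def test_blank_roi_flagged_undefined_not_zero(self, classifier, params):
        spec = SlideSpec(n_tumor_nuclei=0, n_stromal_nuclei=0, seed=3)
        slide, _ = generate_slide(spec)
        score = score_roi(slide, (0, 0, 200, 200), classifier, params)
        assert score.defined is False
        assert np.isnan(score.index)

    def test_recovers_30_percent_positivity_within_3_points(
        self, classifier, params, reference_slide
    ):
        slide, gt = reference_slide
        score = score_roi(slide, (0, 0, 480, 480), classifier, params)
        assert score.index == pytest.approx(30.0, abs=3.0)
        assert score.n_positive + score.n_negative == score.n_total

    def test_index_stable_under_roi_translation(self, classifier, params):
        slide, _ = generate_slide(
            SlideSpec(width_px=640, height_px=640, n_tumor_nuclei=220,
                      n_stromal_nuclei=0, positive_fraction=0.4, seed=19)
        )
        calls = detect_and_classify(slide.image, classifier, params)
        a = score_roi(slide, (0, 0, 560, 560), classifier, params, calls=calls)
        b = score_roi(slide, (80, 80, 640, 640), classifier, params, calls=calls)
        assert a.index == pytest.approx(b.index, abs=5.0)

    def test_roi_outside_image_rejected(self, classifier, params, reference_slide):
        slide, _ = reference_slide
        with pytest.raises(ValueError, match="ROI"):
            score_roi(slide, (0, 0, 481, 100), classifier, params)

    def test_monotone_in_positive_fraction_for_paired_seeds(
        self, classifier, params
    ):
        indices = []
        for frac in (0.1, 0.3, 0.5, 0.7):
            slide, _ = generate_slide(SlideSpec(positive_fraction=frac, seed=31))
            sc = score_roi(slide, (0, 0, 480, 480), classifier, params)
            indices.append(sc.index)
        assert indices == sorted(indices)

    def test_deterministic_scores(self, classifier, params, reference_slide):
        slide, _ = reference_slide
        a = score_roi(slide, (0, 0, 480, 480), classifier, params)
        b = score_roi(slide, (0, 0, 480, 480), classifier, params)
        assert (a.n_total, a.n_positive) == (b.n_total, b.n_positive)


@pytest.fixture(scope="module")
def small_roi_params():
    return PipelineParams(min_cells=20)


class TestHotspot:
    def test_finds_high_positivity_cluster(self, classifier, small_roi_params):
        """Two half-slides with different positivity: the hotspot must sit on
        the high side."""
        spec_hi = SlideSpec(width_px=480, height_px=240, n_tumor_nuclei=60,
                            n_stromal_nuclei=0, positive_fraction=0.8, seed=41)
        spec_lo = dataclasses.replace(spec_hi, positive_fraction=0.05, seed=42)
        hi, _ = generate_slide(spec_hi)
        lo, _ = generate_slide(spec_lo)
        image = np.concatenate([hi.image, lo.image], axis=0)
        slide = dataclasses.replace(hi, image=image)
        roi = find_hotspot(
            slide, classifier, small_roi_params,
            roi_area_mm2=(200 * 0.5 / 1000) ** 2,
        )
        r0, _, r1, _ = roi
        assert (r0 + r1) / 2 < 240  # centred in the high-positivity half

    def test_uniform_slide_hotspot_index_close_to_global(
        self, classifier, small_roi_params, reference_slide
    ):
        slide, _ = reference_slide
        calls = detect_and_classify(slide.image, classifier, small_roi_params)
        roi = find_hotspot(
            slide, classifier, small_roi_params,
            roi_area_mm2=(360 * 0.5 / 1000) ** 2, calls=calls,
        )
        hot = score_roi(slide, roi, classifier, small_roi_params, calls=calls)
        full = score_roi(slide, (0, 0, 480, 480), classifier, small_roi_params,
                         calls=calls)
        # a hotspot is by construction at least the global index, and on a
        # statistically uniform slide not far above it
        assert hot.index >= full.index - 1e-9
        assert hot.index - full.index <= 12.0

    def test_min_cells_unreachable_raises(self, classifier, reference_slide):
        slide, _ = reference_slide
        with pytest.raises(ValueError, match="min_cells"):
            find_hotspot(slide, classifier, PipelineParams(min_cells=10**6),
                         roi_area_mm2=0.01)

    def test_roi_larger_than_image_rejected(self, classifier, params,
                                            reference_slide):
        slide, _ = reference_slide
        with pytest.raises(ValueError, match="exceeds"):
            find_hotspot(slide, classifier, params, roi_area_mm2=1.0)
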