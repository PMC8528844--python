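"""Plain-format I/O: 8-bit RGB TIFF/PNG images and CSV nucleus tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .ihc.nuclei import NucleusCall
from .simulate.slides import GroundTruth, SlideImage

__all__ = ["write_image", "read_slide", "calls_to_frame", "write_calls_csv"]


def write_image(slide: SlideImage, path) -> None:
    """Write a slide as 8-bit RGB TIFF (with resolution tags) or PNG."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        px_per_cm = 10000.0 / slide.microns_per_pixel
        tifffile.imwrite(
            path,
            slide.image,
            photometric="rgb",
            resolution=(px_per_cm, px_per_cm),
            resolutionunit="CENTIMETER",
        )
    else:
        Image.fromarray(slide.image).save(path)


def read_slide(
    path, microns_per_pixel: float, ground_truth_csv=None
) -> SlideImage:
    """Read an RGB image file into a :class:`SlideImage`."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        image = tifffile.imread(path)
    else:
        image = np.asarray(Image.open(path).convert("RGB"))
    gt = GroundTruth.from_csv(ground_truth_csv) if ground_truth_csv else None
    return SlideImage(image=image, microns_per_pixel=microns_per_pixel, ground_truth=gt)


def calls_to_frame(calls: list[NucleusCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "center_row": [c.center_row for c in calls],
            "center_col": [c.center_col for c in calls],
            "dab_od": [c.mean_dab_od for c in calls],
            "brightness": [c.mean_brightness for c in calls],
            "positive": [c.positive for c in calls],
            "valid": [c.valid for c in calls],
        }
    )


def write_calls_csv(calls: list[NucleusCall], path) -> None:
    calls_to_frame(calls).to_csv(path, index=False)
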