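"""Sliding-window patch grid, patch extraction and training-set sampling.

The scoring pipeline slides an 80x80 px window with a 10 px stride over the
stained image; the same grid serves both classifier training (sampled,
labelled tiles) and inference (the full probability map), so the anchor
bookkeeping lives here once.  Anchors are 0-based, row-major, top-left
corners of fully-contained windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import features_at

__all__ = [
    "PatchGrid",
    "PatchSample",
    "extract_patches",
    "training_split_counts",
    "sample_training_patches",
]


@dataclass(frozen=True)
class PatchGrid:
    """Sliding-window geometry: window side and stride, both in pixels."""

    window_px: int = 80
    stride_px: int = 10

    def __post_init__(self) -> None:
        if self.window_px <= 0 or self.stride_px <= 0:
            raise ValueError("window_px and stride_px must be positive")

    def n_anchors(self, image_shape: tuple[int, int]) -> tuple[int, int]:
        """Grid dimensions: ``floor((dim - window) / stride) + 1`` per axis."""
        h, w = image_shape[0], image_shape[1]
        if h < self.window_px or w < self.window_px:
            raise ValueError(
                f"image {h}x{w} smaller than the {self.window_px} px window"
            )
        return (
            (h - self.window_px) // self.stride_px + 1,
            (w - self.window_px) // self.stride_px + 1,
        )

    def anchors(self, image_shape: tuple[int, int]) -> np.ndarray:
        """(n, 2) array of top-left anchors in row-major order."""
        nr, nc = self.n_anchors(image_shape)
        rows = np.arange(nr) * self.stride_px
        cols = np.arange(nc) * self.stride_px
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        return np.stack([rr.ravel(), cc.ravel()], axis=1)

    def centers(self, image_shape: tuple[int, int]) -> np.ndarray:
        """Window-centre pixel for every anchor, row-major."""
        return self.anchors(image_shape) + self.window_px // 2


def extract_patches(image: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """All grid patches of ``image`` as an (n, window, window, channels) array.

    Row-major anchor order; raises if the image is smaller than the window.
    """
    nr, nc = grid.n_anchors(image.shape[:2])
    w, s = grid.window_px, grid.stride_px
    view = np.lib.stride_tricks.sliding_window_view(image, (w, w), axis=(0, 1))
    view = view[::s, ::s][:nr, :nc]
    # view axes: (nr, nc, channels, w, w) for RGB input
    if image.ndim == 3:
        patches = np.moveaxis(view, 2, -1)
    else:
        patches = view
    return patches.reshape(nr * nc, w, w, *image.shape[2:])


def training_split_counts(
    n_slides: int, per_slide: int, split_fraction: float
) -> dict[str, int]:
    """Exact patch bookkeeping for an n-slide sampling campaign.

    ``n_train`` is ``round(total * split_fraction)``; validation gets the
    remainder, so the two always sum to the total.
    """
    if per_slide < 1:
        raise ValueError("per_slide must be >= 1")
    if not 0.0 < split_fraction < 1.0:
        raise ValueError("split_fraction must lie strictly in (0, 1)")
    total = n_slides * per_slide
    n_train = int(round(total * split_fraction))
    return {"total": total, "n_train": n_train, "n_val": total - n_train}


@dataclass
class PatchSample:
    """Labelled, featurised patch sample with a frozen train/validation split."""

    features: np.ndarray
    labels: np.ndarray
    centers: np.ndarray
    slide_index: np.ndarray
    train_idx: np.ndarray
    val_idx: np.ndarray
    seed: int

    @property
    def n_train(self) -> int:
        return len(self.train_idx)

    @property
    def n_val(self) -> int:
        return len(self.val_idx)


def sample_training_patches(
    slides,
    per_slide: int,
    split_fraction: float = 0.8,
    seed: int = 0,
    grid: PatchGrid | None = None,
    label_radius_px: float = 7.5,
) -> PatchSample:
    """Sample labelled tiles from ground-truthed slides and split them.

    A tile is labelled positive when a *tumour* nucleus centre lies within
    ``label_radius_px`` of the tile centre; stromal nuclei and empty
    background are both negatives, mirroring a scorer that must treat stroma
    as noise.  Counts follow :func:`training_split_counts` exactly and the
    sampling is reproducible from ``seed``.
    """
    grid = grid or PatchGrid()
    rng = np.random.default_rng(seed)
    feats, labels, centers_all, slide_idx = [], [], [], []
    for si, (slide, gt) in enumerate(slides):
        image = slide.image
        centers = grid.centers(image.shape[:2])
        if per_slide > len(centers):
            raise ValueError(
                f"per_slide={per_slide} exceeds the {len(centers)} distinct "
                f"anchors available on slide {si}"
            )
        pick = rng.choice(len(centers), size=per_slide, replace=False)
        pick.sort()
        chosen = centers[pick]
        tumor = gt.table[gt.table["cell_class"] == "tumor"]
        if len(tumor):
            nuc = tumor[["center_row", "center_col"]].to_numpy()
            d2 = (
                (chosen[:, None, 0] - nuc[None, :, 0]) ** 2
                + (chosen[:, None, 1] - nuc[None, :, 1]) ** 2
            )
            lab = (d2.min(axis=1) <= label_radius_px**2).astype(int)
        else:
            lab = np.zeros(len(chosen), dtype=int)
        feats.append(features_at(image, chosen))
        labels.append(lab)
        centers_all.append(chosen)
        slide_idx.append(np.full(len(chosen), si))

    features = np.concatenate(feats)
    labels = np.concatenate(labels)
    counts = training_split_counts(len(feats), per_slide, split_fraction)
    order = rng.permutation(len(labels))
    train_idx = np.sort(order[: counts["n_train"]])
    val_idx = np.sort(order[counts["n_train"] :])
    return PatchSample(
        features=features,
        labels=labels,
        centers=np.concatenate(centers_all),
        slide_index=np.concatenate(slide_idx),
        train_idx=train_idx,
        val_idx=val_idx,
        seed=seed,
    )
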