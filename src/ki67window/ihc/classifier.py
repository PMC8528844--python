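"""Pluggable patch classifier for nucleus-at-centre probability.

The scoring chain only requires an object with ``predict_probability``; the
default backend is a deterministic regularised logistic regression on the
stain/brightness/gradient features of :mod:`ki67window.ihc.features`.  A
convolutional backend can be registered by callers that have one; none is
shipped, since the feature-based model is already near-ceiling on the
synthetic slides this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .features import featurize_patches
from .patches import PatchSample

__all__ = ["PatchClassifier", "train_patch_classifier"]


@dataclass
class PatchClassifier:
    """Trained tile classifier plus its training bookkeeping."""

    model: Pipeline
    backend: str
    n_train: int
    n_val: int
    seed: int
    val_accuracy: float | None = None
    metadata: dict = field(default_factory=dict)

    def predict_probability_features(self, features: np.ndarray) -> np.ndarray:
        """Nucleus probability for pre-computed feature vectors."""
        features = np.atleast_2d(np.asarray(features, dtype=np.float64))
        return self.model.predict_proba(features)[:, 1]

    def predict_probability(self, patches: np.ndarray) -> np.ndarray:
        """Nucleus-at-centre probability for raw RGB patches (n, w, w, 3)."""
        return self.predict_probability_features(featurize_patches(patches))


def train_patch_classifier(
    sample: PatchSample, backend: str = "classical", seed: int = 0
) -> PatchClassifier:
    """Fit the tile classifier and record held-out validation accuracy.

    Raises if the training split contains a single class; deterministic for
    a fixed sample and seed.
    """
    if backend != "classical":
        raise NotImplementedError(
            f"backend {backend!r} is not shipped; register a custom model or "
            "use backend='classical'"
        )
    x_train = sample.features[sample.train_idx]
    y_train = sample.labels[sample.train_idx]
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set contains a single class; cannot fit")
    model = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "logreg",
                LogisticRegression(C=1.0, max_iter=2000, random_state=seed),
            ),
        ]
    )
    model.fit(x_train, y_train)
    clf = PatchClassifier(
        model=model,
        backend=backend,
        n_train=sample.n_train,
        n_val=sample.n_val,
        seed=seed,
    )
    if sample.n_val:
        x_val = sample.features[sample.val_idx]
        y_val = sample.labels[sample.val_idx]
        pred = (clf.predict_probability_features(x_val) >= 0.5).astype(int)
        clf.val_accuracy = float((pred == y_val).mean())
    return clf
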