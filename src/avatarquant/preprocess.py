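"""Trainable pixel classification and autofluorescence removal.

Increased pigmentation of older embryos produces autofluorescent structures
that appear in both the tumor and GAM channels and masquerade as cells.  A
pixel classifier trained on sparse annotations of the four voxel classes
(tumor, gam, autofluorescence, background) identifies those voxels, which
are then set to zero before segmentation.

The classifier is a scikit-learn-style estimator: a random-forest ensemble
over a multiscale feature bank (Gaussian-smoothed intensity, gradient
magnitude, Laplacian of Gaussian at pixel scales {1, 2, 4} per channel) —
the default feature set of interactive pixel-classification tools.
"""

from __future__ import annotations

import pickle

import numpy as np
import scipy.ndimage as ndi
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .errors import DataError

#: fixed ordered class list; annotation volumes use these integer codes
CLASS_NAMES = ("background", "tumor", "gam", "autofluorescence")
CLASS_CODES = {name: i for i, name in enumerate(CLASS_NAMES)}


def compute_features(
    volume: np.ndarray, scales: tuple[float, ...] = (1.0, 2.0, 4.0)
) -> np.ndarray:
    """Multiscale per-voxel feature stack of one or more channels.

    ``volume`` is (Z, Y, X) or (C, Z, Y, X); the result is (n_features, Z,
    Y, X) with, per channel and scale: Gaussian smoothing, gradient
    magnitude of the smoothed volume, and Laplacian of Gaussian.
    """
    volume = np.asarray(volume, dtype=np.float32)
    if volume.ndim == 3:
        volume = volume[np.newaxis]
    if volume.ndim != 4:
        raise DataError("expected (Z,Y,X) or (C,Z,Y,X) input")
    feats = []
    for chan in volume:
        feats.append(chan)
        for s in scales:
            sm = ndi.gaussian_filter(chan, sigma=s)
            feats.append(sm)
            feats.append(ndi.gaussian_gradient_magnitude(chan, sigma=s))
            feats.append(ndi.gaussian_laplace(chan, sigma=s))
    return np.stack(feats)


class PixelClassifier(BaseEstimator):
    """Random-forest voxel classifier over a multiscale feature bank.

    A scikit-learn estimator (``fit``/``predict``, ``get_params``/
    ``set_params`` inherited); fitted state lives in trailing-underscore
    attributes.  Prediction assigns exactly one of the four classes to every
    voxel and is deterministic given the trained state.

    Parameters
    ----------
    scales
        Pixel scales of the Gaussian feature bank.
    n_estimators, max_depth
        Forest size and depth.
    max_train_per_class
        Annotated voxels are subsampled to at most this many per class.
    random_state
        Seed controlling subsampling and forest construction.
    """

    def __init__(
        self,
        scales: tuple[float, ...] = (1.0, 2.0, 4.0),
        n_estimators: int = 50,
        max_depth: int | None = 12,
        max_train_per_class: int = 10000,
        random_state: int = 0,
    ):
        self.scales = scales
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.max_train_per_class = max_train_per_class
        self.random_state = random_state

    def fit(self, volumes, annotations):
        """Train on annotated volumes.

        Parameters
        ----------
        volumes
            One volume or a list of volumes, each (Z,Y,X) or (C,Z,Y,X).
        annotations
            Matching (Z,Y,X) integer label volumes using the codes of
            :data:`CLASS_NAMES`; voxels with code -1 are unannotated.

        Raises
        ------
        DataError
            If any of the four classes has no annotated voxel (the absent
            classes are listed).
        """
        if isinstance(volumes, np.ndarray):
            volumes = [volumes]
            annotations = [annotations]
        X_parts, y_parts = [], []
        for vol, ann in zip(volumes, annotations):
            ann = np.asarray(ann)
            feats = compute_features(vol, self.scales)
            sel = ann >= 0
            X_parts.append(feats[:, sel].T)
            y_parts.append(ann[sel])
        X = np.concatenate(X_parts)
        y = np.concatenate(y_parts)
        present = set(np.unique(y))
        missing = [n for n, c in CLASS_CODES.items() if c not in present]
        if missing:
            raise DataError(
                "annotations missing class(es): " + ", ".join(missing)
            )
        rng = np.random.default_rng(self.random_state)
        keep = []
        for c in np.unique(y):
            idx = np.flatnonzero(y == c)
            if len(idx) > self.max_train_per_class:
                idx = rng.choice(idx, self.max_train_per_class, replace=False)
            keep.append(idx)
        keep = np.concatenate(keep)
        self.model_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            random_state=self.random_state,
            n_jobs=1,
        )
        self.model_.fit(X[keep], y[keep])
        self.training_accuracy_ = float(self.model_.score(X[keep], y[keep]))
        self.classes_ = CLASS_NAMES
        return self

    def predict(self, volume: np.ndarray) -> np.ndarray:
        """Per-voxel class codes for a (Z,Y,X) or (C,Z,Y,X) volume."""
        check_is_fitted(self, "model_")
        feats = compute_features(volume, self.scales)
        flat = feats.reshape(feats.shape[0], -1).T
        pred = self.model_.predict(flat)
        return pred.reshape(feats.shape[1:]).astype(np.uint8)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "PixelClassifier":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, cls):
            raise DataError(f"{path} does not contain a PixelClassifier")
        return obj


class OraclePixelClassifier:
    """Classifier backed by known ground-truth labels (testing/validation).

    Predicts the stored annotation volume regardless of input intensities;
    used to isolate downstream stages from classifier error.
    """

    def __init__(self, labels: np.ndarray):
        self.labels = np.asarray(labels, dtype=np.uint8)
        self.classes_ = CLASS_NAMES

    def predict(self, volume: np.ndarray) -> np.ndarray:
        shape = volume.shape[-3:]
        if self.labels.shape != shape:
            raise DataError("oracle labels do not match volume shape")
        return self.labels


def train_pixel_classifier(
    volumes, annotations, feature_scales=(1.0, 2.0, 4.0), seed: int = 0
) -> PixelClassifier:
    """Convenience wrapper: construct and fit a :class:`PixelClassifier`."""
    clf = PixelClassifier(scales=tuple(feature_scales), random_state=seed)
    return clf.fit(volumes, annotations)


def remove_autofluorescence(
    channel_volume: np.ndarray,
    classifier,
    feature_volume: np.ndarray | None = None,
) -> np.ndarray:
    """Zero out voxels the classifier calls autofluorescent.

    ``feature_volume`` (e.g. the multichannel stack the classifier was
    trained on) defaults to the channel itself.  Voxels of every other class
    are returned unchanged.
    """
    channel_volume = np.asarray(channel_volume)
    pred = classifier.predict(
        channel_volume if feature_volume is None else feature_volume
    )
    if pred.shape != channel_volume.shape:
        raise DataError("classifier prediction shape mismatch")
    out = channel_volume.copy()
    out[pred == CLASS_CODES["autofluorescence"]] = 0
    return out
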