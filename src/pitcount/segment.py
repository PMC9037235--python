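"""Trainable three-class pixel classification of DIC images.

A classical multi-scale filter bank (smoothed intensity, gradient
magnitude, Laplacian, Hessian eigenvalues, local variance at several
Gaussian scales) feeds a random-forest back end, in the ilastik/trainable-
WEKA tradition: the contract is simply pixel -> {background, cell, pit}.
A pretrained-CNN feature extractor would honour the same contract and is
an extension point, not a default.

:class:`PixelClassifier` is a scikit-learn estimator (``fit`` /
``predict`` / ``predict_proba``, ``get_params``) so it composes with
sklearn tooling; its ``fit`` consumes lists of images and label maps
rather than a flat design matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .types import CLASS_CODES, CLASS_NAMES, DICImage, LabelMap

__all__ = [
    "FeatureConfig",
    "PixelClassifier",
    "SegmentationScore",
    "compute_features",
    "feature_names",
    "train_classifier",
    "predict_labels",
    "evaluate_segmentation",
    "save_classifier",
    "load_classifier",
]

_KIND_ORDER = ("intensity", "gradient", "laplacian", "hessian_max", "hessian_min", "variance")


@dataclass(frozen=True)
class FeatureConfig:
    """Which filter responses, at which Gaussian scales, become features.

    Feature planes are ordered scale-major: all enabled kinds at the first
    scale, then the next scale, so prepending scales never reorders
    existing planes.  The Hessian contributes two planes per scale (larger
    and smaller eigenvalue).
    """

    scales_px: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)
    intensity: bool = True
    gradient: bool = True
    laplacian: bool = True
    hessian: bool = True
    local_variance: bool = True

    def __post_init__(self) -> None:
        if len(self.scales_px) < 1:
            raise ValueError("at least one scale is required")
        if any(s <= 0 for s in self.scales_px):
            raise ValueError("scales must be positive")
        if self.n_kinds < 2:
            raise ValueError("at least two feature kinds must be enabled")
        object.__setattr__(self, "scales_px", tuple(float(s) for s in self.scales_px))

    @property
    def kinds(self) -> tuple[str, ...]:
        kinds = []
        if self.intensity:
            kinds.append("intensity")
        if self.gradient:
            kinds.append("gradient")
        if self.laplacian:
            kinds.append("laplacian")
        if self.hessian:
            kinds.extend(["hessian_max", "hessian_min"])
        if self.local_variance:
            kinds.append("variance")
        return tuple(kinds)

    @property
    def n_kinds(self) -> int:
        n = sum([self.intensity, self.gradient, self.laplacian, self.local_variance])
        return n + (2 if self.hessian else 0)

    @property
    def n_planes(self) -> int:
        return self.n_kinds * len(self.scales_px)


def feature_names(config: FeatureConfig) -> list[str]:
    return [f"{kind}_s{s:g}" for s in config.scales_px for kind in config.kinds]


def compute_features(image: DICImage, config: FeatureConfig | None = None) -> np.ndarray:
    """Per-pixel feature stack, shape (H, W, n_planes), float32.

    Boundary handling is reflective, so features commute exactly with
    image mirroring (up to the mirrored shear axis of the input).
    """
    if config is None:
        config = FeatureConfig()
    img = np.asarray(image.intensity, dtype=np.float64)
    h, w = img.shape
    if max(config.scales_px) > min(h, w) / 2:
        raise ValueError(
            f"largest scale {max(config.scales_px):g} px exceeds half the "
            f"image size ({min(h, w)} px)"
        )
    planes: list[np.ndarray] = []
    img_sq = img * img
    for s in config.scales_px:
        smooth = ndimage.gaussian_filter(img, s, mode="reflect")
        if config.intensity:
            planes.append(smooth)
        if config.gradient:
            planes.append(ndimage.gaussian_gradient_magnitude(img, s, mode="reflect"))
        if config.laplacian:
            planes.append(ndimage.gaussian_laplace(img, s, mode="reflect"))
        if config.hessian:
            hrr = ndimage.gaussian_filter(img, s, order=(2, 0), mode="reflect")
            hcc = ndimage.gaussian_filter(img, s, order=(0, 2), mode="reflect")
            hrc = ndimage.gaussian_filter(img, s, order=(1, 1), mode="reflect")
            tr = 0.5 * (hrr + hcc)
            det = np.sqrt(np.maximum((0.5 * (hrr - hcc)) ** 2 + hrc**2, 0.0))
            planes.append(tr + det)
            planes.append(tr - det)
        if config.local_variance:
            m = smooth
            m2 = ndimage.gaussian_filter(img_sq, s, mode="reflect")
            planes.append(np.maximum(m2 - m * m, 0.0))
    return np.stack(planes, axis=-1).astype(np.float32)


class PixelClassifier(ClassifierMixin, BaseEstimator):
    """Filter-bank + random-forest pixel classifier for DIC scenes.

    Parameters
    ----------
    n_trees : int
        Forest size.
    max_depth : int or None
        Tree depth cap; bounded depth keeps training predictable on
        large pixel samples.
    max_pixels_per_class : int
        Stratified per-class, per-image cap on training pixels; the
        simple, exactly reproducible answer to class imbalance (pit
        pixels are rare).
    feature_config : FeatureConfig or None
        Filter bank; None means the default bank.
    holdout_fraction : float
        Fraction of sampled pixels (per class) held out to report
        per-class accuracy in the fitted metadata.
    random_state : int
        Seed for pixel sampling and forest training; fixed seed and data
        give bit-identical predictions.

    Attributes
    ----------
    forest_ : RandomForestClassifier
    feature_config_ : FeatureConfig
    classes_ : ndarray — fixed code order [0, 1, 2]
    holdout_accuracy_ : dict — per-class held-out recall
    n_training_pixels_ : dict — pixels used per class
    """

    def __init__(
        self,
        n_trees: int = 100,
        max_depth: int | None = 20,
        max_pixels_per_class: int = 10_000,
        feature_config: FeatureConfig | None = None,
        holdout_fraction: float = 0.2,
        random_state: int = 0,
    ):
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.max_pixels_per_class = max_pixels_per_class
        self.feature_config = feature_config
        self.holdout_fraction = holdout_fraction
        self.random_state = random_state

    def fit(self, X: list[DICImage], y: list[LabelMap]) -> "PixelClassifier":
        """Fit on training images and their three-class label maps."""
        if len(X) < 1 or len(X) != len(y):
            raise ValueError("need >=1 training image with one label map each")
        cfg = self.feature_config if self.feature_config is not None else FeatureConfig()
        present = set()
        for lm in y:
            present.update(int(c) for c in np.unique(lm.codes))
        for code in CLASS_CODES:
            if code not in present:
                raise ValueError(
                    f"class {CLASS_NAMES[code]} absent from all training label maps"
                )
        rng = np.random.default_rng(self.random_state)
        feats, labels = [], []
        for img, lm in zip(X, y):
            if img.shape != lm.shape:
                raise ValueError("image and label map geometry differ")
            stack = compute_features(img, cfg).reshape(-1, cfg.n_planes)
            flat = lm.codes.ravel()
            for code in CLASS_CODES:
                idx = np.flatnonzero(flat == code)
                if idx.size > self.max_pixels_per_class:
                    idx = rng.choice(idx, self.max_pixels_per_class, replace=False)
                feats.append(stack[idx])
                labels.append(np.full(idx.size, code, dtype=np.int64))
        Xmat = np.concatenate(feats)
        yvec = np.concatenate(labels)

        # stratified holdout for the per-class accuracy metadata
        train_idx, hold_idx = [], []
        for code in CLASS_CODES:
            idx = np.flatnonzero(yvec == code)
            idx = rng.permutation(idx)
            n_hold = max(int(round(self.holdout_fraction * idx.size)), 1)
            n_hold = min(n_hold, idx.size - 1) if idx.size > 1 else 0
            hold_idx.append(idx[:n_hold])
            train_idx.append(idx[n_hold:])
        train_idx = np.concatenate(train_idx)
        hold_idx = np.concatenate(hold_idx)

        forest = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_depth=self.max_depth,
            random_state=self.random_state,
            n_jobs=1,
        )
        forest.fit(Xmat[train_idx], yvec[train_idx])

        self.forest_ = forest
        self.feature_config_ = cfg
        self.classes_ = np.array(CLASS_CODES)
        self.n_training_pixels_ = {
            CLASS_NAMES[c]: int((yvec[train_idx] == c).sum()) for c in CLASS_CODES
        }
        acc: dict[str, float] = {}
        if hold_idx.size:
            pred = forest.predict(Xmat[hold_idx])
            truth = yvec[hold_idx]
            for code in CLASS_CODES:
                m = truth == code
                acc[CLASS_NAMES[code]] = float((pred[m] == code).mean()) if m.any() else float("nan")
        self.holdout_accuracy_ = acc
        return self

    def predict_proba(self, image: DICImage) -> np.ndarray:
        """Per-class posterior grid, shape (H, W, 3) in fixed class order."""
        check_is_fitted(self, "forest_")
        stack = compute_features(image, self.feature_config_)
        h, w, p = stack.shape
        proba = self.forest_.predict_proba(stack.reshape(-1, p))
        # forest classes_ are sorted codes [0,1,2]; keep that fixed order
        return proba.reshape(h, w, 3)

    def predict(self, image: DICImage, return_posteriors: bool = False) -> LabelMap:
        """Argmax-of-posterior label map; ties break toward the lower code
        (background < cell < pit)."""
        proba = self.predict_proba(image)
        codes = np.argmax(proba, axis=-1).astype(np.uint8)
        return LabelMap(codes, posteriors=proba if return_posteriors else None)


@dataclass
class SegmentationScore:
    """Per-class IoU, overall pixel accuracy, and the 3x3 confusion table
    (rows = truth, cols = prediction, fixed class order)."""

    iou: dict[str, float]
    accuracy: float
    confusion: np.ndarray = field(repr=False)


def evaluate_segmentation(predicted: LabelMap, truth: LabelMap) -> SegmentationScore:
    """Compare a predicted label map against truth.

    IoU with an empty union is defined as 1 (the class is absent from
    both maps and nothing was wrong about it).
    """
    if predicted.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: predicted {predicted.shape} vs truth {truth.shape}"
        )
    p = predicted.codes.ravel()
    t = truth.codes.ravel()
    confusion = np.zeros((3, 3), dtype=np.int64)
    np.add.at(confusion, (t, p), 1)
    iou = {}
    for code in CLASS_CODES:
        inter = confusion[code, code]
        union = confusion[code, :].sum() + confusion[:, code].sum() - inter
        iou[CLASS_NAMES[code]] = float(inter / union) if union > 0 else 1.0
    accuracy = float(np.trace(confusion) / max(confusion.sum(), 1))
    return SegmentationScore(iou, accuracy, confusion)


# thin functional wrappers ---------------------------------------------------

def train_classifier(
    images: list[DICImage],
    label_maps: list[LabelMap],
    seed: int = 0,
    **hyperparams,
) -> PixelClassifier:
    return PixelClassifier(random_state=seed, **hyperparams).fit(images, label_maps)


def predict_labels(classifier: PixelClassifier, image: DICImage, **kw) -> LabelMap:
    return classifier.predict(image, **kw)


def save_classifier(classifier: PixelClassifier, path) -> None:
    """Serialise the fitted model (feature config, class order, seed and
    training metadata embedded) to a single file."""
    check_is_fitted(classifier, "forest_")
    joblib.dump(classifier, path)


def load_classifier(path) -> PixelClassifier:
    clf = joblib.load(path)
    if not isinstance(clf, PixelClassifier):
        raise TypeError(f"{path} does not contain a PixelClassifier")
    return clf
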