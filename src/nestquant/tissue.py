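"""Pixel-wise tumor-nest vs stroma classification.

Each pixel is described by local-homogeneity color features (one per RGB
channel, ``1 - sd_window / sd_max``), the raw channel intensities, and a
texture descriptor (8-bin uniform local-binary-pattern histogram plus local
gray variance).  A standardized RBF support-vector machine trained on
labeled pixels classifies every pixel, and morphological postprocessing
removes small components, mirroring the expert-aided cleanup of manual
workflows in a deterministic way.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import uniform_filter
from skimage import color as skcolor
from skimage import measure, morphology
from skimage.feature import local_binary_pattern
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .synthetic import LabeledPixels

STROMA, NEST = 0, 1

#: Pseudo-color code for rendered segmentations: nest regions yellow, stroma
#: black, epithelial nuclei red, stromal non-round green, stromal round purple.
PSEUDO_COLORS = {
    "nest": (255, 255, 0),
    "stroma": (0, 0, 0),
    "epithelial": (255, 0, 0),
    "stromal_nonround": (0, 255, 0),
    "stromal_round": (160, 32, 240),
}

_LBP_POINTS = 8  # uniform LBP => P+2 = 10 bins; first 8 non-uniform-capped
_LBP_BINS = 9  # histogram bins used (uniform patterns 0..8 pooled)


def _local_sd(channel: np.ndarray, window: int) -> np.ndarray:
    m = uniform_filter(channel, window, mode="nearest")
    m2 = uniform_filter(channel * channel, window, mode="nearest")
    return np.sqrt(np.clip(m2 - m * m, 0.0, None))


def pixel_features(image: np.ndarray, window: int = 9) -> np.ndarray:
    """Per-pixel feature field of shape (H, W, 15).

    Layout: 3 local-homogeneity values (one per channel), 3 raw colors
    (scaled to [0, 1]), 9 texture values (8-bin LBP histogram + local gray
    variance).  Homogeneity is ``1 - sd_w(c) / sd_max`` with ``sd_max`` the
    largest possible standard deviation of 8-bit values (127.5), so constant
    neighborhoods score 1 and maximal-contrast neighborhoods 0.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    img = np.asarray(image, dtype=float)
    h, w = img.shape[:2]
    sd_max = 127.5
    feats = [
        np.clip(1.0 - _local_sd(img[..., c], window) / sd_max, 0.0, 1.0)
        for c in range(3)
    ]
    feats += [img[..., c] / 255.0 for c in range(3)]
    gray = skcolor.rgb2gray(image) * 255.0
    lbp = local_binary_pattern(gray.astype(np.uint8), _LBP_POINTS, 1, method="uniform")
    # per-pixel histogram of LBP codes over the window, via one box filter
    # per bin; codes 8 and 9 (non-uniform) pooled into the last bin
    codes = np.minimum(lbp, _LBP_BINS - 1)
    for b in range(_LBP_BINS - 1):
        feats.append(uniform_filter((codes == b).astype(float), window, mode="nearest"))
    feats.append(_local_sd(gray, window) ** 2 / sd_max**2)
    return np.stack(feats, axis=-1)


@dataclass
class TissueClassifier:
    """A trained pixel classifier (z-scoring + RBF SVM)."""

    scaler: StandardScaler
    svm: SVC
    window: int
    n_features: int
    training_accuracy: float

    def save(self, path: str | Path) -> None:
        Path(path).write_bytes(pickle.dumps(self))

    @staticmethod
    def load(path: str | Path) -> "TissueClassifier":
        obj = pickle.loads(Path(path).read_bytes())
        if not isinstance(obj, TissueClassifier):
            raise TypeError("file does not contain a TissueClassifier")
        return obj


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    window: int = 9,
    C: float = 1.0,
    gamma: float | str = "scale_dim",
    seed: int = 0,
) -> TissueClassifier:
    """Fit a standardized RBF SVM on labeled pixel feature vectors.

    ``gamma='scale_dim'`` uses 1/n_features on the z-scored inputs.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train")
    if counts.min() < 10:
        raise ValueError("need at least 10 samples per class")
    scaler = StandardScaler().fit(X)
    g = 1.0 / X.shape[1] if gamma == "scale_dim" else gamma
    svm = SVC(kernel="rbf", C=C, gamma=g, random_state=seed)
    Xs = scaler.transform(X)
    svm.fit(Xs, y)
    acc = float((svm.predict(Xs) == y).mean())
    return TissueClassifier(
        scaler=scaler,
        svm=svm,
        window=window,
        n_features=X.shape[1],
        training_accuracy=acc,
    )


def features_at(field: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Extract the feature vectors of a pixel feature field at (row, col)
    coordinates."""
    coords = np.asarray(coords)
    return field[coords[:, 0], coords[:, 1]]


def train_from_labeled_pixels(
    image: np.ndarray, sample: LabeledPixels, window: int = 9, seed: int = 0
) -> TissueClassifier:
    """Convenience wrapper: compute features and fit on a pixel sample."""
    field = pixel_features(image, window)
    return train_classifier(
        features_at(field, sample.coords), sample.labels, window=window, seed=seed
    )


def classify_pixels(image: np.ndarray, model: TissueClassifier) -> np.ndarray:
    """Label every pixel nest (1) or stroma (0)."""
    field = pixel_features(image, model.window)
    h, w, d = field.shape
    if d != model.n_features:
        raise ValueError(
            f"feature length {d} does not match model ({model.n_features})"
        )
    flat = model.scaler.transform(field.reshape(-1, d))
    return model.svm.predict(flat).reshape(h, w).astype(np.uint8)


def postprocess_mask(
    mask: np.ndarray,
    min_region: int = 500,
    closing_radius: int = 3,
    correction: np.ndarray | None = None,
) -> np.ndarray:
    """Morphological cleanup of a nest/stroma mask.

    Closing with a disk of ``closing_radius`` bridges gaps between the
    nuclei of one nest; nest components and stroma holes smaller than
    ``min_region`` px^2 are reassigned.  If a ``correction`` mask is given
    (external expert relabeling), it simply replaces the result — the
    deterministic stand-in for interactive editing.
    """
    if correction is not None:
        return np.asarray(correction, dtype=np.uint8)
    m = np.asarray(mask, bool)
    if closing_radius > 0:
        m = morphology.closing(m, morphology.disk(closing_radius))
    m = morphology.remove_small_objects(m, max_size=min_region - 1)
    m = ~morphology.remove_small_objects(~m, max_size=min_region - 1)
    return m.astype(np.uint8)


def count_components(mask: np.ndarray, min_region: int = 0) -> int:
    """Number of 8-connected nest components with area >= ``min_region``."""
    labels = measure.label(np.asarray(mask, bool), connectivity=2)
    if min_region <= 0:
        return int(labels.max())
    return int(sum(1 for rp in measure.regionprops(labels) if rp.area >= min_region))


def render_pseudocolor(
    tissue_mask: np.ndarray,
    nuclei_labels: np.ndarray | None = None,
    nucleus_classes: dict[int, str] | None = None,
) -> np.ndarray:
    """Five-class pseudo-color rendering of the segmentation results."""
    h, w = np.asarray(tissue_mask).shape
    out = np.zeros((h, w, 3), dtype=np.uint8)
    out[np.asarray(tissue_mask) == NEST] = PSEUDO_COLORS["nest"]
    if nuclei_labels is not None and nucleus_classes:
        for nid, cls in nucleus_classes.items():
            out[nuclei_labels == nid] = PSEUDO_COLORS[cls]
    return out
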