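"""Classical voxel classifiers on patchwise PET+CT intensity features.

Each voxel is represented by the raw intensities of its 3x3x3 neighborhood
in CT and in PET (27 + 27 = 54 values, volumes z-scored beforehand, edges
replicated at the boundary).  PCA reduces the 54 dimensions to 15, and a
random forest (20 trees), k-NN (k = 15) or linear SVM (C = 0.5) classifies
lesion vs nonlesion.  Training samples are 2000 lesion and 2000 nonlesion
voxels per volume, drawn uniformly without replacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.svm import LinearSVC

logger = logging.getLogger(__name__)

FEATURE_DIM = 54

_OFFSETS = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
]


@dataclass(frozen=True)
class BaselineConfig:
    n_trees: int = 20
    k_neighbors: int = 15
    svm_c: float = 0.5
    n_samples_per_class: int = 2000
    pca_components: int = 15
    cv_folds: int = 3

    def __post_init__(self):
        for name in ("n_trees", "k_neighbors", "n_samples_per_class",
                     "pca_components", "cv_folds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def zscore(volume: np.ndarray) -> np.ndarray:
    """Per-volume standardization; constant volumes map to zeros."""
    v = np.asarray(volume, dtype=np.float64)
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def _neighborhoods(volume: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """(n, 27) raster-ordered 3x3x3 neighborhoods with edge replication."""
    padded = np.pad(volume, 1, mode="edge")
    c = centers + 1
    out = np.empty((len(centers), 27), dtype=np.float64)
    for j, (dz, dy, dx) in enumerate(_OFFSETS):
        out[:, j] = padded[c[:, 0] + dz, c[:, 1] + dy, c[:, 2] + dx]
    return out


def patch_features(
    ct: np.ndarray,
    pet: np.ndarray,
    voxel: tuple[int, int, int] | np.ndarray,
    normalize: bool = True,
) -> np.ndarray:
    """54-dimensional feature vector(s): CT block then PET block.

    ``voxel`` may be a single (i, j, k) index or an (n, 3) array of centers;
    the result is a (54,) vector or an (n, 54) matrix.  Boundary voxels use
    edge-replicated neighborhoods.
    """
    centers = np.atleast_2d(np.asarray(voxel, dtype=np.int64))
    if normalize:
        ct, pet = zscore(ct), zscore(pet)
    feats = np.hstack([_neighborhoods(ct, centers), _neighborhoods(pet, centers)])
    if np.asarray(voxel).ndim == 1:
        return feats[0]
    return feats


def sample_training_set(
    volumes: list[tuple[np.ndarray, np.ndarray]],
    labels: list[np.ndarray],
    seed: int = 0,
    config: BaselineConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced voxel-center sampling across volumes.

    Per volume: ``n_samples_per_class`` lesion and nonlesion voxel centers,
    uniform without replacement (with replacement, logged, when a volume has
    fewer lesion voxels than requested).  Volumes without lesions are skipped
    with a warning.  Returns (features, targets).
    """
    config = config or BaselineConfig()
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for (ct, pet), lab in zip(volumes, labels):
        lab = np.asarray(lab, dtype=bool)
        pos = np.argwhere(lab)
        neg = np.argwhere(~lab)
        if len(pos) == 0:
            logger.warning("volume without lesion voxels skipped")
            continue
        n = config.n_samples_per_class
        replace_pos = len(pos) < n
        if replace_pos:
            logger.info("only %d lesion voxels; sampling with replacement", len(pos))
        pos_sel = pos[rng.choice(len(pos), size=n, replace=replace_pos)]
        neg_sel = neg[rng.choice(len(neg), size=n, replace=len(neg) < n)]
        centers = np.vstack([pos_sel, neg_sel])
        xs.append(patch_features(ct, pet, centers))
        ys.append(np.concatenate([np.ones(n), np.zeros(n)]))
    if not xs:
        raise ValueError("no volume contained lesion voxels")
    return np.vstack(xs), np.concatenate(ys)


def _make_classifier(method: str, config: BaselineConfig, seed: int):
    if method == "rf":
        return RandomForestClassifier(
            n_estimators=config.n_trees, random_state=seed
        )
    if method == "knn":
        return KNeighborsClassifier(n_neighbors=config.k_neighbors)
    if method == "svm":
        return LinearSVC(C=config.svm_c, random_state=seed)
    raise ValueError(f"unknown baseline method {method!r}; use rf, knn or svm")


_GRIDS = {
    "rf": {"clf__n_estimators": [10, 20, 40]},
    "knn": {"clf__n_neighbors": [5, 15, 25]},
    "svm": {"clf__C": [0.1, 0.5, 1.0]},
}


def fit_baseline(
    features: np.ndarray,
    targets: np.ndarray,
    method: str,
    config: BaselineConfig | None = None,
    seed: int = 0,
    grid_search: bool = False,
) -> Pipeline:
    """PCA-15 + classifier pipeline fitted on the sampled voxels.

    With ``grid_search`` the hyperparameter is selected by 3-fold CV over a
    small grid centered on the reference value; otherwise the reference
    value is used directly.
    """
    config = config or BaselineConfig()
    if len(np.unique(targets)) < 2:
        raise ValueError("both classes must be present to fit a baseline")
    if features.shape[1] != FEATURE_DIM:
        raise ValueError(f"expected {FEATURE_DIM}-dim features, got {features.shape[1]}")
    rank = np.linalg.matrix_rank(features - features.mean(axis=0))
    if rank < config.pca_components:
        logger.warning("feature matrix rank %d < %d PCA components",
                       rank, config.pca_components)
    pipe = Pipeline(
        [
            ("pca", PCA(n_components=config.pca_components, random_state=seed)),
            ("clf", _make_classifier(method, config, seed)),
        ]
    )
    if grid_search:
        pipe = GridSearchCV(pipe, _GRIDS[method], cv=config.cv_folds)
    pipe.fit(features, targets)
    return pipe


def predict_baseline(
    classifier: Pipeline,
    ct: np.ndarray,
    pet: np.ndarray,
    region: np.ndarray | None = None,
    chunk: int = 200_000,
) -> np.ndarray:
    """Classify every voxel (optionally restricted to a region mask).

    Voxels outside ``region`` stay negative.  Returns a binary lesion mask
    of the input shape.
    """
    if not hasattr(classifier, "predict"):
        raise ValueError("classifier is not fitted")
    ct_n, pet_n = zscore(ct), zscore(pet)
    if region is None:
        centers = np.argwhere(np.ones(ct.shape, dtype=bool))
    else:
        centers = np.argwhere(np.asarray(region, dtype=bool))
    mask = np.zeros(ct.shape, dtype=bool)
    for start in range(0, len(centers), chunk):
        sub = centers[start : start + chunk]
        feats = patch_features(ct_n, pet_n, sub, normalize=False)
        pred = classifier.predict(feats).astype(bool)
        mask[sub[:, 0], sub[:, 1], sub[:, 2]] = pred
    return mask
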