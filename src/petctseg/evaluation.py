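"""Segmentation metrics, lesionwise patch-overlap detection, CV utilities.

Voxelwise metrics (Dice, sensitivity, specificity, precision) treat the
volume as a bag of voxels.  The lesionwise detection metric instead tiles
the region of interest with 9x9x9 patches overlapping by 4 voxels (stride
5): a patch is positive when more than 10 % of its voxels carry the lesion
label, and detection statistics are computed over patches, which rewards
finding each lesion rather than delineating it perfectly.

Also provided: the half-maximum thresholding rule used to delineate hot
lesions on PET (connected region above 50 % of the local maximum), and a
deterministic k-fold splitter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


def dice_score(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|), in percent; 100 if both empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 100.0
    return 200.0 * int((a & b).sum()) / denom


def voxel_confusion(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Sensitivity, specificity and precision (percent) over voxels.

    Metrics with an undefined denominator are reported as ``None``.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    tn = int((~pred & ~truth).sum())

    def rate(num, den):
        return 100.0 * num / den if den > 0 else None

    return {
        "sensitivity": rate(tp, tp + fn),
        "specificity": rate(tn, tn + fp),
        "precision": rate(tp, tp + fp),
        "counts": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    }


@dataclass(frozen=True)
class DetectionPatchGrid:
    """Geometry of the lesionwise detection tiling."""

    size: int = 9
    overlap: int = 4
    threshold: float = 0.10  # strict: positive when fraction > threshold
    margin: int = 9

    @property
    def stride(self) -> int:
        return self.size - self.overlap

    def __post_init__(self):
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")


def _grid_corners(lo: int, hi: int, size: int, stride: int) -> list[int]:
    span = hi - lo
    if span <= size:
        return [lo]
    corners = list(range(lo, hi - size + 1, stride))
    if corners[-1] != hi - size:
        corners.append(hi - size)
    return corners


def lesionwise_detection(
    pred: np.ndarray,
    truth: np.ndarray,
    grid: DetectionPatchGrid | None = None,
    region: np.ndarray | None = None,
) -> dict:
    """Patch-overlap detection statistics.

    The patch universe tiles the bounding box of ``region`` (typically the
    skeleton; defaults to the union of pred and truth) expanded by the grid
    margin.  A patch is ground-truth positive when more than ``threshold`` of
    its voxels are truth lesion, and predicted positive by the same rule on
    ``pred``; sensitivity/specificity/precision are computed over patches.
    """
    grid = grid or DetectionPatchGrid()
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if region is None:
        region = pred | truth
    if not region.any():
        return {"sensitivity": None, "specificity": None, "precision": None,
                "counts": {"tp": 0, "fp": 0, "fn": 0, "tn": 0}}
    nz = np.argwhere(region)
    lo = np.maximum(nz.min(axis=0) - grid.margin, 0)
    hi = np.minimum(nz.max(axis=0) + 1 + grid.margin, truth.shape)

    tp = fp = fn = tn = 0
    nvox = grid.size**3
    corners = [
        _grid_corners(int(lo[a]), int(hi[a]), grid.size, grid.stride)
        for a in range(3)
    ]
    for ci in corners[0]:
        for cj in corners[1]:
            for ck in corners[2]:
                sl = (
                    slice(ci, min(ci + grid.size, truth.shape[0])),
                    slice(cj, min(cj + grid.size, truth.shape[1])),
                    slice(ck, min(ck + grid.size, truth.shape[2])),
                )
                t_pos = truth[sl].sum() / nvox > grid.threshold
                p_pos = pred[sl].sum() / nvox > grid.threshold
                if t_pos and p_pos:
                    tp += 1
                elif t_pos:
                    fn += 1
                elif p_pos:
                    fp += 1
                else:
                    tn += 1

    def rate(num, den):
        return 100.0 * num / den if den > 0 else None

    return {
        "sensitivity": rate(tp, tp + fn),
        "specificity": rate(tn, tn + fp),
        "precision": rate(tp, tp + fp),
        "counts": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    }


def half_max_segment(
    pet: np.ndarray,
    seed_voxel: tuple[int, int, int],
    search_radius: int = 15,
) -> np.ndarray:
    """Local thresholding at half maximum around a seed voxel.

    The local maximum is taken within ``search_radius`` voxels of the seed;
    the returned mask is the 26-connected component containing the seed of
    voxels at or above half that maximum, restricted to the search window.
    A seed on background (below the global mean) yields an empty mask.
    """
    pet = np.asarray(pet, dtype=float)
    seed_voxel = tuple(int(c) for c in seed_voxel)
    if pet[seed_voxel] < pet.mean():
        warnings.warn("seed voxel lies on background; returning empty mask")
        return np.zeros(pet.shape, dtype=bool)
    lo = [max(c - search_radius, 0) for c in seed_voxel]
    hi = [min(c + search_radius + 1, s) for c, s in zip(seed_voxel, pet.shape)]
    window = pet[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    thresh = 0.5 * window.max()
    above = window >= thresh
    lab, _ = ndimage.label(above, structure=np.ones((3, 3, 3)))
    seed_local = tuple(c - l for c, l in zip(seed_voxel, lo))
    comp = lab[seed_local]
    mask = np.zeros(pet.shape, dtype=bool)
    if comp > 0:
        mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = lab == comp
    return mask


def kfold_split(ids: list, k: int = 3, seed: int = 0) -> list[list]:
    """Disjoint, exhaustive, size-balanced folds; deterministic given seed."""
    ids = list(ids)
    if k > len(ids):
        raise ValueError(f"cannot split {len(ids)} ids into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    return [[ids[i] for i in chunk] for chunk in np.array_split(order, k)]


@dataclass
class MetricReport:
    """Voxelwise and lesionwise results, per fold and pooled."""

    voxelwise: dict = field(default_factory=dict)
    lesionwise: dict = field(default_factory=dict)
    per_fold: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_masks(cls, pred, truth, region=None, meta=None) -> "MetricReport":
        vox = voxel_confusion(pred, truth)
        vox["dice"] = dice_score(pred, truth)
        return cls(
            voxelwise=vox,
            lesionwise=lesionwise_detection(pred, truth, region=region),
            meta=meta or {},
        )

    def as_dict(self) -> dict:
        return {
            "voxelwise": self.voxelwise,
            "lesionwise": self.lesionwise,
            "per_fold": self.per_fold,
            "meta": self.meta,
        }
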