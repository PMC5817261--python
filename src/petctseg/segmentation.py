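"""V-Net / W-Net volumetric segmentation with class-weighted cross-entropy.

The single V-Net is an encoder-decoder with skip concatenations: a
compression path of same-padded 3x3x3 convolutions with stride-2 resampling
between resolution stages, mirrored by a decompression path of stride-2
transposed convolutions, ending in a voxelwise sigmoid.  The W-Net cascades
two V-Nets: the first (5 stages, CT input) predicts a binary skeleton mask,
the second (3 stages) consumes CT + PET + that mask and predicts lesion
probability; the first stage is frozen while the second trains.

Class imbalance is addressed twice: (i) the cross-entropy loss weights
each voxel inversely to the voxel count of its class, and (ii) training
patches (64^3, 5-voxel overlap) are ranked by foreground ratio and only
the top 30 per volume are used to pretrain, before optional fine-tuning on
full volumes until convergence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .layers import (SGD, Conv3d, ConvTranspose3d, InstanceNorm3d, ReLU,
                     Sequential, Sigmoid)

logger = logging.getLogger(__name__)

PROB_EPS = 1e-7  # probability clipping for loss stability


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def class_weights(labels: np.ndarray) -> np.ndarray:
    """Per-class weights inversely proportional to class voxel counts.

    Returns ``(w_background, w_foreground)`` normalized so that
    ``w0 * n0 + w1 * n1 == N`` — each class then contributes equally to the
    loss, and the loss scale stays comparable to the unweighted case.  If one
    class is absent the weights fall back to (1, 1) with a warning.
    """
    labels = np.asarray(labels)
    n = labels.size
    n_fg = int(np.count_nonzero(labels))
    n_bg = n - n_fg
    if n_fg == 0 or n_bg == 0:
        warnings.warn("only one class present; falling back to unweighted loss")
        return np.array([1.0, 1.0])
    return np.array([n / (2.0 * n_bg), n / (2.0 * n_fg)])


def weighted_cross_entropy(
    pred: np.ndarray,
    truth: np.ndarray,
    weights: np.ndarray | None = None,
    eps: float = PROB_EPS,
    return_grad: bool = False,
):
    """Voxelwise class-weighted binary cross-entropy.

    ``L = -(1/N) sum_i w_i [ t_i log p_i + (1 - t_i) log(1 - p_i) ]`` with
    ``w_i`` the weight of voxel i's class and probabilities clipped to
    ``[eps, 1 - eps]``.  Optionally returns the gradient with respect to the
    predicted probabilities.
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if np.any(np.isnan(pred)):
        raise ValueError("NaN in predicted probabilities")
    if weights is None:
        weights = np.array([1.0, 1.0])
    t = (truth != 0).astype(np.float64)
    w = np.where(t > 0, weights[1], weights[0])
    p = np.clip(pred, eps, 1.0 - eps)
    n = p.size
    loss = -np.sum(w * (t * np.log(p) + (1.0 - t) * np.log1p(-p))) / n
    if not return_grad:
        return float(loss)
    grad = -(w / n) * (t / p - (1.0 - t) / (1.0 - p))
    return float(loss), grad


# ---------------------------------------------------------------------------
# patch grid / balancing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Patch:
    volume_id: int
    corner: tuple[int, int, int]
    size: tuple[int, int, int]
    label_ratio: float


@dataclass
class PatchSet:
    patches: list[Patch]
    patch_size: tuple[int, int, int]
    overlap: int

    def __len__(self):
        return len(self.patches)

    def for_volume(self, volume_id: int) -> list[Patch]:
        return [p for p in self.patches if p.volume_id == volume_id]


def patch_grid_1d(dim: int, size: int, stride: int) -> list[int]:
    """Corner positions along one axis: regular stride, final patch flush."""
    if dim <= size:
        return [0]
    corners = list(range(0, dim - size + 1, stride))
    if corners[-1] != dim - size:
        corners.append(dim - size)
    return corners


def extract_patches(
    label_volumes: list[np.ndarray],
    size: int | tuple[int, int, int] = 64,
    overlap: int = 5,
) -> PatchSet:
    """Tile each volume with overlapping patches and record foreground ratios.

    The grid uses stride ``size - overlap``; the last patch per axis is
    shifted to end flush with the volume boundary so the union of patches
    covers every voxel.  Volumes smaller than the patch along an axis get a
    single full-extent patch there.
    """
    if np.isscalar(size):
        size = (int(size),) * 3
    patches = []
    for vid, lab in enumerate(label_volumes):
        eff = tuple(min(s, d) for s, d in zip(size, lab.shape))
        corners = [
            patch_grid_1d(d, s, s - overlap)
            for d, s in zip(lab.shape, eff)
        ]
        nvox = int(np.prod(eff))
        for ci in corners[0]:
            for cj in corners[1]:
                for ck in corners[2]:
                    sub = lab[ci : ci + eff[0], cj : cj + eff[1], ck : ck + eff[2]]
                    ratio = float(np.count_nonzero(sub)) / nvox
                    patches.append(Patch(vid, (ci, cj, ck), eff, ratio))
    return PatchSet(patches, size, overlap)


def select_top_patches(ps: PatchSet, k: int = 30) -> PatchSet:
    """Per volume, keep the k patches with the highest foreground ratio.

    Ties are broken by lexicographic corner order; volumes with fewer than k
    patches keep all of them.
    """
    selected = []
    for vid in sorted({p.volume_id for p in ps.patches}):
        vol_patches = ps.for_volume(vid)
        vol_patches.sort(key=lambda p: (-p.label_ratio, p.corner))
        selected.extend(vol_patches[:k])
    return PatchSet(selected, ps.patch_size, ps.overlap)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkSpec:
    """V-Net architecture hyperparameters.

    ``depth`` resolution stages connected by stride-2 resampling; all
    convolutions are same-padded 3x3x3 (1x1x1 for the output head); feature
    width doubles per stage from ``base_width`` up to ``width_cap``.
    """

    depth: int = 3
    in_channels: int = 2
    base_width: int = 16
    width_cap: int = 128
    n_convs_per_stage: int = 1
    normalization: str = "none"  # "instance" available; HU calibration
    # carries class information, so normalizing it away hurts on CT
    dtype: str = "float32"  # float64 available for numerical verification

    def stage_widths(self) -> list[int]:
        return [min(self.base_width * 2**i, self.width_cap) for i in range(self.depth)]


class VNet:
    """Encoder-decoder 3D segmentation network with skip concatenations."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        self.trained = False
        self.dtype = np.dtype(spec.dtype)
        rng = np.random.default_rng(seed)
        w = spec.stage_widths()
        d = spec.depth
        dt = self.dtype

        def norm(ch):
            if spec.normalization == "instance":
                return [InstanceNorm3d(ch, dtype=dt)]
            return []

        def conv_block(cin, cout, n):
            layers = []
            for j in range(n):
                layers += [Conv3d(cin if j == 0 else cout, cout, 3, 1, rng, dt),
                           *norm(cout), ReLU()]
            return Sequential(*layers)

        nc = spec.n_convs_per_stage
        self.enc = [conv_block(spec.in_channels if i == 0 else w[i], w[i], nc)
                    for i in range(d)]
        self.down = [
            Sequential(Conv3d(w[i], w[i + 1], 3, 2, rng, dt), *norm(w[i + 1]),
                       ReLU())
            for i in range(d - 1)
        ]
        self.up = [ConvTranspose3d(w[i + 1], w[i], rng, dt) for i in range(d - 1)]
        self.dec = [conv_block(2 * w[i], w[i], nc) for i in range(d - 1)]
        self.head = Conv3d(w[0], 1, kernel=1, rng=rng, dtype=dt)
        self.out_act = Sigmoid()

    # -- plumbing ----------------------------------------------------------
    def params(self):
        mods = self.enc + self.down + self.up + self.dec + [self.head]
        return [p for m in mods for p in m.params()]

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def _pad_to_multiple(self, x):
        f = 2 ** (self.spec.depth - 1)
        sp = x.shape[1:]
        target = [int(np.ceil(s / f)) * f for s in sp]
        pad = [(0, t - s) for t, s in zip(target, sp)]
        if any(p[1] for p in pad):
            x = np.pad(x, [(0, 0)] + pad)
        return x, sp

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """(C, D, H, W) input -> (D, H, W) foreground probability."""
        if x.shape[0] != self.spec.in_channels:
            raise ValueError(
                f"expected {self.spec.in_channels} input channels, got {x.shape[0]}"
            )
        x = np.asarray(x, dtype=self.dtype)
        x, self._orig_shape = self._pad_to_multiple(x)
        d = self.spec.depth
        self._skips = []
        h = self.enc[0].forward(x)
        for i in range(d - 1):
            self._skips.append(h)
            h = self.down[i].forward(h)
            h = self.enc[i + 1].forward(h)
        for i in reversed(range(d - 1)):
            u = self.up[i].forward(h)
            cat = np.concatenate([self._skips[i], u], axis=0)
            h = self.dec[i].forward(cat)
        prob = self.out_act.forward(self.head.forward(h))[0]
        sp = self._orig_shape
        return prob[: sp[0], : sp[1], : sp[2]]

    def backward(self, dprob: np.ndarray) -> np.ndarray:
        d = self.spec.depth
        w = self.spec.stage_widths()
        full = [int(np.ceil(s / 2 ** (d - 1))) * 2 ** (d - 1) for s in self._orig_shape]
        dp = np.zeros((1, *full), dtype=self.dtype)
        sp = self._orig_shape
        dp[0, : sp[0], : sp[1], : sp[2]] = dprob
        dh = self.head.backward(self.out_act.backward(dp))
        dskips = {}
        for i in range(d - 1):
            dcat = self.dec[i].backward(dh)
            dskips[i] = dcat[: w[i]]
            dh = self.up[i].backward(dcat[w[i] :])
        for i in reversed(range(d - 1)):
            dh = self.enc[i + 1].backward(dh)
            dh = self.down[i].backward(dh)
            dh = dh + dskips[i]
        return self.enc[0].backward(dh)


def build_vnet(spec: NetworkSpec, seed: int = 0) -> VNet:
    """Construct a randomly initialized V-Net from its spec."""
    return VNet(spec, seed=seed)


class WNet:
    """Cascade of two V-Nets: CT -> skeleton mask -> lesion probability."""

    def __init__(self, spec1: NetworkSpec, spec2: NetworkSpec, seed: int = 0):
        if spec1.in_channels != 1:
            raise ValueError("stage-1 V-Net must take a single CT channel")
        if spec2.in_channels != 3:
            raise ValueError("stage-2 V-Net must take CT + PET + mask channels")
        self.net1 = VNet(spec1, seed=seed)
        self.net2 = VNet(spec2, seed=seed + 1)
        self.mask_threshold = 0.5

    @property
    def trained(self):
        return self.net1.trained and self.net2.trained

    def stage1_mask(self, ct: np.ndarray) -> np.ndarray:
        """Hard binary skeleton mask from the (frozen) first stage."""
        return (self.net1.forward(ct[None]) > self.mask_threshold).astype(np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x = (ct, pet) channels -> lesion probability via the cascade."""
        if x.shape[0] != 2:
            raise ValueError("W-Net forward expects (ct, pet) channels")
        mask = self.stage1_mask(x[0])
        x2 = np.stack([x[0], x[1], mask])
        return self.net2.forward(x2)


def build_wnet(
    spec1: NetworkSpec | None = None,
    spec2: NetworkSpec | None = None,
    seed: int = 0,
) -> WNet:
    """W-Net with the canonical stage depths: 5 (CT->bone), 3 (CT+PET+mask)."""
    spec1 = spec1 or NetworkSpec(depth=5, in_channels=1)
    spec2 = spec2 or NetworkSpec(depth=3, in_channels=3)
    return WNet(spec1, spec2, seed=seed)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingSchedule:
    """Two-phase schedule: patch pretraining then full-volume fine-tuning.

    SGD with momentum runs every iteration; every ``checkpoint_every``
    iterations the running loss is recorded (and validation evaluated when
    available).  Fine-tuning stops when the monitored loss has not improved
    by more than ``finetune_min_delta`` over ``finetune_patience``
    consecutive checkpoints, or at ``finetune_max_iters``.
    """

    learning_rate: float = 0.001
    momentum: float = 0.95
    pretrain_iterations: int = 1000
    checkpoint_every: int = 100
    batch_size: int = 2
    patch_size: int = 64
    patch_overlap: int = 5
    top_k_patches: int = 30
    finetune_patience: int = 5
    finetune_min_delta: float = 1e-4
    finetune_max_iters: int = 500

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.finetune_patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainingHistory:
    checkpoints: list[int] = field(default_factory=list)
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    phase_boundaries: list[int] = field(default_factory=list)


def _batch_step(model, optimizer, batch, weights, eps=PROB_EPS):
    """One SGD step on a batch of (channels, truth) pairs; returns mean loss."""
    optimizer.zero_grad()
    total = 0.0
    for channels, truth in batch:
        prob = model.forward(channels)
        loss, grad = weighted_cross_entropy(
            prob, truth, weights, eps=eps, return_grad=True
        )
        model.backward((grad / len(batch)).astype(np.float32))
        total += loss
    optimizer.step()
    return total / len(batch)


def _crop(volumes, truth, patch: Patch):
    ci, cj, ck = patch.corner
    si, sj, sk = patch.size
    ch = volumes[:, ci : ci + si, cj : cj + sj, ck : ck + sk]
    t = truth[ci : ci + si, cj : cj + sj, ck : ck + sk]
    return ch, t


def train(
    model: VNet,
    volumes: list[np.ndarray],
    labels: list[np.ndarray],
    schedule: TrainingSchedule | None = None,
    seed: int = 0,
    val_volumes: list[np.ndarray] | None = None,
    val_labels: list[np.ndarray] | None = None,
) -> TrainingHistory:
    """Train a V-Net with patch pretraining and full-volume fine-tuning.

    ``volumes`` are multi-channel inputs (C, D, H, W); ``labels`` are binary
    foreground maps.  Phase 1 draws batches from the top-ratio patches of
    each volume; phase 2 iterates over whole volumes until the convergence
    criterion of the schedule fires.  Deterministic given ``seed``.
    """
    schedule = schedule or TrainingSchedule()
    rng = np.random.default_rng(seed)
    if not any(lab.any() for lab in labels):
        raise ValueError("training set contains no foreground voxels")

    ps = extract_patches(labels, schedule.patch_size, schedule.patch_overlap)
    ps = select_top_patches(ps, schedule.top_k_patches)
    pool = ps.patches
    # inverse-frequency class weights over the selected-patch pool, computed
    # once so every step optimizes the same objective
    n_fg = n_tot = 0
    for p in pool:
        _, t = _crop(volumes[p.volume_id], labels[p.volume_id], p)
        n_fg += int(np.count_nonzero(t))
        n_tot += t.size
    if 0 < n_fg < n_tot:
        weights = np.array([n_tot / (2.0 * (n_tot - n_fg)), n_tot / (2.0 * n_fg)])
    else:
        weights = np.array([1.0, 1.0])
    history = TrainingHistory()
    optimizer = SGD(model.params(), schedule.learning_rate, schedule.momentum)

    def checkpoint(it, running):
        history.checkpoints.append(it)
        history.train_losses.append(float(np.mean(running)))
        if val_volumes is not None:
            vloss = _evaluate_loss(model, val_volumes, val_labels)
            history.val_losses.append(vloss)

    running = []
    for it in range(1, schedule.pretrain_iterations + 1):
        idx = rng.integers(len(pool), size=schedule.batch_size)
        batch = [_crop(volumes[pool[i].volume_id], labels[pool[i].volume_id], pool[i])
                 for i in idx]
        loss = _batch_step(model, optimizer, batch, weights)
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged at iteration {it} (loss={loss})")
        running.append(loss)
        if it % schedule.checkpoint_every == 0:
            checkpoint(it, running)
            running = []
    history.phase_boundaries.append(schedule.pretrain_iterations)

    # phase 2: full volumes until convergence
    best = np.inf
    stale = 0
    it = schedule.pretrain_iterations
    running = []
    while it - schedule.pretrain_iterations < schedule.finetune_max_iters:
        it += 1
        i = int(rng.integers(len(volumes)))
        loss = _batch_step(model, optimizer, [(volumes[i], labels[i])], weights)
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged at iteration {it} (loss={loss})")
        running.append(loss)
        if it % schedule.checkpoint_every == 0:
            checkpoint(it, running)
            monitored = (history.val_losses[-1] if val_volumes is not None
                         else history.train_losses[-1])
            running = []
            if monitored < best - schedule.finetune_min_delta:
                best = monitored
                stale = 0
            else:
                stale += 1
                if stale >= schedule.finetune_patience:
                    break
    model.trained = True
    return history


def _evaluate_loss(model, volumes, labels):
    losses = []
    for v, t in zip(volumes, labels):
        prob = model.forward(v)
        w = class_weights(t) if (t.any() and not t.all()) else np.array([1.0, 1.0])
        losses.append(weighted_cross_entropy(prob, t, w))
    return float(np.mean(losses))


def train_wnet(
    wnet: WNet,
    ct_volumes: list[np.ndarray],
    pet_volumes: list[np.ndarray],
    bone_labels: list[np.ndarray],
    lesion_labels: list[np.ndarray],
    schedule1: TrainingSchedule,
    schedule2: TrainingSchedule,
    seed: int = 0,
) -> tuple[TrainingHistory, TrainingHistory]:
    """Sequential W-Net training: skeleton stage first, then lesion stage.

    Stage 2 sees the *predicted* (hard, frozen) stage-1 mask as its third
    channel, matching inference conditions.
    """
    h1 = train(
        wnet.net1,
        [ct[None] for ct in ct_volumes],
        bone_labels,
        schedule1,
        seed=seed,
    )
    stage2_inputs = []
    for ct, pet in zip(ct_volumes, pet_volumes):
        mask = predict_volume(
            wnet.net1, ct[None],
            patch_size=schedule1.patch_size, overlap=schedule1.patch_overlap,
        )[1] > wnet.mask_threshold
        stage2_inputs.append(np.stack([ct, pet, mask.astype(np.float32)]))
    h2 = train(wnet.net2, stage2_inputs, lesion_labels, schedule2, seed=seed + 1)
    return h1, h2


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def predict_volume(
    model: VNet,
    channels: np.ndarray,
    patch_size: int = 64,
    overlap: int = 5,
    threshold: float = 0.5,
    require_trained: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window inference: averaged overlapping probabilities, then 0.5.

    Returns ``(mask, probability)`` at the input resolution.
    """
    if require_trained and not getattr(model, "trained", False):
        raise RuntimeError("refusing to predict with an untrained model")
    shape = channels.shape[1:]
    eff = tuple(min(patch_size, d) for d in shape)
    corners = [patch_grid_1d(d, s, max(s - overlap, 1)) for d, s in zip(shape, eff)]
    prob_sum = np.zeros(shape, dtype=np.float64)
    count = np.zeros(shape, dtype=np.int32)
    for ci in corners[0]:
        for cj in corners[1]:
            for ck in corners[2]:
                sl = (
                    slice(ci, ci + eff[0]),
                    slice(cj, cj + eff[1]),
                    slice(ck, ck + eff[2]),
                )
                patch = channels[(slice(None),) + sl]
                prob = model.forward(patch)
                prob_sum[sl] += prob
                count[sl] += 1
    prob = prob_sum / count
    return prob > threshold, prob


def predict_wnet_volume(
    wnet: WNet,
    ct: np.ndarray,
    pet: np.ndarray,
    patch_size: int = 64,
    overlap: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage W-Net inference; returns (lesion mask, bone mask)."""
    bone_mask, _ = predict_volume(wnet.net1, ct[None], patch_size, overlap)
    channels = np.stack([ct, pet, bone_mask.astype(np.float32)])
    lesion_mask, _ = predict_volume(wnet.net2, channels, patch_size, overlap)
    return lesion_mask, bone_mask
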