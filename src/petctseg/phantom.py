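"""Procedural whole-body digital phantoms with randomized bone lesions.

A phantom is a triple of co-registered voxel fields on a common grid: a CT
volume in Hounsfield units, a tracer-activity volume in arbitrary units, and
an integer label volume marking air, soft tissue, lungs, liver, spleen,
kidneys, skeleton and lesions.  The anatomy is stylized — geometric
primitives placed in coordinates relative to the grid extent, so the same
template scales from small test grids to the default desk-scale grid — but
carries the features the downstream pipeline needs: a connected skeleton for
lesion placement, organs with distinct uptake (spleen and kidneys hot, as
for a CXCR4-targeted tracer), and lungs with near-air density for
attenuation contrast.

Lesions are randomly deformed ellipsoids seeded uniformly over skeleton
voxels.  Each lesion multiplies local activity by an uptake factor relative
to the bone-marrow background and shifts local CT by a HU delta scaled with
lesion severity, so lytic (negative delta) and sclerotic (positive delta)
presentations both occur.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

# label codes
AIR = 0
SOFT = 1
LUNG = 2
LIVER = 3
SPLEEN = 4
KIDNEY = 5
BONE = 6
LESION = 7

LABEL_NAMES = {
    AIR: "air",
    SOFT: "soft_tissue",
    LUNG: "lung",
    LIVER: "liver",
    SPLEEN: "spleen",
    KIDNEY: "kidney",
    BONE: "bone",
    LESION: "lesion",
}

#: mean CT value (HU) per tissue class
CT_MEANS = {
    AIR: -1000.0,
    SOFT: 40.0,
    LUNG: -700.0,
    LIVER: 60.0,
    SPLEEN: 50.0,
    KIDNEY: 45.0,
}
CT_NOISE_HU = 15.0
BONE_HU_MEAN = 750.0
BONE_HU_SD = 150.0
BONE_HU_RANGE = (400.0, 1200.0)

#: baseline tracer activity per tissue class (arbitrary units).  Spleen and
#: kidneys are the hottest organs, marrow/bone sits at 1.0 and is the
#: reference for lesion uptake multipliers.
ACTIVITY_MEANS = {
    AIR: 0.0,
    SOFT: 0.5,
    LUNG: 0.05,
    LIVER: 1.5,
    SPLEEN: 3.0,
    KIDNEY: 2.5,
    BONE: 1.0,
}
ACTIVITY_NOISE_FRACTION = 0.05

#: uptake value at which a lesion's full ct_delta is applied; severity of a
#: lesion scales linearly with uptake up to this reference.
UPTAKE_SEVERITY_REF = 10.0


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3D voxel lattice: shape (nx, ny, nz), spacing and origin in mm."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) < 8 for s in self.shape):
            raise ValueError(f"grid shape must be 3 entries >= 8, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def world_coordinates(self):
        """Voxel-center world coordinates along each axis (mm)."""
        return [
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        ]

    def normalized_coordinates(self):
        """x, y in [-1, 1] about the transaxial center; z in [0, 1] feet->head."""
        nx, ny, nz = self.shape
        x = (np.arange(nx) + 0.5) / nx * 2.0 - 1.0
        y = (np.arange(ny) + 0.5) / ny * 2.0 - 1.0
        z = (np.arange(nz) + 0.5) / nz
        return np.meshgrid(x, y, z, indexing="ij")


@dataclass(frozen=True)
class LesionSpec:
    """One bone lesion: deformed ellipsoid with uptake and CT change.

    ``uptake`` multiplies the local activity (relative to the bone-marrow
    background of 1.0); ``ct_delta`` is the full-severity HU shift, applied
    scaled by ``uptake / UPTAKE_SEVERITY_REF``.  ``deform`` holds the radial
    perturbation modes (amplitudes, wave vectors, phases) or ``None`` for a
    pure ellipsoid.
    """

    center: tuple[int, int, int]
    semi_axes: tuple[float, float, float]
    uptake: float
    ct_delta: float
    id: int
    deform: tuple | None = None

    def __post_init__(self):
        if self.uptake <= 1.0:
            raise ValueError(f"lesion uptake must exceed 1, got {self.uptake}")
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")

    def to_json(self) -> dict:
        d = {
            "center": [int(c) for c in self.center],
            "semi_axes": [float(a) for a in self.semi_axes],
            "uptake": float(self.uptake),
            "ct_delta": float(self.ct_delta),
            "id": int(self.id),
        }
        if self.deform is not None:
            amps, kvecs, phases = self.deform
            d["deform"] = {
                "amplitudes": np.asarray(amps).tolist(),
                "wave_vectors": np.asarray(kvecs).tolist(),
                "phases": np.asarray(phases).tolist(),
            }
        return d


@dataclass
class PhantomVolume:
    """Co-registered CT, activity and label grids plus the lesion ledger."""

    grid: VoxelGrid
    ct: np.ndarray
    activity: np.ndarray
    labels: np.ndarray
    lesions: list[LesionSpec] = field(default_factory=list)

    def __post_init__(self):
        shp = self.grid.shape
        for name in ("ct", "activity", "labels"):
            arr = getattr(self, name)
            if arr.shape != shp:
                raise ValueError(f"{name} shape {arr.shape} != grid shape {shp}")
        if np.any(self.activity < 0):
            raise ValueError("activity must be nonnegative")

    @property
    def skeleton_mask(self) -> np.ndarray:
        """Bone plus lesion voxels (lesions override the bone code)."""
        return (self.labels == BONE) | (self.labels == LESION)

    @property
    def lesion_mask(self) -> np.ndarray:
        return self.labels == LESION

    @property
    def body_mask(self) -> np.ndarray:
        return self.labels != AIR

    def copy(self) -> "PhantomVolume":
        return PhantomVolume(
            grid=self.grid,
            ct=self.ct.copy(),
            activity=self.activity.copy(),
            labels=self.labels.copy(),
            lesions=list(self.lesions),
        )


@dataclass(frozen=True)
class LesionConfig:
    """Sampling ranges for random lesions (mm / HU / multipliers)."""

    semi_axis_range_mm: tuple[float, float] = (4.0, 16.0)
    uptake_range: tuple[float, float] = (2.0, 10.0)
    ct_delta_range: tuple[float, float] = (-400.0, 200.0)
    count_range: tuple[int, int] = (5, 40)
    deform_amplitude: float = 0.30
    max_retries_per_lesion: int = 10


def _ellipse(x, y, cx, cy, rx, ry):
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0


def _ellipsoid_n(x, y, z, c, r):
    """Ellipsoid in normalized coordinates."""
    return (
        ((x - c[0]) / r[0]) ** 2
        + ((y - c[1]) / r[1]) ** 2
        + ((z - c[2]) / r[2]) ** 2
        <= 1.0
    )


def build_anatomy(grid: VoxelGrid, seed: int) -> PhantomVolume:
    """Construct a lesion-free stylized whole-body phantom.

    The template is defined in coordinates relative to the grid extent
    (x, y in [-1, 1] transaxially, z in [0, 1] feet-to-head), so any grid of
    at least ~24 voxels per transaxial axis yields the same body plan:
    head with skull shell, thorax with lungs and rib rings, abdomen with
    liver/spleen/kidneys, pelvic ring, spine and femoral stubs.  All skeleton
    parts touch the spine or pelvis, making the skeleton one 26-connected
    component.  CT and activity are drawn per tissue class with mild noise.
    Deterministic for a given (grid, seed).
    """
    rng = np.random.default_rng(seed)
    x, y, z = grid.normalized_coordinates()
    labels = np.zeros(grid.shape, dtype=np.int16)

    # --- soft-tissue body envelope ---------------------------------------
    torso = _ellipse(x, y, 0.0, 0.0, 0.80, 0.58) & (z >= 0.28) & (z < 0.86)
    head = _ellipsoid_n(x, y, z, (0.0, 0.0, 0.92), (0.34, 0.34, 0.075))
    legs = (
        (_ellipse(x, y, 0.42, 0.0, 0.27, 0.27) | _ellipse(x, y, -0.42, 0.0, 0.27, 0.27))
        & (z >= 0.02)
        & (z < 0.28)
    )
    labels[torso | head | legs] = SOFT

    # --- organs -----------------------------------------------------------
    lungs = _ellipsoid_n(x, y, z, (0.33, -0.05, 0.74), (0.26, 0.32, 0.10)) | _ellipsoid_n(
        x, y, z, (-0.33, -0.05, 0.74), (0.26, 0.32, 0.10)
    )
    labels[lungs & torso] = LUNG
    liver = _ellipsoid_n(x, y, z, (0.30, 0.08, 0.565), (0.34, 0.30, 0.065))
    labels[liver & torso] = LIVER
    spleen = _ellipsoid_n(x, y, z, (-0.40, 0.02, 0.58), (0.16, 0.19, 0.05))
    labels[spleen & torso] = SPLEEN
    kidneys = _ellipsoid_n(x, y, z, (0.28, 0.28, 0.47), (0.11, 0.13, 0.05)) | _ellipsoid_n(
        x, y, z, (-0.28, 0.28, 0.47), (0.11, 0.13, 0.05)
    )
    labels[kidneys & torso] = KIDNEY

    # --- skeleton (all parts meet the spine or the pelvic ring) ----------
    spine = _ellipse(x, y, 0.0, 0.36, 0.11, 0.11) & (z >= 0.30) & (z < 0.90)
    skull = head & ~_ellipsoid_n(x, y, z, (0.0, 0.0, 0.92), (0.26, 0.26, 0.058))
    rib_band = _ellipse(x, y, 0.0, 0.02, 0.74, 0.52) & ~_ellipse(
        x, y, 0.0, 0.02, 0.62, 0.40
    )
    rib_z = np.zeros_like(z, dtype=bool)
    for zc in np.arange(0.46, 0.82, 0.07):
        rib_z |= np.abs(z - zc) < 0.016
    ribs = rib_band & rib_z & torso
    pelvis = (
        _ellipse(x, y, 0.0, 0.10, 0.62, 0.50)
        & ~_ellipse(x, y, 0.0, 0.10, 0.42, 0.32)
        & (z >= 0.29)
        & (z < 0.36)
    )
    femora = (
        _ellipse(x, y, 0.42, 0.0, 0.12, 0.12) | _ellipse(x, y, -0.42, 0.0, 0.12, 0.12)
    ) & (z >= 0.04) & (z < 0.345)
    femora &= legs | torso | pelvis
    skeleton = spine | skull | ribs | pelvis | femora

    for part, mask in (("spine", spine), ("skull", skull), ("ribs", ribs),
                       ("pelvis", pelvis), ("femora", femora)):
        if not mask.any():
            raise ValueError(
                f"grid {grid.shape} too small to contain the skeleton template "
                f"(empty {part})"
            )
    labels[skeleton] = BONE

    # --- CT ---------------------------------------------------------------
    ct = np.full(grid.shape, CT_MEANS[AIR], dtype=np.float32)
    for code, mean in CT_MEANS.items():
        if code == AIR:
            continue
        ct[labels == code] = mean
    # trabecular/cortical gradation: a smooth random field, not voxel noise
    bone_idx = labels == BONE
    bone_field = ndimage.gaussian_filter(rng.standard_normal(grid.shape), sigma=1.5)
    bone_field /= max(bone_field.std(), 1e-12)
    ct[bone_idx] = np.clip(
        BONE_HU_MEAN + BONE_HU_SD * bone_field[bone_idx], *BONE_HU_RANGE
    )
    body = labels != AIR
    ct[body] += rng.normal(0.0, CT_NOISE_HU, size=int(body.sum()))

    # --- activity ---------------------------------------------------------
    activity = np.zeros(grid.shape, dtype=np.float32)
    for code, mean in ACTIVITY_MEANS.items():
        activity[labels == code] = mean
    noise = ndimage.gaussian_filter(rng.standard_normal(grid.shape), sigma=2.0)
    noise /= max(noise.std(), 1e-12)
    activity *= np.clip(1.0 + ACTIVITY_NOISE_FRACTION * noise, 0.0, None).astype(
        np.float32
    )

    return PhantomVolume(grid=grid, ct=ct, activity=activity, labels=labels)


def _lesion_mask(grid: VoxelGrid, lesion: LesionSpec) -> np.ndarray:
    """Binary mask of a (possibly deformed) ellipsoidal lesion, clipped to grid."""
    shape = grid.shape
    spacing = np.asarray(grid.spacing)
    semi = np.asarray(lesion.semi_axes, dtype=float)
    center = np.asarray(lesion.center, dtype=float)
    # bounding box with deformation headroom
    margin = semi * 1.4 / spacing + 1
    lo = np.maximum(np.floor(center - margin).astype(int), 0)
    hi = np.minimum(np.ceil(center + margin).astype(int) + 1, shape)
    if np.any(lo >= hi):
        warnings.warn(f"lesion {lesion.id} lies outside the grid; clipped away")
        return np.zeros(shape, dtype=bool)
    idx = [np.arange(lo[a], hi[a]) for a in range(3)]
    ii, jj, kk = np.meshgrid(*idx, indexing="ij")
    # offsets in mm from lesion center
    d = np.stack(
        [(g - c) * s for g, c, s in zip((ii, jj, kk), center, spacing)], axis=-1
    )
    rho = np.sqrt(np.sum((d / semi) ** 2, axis=-1))  # 1.0 = ellipsoid surface
    if lesion.deform is not None:
        amps, kvecs, phases = lesion.deform
        amps = np.asarray(amps, dtype=float)
        kvecs = np.asarray(kvecs, dtype=float)
        phases = np.asarray(phases, dtype=float)
        norm = np.maximum(np.linalg.norm(d, axis=-1, keepdims=True), 1e-9)
        u = d / norm
        pert = np.zeros(rho.shape)
        for a, kv, ph in zip(amps, kvecs, phases):
            pert += a * np.cos(u @ kv + ph)
        boundary = np.clip(1.0 + pert, 0.7, 1.3)  # radial warp <= 30 %
    else:
        boundary = 1.0
    sub = rho <= boundary
    mask = np.zeros(shape, dtype=bool)
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = sub
    return mask


def _draw_deform(rng: np.random.Generator, amplitude: float) -> tuple:
    """Low-frequency radial perturbation: 3 cosine modes summing to <= amplitude."""
    amps = rng.uniform(0.0, amplitude / 3.0, size=3)
    kvecs = rng.uniform(-2.5, 2.5, size=(3, 3))
    phases = rng.uniform(0.0, 2 * np.pi, size=3)
    return (amps, kvecs, phases)


def sample_lesions(
    phantom: PhantomVolume,
    n_range: tuple[int, int] | None = None,
    seed: int = 0,
    config: LesionConfig | None = None,
) -> list[LesionSpec]:
    """Draw random lesions with centers uniform over skeleton voxels.

    The lesion count is uniform over ``n_range`` (inclusive).  Candidates
    overlapping an already accepted lesion are redrawn up to a bounded retry
    budget; if the budget is exhausted a warning is logged and fewer lesions
    are returned.
    """
    config = config or LesionConfig()
    if n_range is None:
        n_range = config.count_range
    rng = np.random.default_rng(seed)
    lo, hi = int(n_range[0]), int(n_range[1])
    n = int(rng.integers(lo, hi + 1))
    if n == 0:
        return []
    skeleton = phantom.labels == BONE
    sk_idx = np.argwhere(skeleton)
    if len(sk_idx) == 0:
        raise ValueError("phantom has an empty skeleton; cannot place lesions")

    occupied = np.zeros(phantom.grid.shape, dtype=bool)
    lesions: list[LesionSpec] = []
    next_id = 0
    for _ in range(n):
        placed = False
        for _try in range(config.max_retries_per_lesion):
            center = tuple(int(c) for c in sk_idx[rng.integers(len(sk_idx))])
            semi = tuple(rng.uniform(*config.semi_axis_range_mm, size=3))
            uptake = float(rng.uniform(*config.uptake_range))
            ct_delta = float(rng.uniform(*config.ct_delta_range))
            deform = _draw_deform(rng, config.deform_amplitude)
            cand = LesionSpec(
                center=center,
                semi_axes=semi,
                uptake=uptake,
                ct_delta=ct_delta,
                id=next_id,
                deform=deform,
            )
            mask = _lesion_mask(phantom.grid, cand)
            if mask.any() and not (mask & occupied).any():
                occupied |= mask
                lesions.append(cand)
                next_id += 1
                placed = True
                break
        if not placed:
            logger.warning(
                "lesion retry budget exhausted: placed %d of %d lesions",
                len(lesions),
                n,
            )
            break
    return lesions


def apply_lesions(
    phantom: PhantomVolume, lesions: list[LesionSpec]
) -> PhantomVolume:
    """Insert lesions into a phantom: label, activity and CT modification.

    Inside each lesion mask the label becomes :data:`LESION`, activity is
    multiplied by the lesion uptake, and CT is shifted by ``ct_delta`` scaled
    by severity (uptake relative to :data:`UPTAKE_SEVERITY_REF`).  Re-applying
    a lesion id already present is a no-op, so the operation is idempotent
    per lesion.  Returns a new phantom.
    """
    out = phantom.copy()
    present = {les.id for les in out.lesions}
    for lesion in lesions:
        if lesion.id in present:
            continue
        mask = _lesion_mask(out.grid, lesion)
        if not mask.any():
            continue
        out.labels[mask] = LESION
        out.activity[mask] *= lesion.uptake
        severity = min(lesion.uptake / UPTAKE_SEVERITY_REF, 1.0)
        out.ct[mask] += lesion.ct_delta * severity
        out.lesions.append(lesion)
        present.add(lesion.id)
    return out


def make_phantom(
    grid: VoxelGrid,
    seed: int,
    lesion_config: LesionConfig | None = None,
) -> PhantomVolume:
    """Convenience: anatomy + sampled lesions, all from one seed."""
    base = build_anatomy(grid, seed)
    lesions = sample_lesions(base, seed=seed + 1, config=lesion_config)
    return apply_lesions(base, lesions)


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a simulated cohort (grid, lesions, acquisition)."""

    grid_shape: tuple[int, int, int] = (96, 96, 192)
    spacing_mm: float = 4.0
    lesions: LesionConfig = field(default_factory=LesionConfig)
    mlem_iterations: int = 20

    def make_grid(self) -> VoxelGrid:
        return VoxelGrid(shape=self.grid_shape, spacing=(self.spacing_mm,) * 3)


def derive_seed(base_seed: int, index: int, stream: int = 0) -> int:
    """Stable per-phantom seed derivation (kept below 2**31)."""
    return int((base_seed * 100003 + 7919 * index + 104729 * stream) % (2**31 - 1))


def generate_cohort(
    n: int = 70,
    base_seed: int = 0,
    config: CohortConfig | None = None,
    outdir: str | Path = "cohort",
) -> dict:
    """Simulate ``n`` phantoms with PET measurements and write them to disk.

    Each phantom gets a distinct derived seed for anatomy/lesions and for the
    measurement noise.  Per phantom the CT, reconstructed PET and label
    volumes are written as NIfTI-1, the sinogram as HDF5, and a JSON manifest
    indexes the cohort.  On failure, partially written files are removed.
    """
    from . import petsim, volio

    if n < 1:
        raise ValueError("cohort size must be >= 1")
    config = config or CohortConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = config.make_grid()
    model = petsim.AcquisitionModel(mlem_iterations=config.mlem_iterations)
    projector = petsim.ParallelProjector.for_grid(grid)

    manifest = {"n": n, "base_seed": int(base_seed), "entries": []}
    written: list[Path] = []
    try:
        for i in range(n):
            phantom_seed = derive_seed(base_seed, i, stream=0)
            noise_seed = derive_seed(base_seed, i, stream=1)
            ph = make_phantom(grid, phantom_seed, config.lesions)
            result = petsim.simulate_study(
                ph, model, seed=noise_seed, projector=projector
            )
            case = f"phantom_{i:03d}"
            paths = {
                "ct": outdir / f"{case}_ct.nii.gz",
                "pet": outdir / f"{case}_pet.nii.gz",
                "labels": outdir / f"{case}_labels.nii.gz",
                "sinogram": outdir / f"{case}_sino.h5",
            }
            volio.write_volume(ph.ct, grid, paths["ct"])
            volio.write_volume(result.reconstruction, grid, paths["pet"])
            volio.write_volume(ph.labels, grid, paths["labels"])
            volio.write_sinogram(result.counts, paths["sinogram"],
                                 expectation=result.expectation)
            written.extend(paths.values())
            manifest["entries"].append(
                {
                    "case": case,
                    "phantom_seed": phantom_seed,
                    "noise_seed": noise_seed,
                    "n_lesions": len(ph.lesions),
                    "lesions": [les.to_json() for les in ph.lesions],
                    "files": {k: str(v.name) for k, v in paths.items()},
                }
            )
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def skeleton_components(phantom: PhantomVolume) -> int:
    """Number of 26-connected components of the skeleton mask."""
    _, num = ndimage.label(phantom.skeleton_mask, structure=np.ones((3, 3, 3)))
    return int(num)
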