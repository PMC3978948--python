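"""Synthetic knee-MR phantoms with ground-truth bone and lesion masks.

The phantoms emulate the geometry of a sagittal fat-suppressed knee
acquisition: an anisotropic voxel grid (default in-plane 0.357 x 0.511 mm,
3 mm slices), two bones (femur above the joint line, tibia below) modelled
as super-ellipsoids, and bright bone-marrow-lesion (BML) ellipsoids placed
inside a bone near its articular surface.  Every generator is a pure
function of its spec and seed.

Axes convention: arrays are indexed ``(x, y, z)`` where ``x`` and ``y`` are
in-plane and ``z`` is the slice (medial/lateral) axis.  World coordinates
are ``index * spacing`` in mm, 0-based.  The medial side is ``z <= split``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

MM3_PER_CM3 = 1000.0

DEFAULT_SPACING = (0.357, 0.511, 3.0)


@dataclass(frozen=True)
class BoneSpec:
    """A super-ellipsoid bone: |X/rx|^e + |Y/ry|^e + |Z/rz|^e <= 1 (mm)."""

    name: str
    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    exponent: float = 3.0
    #: +1 if the articular surface faces +y (femur sits above the joint
    #: line at smaller y), -1 if it faces -y (tibia).
    articular_dir: int = 1


@dataclass(frozen=True)
class LesionSpec:
    """An ellipsoidal hyperintense lesion inside a host bone.

    ``contrast_sd`` is the intensity offset above bone interior in units of
    the phantom noise SD (raw intensity units when the phantom is
    noiseless).
    """

    name: str
    bone: str
    center_mm: tuple[float, float, float]
    target_volume_cm3: float
    contrast_sd: float = 4.0
    #: relative axis lengths; scaled so the ellipsoid hits target volume.
    aspect: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def radii_mm(self) -> tuple[float, float, float]:
        ax, ay, az = self.aspect
        if min(ax, ay, az) <= 0:
            raise ValueError(f"lesion {self.name!r}: aspect must be positive")
        v_mm3 = self.target_volume_cm3 * MM3_PER_CM3
        s = (3.0 * v_mm3 / (4.0 * np.pi * ax * ay * az)) ** (1.0 / 3.0)
        return (ax * s, ay * s, az * s)


def _default_bones() -> tuple[BoneSpec, BoneSpec]:
    return (
        BoneSpec("femur", center_mm=(22.8, 19.0, 36.0), radii_mm=(18.0, 14.0, 30.0),
                 articular_dir=+1),
        BoneSpec("tibia", center_mm=(22.8, 48.0, 36.0), radii_mm=(18.0, 12.0, 30.0),
                 articular_dir=-1),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic knee volume."""

    shape: tuple[int, int, int] = (128, 128, 24)
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING
    bones: tuple[BoneSpec, ...] = field(default_factory=_default_bones)
    lesions: tuple[LesionSpec, ...] = ()
    background_intensity: float = 70.0
    bone_intensity: float = 40.0
    noise_sd: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if any(int(s) <= 0 for s in self.shape):
            raise ValueError("phantom shape must be positive")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        names = [b.name for b in self.bones]
        if len(set(names)) != len(names):
            raise ValueError("bone names must be unique")
        for les in self.lesions:
            if les.bone not in names:
                raise ValueError(
                    f"lesion {les.name!r} references unknown bone {les.bone!r}")
            if les.target_volume_cm3 <= 0:
                raise ValueError(f"lesion {les.name!r}: target volume must be > 0")


@dataclass
class TrueLesion:
    """Ground-truth record for one lesion."""

    name: str
    bone: str
    voxels: np.ndarray          # (N, 3) int indices
    volume_cm3: float
    region: str                 # e.g. "medial tibia"


@dataclass
class GroundTruth:
    """Oracle masks and volumes for a generated phantom."""

    spec: PhantomSpec
    bone_masks: dict[str, np.ndarray]
    articular_masks: dict[str, np.ndarray]
    lesions: list[TrueLesion]
    split_z_mm: float

    @property
    def voxel_volume_cm3(self) -> float:
        dx, dy, dz = self.spec.spacing_mm
        return dx * dy * dz / MM3_PER_CM3

    def lesion_union(self) -> np.ndarray:
        out = np.zeros(self.spec.shape, dtype=bool)
        for les in self.lesions:
            out[tuple(les.voxels.T)] = True
        return out

    def total_volume_cm3(self) -> float:
        return float(sum(les.volume_cm3 for les in self.lesions))


def _world_grids(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _superellipsoid_mask(shape, spacing, center, radii, exponent):
    xg, yg, zg = _world_grids(shape, spacing)
    t = (np.abs((xg - center[0]) / radii[0]) ** exponent
         + np.abs((yg - center[1]) / radii[1]) ** exponent
         + np.abs((zg - center[2]) / radii[2]) ** exponent)
    return t <= 1.0


def _rasterize_exact_count(shape, spacing, center, radii, n_target):
    """The ``n_target`` voxels closest (in scaled ellipsoid metric) to the
    lesion centre: an ellipsoidal voxel set with an exact count, so true
    volumes are quantisation-exact."""
    margin = 2.0
    lo = [max(0, int(np.floor((c - margin * r) / s)))
          for c, r, s in zip(center, radii, spacing)]
    hi = [min(n, int(np.ceil((c + margin * r) / s)) + 1)
          for c, r, s, n in zip(center, radii, spacing, shape)]
    axes = [np.arange(a, b) * s for a, b, s in zip(lo, hi, spacing)]
    if any(ax.size == 0 for ax in axes):
        raise ValueError("lesion bounding box lies outside the volume")
    xg, yg, zg = np.meshgrid(*axes, indexing="ij", sparse=True)
    t = (((xg - center[0]) / radii[0]) ** 2
         + ((yg - center[1]) / radii[1]) ** 2
         + ((zg - center[2]) / radii[2]) ** 2)
    flat = np.argsort(t, axis=None, kind="stable")[:n_target]
    if flat.size < n_target:
        raise ValueError("lesion larger than its search window")
    idx = np.column_stack(np.unravel_index(flat, t.shape))
    return idx + np.array(lo)


def _exposed_surface(mask: np.ndarray, direction: int) -> np.ndarray:
    """Boundary voxels of ``mask`` whose +/-y neighbour lies outside."""
    shifted = np.zeros_like(mask)
    if direction > 0:
        shifted[:, :-1, :] = mask[:, 1:, :]
    else:
        shifted[:, 1:, :] = mask[:, :-1, :]
    return mask & ~shifted


def region_label(bone: str, z_mm: float, split_z_mm: float) -> str:
    """Medial/lateral x bone label; the tie at the split goes medial."""
    side = "medial" if z_mm <= split_z_mm else "lateral"
    return f"{side} {bone}"


def generate_knee_phantom(spec: PhantomSpec):
    """Rasterise a phantom and its ground truth.

    Returns ``(volume, truth)`` where ``volume`` is a
    :class:`bmlpipe.segmentation.MRVolume`.  Lesions are brighter than the
    bone interior by ``contrast_sd`` noise SDs; the noiseless bone interior
    is exactly ``spec.bone_intensity``.
    """
    from .segmentation import MRVolume  # local import to avoid a cycle

    spec.validate()
    shape = tuple(int(s) for s in spec.shape)
    spacing = spec.spacing_mm
    rng = np.random.default_rng(spec.seed)

    vol = np.full(shape, spec.background_intensity, dtype=np.float64)
    bone_masks: dict[str, np.ndarray] = {}
    articular: dict[str, np.ndarray] = {}
    for bone in spec.bones:
        m = _superellipsoid_mask(shape, spacing, bone.center_mm,
                                 bone.radii_mm, bone.exponent)
        bone_masks[bone.name] = m
        articular[bone.name] = _exposed_surface(m, bone.articular_dir)
        vol[m] = spec.bone_intensity

    split_z_mm = (shape[2] - 1) * spacing[2] / 2.0
    voxel_cm3 = spacing[0] * spacing[1] * spacing[2] / MM3_PER_CM3
    contrast_unit = spec.noise_sd if spec.noise_sd > 0 else 1.0

    occupied = np.zeros(shape, dtype=bool)
    lesions: list[TrueLesion] = []
    for les in spec.lesions:
        n_target = int(round(les.target_volume_cm3 * MM3_PER_CM3
                             / (voxel_cm3 * MM3_PER_CM3)))
        if n_target <= 0:
            raise ValueError(f"lesion {les.name!r} rasterises to zero voxels")
        idx = _rasterize_exact_count(shape, spacing, les.center_mm,
                                     les.radii_mm(), n_target)
        lm = np.zeros(shape, dtype=bool)
        lm[tuple(idx.T)] = True
        host = bone_masks[les.bone]
        if not (lm <= host).all():
            raise ValueError(
                f"lesion {les.name!r} extends outside bone {les.bone!r}")
        if (lm & occupied).any():
            raise ValueError(f"lesion {les.name!r} overlaps another lesion")
        occupied |= lm
        vol[lm] = spec.bone_intensity + les.contrast_sd * contrast_unit
        cz_mm = float(idx[:, 2].mean() * spacing[2])
        lesions.append(TrueLesion(
            name=les.name, bone=les.bone, voxels=idx,
            volume_cm3=idx.shape[0] * voxel_cm3,
            region=region_label(les.bone, cz_mm, split_z_mm)))

    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=shape)

    truth = GroundTruth(spec=spec, bone_masks=bone_masks,
                        articular_masks=articular, lesions=lesions,
                        split_z_mm=split_z_mm)
    return MRVolume(data=vol, spacing_mm=spacing), truth


def demo_phantom_spec(seed: int = 0, noise_sd: float = 3.0) -> PhantomSpec:
    """A two-lesion phantom whose lesions survive the central-slice
    exclusion: 1.0 cm^3 in the lateral tibia, 0.5 cm^3 in the medial femur,
    both within 10 mm of the articular surface."""
    return PhantomSpec(
        lesions=(
            LesionSpec("lat_tibia", "tibia", (22.8, 44.0, 55.0), 1.0,
                       contrast_sd=4.0),
            LesionSpec("med_femur", "femur", (22.8, 25.0, 14.0), 0.5,
                       contrast_sd=4.0, aspect=(1.3, 1.0, 0.5)),
        ),
        noise_sd=noise_sd, seed=seed)


# ---------------------------------------------------------------------------
# boundary annotations

def generate_annotation(truth: GroundTruth, jitter_mm: float = 0.0,
                        seed: int = 0, points_per_slice: int = 28):
    """Simulate a reader marking coarse per-slice bone boundaries.

    Points are sampled along each bone's true in-slice contour (ordered,
    closed loop) and displaced by at most ``jitter_mm``; points on the
    articular side are flagged, the rest stand for the far cutoff marked
    just short of the epiphyseal line.
    """
    from skimage import measure

    from .segmentation import AnnotationSlice, BoundaryAnnotation

    if jitter_mm < 0:
        raise ValueError("jitter must be non-negative")
    if not truth.bone_masks:
        raise ValueError("ground truth contains no bones")
    rng = np.random.default_rng(seed)
    dx, dy, _ = truth.spec.spacing_mm
    art_dirs = {b.name: b.articular_dir for b in truth.spec.bones}
    centers_y = {b.name: b.center_mm[1] for b in truth.spec.bones}

    slices: dict[str, dict[int, AnnotationSlice]] = {}
    for name, mask in truth.bone_masks.items():
        per_slice: dict[int, AnnotationSlice] = {}
        for z in range(mask.shape[2]):
            sl = mask[:, :, z]
            if sl.sum() < 9:
                continue
            contours = measure.find_contours(sl.astype(float), 0.5)
            if not contours:
                continue
            contour = max(contours, key=len)          # (x_idx, y_idx) rows
            pts_mm = contour * np.array([dx, dy])
            pts = _resample_closed(pts_mm, points_per_slice)
            if jitter_mm > 0:
                ang = rng.uniform(0, 2 * np.pi, size=len(pts))
                mag = rng.uniform(0, jitter_mm, size=len(pts))
                pts = pts + np.c_[np.cos(ang), np.sin(ang)] * mag[:, None]
            art = (pts[:, 1] > centers_y[name]) if art_dirs[name] > 0 \
                else (pts[:, 1] < centers_y[name])
            per_slice[z] = AnnotationSlice(points_mm=pts, articular=art)
        slices[name] = per_slice
    return BoundaryAnnotation(slices=slices, articular_dir=art_dirs,
                              split_z_mm=truth.split_z_mm)


def _resample_closed(pts: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to n points uniform in arclength."""
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    tgt = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(tgt, s, closed[:, 0])
    out[:, 1] = np.interp(tgt, s, closed[:, 1])
    return out


# ---------------------------------------------------------------------------
# follow-up phantoms

@dataclass(frozen=True)
class LesionChange:
    """Volume delta (cm^3) for one baseline lesion; shrink past zero removes."""

    name: str
    delta_cm3: float


@dataclass(frozen=True)
class FollowupSpec:
    changes: tuple[LesionChange, ...] = ()
    incident: tuple[LesionSpec, ...] = ()


def generate_followup_phantom(baseline: GroundTruth, change_spec: FollowupSpec,
                              seed: int = 1):
    """Re-generate the phantom with per-lesion volume deltas applied.

    Follow-up true volumes equal baseline truth plus the requested deltas up
    to voxel quantisation; a lesion shrunk to or below zero is removed.
    """
    by_name = {l.name: l for l in baseline.spec.lesions}
    for ch in change_spec.changes:
        if ch.name not in by_name:
            raise ValueError(f"unknown lesion {ch.name!r} in change spec")
    deltas = {ch.name: ch.delta_cm3 for ch in change_spec.changes}

    new_lesions: list[LesionSpec] = []
    for les in baseline.spec.lesions:
        # target the realised (rasterised) baseline volume, so the delta is
        # applied to what the oracle actually measured
        base_v = next(t.volume_cm3 for t in baseline.lesions
                      if t.name == les.name)
        new_v = base_v + deltas.get(les.name, 0.0)
        if new_v <= 0:
            continue
        new_lesions.append(replace(les, target_volume_cm3=new_v))
    new_lesions.extend(change_spec.incident)

    fu_spec = replace(baseline.spec, lesions=tuple(new_lesions), seed=seed)
    return generate_knee_phantom(fu_spec)
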