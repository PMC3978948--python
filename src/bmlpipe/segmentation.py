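"""Semi-automated bone and hyperintensity segmentation.

Stage 1 refines coarse per-slice bone annotations into closed contours with
an edge-attracted active-contour step, yielding filled bone masks and the
articular-surface voxel set.  Stage 2 runs a thresholding + two-phase
piecewise-constant curve-evolution pass twice inside the bone masks to pick
out hyperintense (probable bone-marrow-lesion) voxels: the second pass
re-estimates the interior statistics with the first pass's detections
excluded, and the two passes are unioned.  Stage 3 extracts 26-connected
candidate components with slice span and anisotropic distance to the
articular surface, ready for the lesion-definition filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.segmentation import morphological_chan_vese


@dataclass
class MRVolume:
    """Anisotropic 3-D intensity volume, axes (x, y, slice), spacing in mm."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("volume must be 3-D")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError("volume intensities must be finite")

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    @property
    def voxel_volume_cm3(self) -> float:
        dx, dy, dz = self.spacing_mm
        return dx * dy * dz / 1000.0


@dataclass
class AnnotationSlice:
    """Ordered boundary points (mm) on one slice; articular flags per point."""

    points_mm: np.ndarray
    articular: np.ndarray


@dataclass
class BoundaryAnnotation:
    """Coarse reader-marked bone boundaries, per bone and slice."""

    slices: dict[str, dict[int, AnnotationSlice]]
    articular_dir: dict[str, int]
    split_z_mm: float

    def bones(self) -> list[str]:
        return list(self.slices)


@dataclass
class BoneMask:
    """Refined per-bone masks plus articular-surface voxels and the
    medial/lateral split coordinate (mm along the slice axis)."""

    masks: dict[str, np.ndarray]
    articular_masks: dict[str, np.ndarray]
    split_z_mm: float

    def union(self) -> np.ndarray:
        out = None
        for m in self.masks.values():
            out = m.copy() if out is None else (out | m)
        return out

    def articular_union(self) -> np.ndarray:
        out = None
        for m in self.articular_masks.values():
            out = m.copy() if out is None else (out | m)
        return out


@dataclass
class CandidateMask:
    """Probable-BML voxels inside bone; per-pass masks retained."""

    mask: np.ndarray
    pass1: np.ndarray
    pass2: np.ndarray


@dataclass
class LesionCandidate:
    """A 26-connected hyperintense component within one bone."""

    voxels: np.ndarray            # (N, 3) int indices
    voxel_dists_mm: np.ndarray    # distance to articular surface per voxel
    slice_span: int
    min_surface_dist_mm: float
    centroid_mm: tuple[float, float, float]
    bone: str | None = None
    region: str | None = None

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.shape[0])

    def volume_cm3(self, spacing_mm) -> float:
        dx, dy, dz = spacing_mm
        return self.n_voxels * dx * dy * dz / 1000.0


def _exposed_surface(mask: np.ndarray, direction: int) -> np.ndarray:
    shifted = np.zeros_like(mask)
    if direction > 0:
        shifted[:, :-1, :] = mask[:, 1:, :]
    else:
        shifted[:, 1:, :] = mask[:, :-1, :]
    return mask & ~shifted


# ---------------------------------------------------------------------------
# bone boundary refinement

def refine_bone_boundary(vol: MRVolume, ann: BoundaryAnnotation,
                         iterations: int = 8, search_mm: float = 1.5,
                         step: float = 0.4, smooth_window: int = 5,
                         dense_points: int = 240) -> BoneMask:
    """Refine coarse annotations into filled bone masks.

    Per slice, the annotated points are resampled to a dense closed contour
    which is then attracted to the strongest intensity edge along its local
    normal (within ``search_mm``) for a fixed number of iterations, with a
    circular moving-average smoothing step; the final polygon is rasterised
    and filled.
    """
    dx, dy, _ = vol.spacing_mm
    scale = np.array([dx, dy])
    shape = vol.data.shape

    masks: dict[str, np.ndarray] = {}
    articular: dict[str, np.ndarray] = {}
    for bone, per_slice in ann.slices.items():
        mask = np.zeros(shape, dtype=bool)
        for z, sl in sorted(per_slice.items()):
            pts = np.asarray(sl.points_mm, dtype=float)
            if pts.shape[0] < 3:
                raise ValueError(
                    f"bone {bone!r}, slice {z}: need >= 3 annotation points")
            img = vol.data[:, :, z]
            grad = ndimage.gaussian_gradient_magnitude(img, sigma=1.0)
            contour = _resample_closed_mm(pts, dense_points)
            for _ in range(iterations):
                contour = _attract_to_edges(contour, grad, scale,
                                            search_mm, step)
                contour = _smooth_closed(contour, smooth_window)
            sl_mask = _fill_contour(contour / scale, shape[:2])
            if sl_mask.sum() < 3:
                raise ValueError(
                    f"bone {bone!r}, slice {z}: contour failed to close")
            mask[:, :, z] = sl_mask
        # bones must stay disjoint; later bones yield on overlap
        for prev in masks.values():
            mask &= ~prev
        masks[bone] = mask
        articular[bone] = _exposed_surface(mask, ann.articular_dir[bone])
    return BoneMask(masks=masks, articular_masks=articular,
                    split_z_mm=ann.split_z_mm)


def _resample_closed_mm(pts: np.ndarray, n: int) -> np.ndarray:
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    tgt = np.linspace(0.0, s[-1], n, endpoint=False)
    return np.c_[np.interp(tgt, s, closed[:, 0]),
                 np.interp(tgt, s, closed[:, 1])]


def _attract_to_edges(contour, grad, scale, search_mm, step):
    nxt = np.roll(contour, -1, axis=0)
    prv = np.roll(contour, 1, axis=0)
    tang = nxt - prv
    norms = np.c_[-tang[:, 1], tang[:, 0]]
    lens = np.linalg.norm(norms, axis=1)
    lens[lens == 0] = 1.0
    norms /= lens[:, None]

    offsets = np.arange(-search_mm, search_mm + 1e-9, 0.25)
    # sample gradient magnitude at contour +/- offset * normal (mm space)
    samples = contour[None, :, :] + offsets[:, None, None] * norms[None, :, :]
    idx = samples / scale
    gx = np.clip(idx[..., 0], 0, grad.shape[0] - 1)
    gy = np.clip(idx[..., 1], 0, grad.shape[1] - 1)
    vals = ndimage.map_coordinates(grad, [gx.ravel(), gy.ravel()],
                                   order=1).reshape(gx.shape)
    best = offsets[np.argmax(vals, axis=0)]
    return contour + step * best[:, None] * norms


def _smooth_closed(contour: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return contour
    kernel = np.ones(window) / window
    out = np.empty_like(contour)
    for j in range(2):
        ext = np.concatenate([contour[-window:, j], contour[:, j],
                              contour[:window, j]])
        out[:, j] = np.convolve(ext, kernel, mode="same")[window:-window]
    return out


def _fill_contour(idx_pts: np.ndarray, shape2d) -> np.ndarray:
    rr, cc = draw_polygon(idx_pts[:, 0], idx_pts[:, 1], shape=shape2d)
    out = np.zeros(shape2d, dtype=bool)
    out[rr, cc] = True
    return out


# ---------------------------------------------------------------------------
# hyperintensity detection

@dataclass(frozen=True)
class DetectionParams:
    """Threshold and curve-evolution controls.

    ``k`` is the per-bone threshold in interior SD units (mean + k*SD);
    the evolution is a two-phase piecewise-constant (Chan-Vese type)
    morphological scheme seeded by the supra-threshold voxels.
    """

    k: float = 1.5
    iterations: int = 20
    smoothing: int = 2
    lambda1: float = 1.0
    lambda2: float = 1.0

    def validate(self) -> None:
        if self.k <= 0:
            raise ValueError("threshold multiplier k must be positive")
        if self.iterations < 0:
            raise ValueError("iteration budget must be non-negative")


def threshold_seed(vol: MRVolume, bone_mask: np.ndarray, k: float,
                   exclude: np.ndarray | None = None) -> np.ndarray:
    """Supra-threshold voxels at interior mean + k*SD (stats exclude
    ``exclude`` voxels, e.g. a previous pass's detections)."""
    stat_mask = bone_mask if exclude is None else (bone_mask & ~exclude)
    vals = vol.data[stat_mask]
    if vals.size == 0:
        return np.zeros_like(bone_mask)
    mu, sd = float(vals.mean()), float(vals.std())
    if sd == 0:
        return np.zeros_like(bone_mask)
    return bone_mask & (vol.data > mu + k * sd)


def _evolve(vol: MRVolume, bone_mask: np.ndarray, seed_mask: np.ndarray,
            params: DetectionParams) -> np.ndarray:
    """Slice-wise two-phase piecewise-constant evolution from the seed.

    The curves live in-plane (the slice spacing is an order of magnitude
    coarser than the pixel spacing, so isotropic 3-D morphology would
    erode lesions along the slice axis); each annotated slice evolves its
    own closed curves and the results are stacked.
    """
    out = np.zeros_like(bone_mask)
    if not seed_mask.any():
        return out
    interior_mean = float(vol.data[bone_mask].mean())
    for z in np.flatnonzero(seed_mask.any(axis=(0, 1))):
        bone_sl = bone_mask[:, :, z]
        img = vol.data[:, :, z].copy()
        img[~bone_sl] = interior_mean
        evolved = morphological_chan_vese(
            img, num_iter=params.iterations,
            init_level_set=seed_mask[:, :, z].astype(np.int8),
            smoothing=params.smoothing, lambda1=params.lambda1,
            lambda2=params.lambda2).astype(bool)
        evolved &= bone_sl
        if not evolved.any():
            continue
        # the two-phase labelling is arbitrary; keep the bright phase
        rest = bone_sl & ~evolved
        if rest.any() and vol.data[:, :, z][evolved].mean() < \
                vol.data[:, :, z][rest].mean():
            evolved = rest
        out[:, :, z] = evolved
    return out


def detect_hyperintensities(vol: MRVolume, bones: BoneMask,
                            params: DetectionParams | None = None
                            ) -> CandidateMask:
    """Two-pass threshold + curve-evolution hyperintensity detection.

    Pass 1 thresholds each bone interior at mean + k*SD and evolves a
    region-based curve from the seed; pass 2 re-estimates the interior
    statistics excluding pass-1 voxels and repeats.  The result is the
    union, always restricted to the bone masks.
    """
    params = params or DetectionParams()
    params.validate()
    if not any(m.any() for m in bones.masks.values()):
        raise ValueError("bone mask is empty")

    pass1 = np.zeros(vol.data.shape, dtype=bool)
    pass2 = np.zeros(vol.data.shape, dtype=bool)
    for bone_mask in bones.masks.values():
        if not bone_mask.any():
            continue
        seed1 = threshold_seed(vol, bone_mask, params.k)
        det1 = _evolve(vol, bone_mask, seed1, params)
        pass1 |= det1
        seed2 = threshold_seed(vol, bone_mask, params.k, exclude=det1)
        seed2 &= ~det1
        det2 = _evolve(vol, bone_mask & ~det1, seed2, params)
        pass2 |= det2
    return CandidateMask(mask=pass1 | pass2, pass1=pass1, pass2=pass2)


# ---------------------------------------------------------------------------
# candidate extraction

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def extract_candidates(mask: CandidateMask | np.ndarray, vol: MRVolume,
                       bones: BoneMask) -> list[LesionCandidate]:
    """26-connected components with slice span and articular distance.

    Distances are Euclidean in mm under the anisotropic spacing, measured
    from each candidate voxel to the nearest articular-surface voxel.
    """
    arr = mask.mask if isinstance(mask, CandidateMask) else mask
    if arr.shape != vol.data.shape:
        raise ValueError("candidate mask not aligned with volume")
    labels, n = ndimage.label(arr, structure=_STRUCT_26)
    if n == 0:
        return []

    surface = bones.articular_union()
    if surface is None or not surface.any():
        dist_vol = np.full(arr.shape, np.inf)
    else:
        dist_vol = ndimage.distance_transform_edt(
            ~surface, sampling=vol.spacing_mm)

    spacing = np.asarray(vol.spacing_mm)
    out: list[LesionCandidate] = []
    for lab in range(1, n + 1):
        vox = np.argwhere(labels == lab)
        dists = dist_vol[tuple(vox.T)]
        centroid = tuple((vox.mean(axis=0) * spacing).tolist())
        out.append(LesionCandidate(
            voxels=vox, voxel_dists_mm=dists,
            slice_span=int(np.unique(vox[:, 2]).size),
            min_surface_dist_mm=float(dists.min()),
            centroid_mm=centroid))
    return out
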