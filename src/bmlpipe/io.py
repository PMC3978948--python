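"""File formats: NIfTI volumes and label masks, JSON annotations, CSV
cohort tables."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import COHORT_COLUMNS
from .segmentation import AnnotationSlice, BoundaryAnnotation, BoneMask, MRVolume


def save_volume(vol: MRVolume, path) -> None:
    affine = np.diag([*vol.spacing_mm, 1.0])
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), affine), str(path))


def load_volume(path) -> MRVolume:
    img = nib.load(str(path))
    # pixdim is float32; round away the representation error
    spacing = tuple(round(float(z), 6) for z in img.header.get_zooms()[:3])
    return MRVolume(data=np.asarray(img.dataobj, dtype=np.float64),
                    spacing_mm=spacing)


def save_labels(mask: np.ndarray, spacing_mm, path) -> None:
    affine = np.diag([*spacing_mm, 1.0])
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def load_labels(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj).astype(np.uint8)


def save_bone_mask(bones: BoneMask, spacing_mm, path) -> None:
    """Bone masks as one label volume (femur = 1, tibia = 2, ...) with a
    sidecar JSON naming the labels, the articular voxels and the split."""
    path = Path(path)
    lab = np.zeros(next(iter(bones.masks.values())).shape, dtype=np.uint8)
    names = {}
    art = {}
    for i, (name, m) in enumerate(bones.masks.items(), start=1):
        lab[m] = i
        names[str(i)] = name
        art[name] = np.argwhere(bones.articular_masks[name]).tolist()
    save_labels(lab, spacing_mm, path)
    sidecar = {"labels": names, "split_z_mm": bones.split_z_mm,
               "articular_voxels": art}
    path.with_suffix("").with_suffix(".json").write_text(
        json.dumps(sidecar))


def load_bone_mask(path) -> BoneMask:
    path = Path(path)
    lab = np.asarray(nib.load(str(path)).dataobj).astype(np.uint8)
    sidecar = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    masks, art = {}, {}
    for i, name in sidecar["labels"].items():
        masks[name] = lab == int(i)
        a = np.zeros(lab.shape, dtype=bool)
        vox = np.asarray(sidecar["articular_voxels"][name], dtype=int)
        if vox.size:
            a[tuple(vox.T)] = True
        art[name] = a
    return BoneMask(masks=masks, articular_masks=art,
                    split_z_mm=float(sidecar["split_z_mm"]))


def save_annotation(ann: BoundaryAnnotation, path) -> None:
    doc = {
        "articular_dir": ann.articular_dir,
        "split_z_mm": ann.split_z_mm,
        "slices": {bone: {str(z): {"points_mm": sl.points_mm.tolist(),
                                   "articular": sl.articular.tolist()}
                          for z, sl in per.items()}
                   for bone, per in ann.slices.items()},
    }
    Path(path).write_text(json.dumps(doc))


def load_annotation(path) -> BoundaryAnnotation:
    doc = json.loads(Path(path).read_text())
    slices = {
        bone: {int(z): AnnotationSlice(
            points_mm=np.asarray(sl["points_mm"], dtype=float),
            articular=np.asarray(sl["articular"], dtype=bool))
            for z, sl in per.items()}
        for bone, per in doc["slices"].items()}
    return BoundaryAnnotation(slices=slices,
                              articular_dir={k: int(v) for k, v in
                                             doc["articular_dir"].items()},
                              split_z_mm=float(doc["split_z_mm"]))


def save_cohort(table: pd.DataFrame, path, with_dictionary: bool = True
                ) -> None:
    path = Path(path)
    table.to_csv(path, index=False)
    if with_dictionary:
        dict_path = path.with_name(path.stem + "_columns.json")
        dict_path.write_text(json.dumps(COHORT_COLUMNS, indent=2))


def load_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)


def spec_to_json(spec, path) -> None:
    Path(path).write_text(json.dumps(asdict(spec), indent=2, default=list))
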