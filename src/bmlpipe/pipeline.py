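"""End-to-end orchestration: simulate -> segment -> quantify -> analyze.

A run is a pure function of its config: the manifest records the config
hash, the seeds and every output file, and re-running with the same config
reproduces the reports byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    classify_change,
    confirmatory_ordinal,
    fit_cart,
    fit_jsn_models,
    fit_pain_models,
    fit_tertile_robust,
    medial_sensitivity,
    stratify_baseline_tertiles,
)
from .cohort import CohortSpec, ConfirmatorySpec, generate_cohort, \
    generate_confirmatory_cohort
from .io import save_annotation, save_bone_mask, save_cohort, save_volume
from .phantom import FollowupSpec, LesionChange, demo_phantom_spec, \
    generate_annotation, generate_followup_phantom, generate_knee_phantom
from .quantification import BMLCriteria, apply_bml_criteria, assign_region, \
    compute_measurement, volume_change
from .segmentation import DetectionParams, detect_hyperintensities, \
    extract_candidates, refine_bone_boundary

log = logging.getLogger("bmlpipe")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    output_dir: str = "bmlpipe_run"
    cohort_n: int = 60
    annotation_jitter_mm: float = 1.0
    phantom_noise_sd: float = 3.0
    lesion_change_cm3: float = -0.5
    criteria: BMLCriteria = field(default_factory=BMLCriteria)
    detection: DetectionParams = field(default_factory=DetectionParams)
    run_imaging: bool = True
    run_analysis: bool = True


def _segment_and_measure(vol, truth, cfg: RunConfig, visit: str, outdir: Path):
    ann = generate_annotation(truth, cfg.annotation_jitter_mm,
                              seed=cfg.seed + 17)
    bones = refine_bone_boundary(vol, ann)
    cands = extract_candidates(
        detect_hyperintensities(vol, bones, cfg.detection), vol, bones)
    kept = apply_bml_criteria(cands, cfg.criteria, vol.n_slices)
    for c in kept:
        c.region = assign_region(c, bones)
    meas = compute_measurement(kept, vol, knee_id="phantom", visit=visit)
    save_volume(vol, outdir / f"phantom_{visit}.nii.gz")
    save_annotation(ann, outdir / f"annotation_{visit}.json")
    save_bone_mask(bones, vol.spacing_mm, outdir / f"bones_{visit}.nii.gz")
    return meas


def make_table2(table: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulation of change classes by baseline-volume tertiles.

    One row per baseline tertile with counts, row percentages (one
    decimal) and the per-cell change range in cm^3.
    """
    tert, bounds = stratify_baseline_tertiles(table["bml_total_base"])
    classes, cuts = classify_change(table["bml_total_change"])
    rows = []
    order = ["regression", "minimal", "progression"]
    for t in (0, 1, 2):
        sel = tert == t
        sub = table.loc[sel]
        n_row = int(sel.sum())
        row = {
            "tertile": ["no or small", "moderate", "large"][t],
            "baseline_range_cm3": (
                f"{sub['bml_total_base'].min():.1f} to "
                f"{sub['bml_total_base'].max():.1f}") if n_row else "-",
            "change_median_cm3": round(float(
                sub["bml_total_change"].median()), 1) if n_row else np.nan,
        }
        for cls in order:
            n = int(((classes == cls) & sel).sum())
            pct = 100.0 * n / n_row if n_row else 0.0
            row[f"{cls}_n"] = n
            row[f"{cls}_pct"] = round(pct, 1)
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["tertile_bounds_cm3"] = bounds
    out.attrs["change_cuts_cm3"] = cuts
    return out


def _model_to_dict(res) -> dict:
    d = {"name": res.name, "n_used": res.n_used,
         "c_statistic": res.c_statistic, "overall_p": res.overall_p,
         "diagnostics": res.diagnostics}
    if res.table is not None:
        d["terms"] = json.loads(res.table.to_json(orient="index"))
    return d


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(asdict(config), sort_keys=True, default=str)
    manifest = {
        "bmlpipe_version": __version__,
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "outputs": [],
    }

    if config.run_imaging:
        log.info("stage: imaging (phantom pair)")
        spec = demo_phantom_spec(seed=config.seed,
                                 noise_sd=config.phantom_noise_sd)
        vol, truth = generate_knee_phantom(spec)
        base = _segment_and_measure(vol, truth, config, "baseline", outdir)
        fu_vol, fu_truth = generate_followup_phantom(
            truth, FollowupSpec(changes=(
                LesionChange("lat_tibia", config.lesion_change_cm3),)),
            seed=config.seed + 1)
        fu = _segment_and_measure(fu_vol, fu_truth, config, "followup", outdir)
        deltas = volume_change(base, fu)
        meas_rows = []
        for m in (base, fu):
            meas_rows.append({"knee_id": m.knee_id, "visit": m.visit,
                              **m.region_volumes_cm3, "total": m.total_cm3})
        meas_df = pd.DataFrame(meas_rows)
        meas_df.to_csv(outdir / "measurements.csv", index=False)
        truth_delta = (fu_truth.total_volume_cm3()
                       - truth.total_volume_cm3())
        manifest["imaging"] = {
            "measured_total_baseline_cm3": base.total_cm3,
            "measured_total_followup_cm3": fu.total_cm3,
            "measured_change_cm3": deltas["total"],
            "true_total_baseline_cm3": truth.total_volume_cm3(),
            "true_change_cm3": truth_delta,
        }
        manifest["outputs"] += ["measurements.csv", "phantom_baseline.nii.gz",
                                "phantom_followup.nii.gz"]

    if config.run_analysis:
        log.info("stage: cohort analysis (n=%d)", config.cohort_n)
        cohort = generate_cohort(CohortSpec(n=config.cohort_n,
                                            seed=config.seed))
        save_cohort(cohort, outdir / "cohort.csv")
        t2 = make_table2(cohort)
        t2.to_csv(outdir / "table2.csv", index=False)

        tert, _ = stratify_baseline_tertiles(cohort["bml_total_base"])
        pain = {k: _model_to_dict(v)
                for k, v in fit_pain_models(cohort).items()}
        robust = {str(k): _model_to_dict(v)
                  for k, v in fit_tertile_robust(cohort, tert).items()}
        jsn = {k: _model_to_dict(v)
               for k, v in fit_jsn_models(cohort).items()}
        try:
            medial = _model_to_dict(medial_sensitivity(cohort))
        except ValueError as exc:
            medial = {"error": str(exc)}
        tree = fit_cart(cohort)
        (outdir / "cart.txt").write_text(tree.render() + "\n")
        confirm = generate_confirmatory_cohort(
            ConfirmatorySpec(seed=config.seed))
        ordinal = _model_to_dict(confirmatory_ordinal(confirm))

        reports = {"pain_models": pain, "robust_tertiles": robust,
                   "jsn_models": jsn, "medial_sensitivity": medial,
                   "cart": tree.root.to_dict(),
                   "confirmatory_ordinal": ordinal}
        (outdir / "models.json").write_text(
            json.dumps(reports, indent=2, default=float, sort_keys=True))
        manifest["outputs"] += ["cohort.csv", "table2.csv", "models.json",
                                "cart.txt"]

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=float, sort_keys=True))
    return manifest
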