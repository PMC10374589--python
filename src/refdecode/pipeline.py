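"""Pipeline orchestration: simulate -> qc -> glm -> decode -> group -> roi.

A :class:`PipelineConfig` fully determines a run; every source of
randomness derives from its ``seed`` through named per-stage
``numpy.random.SeedSequence`` children, so reruns with the same config are
reproducible.  :func:`run_pipeline` executes the stages against a work
directory, writing NIfTI volumes, TSV tables and JSON reports, plus a
manifest listing every output with its checksum.  The in-memory helpers
(:func:`fit_participant_betas`, :func:`participant_accuracy_maps`,
:func:`group_analysis`, :func:`analyze_cohort`) are the same computational
path without the file round-trips.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from . import qc as rqc
from .decoding import make_classifier_specs, searchlight_decode
from .glm import build_design_matrix, canonical_hrf, fit_glm_ar1, MICROTIME_BINS
from .inference import cluster_permutation_test, smooth_map
from .roi import (
    bootstrap_ci,
    define_group_rois,
    individual_peak_roi,
    overlap_report,
    roi_mean_accuracy,
)
from .simulate import (
    NoiseModel,
    VolumeGeometry,
    default_region_specs,
    simulate_behavior,
    simulate_participant,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    n_participants: int = 16
    n_runs: int = 12
    n_trials: int = 33
    grid_shape: tuple = (24, 24, 24)
    voxel_size_mm: tuple = (3.0, 3.0, 3.0)
    effect_size: float = 1.0
    shared_patterns: bool = False
    noise: dict = field(default_factory=dict)  # NoiseModel overrides
    error_rate: float = 0.047
    saccade_rate: float = 0.102
    glm_variant: str = "epoch"
    hp_cutoff_s: float = 128.0
    radius_voxels: int = 4
    svm_cost: float = 1.0
    spec_ids: tuple = (1, 2, 3, 4, 5, 6, 7, 8)
    smoothing_fwhm_mm: float = 6.0
    chance_level: float = 50.0
    cluster_p: float = 0.001
    fwe_p: float = 0.05
    n_perm: int = 5000
    roi_radius_mm: float = 6.0
    min_peak_sep_mm: float = 20.0
    drop_one_run: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["voxel_size_mm"] = list(self.voxel_size_mm)
        d["spec_ids"] = list(self.spec_ids)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("grid_shape", "voxel_size_mm", "spec_ids"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def geometry(self) -> VolumeGeometry:
        return VolumeGeometry(self.grid_shape, tuple(self.voxel_size_mm))

    def region_specs(self):
        specs = default_region_specs(self.effect_size)
        if self.shared_patterns:
            for s in specs:
                if s.coded_dimension in ("anatomical", "external"):
                    s.phases = ("localization", "planning")
                    s.shared_weights = True
        return specs

    def noise_model(self) -> NoiseModel:
        return NoiseModel(**self.noise)

    def stage_rng(self, stage: str, index: int = 0) -> np.random.Generator:
        key = int(hashlib.sha256(stage.encode()).hexdigest()[:8], 16)
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(key, index))
        )

    def participant_ids(self) -> list:
        return [f"sub-{i + 1:02d}" for i in range(self.n_participants)]


# ---------------------------------------------------------------------------
# in-memory computational path

def fit_participant_betas(design, runs, mask, variant="epoch", hp_cutoff_s=128.0,
                          excluded=None, include_motion=False):
    """Run-wise GLM fits for one participant.

    ``excluded`` maps run_index -> set of error trial indices; those trials'
    phases load on the shared error predictor.
    """
    hrf = canonical_hrf(design.tr_seconds / MICROTIME_BINS)
    betas = []
    for run_obj in runs:
        run = run_obj.run_index
        trials = design.trials_for_run(run)
        bad = (excluded or {}).get(run, set())
        for t in trials:
            t.is_error = t.trial_index in bad
        dm = build_design_matrix(
            trials,
            design.run_length_tr[run],
            variant=variant,
            hrf=hrf,
            hp_cutoff_s=hp_cutoff_s,
            tr_seconds=design.tr_seconds,
            rest_start_tr=design.rest_start_tr,
            rest_end_tr=design.rest_end_tr,
            motion=run_obj.motion if include_motion else None,
        )
        betas.append(fit_glm_ar1(run_obj.data, dm, mask))
    return betas


def participant_accuracy_maps(betas, spec_ids, mask, radius_voxels=4, C=1.0,
                              participant_id=""):
    specs = {s.id: s for s in make_classifier_specs()}
    return {
        sid: searchlight_decode(
            betas, specs[sid], mask=mask, radius_voxels=radius_voxels, C=C,
            participant_id=participant_id,
        )
        for sid in spec_ids
    }


def group_analysis(acc_maps, mask, fwhm_mm=6.0, voxel_size_mm=(3.0, 3.0, 3.0),
                   chance=50.0, cluster_p=0.001, fwe_p=0.05, n_perm=5000, rng=None):
    """Smooth each participant's map, then sign-flip cluster inference."""
    smoothed = [
        smooth_map(m.data if hasattr(m, "data") else m, mask, fwhm_mm, voxel_size_mm)
        for m in acc_maps
    ]
    return cluster_permutation_test(
        smoothed, chance=chance, cluster_p=cluster_p, fwe_p=fwe_p,
        n_perm=n_perm, rng=rng, mask=mask, voxel_size_mm=voxel_size_mm,
    )


def simulate_cohort_in_memory(config: PipelineConfig):
    """All participants' designs, phantoms and BOLD runs (no disk I/O)."""
    geometry = config.geometry()
    region_specs = config.region_specs()
    noise = config.noise_model()
    cohort = []
    for i, pid in enumerate(config.participant_ids()):
        # 4 randomization protocols (sequence + timing seed families)
        rng = config.stage_rng(f"simulate/protocol-{i % 4}", i)
        start_posture = "uncrossed" if i % 2 == 0 else "crossed"
        design, patterns, truth, runs = simulate_participant(
            pid, geometry, region_specs, noise, seed=rng,
            n_runs=config.n_runs, n_trials=config.n_trials,
            start_posture=start_posture,
        )
        if config.drop_one_run and i == 0:
            runs = runs[:-1]
        cohort.append(
            {"participant_id": pid, "design": design, "patterns": patterns,
             "truth": truth, "runs": runs}
        )
    return geometry, cohort


def analyze_cohort(config: PipelineConfig, cohort=None, geometry=None):
    """Full in-memory pipeline; returns per-spec group results and intermediates."""
    if cohort is None:
        geometry, cohort = simulate_cohort_in_memory(config)
    mask = geometry.brain_mask
    maps_by_spec = {sid: [] for sid in config.spec_ids}
    for i, part in enumerate(cohort):
        excluded = {}
        rng = config.stage_rng("behavior", i)
        for run_obj in part["runs"]:
            trials = part["design"].trials_for_run(run_obj.run_index)
            behavior = simulate_behavior(
                trials, config.error_rate, config.saccade_rate, rng=rng
            )
            flags = [rqc.detect_saccade(b["eye_trace"]) for b in behavior]
            scores = [
                rqc.score_movement(b["executed_direction"], t)
                for b, t in zip(behavior, trials)
            ]
            _, included = rqc.apply_exclusions(trials, flags, scores)
            keep = {t.trial_index for t in included}
            excluded[run_obj.run_index] = {
                t.trial_index for t in trials if t.trial_index not in keep
            }
        betas = fit_participant_betas(
            part["design"], part["runs"], mask,
            variant=config.glm_variant, hp_cutoff_s=config.hp_cutoff_s,
            excluded=excluded,
        )
        acc = participant_accuracy_maps(
            betas, config.spec_ids, mask,
            radius_voxels=config.radius_voxels, C=config.svm_cost,
            participant_id=part["participant_id"],
        )
        for sid in config.spec_ids:
            maps_by_spec[sid].append(acc[sid])
    results = {}
    for sid in config.spec_ids:
        results[sid] = group_analysis(
            maps_by_spec[sid], mask,
            fwhm_mm=config.smoothing_fwhm_mm, voxel_size_mm=config.voxel_size_mm,
            chance=config.chance_level, cluster_p=config.cluster_p,
            fwe_p=config.fwe_p, n_perm=config.n_perm,
            rng=config.stage_rng("group", sid),
        )
    return {"geometry": geometry, "cohort": cohort,
            "accuracy_maps": maps_by_spec, "group_results": results}


# ---------------------------------------------------------------------------
# disk-backed stages

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def stage_simulate(config: PipelineConfig, outdir: Path):
    outdir = Path(outdir)
    geometry, cohort = simulate_cohort_in_memory(config)
    vs = config.voxel_size_mm
    rio.save_volume(geometry.brain_mask.astype(np.uint8), outdir / "mask.nii", vs)
    for i, part in enumerate(cohort):
        pid = part["participant_id"]
        pdir = outdir / pid
        rio.write_json(
            {
                "participant_id": pid,
                "tr_seconds": part["design"].tr_seconds,
                "posture_schedule": {
                    str(k): v for k, v in part["design"].posture_schedule.items()
                },
                "run_length_tr": {
                    str(k): v for k, v in part["design"].run_length_tr.items()
                },
            },
            pdir / "design.json",
        )
        rio.write_json(part["truth"].to_jsonable(), pdir / "ground_truth.json")
        rng = config.stage_rng("behavior", i)
        for run_obj in part["runs"]:
            r = run_obj.run_index
            rio.save_volume(run_obj.data, pdir / f"run-{r:02d}_bold.nii", vs)
            trials = part["design"].trials_for_run(r)
            rio.write_events(
                trials, pdir / f"run-{r:02d}_events.tsv", part["design"].tr_seconds
            )
            behavior = simulate_behavior(
                trials, config.error_rate, config.saccade_rate, rng=rng
            )
            rows = []
            for b in behavior:
                for s, (x, y) in enumerate(b["eye_trace"]):
                    rows.append((b["trial_index"], s, x, y))
            pd.DataFrame(rows, columns=["trial_index", "sample", "x", "y"]).to_csv(
                pdir / f"run-{r:02d}_eyetrace.tsv", sep="\t", index=False
            )
            pd.DataFrame(
                [
                    {
                        "trial_index": b["trial_index"],
                        "executed_direction": b["executed_direction"],
                    }
                    for b in behavior
                ]
            ).to_csv(pdir / f"run-{r:02d}_movements.tsv", sep="\t", index=False)
    return geometry, cohort


def _participant_runs(outdir: Path, pid: str):
    pdir = Path(outdir) / pid
    meta = rio.read_json(pdir / "design.json")
    runs = sorted(
        int(p.name.split("_")[0].split("-")[1]) for p in pdir.glob("run-*_bold.nii")
    )
    return pdir, meta, runs


def stage_qc(config: PipelineConfig, outdir: Path):
    outdir = Path(outdir)
    qcdir = outdir / "qc"
    for pid in config.participant_ids():
        pdir, meta, runs = _participant_runs(outdir, pid)
        excluded = {}
        reports = {}
        for r in runs:
            trials = rio.read_events(
                pdir / f"run-{r:02d}_events.tsv", meta["tr_seconds"], pid, r,
                run_length_tr=meta["run_length_tr"][str(r)],
            )
            eye = pd.read_csv(pdir / f"run-{r:02d}_eyetrace.tsv", sep="\t")
            moves = pd.read_csv(pdir / f"run-{r:02d}_movements.tsv", sep="\t")
            move_of = dict(zip(moves["trial_index"], moves["executed_direction"]))
            flags, scores = [], []
            for t in trials:
                trace = eye.loc[eye["trial_index"] == t.trial_index, ["x", "y"]].values
                flags.append(rqc.detect_saccade(trace))
                scores.append(rqc.score_movement(move_of.get(t.trial_index), t))
            report, included = rqc.apply_exclusions(trials, flags, scores)
            keep = {t.trial_index for t in included}
            excluded[str(r)] = sorted(
                t.trial_index for t in trials if t.trial_index not in keep
            )
            reports[str(r)] = report.to_dict()
        rio.write_json(
            {"excluded_trials": excluded, "reports": reports},
            qcdir / f"{pid}_exclusions.json",
        )


def stage_glm(config: PipelineConfig, outdir: Path):
    outdir = Path(outdir)
    mask, _ = rio.load_volume(outdir / "mask.nii")
    mask = mask.astype(bool)
    for pid in config.participant_ids():
        pdir, meta, runs = _participant_runs(outdir, pid)
        qc_info = rio.read_json(outdir / "qc" / f"{pid}_exclusions.json")
        bdir = outdir / "betas" / pid
        index = {}
        for r in runs:
            trials = rio.read_events(
                pdir / f"run-{r:02d}_events.tsv", meta["tr_seconds"], pid, r
            )
            bad = set(qc_info["excluded_trials"].get(str(r), []))
            for t in trials:
                t.is_error = t.trial_index in bad
            bold, _ = rio.load_volume(pdir / f"run-{r:02d}_bold.nii")
            dm = build_design_matrix(
                trials, meta["run_length_tr"][str(r)], variant=config.glm_variant,
                hp_cutoff_s=config.hp_cutoff_s, tr_seconds=meta["tr_seconds"],
            )
            beta = fit_glm_ar1(bold, dm, mask)
            index[str(r)] = {"ar1": beta.ar1_coefficient, "predictors": {}}
            for name, vol in beta.betas.items():
                fname = f"run-{r:02d}_{name}.nii"
                rio.save_volume(vol.astype(np.float32), bdir / fname,
                                config.voxel_size_mm)
                index[str(r)]["predictors"][name] = fname
        rio.write_json(index, bdir / "index.json")


def _load_betas(config: PipelineConfig, outdir: Path, pid: str, mask):
    from .glm import BetaImages

    bdir = Path(outdir) / "betas" / pid
    index = rio.read_json(bdir / "index.json")
    betas = []
    for r_str, entry in sorted(index.items(), key=lambda kv: int(kv[0])):
        vols = {
            name: rio.load_volume(bdir / fname)[0].astype(np.float64)
            for name, fname in entry["predictors"].items()
        }
        betas.append(
            BetaImages(
                betas=vols,
                residual_variance=np.zeros(mask.shape),
                ar1_coefficient=entry["ar1"],
                run_index=int(r_str),
                mask=mask,
                model_variant=config.glm_variant,
            )
        )
    return betas


def stage_decode(config: PipelineConfig, outdir: Path):
    outdir = Path(outdir)
    mask, _ = rio.load_volume(outdir / "mask.nii")
    mask = mask.astype(bool)
    for pid in config.participant_ids():
        betas = _load_betas(config, outdir, pid, mask)
        acc = participant_accuracy_maps(
            betas, config.spec_ids, mask,
            radius_voxels=config.radius_voxels, C=config.svm_cost,
            participant_id=pid,
        )
        for sid, amap in acc.items():
            rio.save_volume(
                amap.data.astype(np.float32),
                outdir / "accuracy" / f"{pid}_spec-{sid}.nii",
                config.voxel_size_mm,
            )


def stage_group(config: PipelineConfig, outdir: Path):
    outdir = Path(outdir)
    mask, _ = rio.load_volume(outdir / "mask.nii")
    mask = mask.astype(bool)
    gdir = outdir / "group"
    for sid in config.spec_ids:
        maps = [
            rio.load_volume(outdir / "accuracy" / f"{pid}_spec-{sid}.nii")[0]
            for pid in config.participant_ids()
        ]
        result = group_analysis(
            maps, mask, fwhm_mm=config.smoothing_fwhm_mm,
            voxel_size_mm=config.voxel_size_mm, chance=config.chance_level,
            cluster_p=config.cluster_p, fwe_p=config.fwe_p, n_perm=config.n_perm,
            rng=config.stage_rng("group", sid),
        )
        rio.save_volume(np.nan_to_num(result.t_map).astype(np.float32),
                        gdir / f"spec-{sid}_tmap.nii", config.voxel_size_mm)
        rio.save_volume(result.significant_mask.astype(np.uint8),
                        gdir / f"spec-{sid}_sig.nii", config.voxel_size_mm)
        result.cluster_table.to_csv(gdir / f"spec-{sid}_clusters.tsv",
                                    sep="\t", index=False)


def stage_roi(config: PipelineConfig, outdir: Path):
    outdir = Path(outdir)
    mask, _ = rio.load_volume(outdir / "mask.nii")
    mask = mask.astype(bool)
    rdir = outdir / "roi"
    for sid in config.spec_ids:
        t_map, _ = rio.load_volume(outdir / "group" / f"spec-{sid}_tmap.nii")
        sig, _ = rio.load_volume(outdir / "group" / f"spec-{sid}_sig.nii")
        rois = define_group_rois(
            t_map.astype(float), sig.astype(bool),
            radius_mm=config.roi_radius_mm, min_peak_sep_mm=config.min_peak_sep_mm,
            voxel_size_mm=config.voxel_size_mm, brain_mask=mask,
            name_prefix=f"spec{sid}",
        )
        roi_meta = []
        rows = []
        for roi in rois:
            roi_meta.append(
                {"name": roi.name, "center_ijk": list(roi.center_ijk),
                 "center_mm": list(roi.center_mm(config.voxel_size_mm)),
                 "radius_mm": roi.radius_mm, "n_voxels": roi.n_voxels}
            )
            for pid in config.participant_ids():
                amap, _ = rio.load_volume(
                    outdir / "accuracy" / f"{pid}_spec-{sid}.nii"
                )
                amap = amap.astype(float)
                indiv = individual_peak_roi(
                    amap, roi, radius_mm=config.roi_radius_mm,
                    voxel_size_mm=config.voxel_size_mm, brain_mask=mask,
                )
                vals = amap[indiv.member_voxels]
                vals = vals[np.isfinite(vals)]
                lo, hi = bootstrap_ci(
                    vals, rng=config.stage_rng("bootstrap", sid * 1000 + len(rows))
                )
                rows.append(
                    {"roi": roi.name, "participant_id": pid,
                     "mean_accuracy": float(np.mean(vals)),
                     "ci_low": lo, "ci_high": hi}
                )
        rio.write_json(roi_meta, rdir / f"spec-{sid}_rois.json")
        pd.DataFrame(rows).to_csv(rdir / f"spec-{sid}_accuracy.tsv",
                                  sep="\t", index=False)


def stage_overlap(config: PipelineConfig, outdir: Path):
    """Overlap of each sensory/rule significance map with the goal map."""
    outdir = Path(outdir)
    name = {1: "anatomical", 2: "external", 7: "goal", 8: "rule"}
    pairs = [(1, 7), (2, 7), (8, 7)]
    sig = {}
    for sid in set(sum(([a, b] for a, b in pairs), [])):
        path = outdir / "group" / f"spec-{sid}_sig.nii"
        if sid in config.spec_ids and path.exists():
            sig[sid] = rio.load_volume(path)[0].astype(bool)
    vox_mm3 = float(np.prod(config.voxel_size_mm))
    reports = []
    for a, b in pairs:
        if a in sig and b in sig:
            reports.append(
                overlap_report(sig[a], sig[b], vox_mm3, name[a], name[b]).to_dict()
            )
    if all(s in sig for s in (1, 7, 8)):
        triple = sig[1] & sig[7] & sig[8]
        reports.append(
            {"pair": ["anatomical", "goal", "rule"],
             "n_overlap_voxels": int(triple.sum()),
             "overlap_volume_mm3": float(triple.sum() * vox_mm3)}
        )
    rio.write_json(reports, outdir / "overlap" / "overlap.json")


#: write a full synthetic cohort (runs, events, ground truth) to disk
simulate_cohort = stage_simulate

STAGES = ("simulate", "qc", "glm", "decode", "group", "roi", "overlap")


def run_pipeline(config: PipelineConfig, outdir, stages=STAGES) -> Path:
    """Execute the pipeline stages and write a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rio.save_config(config.to_dict(), outdir / "config.json")
    log = []
    funcs = {
        "simulate": stage_simulate, "qc": stage_qc, "glm": stage_glm,
        "decode": stage_decode, "group": stage_group, "roi": stage_roi,
        "overlap": stage_overlap,
    }
    for stage in stages:
        t0 = time.time()
        try:
            funcs[stage](config, outdir)
        except Exception as exc:
            rio.write_json(
                {"failed_stage": stage, "error": str(exc), "log": log},
                outdir / "manifest.json",
            )
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        log.append({"stage": stage, "seconds": round(time.time() - t0, 2)})
        logger.info("stage %s done in %.1fs", stage, log[-1]["seconds"])
    files = sorted(
        p for p in outdir.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": config.to_dict(),
        "stages": log,
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p) for p in files
        },
    }
    rio.write_json(manifest, outdir / "manifest.json")
    return outdir
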