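"""File formats: NIfTI volumes, BIDS-style events tables, configs, JSON.

Events files are tab-separated with one row per trial phase: columns
``onset`` and ``duration`` in seconds plus the trial's condition columns
(posture, foot, stim_site, task_rule, delays, trial_index, phase).  Volumes
are NIfTI-1 with a diagonal affine from the voxel size.  Write-then-read is
the identity for both.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .design import PHASES, TrialRecord

EVENT_COLUMNS = [
    "onset", "duration", "phase", "posture", "foot", "stim_site",
    "task_rule", "loc_delay_tr", "plan_delay_tr", "trial_index",
]


def save_volume(data, path, voxel_size_mm=(3.0, 3.0, 3.0), affine=None):
    path = Path(path)
    if affine is None:
        affine = np.diag(list(voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def load_volume(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def events_table(run_trials, tr_seconds: float) -> pd.DataFrame:
    rows = []
    for t in run_trials:
        for phase in PHASES:
            rows.append(
                {
                    "onset": t.onsets_tr[phase] * tr_seconds,
                    "duration": t.phase_duration_tr(phase) * tr_seconds,
                    "phase": phase,
                    "posture": t.posture,
                    "foot": t.foot,
                    "stim_site": t.stim_site,
                    "task_rule": t.task_rule,
                    "loc_delay_tr": t.loc_delay_tr,
                    "plan_delay_tr": t.plan_delay_tr,
                    "trial_index": t.trial_index,
                }
            )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events(run_trials, path, tr_seconds: float):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    events_table(run_trials, tr_seconds).to_csv(path, sep="\t", index=False)
    return path


def read_events(
    path,
    tr_seconds: float,
    participant_id: str = "",
    run_index: int = 0,
    run_length_tr: int | None = None,
) -> list:
    """Reconstruct TrialRecords from an events file."""
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"malformed events file {path}: missing columns {sorted(missing)}")
    trials = []
    for trial_index, grp in df.groupby("trial_index", sort=True):
        onsets = {}
        for _, row in grp.iterrows():
            onset_tr = row["onset"] / tr_seconds
            if abs(onset_tr - round(onset_tr)) > 1e-6:
                raise ValueError(f"onset {row['onset']} s is not TR-aligned")
            onsets[row["phase"]] = int(round(onset_tr))
        first = grp.iloc[0]
        t = TrialRecord(
            participant_id=participant_id,
            run_index=run_index,
            trial_index=int(trial_index),
            posture=str(first["posture"]),
            foot=str(first["foot"]),
            stim_site=str(first["stim_site"]),
            task_rule=str(first["task_rule"]),
            loc_delay_tr=int(first["loc_delay_tr"]),
            plan_delay_tr=int(first["plan_delay_tr"]),
            onsets_tr=onsets,
        )
        if run_length_tr is not None:
            end = t.onsets_tr["execution"] + 1
            if end > run_length_tr:
                raise ValueError(
                    f"trial {trial_index} ends at TR {end}, beyond run length "
                    f"{run_length_tr}"
                )
        trials.append(t)
    return trials


def write_json(obj, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable))
    return path


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_json(path):
    return json.loads(Path(path).read_text())


def load_config(path) -> dict:
    """Read a pipeline config from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def save_config(cfg: dict, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    else:
        path.write_text(json.dumps(cfg, indent=2, sort_keys=True))
    return path
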