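"""Searchlight SVM decoding: the 8 classifier analyses.

Decoding operates on run-wise GLM beta images.  Each classifier analysis is
a :class:`ClassifierSpec` naming the trial phase(s) whose predictors provide
samples, the coded dimension whose labels are decoded, and the
cross-validation scheme:

==  ============================  ==========================  ===========
id  decoded dimension             train phase -> test phase   scheme
==  ============================  ==========================  ===========
1   anatomical foot               localization                within LORO
2   external side                 localization                within LORO
3   anatomical foot               localization -> planning    cross-phase
4   external side                 localization -> planning    cross-phase
5   anatomical foot               planning                    within LORO
6   external side                 planning                    within LORO
7   movement-goal side            planning                    within LORO
8   task rule (pro/anti)          planning                    within LORO
==  ============================  ==========================  ===========

Because posture is constant within a run while both decoded classes occur in
every run, class counts are balanced in every training fold.  The classifier
is a linear soft-margin SVM with fixed cost C=1 (LIBSVM implementation, via
scikit-learn's SVC); exact-zero decision values are deterministically broken
toward class A.  The searchlight evaluates each in-mask voxel's radius-4
sphere (clipped to the mask) and writes the mean cross-validated accuracy at
the center.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .design import external_side, goal_side

logger = logging.getLogger(__name__)

PHASE_PREDICTOR_PREFIX = {"localization": "loc", "planning": "plan"}


def _label(dimension: str, posture: str, foot: str, task: str | None) -> str:
    if dimension == "anatomical":
        return foot
    if dimension == "external":
        return external_side(foot, posture)
    if dimension == "goal":
        return goal_side(foot, posture, task)
    if dimension == "rule":
        return task
    raise ValueError(f"cannot label dimension {dimension!r}")


@dataclass(frozen=True)
class ClassifierSpec:
    id: int
    name: str
    dimension: str
    train_phase: str
    test_phase: str
    scheme: str  # "within_loro" | "cross_phase"
    classes: tuple

    def label(self, posture: str, foot: str, task: str | None = None) -> str:
        return _label(self.dimension, posture, foot, task)

    @property
    def phases(self) -> tuple:
        if self.scheme == "within_loro":
            return (self.train_phase,)
        return (self.train_phase, self.test_phase)


def make_classifier_specs() -> list:
    """The 8 analysis definitions (see module docstring)."""
    sides = ("left", "right")
    rules = ("pro", "anti")
    return [
        ClassifierSpec(1, "anatomical@localization", "anatomical",
                       "localization", "localization", "within_loro", sides),
        ClassifierSpec(2, "external@localization", "external",
                       "localization", "localization", "within_loro", sides),
        ClassifierSpec(3, "anatomical@cross_interval", "anatomical",
                       "localization", "planning", "cross_phase", sides),
        ClassifierSpec(4, "external@cross_interval", "external",
                       "localization", "planning", "cross_phase", sides),
        ClassifierSpec(5, "anatomical@planning", "anatomical",
                       "planning", "planning", "within_loro", sides),
        ClassifierSpec(6, "external@planning", "external",
                       "planning", "planning", "within_loro", sides),
        ClassifierSpec(7, "goal@planning", "goal",
                       "planning", "planning", "within_loro", sides),
        ClassifierSpec(8, "rule@planning", "rule",
                       "planning", "planning", "within_loro", rules),
    ]


def sphere_offsets(radius_voxels: int = 4) -> np.ndarray:
    """All integer offsets with Euclidean norm <= radius (center included)."""
    if radius_voxels < 0:
        raise ValueError("radius must be non-negative")
    r = int(radius_voxels)
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= radius_voxels**2
    return np.column_stack([dx[keep], dy[keep], dz[keep]])


@dataclass
class SampleSet:
    """Feature matrix plus labels, run chunks, and phase per sample."""

    X: np.ndarray  # n_samples x n_voxels
    y: np.ndarray  # 0/1 (index into classes)
    chunks: np.ndarray  # run index per sample
    phase: np.ndarray  # phase name per sample
    classes: tuple
    mask: np.ndarray | None = None  # voxel mask the columns refer to

    def __len__(self):
        return self.X.shape[0]


def _run_posture(beta) -> str:
    for name in beta.betas:
        if name.startswith("loc_"):
            return name.split("_")[1]
    raise ValueError(f"run {beta.run_index}: no localization predictors found")


def _phase_conditions(phase: str, posture: str):
    """(predictor_name, foot, task) for the phase's condition predictors."""
    prefix = PHASE_PREDICTOR_PREFIX[phase]
    if phase == "localization":
        return [(f"{prefix}_{posture}_{foot}", foot, None) for foot in ("left", "right")]
    return [
        (f"{prefix}_{posture}_{foot}_{task}", foot, task)
        for foot in ("left", "right")
        for task in ("pro", "anti")
    ]


def assemble_samples(
    betas_per_run,
    spec: ClassifierSpec,
    mask: np.ndarray | None = None,
    task_filter: str | None = None,
) -> SampleSet:
    """One sample per (run, phase-condition predictor), over all runs.

    ``task_filter`` restricts planning-phase samples to pro- or anti-pointing
    trials (used for the pro-/anti-only cross-classification variants).
    """
    rows, labels, chunks, phases = [], [], [], []
    for beta in betas_per_run:
        posture = _run_posture(beta)
        use_mask = beta.mask if mask is None else mask
        for phase in spec.phases:
            for pname, foot, task in _phase_conditions(phase, posture):
                if task_filter is not None and task is not None and task != task_filter:
                    continue
                if pname not in beta.betas:
                    raise KeyError(
                        f"run {beta.run_index} is missing predictor {pname!r}"
                    )
                rows.append(beta.betas[pname][use_mask])
                labels.append(spec.label(posture, foot, task))
                chunks.append(beta.run_index)
                phases.append(phase)
    classes = spec.classes
    y = np.array([classes.index(lb) for lb in labels])
    first_mask = betas_per_run[0].mask if mask is None else mask
    return SampleSet(
        X=np.asarray(rows, dtype=np.float64),
        y=y,
        chunks=np.asarray(chunks),
        phase=np.asarray(phases),
        classes=classes,
        mask=first_mask,
    )


def _folds(samples: SampleSet, scheme: str, train_phase: str, test_phase: str):
    if scheme == "within_loro":
        runs = np.unique(samples.chunks)
        if len(runs) < 2:
            raise ValueError("leave-one-run-out needs at least 2 runs")
        return [
            (np.flatnonzero(samples.chunks != r), np.flatnonzero(samples.chunks == r))
            for r in runs
        ]
    if scheme == "cross_phase":
        return [
            (
                np.flatnonzero(samples.phase == train_phase),
                np.flatnonzero(samples.phase == test_phase),
            )
        ]
    raise ValueError(f"unknown scheme {scheme!r}")


def _accuracy(X, y, folds, C=1.0) -> float:
    correct = total = 0
    for train, test in folds:
        ytr = y[train]
        if len(np.unique(ytr)) < 2:
            raise ValueError("training fold contains a single class")
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[train], ytr)
        dec = clf.decision_function(X[test])
        # decision > 0 -> classes_[1]; exact zero -> class A (index 0)
        pred = np.where(dec > 0, clf.classes_[1], clf.classes_[0])
        correct += int(np.sum(pred == y[test]))
        total += len(test)
    return 100.0 * correct / total


def decode_sphere(samples: SampleSet, spec: ClassifierSpec, C: float = 1.0) -> float:
    """Mean cross-validated decoding accuracy (%) for one voxel set."""
    folds = _folds(samples, spec.scheme, spec.train_phase, spec.test_phase)
    return _accuracy(samples.X, samples.y, folds, C=C)


@dataclass
class AccuracyMap:
    data: np.ndarray  # 3D, % accuracy at searchlight centers, NaN outside
    spec_id: int
    participant_id: str
    n_test_predictions: int = 0
    radius_voxels: int = 4
    meta: dict = field(default_factory=dict)


def searchlight_decode(
    betas_per_run,
    spec: ClassifierSpec,
    mask: np.ndarray | None = None,
    radius_voxels: int = 4,
    C: float = 1.0,
    participant_id: str = "",
    task_filter: str | None = None,
) -> AccuracyMap:
    """Decode every in-mask voxel's sphere; write accuracy at the center.

    Spheres are clipped to the mask; centers whose clipped sphere holds
    fewer than 2 voxels are decoded on whatever voxels remain and logged.
    Centers are independent, so any execution order yields the same map.
    """
    if mask is None:
        mask = betas_per_run[0].mask
    samples = assemble_samples(betas_per_run, spec, mask=mask, task_filter=task_filter)
    folds = _folds(samples, spec.scheme, spec.train_phase, spec.test_phase)
    n_test = sum(len(te) for _, te in folds)

    shape = mask.shape
    col_of_voxel = -np.ones(shape, dtype=np.int64)
    coords = np.argwhere(mask)
    col_of_voxel[mask] = np.arange(len(coords))
    offsets = sphere_offsets(radius_voxels)

    out = np.full(shape, np.nan)
    for center in coords:
        pts = center[None, :] + offsets
        ok = np.all((pts >= 0) & (pts < np.array(shape)[None, :]), axis=1)
        cols = col_of_voxel[tuple(pts[ok].T)]
        cols = cols[cols >= 0]
        if len(cols) < 2:
            logger.info(
                "searchlight center %s has %d in-mask voxels", tuple(center), len(cols)
            )
        out[tuple(center)] = _accuracy(samples.X[:, cols], samples.y, folds, C=C)
    return AccuracyMap(
        data=out,
        spec_id=spec.id,
        participant_id=participant_id,
        n_test_predictions=int(n_test * len(coords)),
        radius_voxels=radius_voxels,
        meta={"C": C, "scheme": spec.scheme, "n_samples": len(samples)},
    )
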