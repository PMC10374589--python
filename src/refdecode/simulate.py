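"""Synthetic 4D BOLD data with planted reference-frame codes.

The simulator stands in for raw scanner data: it embeds, in known regions,
zero-mean multivariate voxel patterns whose sign flips with a trial's class
along one coded dimension (anatomical foot, external side, movement-goal
side, or task rule), active during one trial phase (touch localization or
movement planning).  Symmetric two-class coding -- class patterns are
+/- effect_size x weights -- is the simplest structure a linear classifier
can read, and phase-specific (independent) weights are what make
cross-interval decoding fail, mirroring dynamic spatial coding; a
shared-weights option provides the control regime in which sensory codes
persist.

Noise is AR(1)-autocorrelated white noise plus a slow sinusoidal drift,
independent across voxels; optional motion nuisance series can be coupled
into the data.  All signal time courses are phase boxcars convolved with the
canonical HRF, so a correctly specified GLM recovers the planted amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from . import design as dsg
from .glm import MICROTIME_BINS, HrfKernel, canonical_hrf

DIMENSIONS = ("anatomical", "external", "goal", "rule", "none")
SIM_PHASES = ("localization", "planning")
#: trial phase during which each pattern phase is active
PHASE_WINDOW = {"localization": "touch", "planning": "planning"}
#: class label treated as the +1 sign for each coded dimension
POSITIVE_CLASS = {"anatomical": "left", "external": "left", "goal": "left", "rule": "pro"}


@dataclass
class VolumeGeometry:
    shape: tuple
    voxel_size_mm: tuple = (3.0, 3.0, 3.0)
    brain_mask: np.ndarray | None = None

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if self.brain_mask is None:
            self.brain_mask = ellipsoid_mask(self.shape)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.brain_mask.shape != self.shape:
            raise ValueError("brain mask shape does not match geometry")
        if not self.brain_mask.any():
            raise ValueError("brain mask is empty")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        return aff


def ellipsoid_mask(shape, fraction: float = 0.45) -> np.ndarray:
    """Brain-like ellipsoidal mask covering the central part of the grid."""
    grids = np.indices(shape).astype(float)
    m = np.zeros(shape, dtype=bool)
    r2 = np.zeros(shape)
    for ax, n in enumerate(shape):
        c = (n - 1) / 2.0
        r = max(fraction * n, 1.0)
        r2 += ((grids[ax] - c) / r) ** 2
    m[r2 <= 1.0] = True
    return m


def sphere_mask(shape, center, radius) -> np.ndarray:
    grids = np.indices(shape).astype(float)
    r2 = np.zeros(shape)
    for ax in range(len(shape)):
        r2 += (grids[ax] - center[ax]) ** 2
    return r2 <= radius**2


@dataclass
class RegionSpec:
    """Descriptor of one planted region (input to :func:`make_phantom`)."""

    name: str
    center_frac: tuple  # center as a fraction of the grid shape
    radius_frac: float  # radius as a fraction of min(shape)
    coded_dimension: str = "none"
    phases: tuple = ("localization",)
    effect_size: float = 1.0
    shared_weights: bool = False

    def mask(self, geometry: VolumeGeometry) -> np.ndarray:
        center = [f * (n - 1) for f, n in zip(self.center_frac, geometry.shape)]
        radius = max(self.radius_frac * min(geometry.shape), 1.0)
        return sphere_mask(geometry.shape, center, radius) & geometry.brain_mask


def default_region_specs(effect_size: float = 1.0) -> list:
    """The study-style phantom: an anterior region coding anatomical foot and
    a posterior region coding external side during touch localization, a
    broad network coding the movement-goal side during planning, and a rule
    region nested inside the goal network."""
    return [
        RegionSpec("anterior_anatomical", (0.30, 0.50, 0.55), 0.13, "anatomical",
                   ("localization",), effect_size),
        RegionSpec("posterior_external", (0.70, 0.50, 0.55), 0.13, "external",
                   ("localization",), effect_size),
        RegionSpec("goal_network", (0.50, 0.42, 0.38), 0.20, "goal",
                   ("planning",), effect_size),
        RegionSpec("rule_region", (0.50, 0.42, 0.38), 0.08, "rule",
                   ("planning",), effect_size),
    ]


@dataclass
class RegionPattern:
    name: str
    mask: np.ndarray
    coded_dimension: str
    phase: str
    weights: np.ndarray  # zero-mean, unit-RMS over region voxels
    effect_size: float

    def class_sign(self, label: str) -> float:
        return 1.0 if label == POSITIVE_CLASS[self.coded_dimension] else -1.0

    def class_pattern(self, label: str) -> np.ndarray:
        return self.class_sign(label) * self.effect_size * self.weights


@dataclass
class GroundTruth:
    regions: list  # region-level metadata dicts (incl. masks)
    effect_size_by_region: dict = field(default_factory=dict)

    def region_mask(self, name: str) -> np.ndarray:
        for r in self.regions:
            if r["name"] == name:
                return r["mask"]
        raise KeyError(name)

    def to_jsonable(self) -> list:
        out = []
        for r in self.regions:
            d = {k: v for k, v in r.items() if k != "mask"}
            d["voxels"] = [list(map(int, v)) for v in np.argwhere(r["mask"])]
            out.append(d)
        return out


def trial_class(trial, dimension: str) -> str:
    """The trial's class label along a coded dimension."""
    if dimension == "anatomical":
        return trial.foot
    if dimension == "external":
        return trial.external_side
    if dimension == "goal":
        return trial.goal_side
    if dimension == "rule":
        return trial.task_rule
    raise ValueError(f"dimension {dimension!r} has no class labels")


def make_phantom(geometry: VolumeGeometry, specs, rng=None):
    """Draw per-region, per-phase class patterns; returns (patterns, truth).

    Weights are zero-mean unit-RMS Gaussian vectors over the region's voxels,
    drawn independently per phase unless ``shared_weights`` is set.
    """
    rng = np.random.default_rng(rng)
    patterns = []
    truth_regions = []
    for spec in specs:
        mask = spec.mask(geometry)
        n_vox = int(mask.sum())
        if n_vox == 0:
            raise ValueError(f"region {spec.name!r} has an empty mask")
        shared = None
        for phase in spec.phases:
            if spec.shared_weights and shared is not None:
                w = shared
            else:
                w = rng.standard_normal(n_vox)
                w -= w.mean()
                rms = np.sqrt(np.mean(w**2))
                w = w / rms if rms > 0 else w
                shared = w
            patterns.append(
                RegionPattern(
                    name=spec.name,
                    mask=mask,
                    coded_dimension=spec.coded_dimension,
                    phase=phase,
                    weights=w,
                    effect_size=spec.effect_size,
                )
            )
        truth_regions.append(
            {
                "name": spec.name,
                "coded_dimension": spec.coded_dimension,
                "phases": list(spec.phases),
                "effect_size": spec.effect_size,
                "shared_weights": spec.shared_weights,
                "n_voxels": n_vox,
                "mask": mask,
            }
        )
    truth = GroundTruth(
        regions=truth_regions,
        effect_size_by_region={s.name: s.effect_size for s in specs},
    )
    return patterns, truth


@dataclass
class NoiseModel:
    white_sd: float = 1.0
    ar1_coefficient: float = 0.3
    drift_amplitude: float = 0.5
    drift_period_s: float = 192.0
    motion_amplitude: float = 0.0

    def __post_init__(self):
        if not 0 <= self.ar1_coefficient < 1:
            raise ValueError("ar1_coefficient must be in [0, 1)")


@dataclass
class BoldRun:
    data: np.ndarray  # x, y, z, t
    tr_seconds: float
    participant_id: str
    run_index: int
    posture: str
    motion: np.ndarray | None = None  # n_scans x 6


def _phase_signal(trials, run_length_tr, pattern, hrf: HrfKernel):
    """TR-resolution signed activation time course for one region pattern."""
    n_fine = run_length_tr * MICROTIME_BINS
    fine = np.zeros(n_fine)
    window = PHASE_WINDOW[pattern.phase]
    for trial in trials:
        label = trial_class(trial, pattern.coded_dimension)
        amp = pattern.class_sign(label) * pattern.effect_size
        onset = trial.onsets_tr[window]
        dur = trial.phase_duration_tr(window)
        fine[onset * MICROTIME_BINS : (onset + dur) * MICROTIME_BINS] = amp
    conv = np.convolve(fine, hrf.values)[:n_fine]
    return conv[::MICROTIME_BINS]


def simulate_run(
    run_trials,
    run_length_tr: int,
    geometry: VolumeGeometry,
    patterns,
    noise: NoiseModel,
    rng=None,
    tr_seconds: float = dsg.TR_SECONDS,
    hrf: HrfKernel | None = None,
) -> BoldRun:
    """Simulate one run: planted signal + drift + AR(1) + white noise.

    The signal is linear by construction: each (trial, phase, region)
    contributes a boxcar convolved with the HRF, scaled by the trial class's
    signed amplitude and the region's voxel weights.
    """
    if not run_trials:
        raise ValueError("run_trials is empty")
    last = run_trials[-1]
    if last.onsets_tr["execution"] + 1 > run_length_tr:
        raise ValueError("run_length_tr shorter than the trial sequence")
    rng = np.random.default_rng(rng)
    if hrf is None:
        hrf = canonical_hrf(tr_seconds / MICROTIME_BINS)

    shape = geometry.shape
    T = run_length_tr
    data = np.zeros(shape + (T,), dtype=np.float64)
    for pattern in patterns:
        if pattern.effect_size == 0:
            continue
        s = _phase_signal(run_trials, T, pattern, hrf)
        data[pattern.mask] += np.outer(pattern.weights, s)

    # noise only inside the brain mask
    vox = geometry.brain_mask
    n_vox = int(vox.sum())
    burn = 50
    eps = rng.standard_normal((T + burn, n_vox))
    rho = noise.ar1_coefficient
    if rho > 0:
        eps = sp_signal.lfilter([1.0], [1.0, -rho], eps, axis=0)
        eps *= np.sqrt(1 - rho**2)
    eps = eps[burn:] * noise.white_sd
    if noise.drift_amplitude > 0:
        t = np.arange(T) * tr_seconds
        phase0 = rng.uniform(0, 2 * np.pi, n_vox)
        eps += noise.drift_amplitude * np.sin(
            2 * np.pi * t[:, None] / noise.drift_period_s + phase0[None, :]
        )
    motion = None
    if noise.motion_amplitude >= 0:
        motion = np.cumsum(rng.standard_normal((T, 6)) * 0.02, axis=0)
        if noise.motion_amplitude > 0:
            loadings = rng.standard_normal((6, n_vox)) * noise.motion_amplitude
            eps += motion @ loadings
    data[vox] += eps.T

    return BoldRun(
        data=data.astype(np.float32),
        tr_seconds=tr_seconds,
        participant_id=run_trials[0].participant_id,
        run_index=run_trials[0].run_index,
        posture=run_trials[0].posture,
        motion=motion,
    )


def simulate_participant(
    participant_id: str,
    geometry: VolumeGeometry,
    region_specs,
    noise: NoiseModel,
    seed=None,
    n_runs: int = 12,
    n_trials: int = 33,
    start_posture: str = "uncrossed",
):
    """Design + phantom + all runs for one participant.

    Pattern weights are participant-specific while region locations are
    shared across the cohort, mirroring data normalized to a common space.
    Returns (design, patterns, truth, runs).
    """
    rng = np.random.default_rng(seed)
    design_obj = dsg.make_participant_design(
        participant_id,
        seed=rng,
        start_posture=start_posture,
        n_runs=n_runs,
        n_trials=n_trials,
    )
    patterns, truth = make_phantom(geometry, region_specs, rng=rng)
    runs = []
    for run in design_obj.run_indices:
        runs.append(
            simulate_run(
                design_obj.trials_for_run(run),
                design_obj.run_length_tr[run],
                geometry,
                patterns,
                noise,
                rng=rng,
                tr_seconds=design_obj.tr_seconds,
            )
        )
    return design_obj, patterns, truth, runs


def simulate_behavior(
    run_trials,
    error_rate: float = 0.047,
    saccade_rate: float = 0.102,
    rng=None,
    n_samples: int = 100,
    jitter_px: float = 3.0,
    saccade_px: float = 60.0,
):
    """Per-trial executed movement directions and synthetic eye traces.

    Wrong-direction trials flip the goal side; saccade trials get a position
    step well above the 2 s.d. / 20 px detection rule.  Default rates are
    realistic error (4.7%) and saccade (10.2%) frequencies for this task.
    Returns a list of dicts with keys ``executed_direction``, ``eye_trace``,
    ``planted_wrong``, ``planted_saccade``.
    """
    if not 0 <= error_rate <= 1 or not 0 <= saccade_rate <= 1:
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(rng)
    records = []
    for trial in run_trials:
        wrong = bool(rng.random() < error_rate)
        sacc = bool(rng.random() < saccade_rate)
        executed = dsg.opposite(trial.goal_side) if wrong else trial.goal_side
        trace = rng.normal(0.0, jitter_px, size=(n_samples, 2))
        if sacc:
            start = int(rng.integers(n_samples // 2, n_samples - 1))
            angle = rng.uniform(0, 2 * np.pi)
            step = saccade_px * np.array([np.cos(angle), np.sin(angle)])
            trace[start:] += step
        records.append(
            {
                "trial_index": trial.trial_index,
                "run_index": trial.run_index,
                "executed_direction": executed,
                "eye_trace": trace,
                "planted_wrong": wrong,
                "planted_saccade": sacc,
            }
        )
    return records
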