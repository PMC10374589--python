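"""Run-wise GLM: canonical HRF, design matrices, high-pass + AR(1) fitting.

The experiment-wide model comprises 23 predictors: 2 posture baselines
(fixation delays and run rest periods), 4 touch-localization predictors
(posture x foot), 8 planning and 8 execution predictors (posture x foot x
task), and 1 error predictor that absorbs all phases of error trials.
Posture is constant within a run, so any single run's design matrix contains
exactly 12 of them (1 baseline, 2 localization, 4 planning, 4 execution,
1 error).

Phase regressors are built at a microtime resolution (16 bins per TR),
convolved with the canonical double-gamma HRF, and sampled at the TR grid.
Two model variants are supported: ``epoch`` models each phase as a boxcar of
its true 1-4 TR duration (default), ``impulse`` as a fixed 1-TR boxcar at
phase onset.  Fitting projects a 128 s discrete-cosine high-pass basis out
of both data and design, estimates a single AR(1) coefficient pooled over
in-mask voxels from OLS residuals, and returns prewhitened least-squares
betas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .design import PHASES, POSTURES, SIDES, TASKS, TR_SECONDS

#: canonical double-gamma parameters (seconds): response/undershoot delays,
#: dispersions, undershoot ratio, kernel length
HRF_PARAMS = dict(
    peak_delay=6.0,
    undershoot_delay=16.0,
    peak_dispersion=1.0,
    undershoot_dispersion=1.0,
    undershoot_ratio=1.0 / 6.0,
    length=32.0,
)

MICROTIME_BINS = 16


@dataclass
class HrfKernel:
    values: np.ndarray
    dt_seconds: float
    params: dict = field(default_factory=lambda: dict(HRF_PARAMS))

    @property
    def peak_time_s(self) -> float:
        return float(np.argmax(self.values) * self.dt_seconds)


def canonical_hrf(dt_seconds: float) -> HrfKernel:
    """Canonical double-gamma HRF sampled every ``dt_seconds``.

    Difference of two gamma densities (peak at ~5 s, small undershoot),
    normalized to unit sum so convolution preserves sustained amplitudes.
    """
    if dt_seconds <= 0:
        raise ValueError("dt_seconds must be positive")
    p = HRF_PARAMS
    t = np.arange(0, p["length"] + dt_seconds, dt_seconds)
    peak = stats.gamma.pdf(t, p["peak_delay"] / p["peak_dispersion"], scale=p["peak_dispersion"])
    under = stats.gamma.pdf(
        t, p["undershoot_delay"] / p["undershoot_dispersion"], scale=p["undershoot_dispersion"]
    )
    values = peak - p["undershoot_ratio"] * under
    values = values / values.sum()
    return HrfKernel(values=values, dt_seconds=dt_seconds)


def predictor_names_for_posture(posture: str) -> list:
    """The 12 predictors present in a run of the given posture."""
    names = [f"baseline_{posture}"]
    names += [f"loc_{posture}_{foot}" for foot in SIDES]
    names += [f"plan_{posture}_{foot}_{task}" for foot in SIDES for task in TASKS]
    names += [f"exec_{posture}_{foot}_{task}" for foot in SIDES for task in TASKS]
    names.append("error")
    return names


def all_predictor_names() -> list:
    """The experiment-wide union of predictor names (23)."""
    names = []
    for posture in POSTURES:
        names.extend(n for n in predictor_names_for_posture(posture) if n != "error")
    names.append("error")
    return names


def trial_predictor(trial, phase: str) -> str | None:
    """Predictor a trial phase loads on (None -> baseline handles it)."""
    if trial.is_error and phase != "fixation":
        return "error"
    if phase == "fixation":
        return None
    if phase == "touch":
        return f"loc_{trial.posture}_{trial.foot}"
    if phase == "planning":
        return f"plan_{trial.posture}_{trial.foot}_{trial.task_rule}"
    if phase == "execution":
        return f"exec_{trial.posture}_{trial.foot}_{trial.task_rule}"
    raise ValueError(f"unknown phase {phase!r}")


def dct_highpass_basis(n_scans: int, tr_seconds: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Discrete-cosine drift basis (constant + slow cosines below cutoff)."""
    n_basis = int(np.floor(2.0 * n_scans * tr_seconds / cutoff_s + 1))
    n_basis = max(n_basis, 1)
    t = np.arange(n_scans)
    cols = [np.ones(n_scans) / np.sqrt(n_scans)]
    for k in range(1, n_basis):
        cols.append(np.sqrt(2.0 / n_scans) * np.cos(np.pi * k * (2 * t + 1) / (2 * n_scans)))
    return np.column_stack(cols)


@dataclass
class DesignMatrix:
    X: np.ndarray  # n_scans x n_task_predictors
    names: list
    run_index: int
    filter_basis: np.ndarray  # n_scans x n_drift (incl. constant)
    model_variant: str = "epoch"
    motion: np.ndarray | None = None  # optional n_scans x 6 nuisance columns
    empty_columns: list = field(default_factory=list)

    @property
    def n_scans(self) -> int:
        return self.X.shape[0]

    def full_matrix(self) -> np.ndarray:
        blocks = [self.X]
        if self.motion is not None:
            blocks.append(self.motion)
        blocks.append(self.filter_basis)
        return np.column_stack(blocks)


def build_design_matrix(
    run_trials,
    run_length_tr: int,
    variant: str = "epoch",
    hrf: HrfKernel | None = None,
    hp_cutoff_s: float = 128.0,
    tr_seconds: float = TR_SECONDS,
    rest_start_tr: int = 11,
    rest_end_tr: int = 4,
    motion: np.ndarray | None = None,
) -> DesignMatrix:
    """Build one run's design matrix at TR resolution.

    The baseline predictor models the per-trial fixation delays together with
    the run's start/end rest periods.  Error-trial phases are reassigned to
    the shared error predictor.  An all-zero task column (e.g. the error
    column of a run without error trials) is retained and flagged in
    ``empty_columns``.
    """
    if variant not in ("epoch", "impulse"):
        raise ValueError(f"unknown model variant {variant!r}")
    if not run_trials:
        raise ValueError("run_trials is empty")
    posture = run_trials[0].posture
    run_index = run_trials[0].run_index
    names = predictor_names_for_posture(posture)
    if hrf is None or hrf.dt_seconds != tr_seconds / MICROTIME_BINS:
        hrf = canonical_hrf(tr_seconds / MICROTIME_BINS)

    n_fine = run_length_tr * MICROTIME_BINS
    fine = {name: np.zeros(n_fine) for name in names}

    baseline = fine[f"baseline_{posture}"]
    baseline[: rest_start_tr * MICROTIME_BINS] = 1.0
    baseline[n_fine - rest_end_tr * MICROTIME_BINS :] = 1.0

    for trial in run_trials:
        if trial.posture != posture:
            raise ValueError("mixed postures within a run")
        for phase in PHASES:
            onset = trial.onsets_tr[phase]
            dur = trial.phase_duration_tr(phase) if variant == "epoch" else 1
            if onset + trial.phase_duration_tr(phase) > run_length_tr:
                raise ValueError(
                    f"trial {trial.trial_index} phase {phase} extends past run end"
                )
            target = trial_predictor(trial, phase)
            row = fine[f"baseline_{posture}"] if target is None else fine[target]
            row[onset * MICROTIME_BINS : (onset + dur) * MICROTIME_BINS] = 1.0

    X = np.empty((run_length_tr, len(names)))
    for j, name in enumerate(names):
        conv = np.convolve(fine[name], hrf.values)[:n_fine]
        X[:, j] = conv[:: MICROTIME_BINS]
    empty = [names[j] for j in range(len(names)) if not np.any(X[:, j])]

    basis = dct_highpass_basis(run_length_tr, tr_seconds, hp_cutoff_s)
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != run_length_tr:
            raise ValueError("motion regressors do not match run length")
        motion = motion - motion.mean(axis=0)
    return DesignMatrix(
        X=X,
        names=list(names),
        run_index=run_index,
        filter_basis=basis,
        model_variant=variant,
        motion=motion,
        empty_columns=empty,
    )


@dataclass
class BetaImages:
    """Per-run GLM output: one 3D coefficient volume per predictor."""

    betas: dict  # predictor name -> 3D array
    residual_variance: np.ndarray  # 3D
    ar1_coefficient: float
    run_index: int
    mask: np.ndarray
    model_variant: str = "epoch"
    hrf_params: dict = field(default_factory=lambda: dict(HRF_PARAMS))

    def stack(self, names, voxel_index=None):
        """Samples x voxels feature matrix for the named predictors."""
        rows = []
        for name in names:
            vol = self.betas[name]
            rows.append(vol[self.mask] if voxel_index is None else vol.reshape(-1)[voxel_index])
        return np.array(rows)


def _residualize(A: np.ndarray, basis: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(basis, A, rcond=None)
    return A - basis @ coef


def fit_glm_ar1(
    bold: np.ndarray,
    dm: DesignMatrix,
    mask: np.ndarray,
    ar1: float | str = "estimate",
) -> BetaImages:
    """Fit the run GLM with high-pass projection and AR(1) prewhitening.

    ``bold`` is a 4D (x, y, z, t) array; ``mask`` selects the voxels fit.
    The high-pass (and optional motion) basis is projected out of both data
    and task predictors; the AR(1) coefficient is the pooled lag-1
    autocorrelation of the OLS residuals across in-mask voxels (pass a float
    to fix it, e.g. ``ar1=0`` for plain OLS).
    """
    if bold.shape[-1] != dm.n_scans:
        raise ValueError(
            f"BOLD has {bold.shape[-1]} scans but design matrix has {dm.n_scans}"
        )
    Y = bold[mask].T.astype(float)  # n_scans x n_voxels
    nuisance = dm.filter_basis
    if dm.motion is not None:
        nuisance = np.column_stack([nuisance, dm.motion])
    Yf = _residualize(Y, nuisance)
    Xf = _residualize(dm.X, nuisance)

    rank = np.linalg.matrix_rank(Xf)
    n_nonempty = dm.X.shape[1] - len(dm.empty_columns)
    if rank < n_nonempty:
        warnings.warn(
            "rank-deficient design matrix after filtering; dependent or empty "
            f"columns: {dm.empty_columns or 'unknown'} (pseudo-inverse used)",
            stacklevel=2,
        )

    beta, *_ = np.linalg.lstsq(Xf, Yf, rcond=None)
    resid = Yf - Xf @ beta
    if ar1 == "estimate":
        num = float(np.sum(resid[1:] * resid[:-1]))
        den = float(np.sum(resid**2))
        rho = num / den if den > 0 else 0.0
        rho = float(np.clip(rho, -0.99, 0.99))
    else:
        rho = float(ar1)
    if rho != 0.0:
        Yw = np.empty_like(Yf)
        Xw = np.empty_like(Xf)
        Yw[0] = np.sqrt(1 - rho**2) * Yf[0]
        Xw[0] = np.sqrt(1 - rho**2) * Xf[0]
        Yw[1:] = Yf[1:] - rho * Yf[:-1]
        Xw[1:] = Xf[1:] - rho * Xf[:-1]
        beta, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
        resid = Yw - Xw @ beta
    dof = max(dm.n_scans - np.linalg.matrix_rank(dm.X) - nuisance.shape[1], 1)
    resvar_flat = (resid**2).sum(axis=0) / dof

    shape = bold.shape[:3]
    betas = {}
    for j, name in enumerate(dm.names):
        vol = np.zeros(shape)
        vol[mask] = beta[j]
        betas[name] = vol
    resvar = np.zeros(shape)
    resvar[mask] = resvar_flat
    return BetaImages(
        betas=betas,
        residual_variance=resvar,
        ar1_coefficient=rho,
        run_index=dm.run_index,
        mask=mask.astype(bool),
        model_variant=dm.model_variant,
    )


def build_run_design_matrices(design, variant="epoch", hp_cutoff_s=128.0):
    """dm_builder adapter for design selection: yields (run, names, X)."""
    hrf = canonical_hrf(design.tr_seconds / MICROTIME_BINS)
    out = []
    for run in design.run_indices:
        trials = design.trials_for_run(run)
        dm = build_design_matrix(
            trials,
            design.run_length_tr[run],
            variant=variant,
            hrf=hrf,
            hp_cutoff_s=hp_cutoff_s,
            tr_seconds=design.tr_seconds,
            rest_start_tr=design.rest_start_tr,
            rest_end_tr=design.rest_end_tr,
        )
        out.append((run, dm.names, dm.X))
    return out
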