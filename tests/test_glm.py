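"""HRF, design matrices, and AR(1)-prewhitened GLM estimation."""

import numpy as np
import pytest

from refdecode import design as d
from refdecode import glm
from refdecode.simulate import (
    NoiseModel,
    RegionSpec,
    VolumeGeometry,
    make_phantom,
    simulate_run,
)


def small_design(seed=3, n_runs=6, n_trials=17):
    return d.make_participant_design("sub-x", seed=seed, n_runs=n_runs, n_trials=n_trials)


class TestHrf:
    def test_peak_time_near_five_seconds(self):
        h = glm.canonical_hrf(0.01)
        assert h.peak_time_s == pytest.approx(5.0, abs=0.05)

    def test_zero_at_onset_and_undershoot(self):
        h = glm.canonical_hrf(0.1)
        assert h.values[0] == pytest.approx(0.0, abs=1e-8)
        assert h.values.min() < 0  # small negative undershoot
        assert h.values.max() > 0

    def test_peak_time_stable_under_dt_refinement(self):
        coarse = glm.canonical_hrf(0.2)
        fine = glm.canonical_hrf(0.1)
        assert abs(coarse.peak_time_s - fine.peak_time_s) <= 0.2

    def test_invalid_dt_raises(self):
        with pytest.raises(ValueError):
            glm.canonical_hrf(0.0)


class TestDesignMatrix:
    def test_run_has_exactly_12_predictors(self):
        dz = small_design()
        dm = glm.build_design_matrix(dz.trials_for_run(1), dz.run_length_tr[1])
        posture = dz.posture_schedule[1]
        expected = {
            f"baseline_{posture}",
            f"loc_{posture}_left", f"loc_{posture}_right",
            *{f"plan_{posture}_{f}_{t}" for f in d.SIDES for t in d.TASKS},
            *{f"exec_{posture}_{f}_{t}" for f in d.SIDES for t in d.TASKS},
            "error",
        }
        assert set(dm.names) == expected
        assert len(dm.names) == 12

    def test_experiment_wide_union_is_23(self):
        assert len(glm.all_predictor_names()) == 23

    def test_error_free_run_flags_empty_error_column(self):
        dz = small_design()
        dm = glm.build_design_matrix(dz.trials_for_run(1), dz.run_length_tr[1])
        assert "error" in dm.empty_columns
        j = dm.names.index("error")
        assert not np.any(dm.X[:, j])

    def test_error_trial_moves_phases_to_error_predictor(self):
        dz = small_design()
        trials = dz.trials_for_run(1)
        trials[0].is_error = True
        dm = glm.build_design_matrix(trials, dz.run_length_tr[1])
        assert "error" not in dm.empty_columns

    def test_epoch_impulse_agree_when_all_delays_one(self):
        dz = small_design()
        trials = [t for t in dz.trials_for_run(1)]
        # force all delays to 1 TR and recompute contiguous onsets
        cursor = dz.rest_start_tr
        for t in trials:
            t.loc_delay_tr = t.plan_delay_tr = 1
            t.onsets_tr = {
                "fixation": cursor, "touch": cursor + 1,
                "planning": cursor + 2, "execution": cursor + 3,
            }
            cursor += 4
        length = cursor + dz.rest_end_tr
        dm_epoch = glm.build_design_matrix(trials, length, variant="epoch")
        dm_impulse = glm.build_design_matrix(trials, length, variant="impulse")
        np.testing.assert_allclose(dm_epoch.X, dm_impulse.X)

    def test_unknown_variant_raises(self):
        dz = small_design()
        with pytest.raises(ValueError):
            glm.build_design_matrix(dz.trials_for_run(1), dz.run_length_tr[1],
                                    variant="boxcar")

    def test_highpass_basis_attached(self):
        dz = small_design()
        dm = glm.build_design_matrix(dz.trials_for_run(1), dz.run_length_tr[1])
        T = dz.run_length_tr[1]
        expected_cols = int(np.floor(2 * T * d.TR_SECONDS / 128.0 + 1))
        assert dm.filter_basis.shape == (T, expected_cols)


def _one_region_setup(effect_size=1.0, seed=0):
    geometry = VolumeGeometry((10, 10, 10))
    specs = [RegionSpec("r", (0.5, 0.5, 0.5), 0.2, "anatomical",
                        ("localization",), effect_size)]
    patterns, truth = make_phantom(geometry, specs, rng=seed)
    dz = small_design(seed=seed, n_runs=6, n_trials=17)
    return geometry, patterns, dz


class TestFitGlm:
    def test_noiseless_run_recovers_planted_amplitudes(self):
        geometry, patterns, dz = _one_region_setup()
        noise = NoiseModel(white_sd=0.0, ar1_coefficient=0.0, drift_amplitude=0.0)
        run = simulate_run(dz.trials_for_run(1), dz.run_length_tr[1],
                           geometry, patterns, noise, rng=0)
        dm = glm.build_design_matrix(dz.trials_for_run(1), dz.run_length_tr[1])
        beta = glm.fit_glm_ar1(run.data.astype(np.float64), dm, geometry.brain_mask)
        posture = dz.posture_schedule[1]
        p = patterns[0]
        expected_left = p.class_pattern("left")
        got = beta.betas[f"loc_{posture}_left"][p.mask]
        np.testing.assert_allclose(got, expected_left, rtol=1e-5, atol=1e-5)
        got_right = beta.betas[f"loc_{posture}_right"][p.mask]
        np.testing.assert_allclose(got_right, -expected_left, rtol=1e-5, atol=1e-5)

    def test_ar_zero_equals_ols_oracle(self, rng):
        dz = small_design()
        dm = glm.build_design_matrix(dz.trials_for_run(1), dz.run_length_tr[1])
        T = dm.n_scans
        shape = (4, 4, 4)
        mask = np.ones(shape, dtype=bool)
        bold = rng.normal(size=shape + (T,))
        beta = glm.fit_glm_ar1(bold, dm, mask, ar1=0.0)
        # independent OLS: residualize by hand, then lstsq
        Y = bold.reshape(-1, T).T
        F = dm.filter_basis
        R = np.eye(T) - F @ np.linalg.pinv(F)
        b_oracle, *_ = np.linalg.lstsq(R @ dm.X, R @ Y, rcond=None)
        for j, name in enumerate(dm.names):
            np.testing.assert_allclose(
                beta.betas[name].reshape(-1), b_oracle[j], atol=1e-8
            )

    def test_prewhitening_matches_glsar_oracle(self, rng):
        """Betas at a fixed AR(1) coefficient match statsmodels GLSAR."""
        sm = pytest.importorskip("statsmodels.api")
        T, rho = 120, 0.4
        X = rng.normal(size=(T, 2))
        y = rng.normal(size=T)
        dm = glm.DesignMatrix(
            X=X, names=["a", "b"], run_index=1, filter_basis=np.zeros((T, 0))
        )
        bold = y.reshape(1, 1, 1, T)
        mask = np.ones((1, 1, 1), dtype=bool)
        beta = glm.fit_glm_ar1(bold, dm, mask, ar1=rho)
        fit = sm.GLSAR(y, X, rho=[rho]).fit()
        got = [beta.betas["a"].item(), beta.betas["b"].item()]
        # GLSAR drops the first observation instead of scaling it, so
        # agreement is to O(1/T), not exact
        np.testing.assert_allclose(got, fit.params, atol=2e-2)

    def test_highpass_removes_slow_drift(self):
        """A pure drift slower than the cutoff leaves <5% of its variance."""
        dz = small_design()
        dm = glm.build_design_matrix(dz.trials_for_run(1), dz.run_length_tr[1])
        T = dm.n_scans
        t = np.arange(T) * d.TR_SECONDS
        drift = np.sin(2 * np.pi * t / 300.0)  # period 300 s > 128 s cutoff
        bold = np.tile(drift, (2, 2, 2, 1))
        mask = np.ones((2, 2, 2), dtype=bool)
        beta = glm.fit_glm_ar1(bold, dm, mask, ar1=0.0)
        resid_var = float(beta.residual_variance.mean())
        assert resid_var < 0.05 * drift.var()

    def test_zscore_calibration_under_ar1_noise(self):
        """With AR(1)=0.5 null noise, whitened betas are calibrated: the
        empirical variance of beta/se stays within ~15% of 1."""
        rng = np.random.default_rng(42)
        dz = small_design(seed=9)
        dm = glm.build_design_matrix(dz.trials_for_run(1), dz.run_length_tr[1])
        T = dm.n_scans
        n_vox = 200
        rho = 0.5
        eps = rng.normal(size=(T + 50, n_vox))
        for i in range(1, T + 50):
            eps[i] += rho * eps[i - 1]
        eps = eps[50:] * np.sqrt(1 - rho**2)
        bold = eps.T.reshape(n_vox, 1, 1, T)
        mask = np.ones((n_vox, 1, 1), dtype=bool)
        beta = glm.fit_glm_ar1(bold, dm, mask)
        # pooled estimate is attenuated by the high-pass projection (the
        # filter absorbs low-frequency autocorrelation) but stays positive
        assert 0.15 < beta.ar1_coefficient < rho + 0.1
        # analytic se from the whitened design (reconstructed independently;
        # the innovation-scale noise sd is 1 by construction)
        F = dm.filter_basis
        Xf = dm.X - F @ np.linalg.lstsq(F, dm.X, rcond=None)[0]
        r = beta.ar1_coefficient
        Xw = np.vstack([np.sqrt(1 - r**2) * Xf[:1], Xf[1:] - r * Xf[:-1]])
        keep = [j for j, nm in enumerate(dm.names) if nm not in dm.empty_columns]
        cov = np.linalg.pinv(Xw[:, keep].T @ Xw[:, keep])
        j = keep.index(dm.names.index(f"loc_{dz.posture_schedule[1]}_left"))
        se = np.sqrt(cov[j, j])  # noise sd is 1 by construction
        name = dm.names[keep[j]]
        z = np.array([beta.betas[name][i, 0, 0] for i in range(n_vox)]) / se
        assert np.var(z) == pytest.approx(1.0, abs=0.15)
        assert np.mean(z) == pytest.approx(0.0, abs=3.0 / np.sqrt(n_vox))

    def test_scan_mismatch_raises(self):
        dz = small_design()
        dm = glm.build_design_matrix(dz.trials_for_run(1), dz.run_length_tr[1])
        with pytest.raises(ValueError):
            glm.fit_glm_ar1(np.zeros((2, 2, 2, 10)), dm, np.ones((2, 2, 2), bool))
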