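"""Classifier specs, searchlight geometry, and SVM decoding."""

import itertools

import numpy as np
import pytest

from helpers import lattice_ball_count, svm_oracle_predict
from refdecode import design as d
from refdecode.decoding import (
    SampleSet,
    assemble_samples,
    decode_sphere,
    make_classifier_specs,
    searchlight_decode,
    sphere_offsets,
)

SPECS = {s.id: s for s in make_classifier_specs()}


class TestClassifierSpecs:
    def test_eight_specs_with_expected_schemes(self):
        assert sorted(SPECS) == list(range(1, 9))
        assert SPECS[3].scheme == SPECS[4].scheme == "cross_phase"
        for sid in (1, 2, 5, 6, 7, 8):
            assert SPECS[sid].scheme == "within_loro"

    def test_goal_spec_pools_dissociated_cells(self):
        """Cells requiring the same left-directed movement share a class."""
        spec = SPECS[7]
        pooled = [
            ("uncrossed", "left", "pro"),
            ("crossed", "left", "anti"),
            ("crossed", "right", "pro"),
            ("uncrossed", "right", "anti"),
        ]
        labels = {spec.label(p, f, t) for p, f, t in pooled}
        assert labels == {"left"}

    def test_anatomical_spec_ignores_posture(self):
        spec = SPECS[1]
        for foot in d.SIDES:
            assert spec.label("uncrossed", foot) == spec.label("crossed", foot) == foot

    def test_rule_spec_labels_are_the_task(self):
        spec = SPECS[8]
        for posture, foot, task in itertools.product(d.POSTURES, d.SIDES, d.TASKS):
            assert spec.label(posture, foot, task) == task

    def test_external_spec_flips_with_posture(self):
        spec = SPECS[2]
        assert spec.label("crossed", "right") == "left"
        assert spec.label("uncrossed", "right") == "right"


class TestSphereOffsets:
    @pytest.mark.parametrize("radius,expected", [(0, 1), (1, 7), (2, 33), (4, 257)])
    def test_counts_match_lattice_enumeration(self, radius, expected):
        offs = sphere_offsets(radius)
        assert len(offs) == lattice_ball_count(radius) == expected
        assert (offs == 0).all(axis=1).any()  # center included

    def test_negative_radius_raises(self):
        with pytest.raises(ValueError):
            sphere_offsets(-1)


class TestAssembleSamples:
    def test_localization_sample_counts(self, tiny_betas):
        geometry, part, betas = tiny_betas
        samples = assemble_samples(betas, SPECS[1])
        n_runs = len(betas)
        assert len(samples) == 2 * n_runs
        assert np.bincount(samples.y).tolist() == [n_runs, n_runs]

    def test_planning_sample_counts(self, tiny_betas):
        geometry, part, betas = tiny_betas
        samples = assemble_samples(betas, SPECS[7])
        n_runs = len(betas)
        assert len(samples) == 4 * n_runs
        assert np.bincount(samples.y).tolist() == [2 * n_runs, 2 * n_runs]

    def test_external_class_composition(self, tiny_betas):
        """Class 'left space' pools loc_left on uncrossed runs with loc_right
        on crossed runs."""
        geometry, part, betas = tiny_betas
        spec = SPECS[2]
        for beta in betas:
            posture = part["design"].posture_schedule[beta.run_index]
            for foot in d.SIDES:
                expected = foot if posture == "uncrossed" else d.opposite(foot)
                assert spec.label(posture, foot) == expected

    def test_class_balance_in_every_loro_fold(self, tiny_betas):
        """Enumerate folds for all within-run specs: training class counts
        are equal in every fold."""
        geometry, part, betas = tiny_betas
        for sid in (1, 2, 5, 6, 7, 8):
            samples = assemble_samples(betas, SPECS[sid])
            for run in np.unique(samples.chunks):
                train_y = samples.y[samples.chunks != run]
                counts = np.bincount(train_y)
                assert counts[0] == counts[1]

    def test_missing_predictor_raises(self, tiny_betas):
        geometry, part, betas = tiny_betas
        import copy

        broken = [copy.copy(betas[0])]
        broken[0].betas = {
            k: v for k, v in betas[0].betas.items() if not k.startswith("plan")
        }
        broken.append(betas[1])
        with pytest.raises(KeyError, match="plan"):
            assemble_samples(broken, SPECS[7])

    def test_cross_phase_sets(self, tiny_betas):
        geometry, part, betas = tiny_betas
        samples = assemble_samples(betas, SPECS[3])
        n_runs = len(betas)
        assert np.sum(samples.phase == "localization") == 2 * n_runs
        assert np.sum(samples.phase == "planning") == 4 * n_runs


def toy_samples(rng, n_runs=4, n_feat=5, sep=4.0):
    """Linearly separable two-class set, one sample per class per run."""
    w = rng.normal(size=n_feat)
    w /= np.linalg.norm(w)
    X, y, chunks = [], [], []
    for run in range(n_runs):
        for cls in (0, 1):
            X.append((sep / 2 if cls else -sep / 2) * w + rng.normal(0, 0.1, n_feat))
            y.append(cls)
            chunks.append(run)
    return SampleSet(
        X=np.array(X), y=np.array(y), chunks=np.array(chunks),
        phase=np.array(["localization"] * len(y)), classes=("left", "right"),
    )


class TestDecodeSphere:
    def test_separable_data_decodes_perfectly(self, rng):
        samples = toy_samples(rng)
        assert decode_sphere(samples, SPECS[1]) == 100.0

    def test_permuted_labels_give_chance_accuracy(self):
        """With labels permuted within runs (preserving the design's run-wise
        class balance) mean accuracy over many noise problems is ~50%."""
        rng = np.random.default_rng(17)
        accs = []
        n_runs, reps = 6, 300
        for _ in range(reps):
            samples = toy_samples(rng, n_runs=n_runs, sep=0.0)
            for r in range(n_runs):
                idx = np.flatnonzero(samples.chunks == r)
                samples.y[idx] = rng.permutation(samples.y[idx])
            accs.append(decode_sphere(samples, SPECS[1]))
        accs = np.array(accs)
        n_test = 2 * n_runs
        se = 100.0 * 0.5 / np.sqrt(n_test * len(accs))
        assert accs.mean() == pytest.approx(50.0, abs=5 * se + 2.0)

    def test_fold_order_invariance(self, rng):
        samples = toy_samples(rng, n_runs=5, sep=1.0)
        base = decode_sphere(samples, SPECS[1])
        perm = rng.permutation(len(samples.y))
        shuffled = SampleSet(
            X=samples.X[perm], y=samples.y[perm], chunks=samples.chunks[perm],
            phase=samples.phase[perm], classes=samples.classes,
        )
        assert decode_sphere(shuffled, SPECS[1]) == base

    def test_label_flip_equivariance(self, rng):
        samples = toy_samples(rng, n_runs=5, sep=1.0)
        flipped = SampleSet(
            X=samples.X, y=1 - samples.y, chunks=samples.chunks,
            phase=samples.phase, classes=samples.classes,
        )
        assert decode_sphere(flipped, SPECS[1]) == decode_sphere(samples, SPECS[1])

    def test_single_class_training_raises(self, rng):
        samples = toy_samples(rng, n_runs=2)
        samples.y[:] = 0
        with pytest.raises(ValueError):
            decode_sphere(samples, SPECS[1])

    def test_agrees_with_primal_qp_oracle(self):
        """LORO fold predictions match a brute-force soft-margin maximizer
        on <=8-sample problems."""
        rng = np.random.default_rng(5)
        for trial in range(10):
            X = rng.normal(size=(8, 3))
            y = np.array([0, 1] * 4)
            chunks = np.repeat(np.arange(4), 2)
            correct_lib = correct_oracle = 0
            for run in range(4):
                tr, te = chunks != run, chunks == run
                samples = SampleSet(
                    X=X, y=y, chunks=chunks,
                    phase=np.array(["localization"] * 8), classes=("a", "b"),
                )
                pred = svm_oracle_predict(
                    X[tr], 2.0 * y[tr] - 1.0, X[te], C=1.0
                )
                correct_oracle += int(np.sum(pred == 2 * y[te] - 1))
            acc_lib = decode_sphere(samples, SPECS[1])
            acc_oracle = 100.0 * correct_oracle / 8
            assert acc_lib == pytest.approx(acc_oracle)


class TestSearchlight:
    def test_planted_region_peaks_inside_mask(self, tiny_config, tiny_betas):
        geometry, part, betas = tiny_betas
        amap = searchlight_decode(betas, SPECS[1], mask=geometry.brain_mask,
                                  radius_voxels=2)
        truth_mask = part["truth"].region_mask("anterior_anatomical")
        peak = np.unravel_index(np.nanargmax(amap.data), amap.data.shape)
        # peak lies inside or adjacent (within the searchlight radius) of
        # the planted region
        dist = np.min(
            np.linalg.norm(np.argwhere(truth_mask) - np.array(peak), axis=1)
        )
        assert dist <= 2.0
        assert np.nanmax(amap.data) > 90.0

    def test_values_bounded_and_masked(self, tiny_betas):
        geometry, part, betas = tiny_betas
        amap = searchlight_decode(betas, SPECS[8], mask=geometry.brain_mask,
                                  radius_voxels=1)
        inside = amap.data[geometry.brain_mask]
        assert np.isfinite(inside).all()
        assert inside.min() >= 0.0 and inside.max() <= 100.0
        assert np.isnan(amap.data[~geometry.brain_mask]).all()
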