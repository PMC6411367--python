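"""Basis functions, estimator primitives, cross-validation, generalization."""

import numpy as np
import pandas as pd
import pytest
from sklearn.covariance import ledoit_wolf_shrinkage

from oddballiem.design import label_conditions
from oddballiem.encoding import (
    BasisSet,
    apply_encoder,
    compute_filter,
    crossval_decode,
    condition_average,
    default_window_samples,
    evaluate_basis,
    make_design_matrix,
    plan_folds,
    recenter_responses,
    shrinkage_covariance,
    temporal_generalization,
    temporal_smooth,
    train_encoder,
    train_weights,
)


class TestBasis:
    def test_peak_and_trough(self):
        assert evaluate_basis(40.0, 40.0) == 1.0
        assert evaluate_basis(130.0, 40.0) == 0.0  # 90 deg away

    def test_frozen_value_at_20deg(self):
        assert evaluate_basis(60.0, 40.0, power=8) == pytest.approx(0.6079761341, abs=1e-9)

    def test_channel_sum_is_constant(self):
        # harmonic cancellation over 9 equispaced centers: sum = 9*C(8,4)/2^8
        basis = BasisSet()
        rng = np.random.default_rng(0)
        theta = rng.uniform(0, 180, 1000)
        sums = basis(theta).sum(axis=0)
        assert np.allclose(sums, 2.4609375, atol=1e-10)

    def test_wrap_makes_it_180_periodic(self):
        theta = np.linspace(0, 180, 50)
        assert np.allclose(evaluate_basis(theta, 60.0), evaluate_basis(theta + 180.0, 60.0))


class TestDesignMatrix:
    def test_orientation_column_peaks_at_coded_channel(self, grid_events):
        basis = BasisSet()
        C = make_design_matrix(grid_events, basis, "orientation")
        k = grid_events.loc[3, "orientation_deg"] / 20
        assert C[int(k), 3] == 1.0

    def test_mismatch_wraps_onto_orientation_grid(self, grid_events):
        basis = BasisSet()
        ev = grid_events.copy()
        ev["mismatch_deg"] = -40.0
        C_mm = make_design_matrix(ev, basis, "mismatch")
        ev2 = ev.copy()
        ev2["orientation_deg"] = 140.0
        C_or = make_design_matrix(ev2, basis, "orientation")
        assert np.allclose(C_mm, C_or)

    def test_column_sums_constant(self, grid_events):
        C = make_design_matrix(grid_events, BasisSet(), "orientation")
        assert np.allclose(C.sum(axis=0), 2.4609375)

    def test_off_grid_angle_rejected(self, grid_events):
        ev = grid_events.copy()
        ev.loc[0, "orientation_deg"] = 13.0
        with pytest.raises(ValueError, match="grid"):
            make_design_matrix(ev, BasisSet(), "orientation")


class TestTemporalSmooth:
    def test_window_one_is_identity(self):
        data = np.random.default_rng(0).standard_normal((4, 3, 20))
        out = temporal_smooth(data, 10, 1)
        assert np.allclose(out, data[:, :, 10].T)

    def test_constant_signal_unchanged(self):
        data = np.full((2, 3, 20), 7.0)
        assert np.allclose(temporal_smooth(data, 10, 7), 7.0)

    def test_default_window_at_256hz(self):
        n = default_window_samples(256.0)
        assert n == 7
        assert n / 256.0 * 1000 == pytest.approx(27.34, abs=0.05)

    def test_boundary_violation_raises(self):
        data = np.zeros((1, 2, 10))
        with pytest.raises(IndexError):
            temporal_smooth(data, 1, 7)


class TestEstimatorPrimitives:
    def test_train_weights_exact_on_rank_one_data(self):
        rng = np.random.default_rng(1)
        w = rng.standard_normal(5)
        c = rng.random(20)
        assert np.allclose(train_weights(np.outer(w, c), c), w)

    def test_train_weights_matches_lstsq_oracle(self):
        rng = np.random.default_rng(2)
        B = rng.standard_normal((4, 10))
        c = rng.random(10)
        oracle = np.linalg.lstsq(c[:, None], B.T, rcond=None)[0].ravel()
        assert np.allclose(train_weights(B, c), oracle, atol=1e-10)

    def test_train_weights_homogeneity(self):
        rng = np.random.default_rng(3)
        B = rng.standard_normal((4, 10))
        c = rng.random(10)
        assert np.allclose(train_weights(B, 3.0 * c), train_weights(B, c) / 3.0)

    def test_degenerate_channel_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            train_weights(np.ones((3, 5)), np.zeros(5))

    def test_shrinkage_intensity_matches_sklearn(self):
        from oddballiem.encoding import _lw_intensity

        rng = np.random.default_rng(40)
        for n, p in [(30, 6), (200, 16), (12, 8)]:
            eps = rng.standard_normal((p, n)) * (1 + rng.random(p))[:, None]
            lam = float(_lw_intensity(eps @ eps.T, np.sum(eps**2, axis=0), n))
            ref = float(ledoit_wolf_shrinkage(eps.T, assume_centered=True))
            assert lam == pytest.approx(ref, abs=1e-12)

    def test_shrinkage_spherical_residuals_approach_identity(self):
        rng = np.random.default_rng(4)
        eps = 2.0 * rng.standard_normal((6, 5000))
        sigma = shrinkage_covariance(eps)
        assert np.allclose(sigma, 4.0 * np.eye(6), atol=0.25)

    def test_shrinkage_keeps_small_sample_invertible(self):
        rng = np.random.default_rng(5)
        eps = rng.standard_normal((8, 9))
        sigma = shrinkage_covariance(eps)
        eig = np.linalg.eigvalsh(sigma)
        assert eig.min() > 0
        assert eig.max() / eig.min() < 1e6

    def test_zero_residuals_rejected(self):
        with pytest.raises(ValueError):
            shrinkage_covariance(np.zeros((3, 10)))

    def test_filter_identity_covariance(self):
        w = np.array([1.0, 2.0, 2.0])
        v = compute_filter(w, np.eye(3))
        assert np.allclose(v, w / 9.0)

    def test_filter_unit_gain(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            w = rng.standard_normal(5)
            A = rng.standard_normal((5, 5))
            sigma = A @ A.T + 0.5 * np.eye(5)
            assert compute_filter(w, sigma) @ w == pytest.approx(1.0, abs=1e-10)

    def test_filter_matches_dense_solve_oracle(self):
        w = np.array([1.0, 0.0, -1.0])
        sigma = np.diag([1.0, 2.0, 4.0])
        siw = np.linalg.solve(sigma, w)
        assert np.allclose(compute_filter(w, sigma), siw / (w @ siw))

    def test_apply_encoder_linearity_and_permutation_invariance(self):
        rng = np.random.default_rng(7)
        B = rng.standard_normal((6, 40))
        C = np.abs(rng.standard_normal((3, 40)))
        model = train_encoder(B, C)
        assert np.allclose(
            apply_encoder(model, np.tile(model.train_means[:, None], (1, 5))), 0.0
        )
        perm = rng.permutation(6)
        model_p = train_encoder(B[perm], C)
        Bt = rng.standard_normal((6, 8))
        assert np.allclose(
            apply_encoder(model_p, Bt[perm]), apply_encoder(model, Bt), atol=1e-8
        )

    def test_apply_encoder_shape_mismatch(self):
        model = train_encoder(np.random.default_rng(0).standard_normal((4, 30)), np.random.default_rng(1).random((2, 30)))
        with pytest.raises(ValueError):
            apply_encoder(model, np.zeros((5, 3)))

    def test_full_chain_matches_independent_reimplementation(self):
        # dense oracle: explicit textbook formulas for weights, Ledoit-Wolf
        # intensity, shrunk covariance, filter, decoding
        rng = np.random.default_rng(8)
        for _ in range(20):
            n_el = int(rng.integers(3, 7))
            n_tr = int(rng.integers(12, 31))
            B = rng.standard_normal((n_el, n_tr))
            C = np.abs(rng.standard_normal((3, n_tr))) + 0.1
            model = train_encoder(B, C)
            Bt = rng.standard_normal((n_el, 5))
            got = apply_encoder(model, Bt)

            mean = B.mean(axis=1, keepdims=True)
            Bd = B - mean
            V = np.empty((n_el, 3))
            for i in range(3):
                c = C[i]
                w = (Bd @ c) / (c @ c)
                eps = Bd - np.outer(w, c)
                X = eps.T
                emp0 = X.T @ X / n_tr
                mu = np.trace(emp0) / n_el
                d2 = np.sum((emp0 - mu * np.eye(n_el)) ** 2) / n_el
                b2 = min(
                    sum(np.sum((np.outer(x, x) - emp0) ** 2) for x in X) / n_tr**2 / n_el,
                    d2,
                )
                lam = b2 / d2
                emp = X.T @ X / (n_tr - 1)
                nu = np.trace(emp) / n_el
                sig = (1 - lam) * emp + lam * nu * np.eye(n_el)
                siw = np.linalg.solve(sig, w)
                V[:, i] = siw / (w @ siw)
            oracle = V.T @ (Bt - mean)
            assert np.allclose(got, oracle, atol=1e-8)


class TestRecenter:
    def test_peak_moves_to_center_and_sum_preserved(self):
        act = np.zeros((9, 2))
        act[2, 0] = 1.0
        act[7, 1] = 1.0
        out = recenter_responses(act, np.array([2, 7]))
        assert out[4, 0] == 1.0 and out[4, 1] == 1.0
        assert np.allclose(out.sum(axis=0), act.sum(axis=0))

    def test_random_profiles_average_flat(self):
        rng = np.random.default_rng(9)
        act = rng.standard_normal((9, 20000))
        coded = rng.integers(0, 9, 20000)
        mean = recenter_responses(act, coded).mean(axis=1)
        assert np.abs(mean).max() < 0.05


class TestCrossValidation:
    def test_single_label_folds_partition_all_trials(self):
        rng = np.random.default_rng(10)
        blocks = np.repeat(np.arange(6), 10)
        labels = np.zeros(60)
        plan = plan_folds(blocks, labels, 3, np.zeros(60), rng)
        allidx = np.concatenate(plan.folds)
        assert sorted(allidx) == list(range(60))

    def test_balanced_subsets_within_folds(self):
        rng = np.random.default_rng(11)
        blocks = np.repeat(np.arange(6), 12)
        labels = np.tile(np.array(["a", "a", "b"]), 24)
        plan = plan_folds(blocks, labels, 3, np.zeros(72), rng)
        for fold in plan.folds:
            counts = pd.Series(labels[fold]).value_counts()
            assert counts.nunique() == 1

    def test_usage_counts_near_uniform_over_iterations(self):
        rng = np.random.default_rng(12)
        blocks = np.repeat(np.arange(6), 12)
        labels = np.tile(np.array(["a", "a", "b"]), 24)
        usage = np.zeros(72)
        for _ in range(20):
            plan_folds(blocks, labels, 3, usage, rng)
        for lab in ("a", "b"):
            u = usage[labels == lab]
            assert u.max() - u.min() <= 2

    def test_missing_condition_raises(self):
        rng = np.random.default_rng(13)
        blocks = np.repeat(np.arange(3), 4)
        labels = np.array(["a"] * 4 + ["a"] * 4 + ["b"] * 4)
        with pytest.raises(ValueError, match="absent"):
            plan_folds(blocks, labels, 3, np.zeros(12), rng)

    def test_noiseless_decoding_recovers_tuned_profiles(self, grid_events):
        # patterns x basis activations, tiny noise: the centered average
        # profile must peak at 0 offset and fall off with distance
        rng = np.random.default_rng(14)
        ev = pd.concat([grid_events] * 3, ignore_index=True)
        ev["block"] = np.repeat(np.arange(6), 18)
        basis = BasisSet()
        P = rng.standard_normal((8, 9))
        C = basis(ev["orientation_deg"].to_numpy())
        n_s = 15
        data = np.einsum("ec,ct->te", P, C)[:, :, None] * np.ones(n_s)
        data = data + 0.01 * rng.standard_normal(data.shape)
        profiles, counts, tps = crossval_decode(
            data, ev, basis, "orientation", folds=3, iterations=2,
            window_samples=1, timepoints=[7], rng=rng,
        )
        avg = condition_average(profiles, np.zeros(len(ev)))[0.0][:, 0]
        assert np.argmax(avg) == 4
        assert avg[4] > avg[2] > avg[0]

    def test_generalization_diagonal_equals_on_axis_decoding(self, grid_events):
        rng = np.random.default_rng(15)
        ev = pd.concat([grid_events] * 2, ignore_index=True)
        ev["block"] = np.repeat(np.arange(4), 18)
        basis = BasisSet()
        data = rng.standard_normal((len(ev), 6, 30))
        gen, tps = temporal_generalization(
            data, ev, basis, "orientation", folds=2, iterations=2,
            window_samples=3, stride=10, rng=np.random.default_rng(99),
        )
        profiles, _, tps2 = crossval_decode(
            data, ev, basis, "orientation", folds=2, iterations=2,
            window_samples=3, timepoints=tps, rng=np.random.default_rng(99),
        )
        on_axis = condition_average(profiles, ev["condition"].to_numpy())
        assert np.array_equal(tps, tps2)
        for lab, arr in gen.items():
            diag = np.stack([arr[:, i, i] for i in range(tps.size)], axis=1)
            assert np.allclose(diag, on_axis[lab], atol=1e-10)

    def test_time_localized_pattern_does_not_generalize(self, grid_events):
        # signal present only in an early window: training there and testing
        # late must give near-flat profiles
        rng = np.random.default_rng(16)
        ev = pd.concat([grid_events] * 3, ignore_index=True)
        ev["block"] = np.repeat(np.arange(6), 18)
        basis = BasisSet()
        P = rng.standard_normal((8, 9)) * 3
        C = basis(ev["orientation_deg"].to_numpy())
        n_s = 40
        env = np.zeros(n_s)
        env[5:15] = 1.0
        data = np.einsum("ec,ct->te", P, C)[:, :, None] * env
        data = data + 0.5 * rng.standard_normal(data.shape)
        gen, tps = temporal_generalization(
            data, ev, basis, "orientation", folds=3, iterations=2,
            window_samples=3, stride=9, rng=rng,
        )
        arr = gen["control"]
        inside = [i for i, t in enumerate(tps) if 5 <= t < 15]
        outside = [i for i, t in enumerate(tps) if t >= 20]
        tuning_depth = lambda prof: prof[4] - 0.5 * (prof[0] + prof[8])
        on = np.mean([tuning_depth(arr[:, i, i]) for i in inside])
        off = np.mean([abs(tuning_depth(arr[:, i, j])) for i in inside for j in outside])
        assert on > 5 * off
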