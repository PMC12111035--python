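"""Wavelength-selector contracts: PCA/SPA/RFE/iWOA, screeners, joint
strategies and the reduction accounting."""

import itertools

import numpy as np
import pytest

from flourspec.selection import (
    BinarySwarmConfig,
    SelectionError,
    WavelengthSubset,
    _chaotic_init,
    iwoa_select,
    joint_select,
    pca_select,
    reduction_percent,
    rfe_select,
    screen_features,
    spa_select,
)


class TestReductionPercent:
    @pytest.mark.parametrize(
        "p, k, expected", [(360, 20, 94.44), (360, 30, 91.67), (360, 360, 0.0), (3, 1, 66.67)]
    )
    def test_values(self, p, k, expected):
        assert reduction_percent(p, k) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            reduction_percent(10, 11)


class TestWavelengthSubset:
    def test_report_row_and_json(self):
        wl = np.linspace(900, 1700, 360)
        sub = WavelengthSubset(np.array([5, 2]), wl, "spa", 360)
        assert np.array_equal(sub.indices, [2, 5])
        assert sub.reduction == 99.44
        assert "nm" in sub.to_csv_row() and "99.44%" in sub.to_csv_row()

    def test_duplicate_indices_rejected(self):
        with pytest.raises(ValueError):
            WavelengthSubset(np.array([1, 1]), None, "pca", 10)


class TestPcaSelect:
    def test_dominant_variance_column_ranked_first(self, rng):
        X = rng.normal(size=(50, 6))
        X[:, 3] *= 20.0
        sub = pca_select(X, k=1)
        assert sub.indices[0] == 3

    def test_k_equals_p_identity(self, rng):
        X = rng.normal(size=(20, 5))
        assert np.array_equal(pca_select(X, 5).indices, np.arange(5))

    def test_planted_factor_bands_recovered(self):
        """Three latent factors loading on known column blocks: at least 2
        of 3 block centers must appear in the top-10, for 20 seeds."""
        wins = 0
        centers = [5, 20, 35]
        for seed in range(20):
            r = np.random.default_rng(seed)
            F = r.normal(size=(60, 3))
            load = np.zeros((3, 45))
            for f, c in enumerate(centers):
                load[f, c - 2 : c + 3] = [0.5, 0.9, 1.0, 0.9, 0.5]
            X = F @ load + r.normal(0, 0.05, size=(60, 45))
            top10 = set(pca_select(X, 10).indices.tolist())
            near = sum(any(abs(i - c) <= 2 for i in top10) for c in centers)
            wins += near >= 2
        assert wins >= 18

    def test_permutation_consistency(self, rng):
        X = rng.normal(size=(30, 8)) * rng.uniform(0.5, 3.0, 8)
        perm = rng.permutation(8)
        a = pca_select(X, 3).indices
        b = pca_select(X[:, perm], 3).indices
        assert set(perm[b]) == set(a)


class TestSpaSelect:
    def test_collinear_copies_never_both_selected(self, rng):
        v = rng.normal(size=12)
        w = rng.normal(size=12)
        w -= (w @ v) / (v @ v) * v  # orthogonal to v
        X = np.column_stack([v, 2 * v, w])
        sub = spa_select(X, 2, start_index=0)
        assert not {0, 1} <= set(sub.indices.tolist())
        assert 2 in sub.indices

    def test_orthogonal_matrix_full_selection(self):
        X = np.linalg.qr(np.random.default_rng(0).normal(size=(8, 6)))[0]
        sub = spa_select(X, 6, start_index=0)
        assert set(sub.indices.tolist()) == set(range(6))

    def test_near_minimal_collinearity_vs_brute_force(self):
        """On random 8x6 matrices the fixed-start SPA subset's worst
        pairwise correlation is within 0.15 of the exhaustive optimum over
        all 3-subsets containing the start column (autoscaled columns, so
        projected norm is a monotone function of correlation)."""
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.normal(size=(8, 6)) + 0.4 * r.normal(size=(8, 1))
            Xs = (X - X.mean(0)) / X.std(0)
            corr = np.abs(np.corrcoef(X.T))

            def max_corr(cols):
                return max(corr[i, j] for i, j in itertools.combinations(cols, 2))

            best = min(
                max_corr((0,) + c) for c in itertools.combinations(range(1, 6), 2)
            )
            sub = spa_select(Xs, 3, start_index=0)
            assert max_corr(sub.indices.tolist()) <= best + 0.15

    def test_no_perfect_pairwise_correlation(self, rng):
        base = rng.normal(size=(20, 4))
        X = np.column_stack([base, base[:, 0] * 3.0])  # exact copy of col 0
        sub = spa_select(X, 4, start_index=0)
        corr = np.abs(np.corrcoef(X[:, sub.indices].T))
        np.fill_diagonal(corr, 0.0)
        assert corr.max() < 1.0 - 1e-10

    def test_rank_deficient_exhaustion_raises(self):
        v = np.random.default_rng(1).normal(size=10)
        X = np.column_stack([v, 2 * v, -v])
        with pytest.raises(SelectionError):
            spa_select(X, 3, start_index=0)

    def test_auto_start_requires_y(self, rng):
        with pytest.raises(ValueError):
            spa_select(rng.normal(size=(10, 4)), 2, start_index="auto")

    def test_permutation_consistency(self, rng):
        X = rng.normal(size=(15, 6))
        perm = rng.permutation(6)
        a = spa_select(X, 3, start_index=2).indices
        b = spa_select(X[:, perm], 3, start_index=int(np.flatnonzero(perm == 2)[0])).indices
        assert set(perm[b]) == set(a)


class TestRfeSelect:
    def test_perfect_predictor_survives(self, rng):
        X = rng.normal(size=(40, 6))
        y = X[:, 0].copy()
        assert rfe_select(X, y, 1).indices.tolist() == [0]

    def test_k_equals_p_identity(self, rng):
        X = rng.normal(size=(20, 5))
        assert np.array_equal(rfe_select(X, rng.normal(size=20), 5).indices, np.arange(5))

    def test_permutation_consistency(self, rng):
        X = rng.normal(size=(40, 8))
        y = X @ np.array([1.0, 0.8, 0, 0, 0.5, 0, 0, 0]) + rng.normal(0, 0.1, 40)
        perm = rng.permutation(8)
        a = rfe_select(X, y, 3).indices
        b = rfe_select(X[:, perm], y, 3).indices
        assert set(perm[b]) == set(a)


class TestIwoaSelect:
    def test_k_equals_p_full_mask(self, rng):
        X = rng.normal(size=(30, 6))
        y = rng.normal(size=30)
        sub = iwoa_select(X, y, 6, BinarySwarmConfig(seed=0))
        assert np.array_equal(sub.indices, np.arange(6))

    def test_chaotic_init_avoids_degenerate_orbits(self):
        """x0 = 0.5 maps to 1 then sticks at 0 under the logistic map, so
        seeds must avoid the fixed points {0, .25, .5, .75, 1}."""
        pos = _chaotic_init(np.random.default_rng(0), (50, 40), 4.0)
        assert pos.shape == (50, 40)
        assert np.all((pos > 0.0) & (pos < 1.0))
        # no whale's orbit collapsed to a constant
        assert np.all(pos.std(axis=1) > 0.01)

    def test_seed_determinism_and_monotone_trace(self, rng):
        X = rng.normal(size=(40, 12))
        y = X[:, 2] + 0.5 * X[:, 7] + rng.normal(0, 0.2, 40)
        a = iwoa_select(X, y, 4, BinarySwarmConfig(seed=5, iterations=15))
        b = iwoa_select(X, y, 4, BinarySwarmConfig(seed=5, iterations=15))
        assert np.array_equal(a.indices, b.indices)
        assert np.all(np.diff(a.trace) <= 0)

    def test_exact_cardinality(self, rng):
        X = rng.normal(size=(40, 25))
        y = rng.normal(size=40)
        sub = iwoa_select(X, y, 7, BinarySwarmConfig(seed=1, iterations=10))
        assert sub.k == 7


class TestScreenFeatures:
    def test_mi_ranks_deterministic_dependence_first(self, rng):
        X = rng.normal(size=(200, 6))
        y = np.sin(X[:, 3])  # deterministic function of column 3
        pool = screen_features(X, y, "mutual_information", m=1)
        assert pool.tolist() == [3]

    def test_mi_noise_column_within_permutation_null(self, rng):
        from flourspec.selection import _binned_mi

        x = rng.normal(size=150)
        y = rng.normal(size=150)
        observed = _binned_mi(x, y)
        null = [_binned_mi(x, rng.permutation(y)) for _ in range(200)]
        assert observed < np.mean(null) + 2 * np.std(null) + 1e-12

    def test_identity_pool(self, rng):
        X = rng.normal(size=(50, 5))
        assert np.array_equal(
            screen_features(X, rng.normal(size=50), "mutual_information", m=5),
            np.arange(5),
        )

    def test_kernel_pca_mode_runs(self, rng):
        X = rng.normal(size=(40, 10))
        y = X[:, 0] + rng.normal(0, 0.1, 40)
        pool = screen_features(X, y, "kernel_pca", m=4)
        assert pool.size == 4

    def test_bad_mode_and_pool(self, rng):
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        with pytest.raises(ValueError):
            screen_features(X, y, "nope", m=2)
        with pytest.raises(ValueError):
            screen_features(X, y, "mutual_information", m=9)


class TestJointSelect:
    @pytest.mark.parametrize(
        "strategy, k, pool, reduction", [("iwoa_spa", 20, 60, 94.44), ("rfe_iwoa", 30, 90, 91.67)]
    )
    def test_published_cardinality_and_reduction(
        self, strategy, k, pool, reduction, default_synthetic
    ):
        spectra, _ = default_synthetic
        from flourspec.spectra import fit_standardizer_arrays

        std = fit_standardizer_arrays(spectra.absorbance, spectra.reference)
        X = std.transform(spectra.absorbance)
        y = std.transform_target(spectra.reference)
        Xc = spectra.absorbance - spectra.absorbance.mean(0)
        sub = joint_select(
            strategy, X, y, k, pool_size=pool,
            config=BinarySwarmConfig(seed=0, iterations=15),
            wavelengths=spectra.wavelengths_nm, X_spa=Xc,
        )
        assert sub.k == k
        assert sub.reduction == reduction
        assert np.all(np.diff(sub.indices) > 0)

    def test_pool_equals_k_is_stage1_output(self, rng):
        X = rng.normal(size=(40, 15))
        y = X[:, 1] + rng.normal(0, 0.1, 40)
        cfg = BinarySwarmConfig(seed=3, iterations=10)
        joint = joint_select("rfe_iwoa", X, y, 4, pool_size=4, config=cfg)
        stage1 = rfe_select(X, y, 4, step=max(1, 15 // 20))
        assert np.array_equal(joint.indices, stage1.indices)

    def test_invalid_pool(self, rng):
        X = rng.normal(size=(20, 6))
        with pytest.raises(ValueError):
            joint_select("iwoa_spa", X, rng.normal(size=20), 4, pool_size=3)
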