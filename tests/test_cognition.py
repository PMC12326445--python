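"""Missingness exclusion, low-rank completion and g extraction."""

import numpy as np
import pandas as pd
import pytest

from rsvnet import (
    CognitiveMatrix,
    choose_rank,
    exclude_by_missingness,
    extract_g,
    generate_battery,
    lowrank_impute,
)


def _battery(scores: np.ndarray) -> CognitiveMatrix:
    df = pd.DataFrame(scores, columns=[f"t{j}" for j in range(scores.shape[1])])
    return CognitiveMatrix(df)


class TestExclusion:
    def _with_missing(self, counts):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((len(counts), 10))
        for i, c in enumerate(counts):
            X[i, :c] = np.nan
        return _battery(X)

    def test_more_than_seven_missing_dropped(self):
        battery = self._with_missing([8, 0])
        kept, dropped = exclude_by_missingness(battery, max_missing=7)
        assert len(dropped) == 1
        assert kept.n_subjects == 1

    def test_exactly_seven_missing_retained(self):
        battery = self._with_missing([7, 0])
        kept, dropped = exclude_by_missingness(battery, max_missing=7)
        assert dropped == []
        assert kept.n_subjects == 2

    def test_fully_observed_unchanged(self):
        battery = self._with_missing([0, 0, 0])
        kept, dropped = exclude_by_missingness(battery)
        assert dropped == []
        pd.testing.assert_frame_equal(kept.scores, battery.scores)

    def test_everyone_dropped_is_an_error(self):
        battery = self._with_missing([9, 9])
        with pytest.raises(ValueError):
            exclude_by_missingness(battery, max_missing=7)


class TestLowRankImpute:
    def test_complete_matrix_returned_unchanged(self):
        rng = np.random.default_rng(1)
        battery = _battery(rng.standard_normal((20, 5)))
        res = lowrank_impute(battery, rank=2)
        pd.testing.assert_frame_equal(res.matrix.scores, battery.scores)
        assert res.n_iter == 0

    def test_observed_entries_preserved_exactly(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 6))
        mask = rng.random(X.shape) < 0.2
        battery = _battery(np.where(mask, np.nan, X))
        res = lowrank_impute(battery, rank=2)
        out = res.matrix.scores.to_numpy()
        np.testing.assert_array_equal(out[~mask], X[~mask])

    def test_exact_rank1_recovery(self):
        rng = np.random.default_rng(3)
        X = np.outer(rng.standard_normal(100), rng.standard_normal(10) + 2.0)
        mask = rng.random(X.shape) < 0.2
        battery = _battery(np.where(mask, np.nan, X))
        res = lowrank_impute(battery, rank=1, max_iter=2000, tol=1e-13)
        rmse = np.sqrt(np.mean((res.matrix.scores.to_numpy()[mask] - X[mask]) ** 2))
        assert rmse < 1e-6

    def test_noisy_rank2_recovery_within_two_sigma(self):
        rng = np.random.default_rng(4)
        sigma = 0.1
        X = (rng.standard_normal((200, 10)) @ np.diag([3, 2] + [0] * 8)
             @ rng.standard_normal((10, 10)) / np.sqrt(10))
        X += sigma * rng.standard_normal(X.shape)
        mask = rng.random(X.shape) < 0.2
        battery = _battery(np.where(mask, np.nan, X))
        res = lowrank_impute(battery, rank=2)
        rmse = np.sqrt(np.mean((res.matrix.scores.to_numpy()[mask] - X[mask]) ** 2))
        assert rmse < 2 * sigma

    def test_nonconvergence_is_flagged_not_raised(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 8))
        mask = rng.random(X.shape) < 0.3
        battery = _battery(np.where(mask, np.nan, X))
        res = lowrank_impute(battery, rank=3, max_iter=2, tol=1e-15)
        assert not res.converged

    def test_cv_rank_selection_finds_rank_one(self):
        rng = np.random.default_rng(6)
        X = np.outer(rng.standard_normal(120), rng.standard_normal(8) + 1.5)
        X += 0.01 * rng.standard_normal(X.shape)
        mask = rng.random(X.shape) < 0.1
        battery = _battery(np.where(mask, np.nan, X))
        assert choose_rank(battery, ranks=range(1, 5)) == 1


class TestExtractG:
    def test_two_perfectly_correlated_tasks(self):
        x = np.random.default_rng(7).standard_normal(100)
        battery = _battery(np.column_stack([x, 2 * x + 1]))
        res = extract_g(battery)
        assert res.prop_var == pytest.approx(1.0)
        np.testing.assert_allclose(np.abs(res.loadings), 1.0, atol=1e-10)

    def test_g_is_z_normalised(self):
        battery, _ = generate_battery(500, missing_rate=0.0, seed=8)
        res = extract_g(battery)
        assert res.g.mean() == pytest.approx(0.0, abs=1e-8)
        assert res.g.std(ddof=1) == pytest.approx(1.0, abs=1e-8)

    def test_sign_flip_of_one_task_flips_only_its_loading(self):
        battery, _ = generate_battery(300, missing_rate=0.0, seed=9)
        res = extract_g(battery)
        flipped_scores = battery.scores.copy()
        flipped_scores["task05"] = -flipped_scores["task05"]
        flipped = CognitiveMatrix(flipped_scores, battery.sign_convention)
        res2 = extract_g(flipped)
        np.testing.assert_allclose(res2.g, res.g, atol=1e-10)
        assert res2.loadings["task05"] == pytest.approx(-res.loadings["task05"])
        others = [t for t in battery.task_names if t != "task05"]
        np.testing.assert_allclose(res2.loadings[others], res.loadings[others],
                                   atol=1e-10)

    def test_column_order_invariance(self):
        battery, _ = generate_battery(300, missing_rate=0.0, seed=10)
        res = extract_g(battery)
        reordered = CognitiveMatrix(battery.scores.iloc[:, ::-1],
                                    battery.sign_convention)
        res2 = extract_g(reordered)
        np.testing.assert_allclose(res2.g, res.g, atol=1e-8)
        np.testing.assert_allclose(res2.loadings[battery.task_names],
                                   res.loadings[battery.task_names], atol=1e-8)

    def test_affine_rescaling_invariance(self):
        battery, _ = generate_battery(300, missing_rate=0.0, seed=11)
        res = extract_g(battery)
        rescaled_scores = battery.scores.copy()
        rescaled_scores["task02"] = rescaled_scores["task02"] * 37.0 + 5.0
        res2 = extract_g(CognitiveMatrix(rescaled_scores, battery.sign_convention))
        np.testing.assert_allclose(res2.g, res.g, atol=1e-8)
        np.testing.assert_allclose(res2.loadings, res.loadings, atol=1e-8)

    def test_matches_sklearn_pca_first_component(self):
        # independent route: scikit-learn PCA on the z-scored battery
        from sklearn.decomposition import PCA

        battery, _ = generate_battery(400, missing_rate=0.0, seed=12)
        res = extract_g(battery)
        X = battery.scores.to_numpy()
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        pca = PCA(n_components=1).fit(Z)
        score = pca.transform(Z)[:, 0]
        score = (score - score.mean()) / score.std(ddof=1)
        if np.corrcoef(score, res.g)[0, 1] < 0:
            score = -score
        np.testing.assert_allclose(res.g, score, atol=1e-8)
        assert res.prop_var == pytest.approx(
            pca.explained_variance_ratio_[0], abs=1e-10)

    def test_zero_variance_task_named(self):
        X = np.random.default_rng(13).standard_normal((50, 3))
        X[:, 1] = 4.2
        with pytest.raises(ValueError, match="t1"):
            extract_g(_battery(X))

    def test_missing_values_rejected(self):
        X = np.random.default_rng(14).standard_normal((50, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            extract_g(_battery(X))
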