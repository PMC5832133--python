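"""LASSO-LDA fitting, linear scoring, and accumulated-score voting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.stats import pearsonr

from p300screen.classifier import (
    ScoreMatrix,
    fit_lasso_lda,
    score,
    score_repetition,
    select_target,
)
from p300screen.errors import ConfigurationError
from p300screen.preprocessing import FeatureVector
from p300screen.synthetic import (
    DEFAULT_CHANNEL_GAINS,
    DEFAULT_TARGET_COMPONENTS,
    make_erp_template,
)


def _toy_data(rng, n=20, d=5):
    X = rng.standard_normal((n, d))
    w = rng.standard_normal(d)
    y = np.sign(X @ w + 0.1 * rng.standard_normal(n))
    return X, y


class TestFitLassoLda:
    def test_full_shrinkage_limit_is_intercept_only(self, rng):
        X, y = _toy_data(rng)
        model = fit_lasso_lda(X, y, lambda_grid=np.array([1e6]))
        assert not model.w.any()
        assert model.b == pytest.approx(y.mean())
        assert model.support.size == 0

    def test_vanishing_penalty_matches_least_squares(self, rng):
        X, y = _toy_data(rng)
        model = fit_lasso_lda(X, y, lambda_grid=np.array([1e-12]))
        ones = np.column_stack([np.ones(len(y)), X])
        beta = np.linalg.lstsq(ones, y, rcond=None)[0]
        np.testing.assert_allclose(model.w, beta[1:], atol=1e-6)
        assert model.b == pytest.approx(beta[0], abs=1e-6)

    def test_moderate_penalty_selects_the_informative_feature(self, rng):
        y = np.array([1.0, 1.0, 1.0, -1.0, -1.0, -1.0])
        x_informative = y * 1.0
        x_noise = np.array([1.0, -1.0, 0.0, 1.0, -1.0, 0.0])  # orthogonal to y
        X = np.column_stack([x_informative, x_noise])
        model = fit_lasso_lda(X, y, lambda_grid=np.array([0.3]), cv_folds=2)
        assert list(model.support) == [0]

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ConfigurationError):
            fit_lasso_lda(X, np.ones(10))

    def test_too_few_rows_for_folds_rejected(self, rng):
        X = rng.standard_normal((4, 3))
        y = np.array([1.0, -1.0, 1.0, -1.0])
        with pytest.raises(ConfigurationError):
            fit_lasso_lda(X, y, cv_folds=5)

    def test_fit_is_deterministic(self, rng):
        X, y = _toy_data(rng, n=40, d=10)
        a = fit_lasso_lda(X, y)
        b = fit_lasso_lda(X, y)
        assert a.lam == b.lam
        np.testing.assert_array_equal(a.w, b.w)


class TestScore:
    def test_zero_vector_scores_zero(self, rng):
        model = _unit_model(d=5, index=2, b=1.5)
        assert score(model, np.zeros(5)) == 0.0
        assert score(model, np.zeros(5), include_bias=True) == 1.5

    def test_unit_weight_projects_coordinate(self, rng):
        model = _unit_model(d=8, index=3)
        x = rng.standard_normal(8)
        assert score(model, x) == pytest.approx(x[3])

    def test_matches_elementwise_sum_oracle(self, rng):
        from p300screen.classifier import LassoLdaModel

        w = rng.standard_normal(50)
        x = rng.standard_normal(50)
        model = LassoLdaModel(w=w, b=0.3, lam=0.1, cv_folds=5)
        oracle = sum(wi * xi for wi, xi in zip(w, x))
        assert score(model, x) == pytest.approx(oracle, abs=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        model = _unit_model(d=5, index=0)
        with pytest.raises(ConfigurationError):
            score(model, np.zeros(6))


def _unit_model(d, index, b=0.0):
    from p300screen.classifier import LassoLdaModel

    w = np.zeros(d)
    w[index] = 1.0
    return LassoLdaModel(w=w, b=b, lam=0.1, cv_folds=5)


class TestSelectTarget:
    def test_tie_breaks_toward_lowest_marker(self):
        sm = ScoreMatrix(np.array([[1.0, 1.0], [2.0, 0.0], [0.0, 0.0]]))
        result = select_target(sm, 2)
        np.testing.assert_allclose(result.accumulated, [2.0, 2.0, 0.0])
        assert result.selected == 0

    def test_hand_summed_example(self):
        sm = ScoreMatrix(np.array([[0.1, 0.2], [0.5, 0.9], [0.3, 0.1]]))
        result = select_target(sm, 2)
        np.testing.assert_allclose(result.accumulated, [0.3, 1.4, 0.4])
        assert result.selected == 1

    def test_single_trial_reduces_to_first_column_argmax(self, rng):
        scores = rng.standard_normal((12, 10))
        assert select_target(ScoreMatrix(scores), 1).selected == np.argmax(
            scores[:, 0]
        )

    @pytest.mark.parametrize("l", [0, 11])
    def test_l_out_of_range_rejected(self, l, rng):
        sm = ScoreMatrix(rng.standard_normal((12, 10)))
        with pytest.raises(ConfigurationError):
            select_target(sm, l)

    @settings(deadline=None, max_examples=50)
    @given(
        # integer-valued floats keep the sums exact, so ties are preserved
        scores=arrays(np.float64, (6, 8), elements=st.integers(-10, 10).map(float)),
        offsets=arrays(np.float64, (8,), elements=st.integers(-100, 100).map(float)),
        l=st.integers(1, 8),
    )
    def test_invariant_to_per_trial_score_offsets(self, scores, offsets, l):
        """Adding any constant to every marker's score within a trial leaves
        the vote unchanged — the reason the bias term can be dropped."""
        base = select_target(ScoreMatrix(scores), l)
        shifted = select_target(ScoreMatrix(scores + offsets[None, :]), l)
        assert shifted.selected == base.selected


class TestScoreRepetition:
    def _features(self, rng, n_markers=3, n_trials=2):
        out = []
        for trial in range(n_trials):
            for m in range(n_markers):
                out.append(
                    FeatureVector(
                        values=rng.standard_normal(5),
                        marker_id=m,
                        trial=trial,
                        repetition=4,
                        label=1 if m == 1 else -1,
                    )
                )
        return out

    def test_grid_is_complete_and_carries_target(self, rng):
        model = _unit_model(d=5, index=0)
        features = self._features(rng)
        sm = score_repetition(model, features)
        assert sm.scores.shape == (3, 2)
        assert sm.true_target == 1
        assert sm.repetition == 4
        for f in features:
            assert sm.scores[f.marker_id, f.trial] == pytest.approx(score(model, f))

    def test_missing_cell_rejected(self, rng):
        model = _unit_model(d=5, index=0)
        features = self._features(rng)[:-1]
        with pytest.raises(ConfigurationError):
            score_repetition(model, features)


class TestWeightRecoveryOnStudy:
    """The fitted discriminant aligns with the generative ERP template."""

    @staticmethod
    def _index_maps():
        idx = np.arange(1228)
        flat = 2 * idx
        channel, sample = flat // 307, flat % 307
        in_window = (sample / 512.0 * 1000.0 >= 150.0) & (
            sample / 512.0 * 1000.0 <= 450.0
        )
        return channel, sample, in_window

    def test_weights_align_with_template_difference(self, study):
        _, results = study
        template = make_erp_template(DEFAULT_TARGET_COMPONENTS, 307, 512.0)
        gains = np.asarray(DEFAULT_CHANNEL_GAINS)
        target_pattern = gains[:, None] * template[None, :]
        channel, sample, win = self._index_maps()
        pooled, on_support = [], []
        for r in results:
            w = r.model.w
            pooled.append(pearsonr(w[win], target_pattern[channel[win], sample[win]])[0])
            sup = (w != 0) & win
            on_support.append(
                pearsonr(w[sup], target_pattern[channel[sup], sample[sup]])[0]
            )
        # a sparse solution cannot track a dense template closely, but the
        # alignment must be real both pooled and on the selected features
        assert np.median(pooled) >= 0.1
        assert np.median(on_support) >= 0.5

    def test_models_are_sparse(self, study):
        _, results = study
        sizes = np.array([r.model.support.size for r in results])
        assert (sizes > 0).all()
        assert (sizes < 1228 / 2).all()
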