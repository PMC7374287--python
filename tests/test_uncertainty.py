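"""Correctness series, logistic correctness model, threshold exclusion, ROC."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import movelets as mv
from conftest import oracle_logistic


def mk_series(a, v):
    a = np.asarray(a)
    return mv.CorrectnessSeries(np.arange(len(a)) / 10.0, a, np.asarray(v))


def simulate_series(n, beta0, beta1, rng):
    v = rng.uniform(0.0, 1.0, size=n)
    p = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * v)))
    a = (rng.uniform(size=n) < p).astype(int)
    return mk_series(a, v)


class TestCorrectnessSeries:
    def _cls(self, labels, times=None, v=None):
        labels = np.asarray(labels, dtype=str)
        k = len(labels)
        return mv.Classification(
            times=np.asarray(times if times is not None else np.arange(k) / 10.0),
            labels=labels,
            vote_proportion=np.asarray(v if v is not None else np.full(k, 0.8)),
            n_votes=np.full(k, 11),
        )

    def test_all_correct_and_all_wrong(self):
        track = mv.LabelTrack([mv.LabelInterval(0, 1, "walk")])
        assert np.all(mv.correctness_series(self._cls(["walk"] * 5), track).a == 1)
        assert np.all(mv.correctness_series(self._cls(["sit"] * 5), track).a == 0)

    def test_elementwise_comparison_in_time_order(self):
        track = mv.LabelTrack(
            [mv.LabelInterval(0, 0.3, "walk"), mv.LabelInterval(0.3, 0.4, "sit")]
        )
        series = mv.correctness_series(
            self._cls(["walk", "walk", "walk", "walk"]), track
        )
        assert list(series.a) == [1, 1, 1, 0]

    def test_unlabeled_timepoints_dropped(self):
        track = mv.LabelTrack([mv.LabelInterval(0, 0.2, "walk")])
        series = mv.correctness_series(self._cls(["walk"] * 5), track)
        assert len(series) == 2
        with pytest.raises(mv.ValidationError):
            mv.correctness_series(
                self._cls(["walk"], times=np.array([99.0])), track
            )


class TestFitUQ:
    def test_parameter_recovery(self, rng):
        """MLE recovers the generating coefficients (-1, 3) within 3 SE."""
        series = simulate_series(2000, -1.0, 3.0, rng)
        model = mv.fit_uq(series)
        assert not model.separation
        # standard errors from the observed information at the truth are
        # roughly 0.11 / 0.19 at n=2000; 3 SE is a generous envelope
        assert model.beta0 == pytest.approx(-1.0, abs=0.5)
        assert model.beta1 == pytest.approx(3.0, abs=0.9)

    def test_matches_newton_raphson_oracle(self, rng):
        for n in (50, 500, 2000):
            series = simulate_series(n, 0.5, -1.5, rng)
            model = mv.fit_uq(series)
            b0, b1 = oracle_logistic(series.v, series.a)
            assert model.beta0 == pytest.approx(b0, abs=1e-6)
            assert model.beta1 == pytest.approx(b1, abs=1e-6)

    def test_single_class_falls_back_with_flag(self, rng):
        series = mk_series(np.ones(50, dtype=int), rng.uniform(size=50))
        model = mv.fit_uq(series)
        assert model.separation
        assert np.isfinite(model.beta0) and np.isfinite(model.beta1)
        # fitted probabilities should still be near 1 everywhere
        assert mv.predict_correct_prob(model, 0.5) > 0.9

    def test_constant_v_falls_back_with_flag(self):
        series = mk_series([0, 1] * 25, np.full(50, 0.7))
        model = mv.fit_uq(series)
        assert model.separation

    def test_perfect_separation_falls_back(self):
        v = np.linspace(0.0, 1.0, 40)
        series = mk_series((v > 0.5).astype(int), v)
        model = mv.fit_uq(series)
        assert model.separation and np.isfinite(model.beta1)

    def test_empty_series_rejected(self):
        with pytest.raises(mv.ValidationError):
            mv.fit_uq(mk_series([], []))

    def test_optional_covariate_extends_the_model(self, rng):
        """An informative extra regressor (e.g. a predicted-label indicator)
        gets a coefficient and must be supplied again at prediction time."""
        n = 2000
        v = rng.uniform(size=n)
        z = rng.integers(0, 2, size=n).astype(float)
        p = 1.0 / (1.0 + np.exp(-(-1.0 + 2.0 * v + 1.5 * z)))
        a = (rng.uniform(size=n) < p).astype(int)
        series = mk_series(a, v)
        model = mv.fit_uq(series, covariates=z)
        assert len(model.extra_betas) == 1
        assert model.extra_betas[0] == pytest.approx(1.5, abs=0.5)
        p1 = mv.predict_correct_prob(model, 0.5, covariates=np.array([[1.0]]))
        p0 = mv.predict_correct_prob(model, 0.5, covariates=np.array([[0.0]]))
        assert p1 > p0
        with pytest.raises(mv.ValidationError):
            mv.predict_correct_prob(model, 0.5)


class TestPredictCorrectProb:
    def test_zero_coefficients_give_half(self):
        model = mv.UQModel(0.0, 0.0, 10)
        assert mv.predict_correct_prob(model, 0.3) == 0.5

    def test_logistic_formula(self):
        model = mv.UQModel(-1.0, 2.0, 10)
        # eta = -1 + 2 * 0.75 = 0.5
        assert mv.predict_correct_prob(model, 0.75) == pytest.approx(
            1.0 / (1.0 + np.exp(-0.5))
        )

    def test_saturates_toward_one(self):
        assert mv.predict_correct_prob(mv.UQModel(0.0, 500.0, 10), 1.0) > 1 - 1e-9

    @given(
        beta1=st.floats(0.1, 20),
        v1=st.floats(0, 1),
        v2=st.floats(0, 1),
    )
    def test_strictly_increasing_in_v_for_positive_slope(self, beta1, v1, v2):
        model = mv.UQModel(-1.0, beta1, 10)
        if v2 - v1 > 1e-9:
            assert mv.predict_correct_prob(model, v1) < mv.predict_correct_prob(model, v2)


class TestThresholding:
    def test_boundary_thresholds(self, rng):
        probs = rng.uniform(0.01, 0.99, size=100)
        assert not mv.apply_threshold(probs, 0.0).any()  # nothing below 0
        assert mv.apply_threshold(probs, 1.0).all()  # everything below 1
        with pytest.raises(mv.ValidationError):
            mv.apply_threshold(probs, 1.5)

    def test_exclusions_nested_in_threshold(self, rng):
        probs = rng.uniform(size=200)
        lo = mv.apply_threshold(probs, 0.5)
        hi = mv.apply_threshold(probs, 0.75)
        assert np.all(hi[lo])  # excluded at 0.5 -> excluded at 0.75

    def test_sweep_step_function_location(self):
        sweep = mv.threshold_sweep(np.full(40, 0.6))
        below = sweep[sweep.threshold <= 0.6]
        above = sweep[sweep.threshold > 0.6]
        assert (below.prop_excluded == 0.0).all()
        assert (above.prop_excluded == 1.0).all()

    def test_sweep_has_101_points_and_rejects_empty(self):
        sweep = mv.threshold_sweep(np.array([0.4]))
        assert len(sweep) == 101
        assert sweep.threshold.iloc[0] == 0.0 and sweep.threshold.iloc[-1] == 1.0
        with pytest.raises(mv.ValidationError):
            mv.threshold_sweep(np.array([]))

    @given(seed=st.integers(0, 1000))
    def test_sweep_and_roc_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        n = 80
        a = rng.integers(0, 2, size=n)
        if len(np.unique(a)) < 2:
            a[0], a[1] = 0, 1
        probs = rng.uniform(size=n)
        roc = mv.exclusion_roc(probs, mk_series(a, probs))
        for col in ("prop_excluded", "sensitivity", "one_minus_specificity"):
            assert (np.diff(roc[col]) >= -1e-12).all()
        assert roc.iloc[0][["prop_excluded", "sensitivity",
                            "one_minus_specificity"]].tolist() == [0.0, 0.0, 0.0]
        assert roc.iloc[-1][["sensitivity", "one_minus_specificity"]].tolist() == [1.0, 1.0]


class TestExclusionROC:
    def test_direct_enumeration(self):
        # A = (1,1,0,0), excluded = (F,T,T,F)
        sens, fpr = mv.exclusion_rates(
            np.array([False, True, True, False]), np.array([1, 1, 0, 0])
        )
        assert sens == 0.5 and fpr == 0.5

    def test_single_class_yields_nan_coordinate(self):
        sens, fpr = mv.exclusion_rates(np.array([True, False]), np.array([1, 1]))
        assert np.isnan(sens) and fpr == 0.5

    def test_apply_uq_flags_without_deleting(self, rng):
        k = 20
        cls = mv.Classification(
            times=np.arange(k) / 10.0,
            labels=np.array(["walk"] * k),
            vote_proportion=rng.uniform(0.1, 1.0, size=k),
            n_votes=np.full(k, 11),
        )
        model = mv.UQModel(-2.0, 4.0, 100)
        out = mv.apply_uq(cls, model, threshold=0.5)
        assert out.excluded is not None and out.correct_probability is not None
        assert len(out.labels) == k  # nothing deleted
        expected = mv.predict_correct_prob(model, out.vote_proportion) < 0.5
        assert np.array_equal(out.excluded, expected)
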