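"""Distance metrics, nearest-movelet matching, majority-vote classification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

import movelets as mv
from conftest import make_stream, oracle_match


def mk_movelet(values, t0=0.0, idx=0):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    channels = ("x", "y", "z") if values.shape[1] == 3 else ("magnitude",)
    return mv.Movelet(t0, idx, values, channels)


def mk_dictionary(entries, data_type="magnitude", rate_h=10.0, window_seconds=None):
    """Dictionary from {activity: [movelet values]} preserving order."""
    built = {
        a: [mk_movelet(v, idx=i) for i, v in enumerate(vals)]
        for a, vals in entries.items()
    }
    n = next(iter(built.values()))[0].n
    return mv.Dictionary(
        subject_id="t",
        sensor_kind="gyroscope",
        placement="front_pocket",
        data_type=data_type,
        rate_h=rate_h,
        window_seconds=window_seconds if window_seconds is not None else n / rate_h,
        entries=built,
    )


movelet_values = hnp.arrays(
    float,
    st.tuples(st.integers(2, 8), st.sampled_from([1, 3])),
    elements=st.floats(-10, 10, allow_nan=False, width=32),
)


class TestDistL2:
    def test_identity_is_zero(self, rng):
        m = mk_movelet(rng.normal(size=(10, 3)))
        assert mv.dist_l2(m, m) == 0.0

    def test_three_four_five_triangle(self):
        a = mk_movelet([[1.0], [2.0]])
        b = mk_movelet([[4.0], [6.0]])
        assert mv.dist_l2(a, b) == pytest.approx(5.0)

    def test_triaxial_mean_of_axis_distances(self):
        # per-axis Euclidean distances 3, 4, 5 -> mean 4
        a = mk_movelet(np.zeros((2, 3)))
        b = mk_movelet([[3.0, 4.0, 5.0], [0.0, 0.0, 0.0]])
        assert mv.dist_l2(a, b) == pytest.approx((3 + 4 + 5) / 3)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(TypeError):
            mv.dist_l2(
                mk_movelet(rng.normal(size=(10, 3))),
                mk_movelet(rng.normal(size=(8, 3))),
            )

    @given(a=movelet_values, b=movelet_values)
    def test_pseudometric(self, a, b):
        """Symmetric, non-negative, zero iff values equal."""
        if a.shape != b.shape:
            a = b = a  # only same-shape pairs are comparable
        ma, mb = mk_movelet(a), mk_movelet(b)
        d = mv.dist_l2(ma, mb)
        assert d >= 0.0
        assert d == mv.dist_l2(mb, ma)
        assert (d == 0.0) == bool(np.array_equal(ma.values, mb.values))


class TestSimCorr:
    def test_affine_images_have_unit_correlation(self, rng):
        m = mk_movelet(rng.normal(size=(10, 3)))
        m2 = mk_movelet(2.5 * m.values + 7.0)
        assert mv.sim_corr(m, m2) == pytest.approx(1.0)

    def test_negated_movelet_has_minus_one(self, rng):
        m = mk_movelet(rng.normal(size=(10, 3)))
        assert mv.sim_corr(m, mk_movelet(-m.values)) == pytest.approx(-1.0)

    def test_constant_movelet_scores_zero(self, rng):
        const = mk_movelet(np.full((10, 3), 2.0))
        other = mk_movelet(rng.normal(size=(10, 3)))
        assert mv.sim_corr(const, other) == 0.0

    @given(a=movelet_values, b=movelet_values)
    def test_bounded(self, a, b):
        if a.shape != b.shape:
            a = b = a
        r = mv.sim_corr(mk_movelet(a), mk_movelet(b))
        assert -1.0 - 1e-9 <= r <= 1.0 + 1e-9


class TestMatchMovelet:
    def test_exact_dictionary_member_wins_with_zero_distance(self, rng):
        w = rng.normal(size=(10, 1))
        d = mk_dictionary({"stand": [rng.normal(size=(10, 1))], "walk": [w]})
        match = mv.match_movelet(mk_movelet(w), d, mv.MatchConfig("l2", "magnitude"))
        assert match.best_activity == "walk" and match.best_score == 0.0

    def test_single_entry_dictionary_always_wins(self, rng):
        d = mk_dictionary({"sit": [rng.normal(size=(10, 1))]})
        m = mk_movelet(rng.normal(size=(10, 1)) + 100)
        assert mv.match_movelet(m, d, mv.MatchConfig("l2", "magnitude")).best_activity == "sit"

    def test_exact_tie_breaks_by_activity_order(self):
        probe = np.zeros((10, 1))
        up = np.ones((10, 1))
        down = -np.ones((10, 1))  # same L2 distance to the zero probe
        d1 = mk_dictionary({"a_up": [up], "b_down": [down]})
        d2 = mk_dictionary({"b_down": [down], "a_up": [up]})
        cfg = mv.MatchConfig("l2", "magnitude")
        assert mv.match_movelet(mk_movelet(probe), d1, cfg).best_activity == "a_up"
        assert mv.match_movelet(mk_movelet(probe), d2, cfg).best_activity == "b_down"

    def test_incompatible_shape_raises(self, rng):
        d = mk_dictionary({"walk": [rng.normal(size=(10, 1))]})
        with pytest.raises(TypeError):
            mv.match_movelet(
                mk_movelet(rng.normal(size=(10, 3))), d,
                mv.MatchConfig("l2", "magnitude"),
            )

    @pytest.mark.parametrize("metric", ["l2", "correlation"])
    @pytest.mark.parametrize("n_channels", [1, 3])
    def test_agrees_with_bruteforce_oracle(self, metric, n_channels, rng):
        """Exhaustive scan equals a naive double-loop scorer on random
        dictionaries (up to 5 activities x 10 movelets)."""
        data_type = "magnitude" if n_channels == 1 else "triaxial"
        cfg = mv.MatchConfig(metric, data_type)
        for _ in range(40):
            n = int(rng.integers(3, 12))
            acts = [f"act{i}" for i in range(rng.integers(1, 6))]
            entries = {
                a: [rng.normal(size=(n, n_channels)) for _ in
                    range(rng.integers(1, 11))]
                for a in acts
            }
            d = mk_dictionary(entries, data_type=data_type)
            probe = rng.normal(size=(n, n_channels))
            got = mv.match_movelet(mk_movelet(probe), d, cfg)
            want_act, want_score = oracle_match(
                probe, [(a, entries[a]) for a in acts], metric
            )
            assert got.best_activity == want_act
            assert got.best_score == pytest.approx(want_score, abs=1e-9)


class TestClassify:
    def _two_activity_setup(self, rng):
        """20 s stream: 10 s 'low' around 0, 10 s 'high' around 5."""
        low = rng.normal(0.0, 0.1, size=(100, 1))
        high = rng.normal(5.0, 0.1, size=(100, 1))
        stream = make_stream(np.vstack([low, high]))
        track = mv.LabelTrack(
            [mv.LabelInterval(0, 10, "low"), mv.LabelInterval(10, 20, "high")]
        )
        d = mv.build_dictionary(stream, track, ("low", "high"))
        return stream, track, d

    def test_unanimous_vote(self, rng):
        stream, _, d = self._two_activity_setup(rng)
        cls = mv.classify(stream, d, mv.MatchConfig("l2", "magnitude"))
        # deep inside the 'low' segment every vote is 'low'
        assert cls.labels[30] == "low"
        assert cls.vote_proportion[30] == 1.0 and cls.n_votes[30] == 11

    def test_prediction_count_and_edge_votes(self, rng):
        stream, _, d = self._two_activity_setup(rng)
        cls = mv.classify(stream, d, mv.MatchConfig("l2", "magnitude"))
        # N = 200, n = 10: movelets/timepoints with predictions = 191
        assert len(cls) == 200 - 10 + 1
        # vote window shrinks near the end: final timepoint has a single vote
        assert cls.n_votes[-1] == 1
        assert list(cls.n_votes[-11:]) == list(range(11, 0, -1))
        # v(t) >= 1/n_votes always
        assert np.all(cls.vote_proportion >= 1.0 / cls.n_votes)

    def test_majority_vote_proportion_counts_votes(self, rng):
        """v(t) equals the modal share of cast votes, recomputed from the
        individual movelet matches."""
        stream, _, d = self._two_activity_setup(rng)
        cls = mv.classify(stream, d, mv.MatchConfig("l2", "magnitude"))
        matched = np.array([m.best_activity for m in cls.matches])
        for i in [85, 90, 92, 95, 98]:  # straddling the activity change
            votes = matched[i : min(i + 11, len(matched))]
            labs, counts = np.unique(votes, return_counts=True)
            assert cls.vote_proportion[i] == pytest.approx(
                counts.max() / len(votes)
            )
            assert cls.labels[i] in labs[counts == counts.max()]

    def test_vote_tie_prefers_label_with_best_scoring_vote(self):
        d = mk_dictionary(
            {"zero": [np.zeros((10, 1))], "four": [np.full((10, 1), 4.0)]},
            window_seconds=1.0,
        )
        stream = make_stream(np.vstack([np.zeros((5, 1)), np.full((15, 1), 4.0)]))
        cls = mv.classify(
            stream, d, mv.MatchConfig("l2", "magnitude", votes_per_point=2)
        )
        # timepoint 0 votes with movelets 0 (5 zeros + 5 fours, itself an
        # exact score tie resolved to "zero" by activity order) and 1
        # (4 zeros + 6 fours -> "four" at the better score): the 1-1 vote
        # tie goes to the label holding the best-scoring single vote
        matched = [m.best_activity for m in cls.matches]
        assert matched[0] == "zero" and matched[1] == "four"
        assert cls.labels[0] == "four"

    def test_exact_recall_on_training_stream(self, fixture_study, gyro_dictionary):
        """Classifying the training stream with its own dictionary: every
        movelet inside a selected training segment matches at distance zero,
        and timepoints whose full vote window lies inside one segment get
        the true label."""
        training = fixture_study.training
        cls = mv.classify(training.gyro, gyro_dictionary, mv.MatchConfig("l2", "triaxial"))
        scores = np.array([m.best_score for m in cls.matches])
        n = gyro_dictionary.n
        h = int(training.gyro.rate_h)
        for activity in gyro_dictionary.activity_order:
            seg = mv.select_training_segment(
                training.gyro, training.track, activity
            )
            t0, t1 = seg.timestamps[0], seg.timestamps[-1]
            # movelets fully inside the selected segment
            inside = (cls.times >= t0) & (cls.times <= t1 - (n - 1) / h)
            assert np.all(scores[inside] == 0.0)
            # timepoints whose entire vote window (movelets i..i+h) fits
            interior = (cls.times >= t0) & (cls.times <= t1 - (n - 1 + h) / h)
            assert np.all(cls.labels[interior] == activity)
            assert np.all(cls.vote_proportion[interior] == 1.0)

    def test_data_type_mismatch_rejected(self, fixture_study, gyro_dictionary):
        with pytest.raises(mv.ValidationError):
            mv.classify(
                mv.magnitude(fixture_study.course.gyro),
                gyro_dictionary,
                mv.MatchConfig("l2", "magnitude"),
            )
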