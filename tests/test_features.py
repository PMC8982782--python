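import numpy as np
import pytest

from faceattn import (
    ATTENTION,
    FrameLandmarks,
    InsufficientDataError,
    SchemaError,
    SessionRecording,
    ValidationError,
    euclidean_distance,
    frame_distance_vector,
    landmark_mae,
    pair_index,
    standardize_apply,
    standardize_fit,
)
from faceattn.features import FeatureMatrix, standardize_invert
from tests.conftest import random_session


class TestEuclideanDistance:
    def test_345_triangle(self):
        assert euclidean_distance((0, 0), (3, 4)) == 5.0

    def test_identity(self):
        assert euclidean_distance((1, 1), (1, 1)) == 0.0

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            euclidean_distance((np.nan, 0), (1, 1))

    def test_matches_arbitrary_precision_oracle(self, rng):
        import sympy

        for _ in range(20):
            p, q = rng.uniform(-500, 500, size=(2, 2))
            exact = sympy.sqrt(
                (sympy.Float(p[0], 30) - sympy.Float(q[0], 30)) ** 2
                + (sympy.Float(p[1], 30) - sympy.Float(q[1], 30)) ** 2
            )
            assert abs(euclidean_distance(p, q) - float(sympy.N(exact, 30))) < 1e-9


class TestFrameDistanceVector:
    def test_coincident_points_give_zero_vector(self):
        frame = FrameLandmarks(0, 0.0, np.tile([5.0, 7.0], (34, 1)))
        np.testing.assert_array_equal(frame_distance_vector(frame), np.zeros(561))

    def test_matches_double_loop_oracle(self, rng):
        coords = rng.uniform(0, 100, size=(34, 2))
        vec = frame_distance_vector(FrameLandmarks(0, 0.0, coords))
        oracle = []
        for i in range(34):
            for j in range(i + 1, 34):
                oracle.append(np.hypot(*(coords[i] - coords[j])))
        np.testing.assert_allclose(vec, oracle, atol=1e-12)

    def test_translation_invariance(self, rng):
        coords = rng.uniform(0, 100, size=(34, 2))
        v1 = frame_distance_vector(FrameLandmarks(0, 0.0, coords))
        v2 = frame_distance_vector(FrameLandmarks(0, 0.0, coords + np.array([10.0, 10.0])))
        np.testing.assert_allclose(v1, v2, atol=1e-9)

    def test_uniform_scaling_equivariance(self, rng):
        coords = rng.uniform(0, 100, size=(34, 2))
        v1 = frame_distance_vector(FrameLandmarks(0, 0.0, coords))
        v2 = frame_distance_vector(FrameLandmarks(0, 0.0, coords * 2.5))
        np.testing.assert_allclose(v2, 2.5 * v1, rtol=1e-12)

    def test_invalid_frame_is_a_skip_signal(self):
        frame = FrameLandmarks(0, 0.0, np.full((34, 2), np.nan), valid=False)
        assert frame_distance_vector(frame) is None


def _matrix(X, labels=None, fids=None):
    X = np.asarray(X, dtype=float)
    n, f = X.shape
    return FeatureMatrix(
        X,
        np.arange(f) if fids is None else fids,
        np.ones(n, dtype=int) if labels is None else labels,
        np.array(["P1"] * n, dtype=object),
    )


class TestStandardization:
    def test_two_point_population_convention(self):
        params = standardize_fit(_matrix([[1.0], [3.0]]))
        assert params.mean[0] == 2.0
        assert params.std[0] == 1.0  # population sd: sqrt(((1-2)^2+(3-2)^2)/2)

    def test_training_columns_become_zero_mean_unit_sd(self, rng):
        m = _matrix(rng.uniform(0, 50, size=(40, 6)))
        z = standardize_apply(standardize_fit(m), m)
        np.testing.assert_allclose(z.X.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.X.std(axis=0), 1.0, atol=1e-9)

    def test_fixed_points(self):
        m = _matrix([[1.0], [3.0]])
        params = standardize_fit(m)
        z = standardize_apply(params, _matrix([[2.0], [3.0]]))  # x=m -> 0, x=m+s -> 1
        np.testing.assert_allclose(z.X[:, 0], [0.0, 1.0])

    def test_matches_independent_moment_oracle(self, rng):
        X = rng.normal(10, 3, size=(30, 4))
        params = standardize_fit(_matrix(X))
        # independent streaming (two-pass) moments
        for k in range(4):
            mean = sum(X[:, k]) / 30
            var = sum((v - mean) ** 2 for v in X[:, k]) / 30
            assert abs(params.mean[k] - mean) < 1e-9
            assert abs(params.std[k] - np.sqrt(var)) < 1e-9

    def test_round_trip(self, rng):
        m = _matrix(rng.uniform(0, 100, size=(20, 5)))
        params = standardize_fit(m)
        back = standardize_invert(params, standardize_apply(params, m))
        np.testing.assert_allclose(back.X, m.X, atol=1e-9)

    def test_constant_feature_dropped_and_recorded(self, rng):
        X = rng.uniform(0, 10, size=(10, 3))
        X[:, 1] = 4.2
        params = standardize_fit(_matrix(X))
        assert list(params.dropped_feature_ids) == [1]
        assert list(params.feature_ids) == [0, 2]

    def test_misaligned_features_raise(self, rng):
        m = _matrix(rng.uniform(0, 10, size=(5, 3)))
        params = standardize_fit(m)
        other = _matrix(rng.uniform(0, 10, size=(5, 2)), fids=np.array([7, 9]))
        with pytest.raises(SchemaError):
            standardize_apply(params, other)

    def test_needs_two_rows(self):
        with pytest.raises(InsufficientDataError):
            standardize_fit(_matrix([[1.0, 2.0]]))


def _session_with_pair_distances(distances):
    """Frames where landmark 0 is at the origin and landmark 4 at (d, 0)."""
    frames = []
    for f, d in enumerate(distances):
        coords = np.zeros((34, 2))
        coords[4, 0] = d
        frames.append(FrameLandmarks(f, f * 62.5, coords))
    return SessionRecording(participant_id="P1", frames=frames)


class TestLandmarkMae:
    def test_static_session_has_zero_mae(self):
        s = _session_with_pair_distances([100.0, 100.0, 100.0])
        labels = np.array([ATTENTION] * 3)
        assert landmark_mae(s, labels) == 0.0

    def test_alternating_distances(self):
        # distances 100, 101, 100 over 3 frames: |101-100| + |100-101| over n=2
        s = _session_with_pair_distances([100.0, 101.0, 100.0])
        labels = np.array([ATTENTION] * 3)
        assert landmark_mae(s, labels) == pytest.approx(1.0)

    def test_matches_brute_force_oracle_and_gap_breaking(self, rng):
        n = 20
        session = random_session(rng, n_frames=n, invalid=(7,))
        labels = np.array([ATTENTION] * n)
        labels[12] = "inattention"
        pair = pair_index(0, 4)
        got = landmark_mae(session, labels, pair=pair)

        coords = session.coords_array()
        usable = [
            f
            for f in range(n)
            if session.valid_mask()[f] and labels[f] == ATTENTION
        ]
        diffs = []
        for a, b in zip(usable, usable[1:]):
            if b == a + 1:  # invalid/other-label frames break consecutive pairing
                da = np.hypot(*(coords[a, 0] - coords[a, 4]))
                db = np.hypot(*(coords[b, 0] - coords[b, 4]))
                diffs.append(abs(db - da))
        assert got == pytest.approx(np.mean(diffs))
        assert got >= 0.0

    def test_insufficient_data(self):
        s = _session_with_pair_distances([100.0])
        with pytest.raises(InsufficientDataError):
            landmark_mae(s, np.array([ATTENTION]))
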