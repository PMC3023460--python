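import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diffindex import (
    DevelopingLineModel,
    TimeCourse,
    TimeCourseError,
    fit_developing_line,
    load_line,
    orient_line,
    project,
    segment_vectors,
)
from conftest import random_course


class TestTimeCourse:
    def test_rejects_too_few_stages_or_probes(self):
        with pytest.raises(TimeCourseError, match="2 time points"):
            TimeCourse(pd.DataFrame({"t0": [1.0, 2.0, 3.0]}))
        with pytest.raises(TimeCourseError, match="more probes"):
            TimeCourse(pd.DataFrame(np.eye(3), columns=list("abc")))

    def test_rejects_identical_consecutive_stages(self):
        X = pd.DataFrame({"t0": [0.0, 1.0, 2.0], "t1": [0.0, 1.0, 2.0]})
        with pytest.raises(TimeCourseError, match="average"):
            TimeCourse(X)


class TestSegmentVectors:
    def test_worked_example(self, worked_course):
        A = segment_vectors(worked_course)
        assert np.array_equal(A[:, 0], [1, 0, 0, 0])
        assert np.array_equal(A[:, 1], [0, 1, 0, 0])

    def test_shift_invariance(self, worked_course):
        shifted = TimeCourse(worked_course.values + 7.0)
        assert np.array_equal(segment_vectors(shifted),
                              segment_vectors(worked_course))

    def test_two_stages_single_segment(self):
        X = pd.DataFrame({"a": [0.0, 0.0, 0.0], "b": [1.0, 2.0, 0.0]})
        assert np.array_equal(segment_vectors(TimeCourse(X))[:, 0],
                              [1.0, 2.0, 0.0])


class TestFit:
    def test_worked_t3_solution(self, worked_course):
        res = DevelopingLineModel(worked_course).fit()
        assert np.allclose(res.lambdas, [1.0, 1.0])
        assert np.allclose(res.weights.to_numpy(), [1, 1, 0, 0])
        assert res.cosine_constant == pytest.approx(1.0)
        # both segments at 45 degrees to v
        A = segment_vectors(worked_course)
        v = res.weights.to_numpy()
        cos = A.T @ v / np.linalg.norm(A, axis=0) / np.linalg.norm(v)
        assert np.allclose(cos, np.cos(np.pi / 4))

    def test_t2_line_is_the_segment_itself(self):
        X = pd.DataFrame({"a": [0.0, 0.0, 0.0], "b": [3.0, 4.0, 0.0]})
        res = fit_developing_line(TimeCourse(X))
        assert np.allclose(res.weights.to_numpy(), [3, 4, 0])
        assert res.cosine_constant == pytest.approx(5.0)

    def test_collinear_course_recovers_direction(self, rng):
        u = rng.normal(size=12)
        X = pd.DataFrame({f"t{i}": i * u for i in range(4)})
        res = fit_developing_line(TimeCourse(X))
        v = res.weights.to_numpy()
        cos = v @ u / np.linalg.norm(v) / np.linalg.norm(u)
        assert cos == pytest.approx(1.0, abs=1e-10)
        assert res.residual < 1e-10

    @pytest.mark.parametrize("t", [3, 4, 5])
    def test_equal_angle_on_random_courses(self, rng, t):
        for _ in range(10):
            tc = random_course(rng, 200, t)
            res = fit_developing_line(tc)
            A = segment_vectors(tc)
            v = res.weights.to_numpy()
            cos = A.T @ v / (np.linalg.norm(A, axis=0) * np.linalg.norm(v))
            common = res.cosine_constant / np.linalg.norm(v)
            assert np.max(np.abs(cos - common)) < 1e-8
            assert res.lambdas[0] == 1.0

    def test_order_and_ratio_preservation(self, rng):
        tc = random_course(rng, 150, 5)
        res = fit_developing_line(tc)
        P = res.project(tc.values.to_numpy())
        assert np.all(np.diff(P) > 0)
        norms = np.linalg.norm(segment_vectors(tc), axis=0)
        dP = np.diff(P)
        for i in range(len(dP)):
            for j in range(len(dP)):
                assert dP[i] / dP[j] == pytest.approx(norms[i] / norms[j],
                                                      abs=1e-8)


class TestProject:
    def test_worked_projections(self, worked_course):
        res = DevelopingLineModel(worked_course).fit()
        P = [res.project(worked_course.values[c].to_numpy())
             for c in worked_course.values]
        assert P == pytest.approx([0.0, 0.70711, 1.41421], abs=5e-6)

    def test_zero_sample_and_length_mismatch(self, worked_course):
        res = DevelopingLineModel(worked_course).fit()
        assert res.project(np.zeros(4)) == 0.0
        with pytest.raises(ValueError, match="probes"):
            res.project(np.zeros(5))

    @given(scale=st.floats(min_value=1e-6, max_value=1e6))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_invariant_to_positive_rescaling_of_v(self, scale):
        X = pd.DataFrame(
            {"t0": [0, 0, 0, 0], "t1": [1, 0, 0, 0], "t2": [1, 1, 0, 0]},
            index=["pA", "pB", "pC", "pD"], dtype=float)
        res = DevelopingLineModel(TimeCourse(X)).fit()
        scaled = res.restrict(res.probe_ids)
        scaled.weights *= scale
        s = np.array([0.3, -1.2, 0.5, 2.0])
        assert project(scaled, s) == pytest.approx(project(res, s),
                                                   rel=1e-9)


class TestOrient:
    def test_reversed_course_gets_flipped(self, worked_course):
        rev = TimeCourse(worked_course.values.iloc[:, ::-1])
        res = DevelopingLineModel(rev).fit(orient=False)
        P = res.project(rev.values.to_numpy())
        flipped = orient_line(res, rev)
        P2 = flipped.project(rev.values.to_numpy())
        assert np.all(np.diff(P2) > 0) or np.all(np.diff(P) > 0)
        assert flipped.oriented
        assert flipped.cosine_constant > 0

    def test_orientation_is_idempotent_and_involutive(self, rng):
        tc = random_course(rng, 60, 4)
        res = DevelopingLineModel(tc).fit()
        again = orient_line(res, tc)
        assert np.allclose(again.weights.to_numpy(),
                           res.weights.to_numpy())
        neg = res.restrict(res.probe_ids)
        neg.weights = -neg.weights
        neg.cosine_constant = -neg.cosine_constant
        back = orient_line(neg, tc)
        assert np.allclose(back.weights.to_numpy(), res.weights.to_numpy())


class TestSerialization:
    def test_save_load_roundtrip(self, tmp_path, worked_course):
        res = DevelopingLineModel(worked_course).fit()
        res.save(tmp_path / "l.weights.tsv", tmp_path / "l.json")
        back = load_line(tmp_path / "l.weights.tsv", tmp_path / "l.json")
        assert np.allclose(back.weights.to_numpy(),
                           res.weights.to_numpy(), atol=1e-12)
        assert back.cosine_constant == pytest.approx(res.cosine_constant)
        assert back.time_labels == res.time_labels
        assert back.oriented == res.oriented

    def test_summary_mentions_fit_quality(self, worked_course):
        res = DevelopingLineModel(worked_course).fit()
        text = res.summary()
        assert "cosine constant" in text
        assert "residual" in text
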