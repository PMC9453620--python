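"""Clock training/prediction, signed circular angles, tolerance-accuracy curve."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circphen import pipeline as pl
from circphen import synthetic_cohort as sc
from circphen import transcriptomic_clock as tc
from circphen.errors import (MissingGeneError, SingularDesignError,
                             UndefinedPhaseError)


class _Sample:
    def __init__(self, values, clock_time=0.0, session="AM", gene_ids=None):
        self.values = np.asarray(values, dtype=float)
        self.clock_time = clock_time
        self.session = session
        if gene_ids is not None:
            self.gene_ids = gene_ids


class TestNormalization:
    def test_mean_subtraction(self):
        out = tc.within_subject_normalize({"s": [_Sample([5.0]), _Sample([7.0])]})
        np.testing.assert_array_equal(out["s"][0][1], [-1.0])
        np.testing.assert_array_equal(out["s"][1][1], [1.0])

    def test_idempotence(self):
        centered = {"s": [_Sample([-1.0, 2.0]), _Sample([1.0, -2.0])]}
        once = tc.within_subject_normalize(centered)
        np.testing.assert_array_equal(once["s"][0][1], [-1.0, 2.0])

    @given(st.floats(-100, 100))
    @settings(max_examples=25, deadline=None)
    def test_shift_invariance(self, c):
        a = tc.within_subject_normalize({"s": [_Sample([1.0, 4.0]), _Sample([3.0, 0.0])]})
        b = tc.within_subject_normalize(
            {"s": [_Sample([1.0 + c, 4.0 + c]), _Sample([3.0 + c, 0.0 + c])]})
        for (_, va), (_, vb) in zip(a["s"], b["s"]):
            np.testing.assert_allclose(va, vb, atol=1e-9)

    def test_single_sample_subject_zeroed_and_flagged(self):
        grouped = {"solo": [_Sample([3.0, 4.0])]}
        out = tc.within_subject_normalize(grouped)
        np.testing.assert_array_equal(out["solo"][0][1], [0.0, 0.0])
        assert tc.single_sample_subjects(grouped) == {"solo"}

    def test_normalized_values_sum_to_zero_per_gene(self):
        rng = np.random.default_rng(0)
        grouped = {"s": [_Sample(rng.normal(size=5)) for _ in range(3)]}
        out = tc.within_subject_normalize(grouped)
        total = np.sum([v for _, v in out["s"]], axis=0)
        np.testing.assert_allclose(total, 0.0, atol=1e-12)


class TestSignedAngle:
    @pytest.mark.parametrize("pred,true,expect", [
        (22.0, 20.0, 2.0),    # no wrap
        (1.0, 23.0, 2.0),     # wraps midnight
        (8.0, 20.0, -12.0),   # antipodal maps to -12
        (20.0, 22.0, -2.0),
        (5.0, 5.0, 0.0),
    ])
    def test_examples(self, pred, true, expect):
        assert tc.signed_angle(pred, true) == pytest.approx(expect, abs=1e-12)

    @given(st.floats(0, 23.999), st.floats(0, 23.999))
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry_and_bounds(self, a, b):
        x = tc.signed_angle(a, b)
        assert -12.0 <= x < 12.0
        if x != -12.0:  # boundary excepted by convention
            assert tc.signed_angle(b, a) == pytest.approx(-x, abs=1e-9)

    @pytest.mark.parametrize("bad", [-0.1, 24.0, 30.0])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            tc.signed_angle(bad, 5.0)
        with pytest.raises(ValueError):
            tc.signed_angle(5.0, bad)


class TestSubjectAngle:
    def test_arithmetic_mean(self):
        ph = tc.subject_angle({"subject_id": "s", "AM": 3.0, "PM": 1.0})
        assert ph.angle_mean == pytest.approx(2.0)
        assert not ph.single_session

    def test_zero_identity(self):
        assert tc.subject_angle({"AM": 0.0, "PM": 0.0}).angle_mean == 0.0

    def test_single_session_flagged(self):
        ph = tc.subject_angle({"AM": 1.5})
        assert ph.single_session and ph.angle_mean == 1.5

    def test_no_sessions_errors(self):
        with pytest.raises(ValueError):
            tc.subject_angle({"subject_id": "s"})


class TestPredictTime:
    def _identity_model(self):
        # chooses weights so that (c_hat, s_hat) = (cos, sin) of the sample
        return tc.ClockModel(["c", "s"], np.array([1.0, 0.0]),
                             np.array([0.0, 1.0]), 0.0, 0.0, 0.0)

    def test_exact_inversion(self):
        model = self._identity_model()
        w = 2 * np.pi / 24
        for t in (20.0, 0.0, 11.3):
            vals = [np.cos(w * t), np.sin(w * t)]
            assert tc.predict_time(model, vals, ["c", "s"]) == pytest.approx(t % 24, abs=1e-9)

    def test_quadrants(self):
        model = self._identity_model()
        assert tc.predict_time(model, [1.0, 0.0], ["c", "s"]) == pytest.approx(0.0)
        assert tc.predict_time(model, [0.0, 1.0], ["c", "s"]) == pytest.approx(6.0)

    def test_gene_matching_by_identifier(self):
        model = self._identity_model()
        w = 2 * np.pi / 24
        t = 20.0
        # genes supplied in reversed order must give the same answer
        assert tc.predict_time(model, [np.sin(w * t), np.cos(w * t)],
                               ["s", "c"]) == pytest.approx(t, abs=1e-9)

    def test_missing_gene_error_lists_identifiers(self):
        with pytest.raises(MissingGeneError) as err:
            tc.predict_time(self._identity_model(), [1.0], ["c"])
        assert "s" in err.value.missing

    def test_undefined_phase(self):
        model = tc.ClockModel(["g"], np.zeros(1), np.zeros(1), 0.0, 0.0, 0.0)
        with pytest.raises(UndefinedPhaseError):
            tc.predict_time(model, [1.0], ["g"])


def _noise_free_cfg(seed, mode="uniform", n=20):
    return sc.default_config(n_subjects=n, seed=seed, gene_noise_sd=0.0,
                             phase_offset_sd=0.0, sample_times_mode=mode,
                             phase_offset_mean_by_type={"morning": 0.0,
                                                        "intermediate": 0.0,
                                                        "evening": 0.0})


class TestTrainClock:
    def test_noiseless_in_sample_error_below_half_hour(self):
        cohort = sc.generate_cohort(_noise_free_cfg(5))
        model = pl.train_clock_on_cohort(cohort, ridge_penalty=0.01)
        ang = pl.predict_angles(model, pl.cohort_expression_by_subject(cohort))
        assert ang["angle"].abs().mean() < 0.5

    def test_noiseless_held_out_subject_error_below_one_hour(self):
        train = sc.generate_cohort(_noise_free_cfg(5))
        test = sc.generate_cohort(_noise_free_cfg(6, n=10))
        model = pl.train_clock_on_cohort(train, ridge_penalty=0.01)
        ang = pl.predict_angles(model, pl.cohort_expression_by_subject(test))
        assert ang["angle"].abs().max() < 1.0

    def test_huge_penalty_collapses_to_intercept(self):
        cohort = sc.generate_cohort(_noise_free_cfg(5))
        model = pl.train_clock_on_cohort(cohort, ridge_penalty=1e9)
        assert np.abs(model.w_cos).max() < 1e-6
        assert np.abs(model.w_sin).max() < 1e-6
        intercept_time = (np.arctan2(model.b_sin, model.b_cos) * 24 / (2 * np.pi)) % 24
        vals = np.zeros(len(model.gene_ids)) + 0.1
        assert tc.predict_time(model, vals, model.gene_ids) == pytest.approx(
            intercept_time, abs=0.05)

    def test_degenerate_design_needs_penalty(self):
        same = np.ones(4)
        grouped = {"a": [_Sample(same, 3.0), _Sample(same, 9.0)],
                   "b": [_Sample(same, 15.0), _Sample(same, 21.0)]}
        normalized = tc.within_subject_normalize(grouped)
        with pytest.raises(SingularDesignError):
            tc.train_clock(normalized, ridge_penalty=0.0)
        model = tc.train_clock(normalized, ridge_penalty=1.0)
        assert np.all(np.isfinite(model.w_cos))

    def test_gene_row_permutation_invariance(self):
        cohort = sc.generate_cohort(_noise_free_cfg(5))
        model = pl.train_clock_on_cohort(cohort, ridge_penalty=0.1)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(model.gene_ids))
        sample = cohort.subjects[0].expression_samples[0]
        other = cohort.subjects[0].expression_samples[1]
        centered = sample.values - (sample.values + other.values) / 2
        direct = tc.predict_time(model, centered, model.gene_ids)
        permuted = tc.predict_time(model, centered[perm],
                                   [model.gene_ids[i] for i in perm])
        assert permuted == pytest.approx(direct, abs=1e-9)

    def test_requires_two_distinct_times(self):
        grouped = {"a": [_Sample([1.0, 2.0], 5.0), _Sample([2.0, 1.0], 5.0)]}
        with pytest.raises(ValueError):
            tc.train_clock(tc.within_subject_normalize(grouped), ridge_penalty=1.0)


class TestAccuracyCurve:
    def test_perfect_predictor(self):
        c = tc.accuracy_curve(np.zeros(10))
        assert np.all(c.fraction_correct == 1.0)
        assert c.nauc == 1.0

    def test_single_angle_six_hours_is_exactly_half(self):
        assert tc.accuracy_curve([6.0]).nauc == 0.5

    def test_uniform_angles_converge_to_half(self):
        rng = np.random.default_rng(8)
        angles = rng.uniform(-12, 12, 100_000)
        assert tc.accuracy_curve(angles).nauc == pytest.approx(0.5, abs=0.01)

    def test_sign_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(-11.9, 11.9, 500)
        signs = rng.choice([-1.0, 1.0], 500)
        c1, c2 = tc.accuracy_curve(a), tc.accuracy_curve(a * signs)
        np.testing.assert_array_equal(c1.fraction_correct, c2.fraction_correct)
        assert c1.nauc == c2.nauc

    def test_curve_monotone_and_complete_at_12h(self):
        rng = np.random.default_rng(4)
        c = tc.accuracy_curve(rng.uniform(-11.9, 11.9, 200))
        assert np.all(np.diff(c.fraction_correct) >= 0)
        assert c.fraction_correct[-1] == 1.0
        assert c.tolerances[0] == 0.0 and c.tolerances[-1] == 12.0

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            tc.accuracy_curve([])


def test_held_out_angle_tracks_latent_offset():
    """Parameter recovery: angle_mean correlates >= 0.8 with true delta (n=100)."""
    cfg_tr = sc.default_config(n_subjects=100, phase_offset_sd=1.5, seed=11,
                               sample_times_mode="uniform")
    cfg_te = sc.default_config(n_subjects=100, phase_offset_sd=1.5, seed=22)
    model = pl.train_clock_on_cohort(sc.generate_cohort(cfg_tr), ridge_penalty="auto")
    te = sc.generate_cohort(cfg_te)
    ang = pl.predict_angles(model, pl.cohort_expression_by_subject(te))
    per_subject = ang.groupby("subject_id")["angle_mean"].first()
    delta = {s.subject_id: s.phase_offset_delta for s in te.subjects}
    d = np.array([delta[s] for s in per_subject.index])
    assert np.corrcoef(d, per_subject.to_numpy())[0, 1] >= 0.8
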