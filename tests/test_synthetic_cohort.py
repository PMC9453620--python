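"""Generator correctness: determinism, closed-form noise-free curves, latent coherence."""

import dataclasses

import numpy as np
import pytest

from circphen import actigraphy_metrics as am
from circphen import melatonin_dlmo as md
from circphen import synthetic_cohort as sc
from circphen.errors import ConfigError


def _noise_free(**over):
    base = dict(gene_noise_sd=0.0, saliva_noise_sd=0.0, activity_noise_sd=0.0,
                meq_noise_sd=0.0, sample_time_jitter_sd=0.0,
                sleep_time_jitter_sd=0.0, fragmentation=0.0)
    base.update(over)
    return sc.default_config(**base)


class TestGenerateCohort:
    def test_study_emulating_defaults(self, default_cohort_40):
        cohort = default_cohort_40
        assert len(cohort) == 40
        labels = [s.chronotype_label for s in cohort.subjects]
        # Table-1-style mix: ~28 morning / ~12 intermediate
        assert 20 <= labels.count("morning") <= 34
        assert 5 <= labels.count("intermediate") <= 18
        for s in cohort.subjects:
            assert len(s.expression_samples) == 2
            assert {x.session for x in s.expression_samples} == {"AM", "PM"}
            assert s.melatonin_saliva is not None and s.melatonin_plasma is not None
            assert s.activity is not None and np.all(s.activity.counts >= 0)
            assert 16 <= s.meq_score <= 86
            assert s.chronotype_label == sc.classify_meq(s.meq_score)
            assert np.isfinite(s.phase_offset_delta)

    def test_empty_cohort(self):
        cohort = sc.generate_cohort(sc.default_config(n_subjects=0))
        assert len(cohort) == 0

    def test_same_seed_is_bit_identical(self):
        cfg = sc.default_config(n_subjects=6, seed=9)
        a, b = sc.generate_cohort(cfg), sc.generate_cohort(cfg)
        for sa, sb in zip(a.subjects, b.subjects):
            assert sa.meq_score == sb.meq_score
            assert sa.phase_offset_delta == sb.phase_offset_delta
            for xa, xb in zip(sa.expression_samples, sb.expression_samples):
                np.testing.assert_array_equal(xa.values, xb.values)
            np.testing.assert_array_equal(sa.melatonin_saliva.concentrations,
                                          sb.melatonin_saliva.concentrations)
            np.testing.assert_array_equal(sa.activity.counts, sb.activity.counts)

    def test_cohort_growth_does_not_perturb_existing_subjects(self):
        small = sc.generate_cohort(sc.default_config(n_subjects=3, seed=9))
        large = sc.generate_cohort(sc.default_config(n_subjects=8, seed=9))
        for sa, sb in zip(small.subjects, large.subjects[:3]):
            assert sa.phase_offset_delta == sb.phase_offset_delta
            np.testing.assert_array_equal(sa.activity.counts, sb.activity.counts)

    @pytest.mark.parametrize("field,value", [
        ("n_subjects", -1), ("fragmentation", 1.5), ("epoch_minutes", 7),
        ("n_genes", 0), ("saliva_plasma_ratio_true", 0.0), ("n_days", 0),
    ])
    def test_invalid_config_names_field(self, field, value):
        with pytest.raises(ConfigError) as err:
            sc.default_config(**{field: value})
        assert field in str(err.value)

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ConfigError):
            sc.CohortConfig.from_dict({"not_a_knob": 1})


class TestExpression:
    def test_noise_free_equals_cosinor_curve(self):
        cfg = _noise_free(n_subjects=1)
        cohort = sc.generate_cohort(cfg)
        subj, panel = cohort.subjects[0], cohort.gene_panel
        t = np.array([3.25])
        sample = sc.simulate_expression(subj, t, cfg, panel)[0]
        expect = panel.mesor + panel.amplitude * np.cos(
            2 * np.pi * (t[0] - (panel.acrophase - subj.phase_offset_delta)) / 24.0)
        np.testing.assert_allclose(sample.values, expect, rtol=0, atol=1e-12)

    def test_zero_amplitude_gives_mesor(self):
        cfg = _noise_free(n_subjects=1, gene_amplitude_mean=0.0, gene_amplitude_sd=0.0)
        cohort = sc.generate_cohort(cfg)
        panel = cohort.gene_panel
        for t in (0.0, 7.5, 18.0):
            s = sc.simulate_expression(cohort.subjects[0], [t], cfg, panel)[0]
            np.testing.assert_allclose(s.values, panel.mesor, atol=1e-12)

    def test_advanced_subject_peaks_earlier(self):
        cfg = _noise_free(n_subjects=1)
        cohort = sc.generate_cohort(cfg)
        subj, panel = cohort.subjects[0], cohort.gene_panel
        subj = dataclasses.replace(subj, phase_offset_delta=2.0)
        t_peak = (panel.acrophase[0] - 2.0) % 24.0
        peak = sc.simulate_expression(subj, [t_peak], cfg, panel)[0].values[0]
        assert peak == pytest.approx(panel.mesor[0] + panel.amplitude[0], abs=1e-12)

    def test_cosine_maximum_unit_case(self):
        cfg = _noise_free(n_subjects=1)
        panel = sc.GenePanel(["g"], np.array([0.0]), np.array([1.0]), np.array([13.0]))
        subj = sc.SubjectProfile("x", 70, 1, 0.0, 50, "intermediate")
        val = sc.simulate_expression(subj, [13.0], cfg, panel)[0].values[0]
        assert val == pytest.approx(1.0, abs=1e-12)


class TestMelatonin:
    def test_piecewise_linear_rise(self):
        cfg = _noise_free(n_subjects=1, melatonin_baseline=2.0, melatonin_rise_rate=8.0)
        cohort = sc.generate_cohort(cfg)
        subj = cohort.subjects[0]
        onset = sc.true_dlmo(subj, cfg)
        sal, pla = sc.simulate_melatonin(subj, [onset - 1.0, onset, onset + 1.0], cfg)
        np.testing.assert_allclose(pla.concentrations, [2.0, 2.0, 10.0], atol=1e-12)

    def test_saliva_is_constant_ratio_of_plasma(self):
        cfg = _noise_free(n_subjects=1, saliva_plasma_ratio_true=0.3)
        cohort = sc.generate_cohort(cfg)
        subj = cohort.subjects[0]
        sal, pla = sc.simulate_melatonin(subj, np.linspace(18, 25, 8), cfg)
        np.testing.assert_allclose(sal.concentrations, 0.3 * pla.concentrations,
                                   atol=1e-12)

    @pytest.mark.parametrize("k", [2.0, 8.0, 20.0])
    def test_dlmo_round_trip_closed_form(self, k):
        # threshold = baseline + k recovers onset + k/rise_rate exactly
        cfg = _noise_free(n_subjects=1, melatonin_baseline=2.0, melatonin_rise_rate=8.0)
        cohort = sc.generate_cohort(cfg)
        subj = cohort.subjects[0]
        onset = sc.true_dlmo(subj, cfg)
        times = np.arange(onset - 2.0, onset + 4.0, 0.5)
        _, pla = sc.simulate_melatonin(subj, times, cfg)
        got = md.compute_dlmo(pla, cfg.melatonin_baseline + k)
        assert got == pytest.approx(onset + k / 8.0, abs=1e-10)


class TestActivity:
    def test_noiseless_square_wave(self):
        cfg = _noise_free(n_subjects=1, activity_day_level=300.0,
                          activity_night_level=0.0)
        cohort = sc.generate_cohort(cfg)
        a = cohort.subjects[0].activity
        centers = a.epoch_start_hours + a.epoch_minutes / 120.0
        in_rest = np.zeros(centers.size, bool)
        for bed, wake in a.rest_intervals:
            in_rest |= (centers >= bed) & (centers < wake)
        assert np.all(a.counts[~in_rest] == 300.0)
        assert np.all(a.counts[in_rest] == 0.0)

    def test_identical_days_give_perfect_interdaily_stability(self):
        cfg = _noise_free(n_subjects=1)
        a = sc.generate_cohort(cfg).subjects[0].activity
        assert am.interdaily_stability(a) == pytest.approx(1.0, abs=1e-12)

    def test_rest_intervals_within_span_and_disjoint(self, default_cohort_40):
        for s in default_cohort_40.subjects:
            a = s.activity
            span = (a.epoch_start_hours[0],
                    a.epoch_start_hours[-1] + a.epoch_minutes / 60.0)
            prev_end = -np.inf
            for bed, wake in a.rest_intervals:
                assert span[0] <= bed < wake <= span[1] + 1e-9
                assert bed >= prev_end
                prev_end = wake

    def test_fragmentation_raises_intradaily_variability(self):
        # Monte-Carlo monotonicity averaged over 20 seeds
        means = []
        for frag in (0.0, 0.5, 1.0):
            ivs = []
            for s in range(20):
                cfg = sc.default_config(n_subjects=1, seed=3000 + s, n_days=4,
                                        epoch_minutes=5, fragmentation=frag)
                coh = sc.generate_cohort(cfg)
                ivs.append(am.intradaily_variability(coh.subjects[0].activity))
            means.append(np.mean(ivs))
        assert means[0] < means[1] < means[2]


class TestMeq:
    @pytest.mark.parametrize("score,label", [
        (64, "morning"), (59, "morning"), (86, "morning"),
        (52, "intermediate"), (58, "intermediate"), (42, "intermediate"),
        (41, "evening"), (16, "evening"),
    ])
    def test_band_assignment(self, score, label):
        assert sc.classify_meq(score) == label

    def test_score_clipped_to_instrument_range(self):
        cfg = _noise_free(n_subjects=1, meq_slope=6.0)
        subj = sc.SubjectProfile("x", 70, 1, 50.0, 0, "")  # raw score 53+300
        score, label = sc.assign_meq(subj, cfg)
        assert score == 86 and label == "morning"
        subj_low = dataclasses.replace(subj, phase_offset_delta=-50.0)
        score, label = sc.assign_meq(subj_low, cfg)
        assert score == 16 and label == "evening"

    def test_noise_free_score_is_linear_in_delta(self):
        cfg = _noise_free(n_subjects=1)
        subj = sc.SubjectProfile("x", 70, 1, 2.0, 0, "")
        score, _ = sc.assign_meq(subj, cfg)
        assert score == round(53.0 + 6.0 * 2.0)


def test_latent_trait_coherence_across_modalities():
    """delta drives every modality in the hypothesized direction (n=200)."""
    cfg = sc.default_config(n_subjects=200, seed=77)
    cohort = sc.generate_cohort(cfg)
    delta = np.array([s.phase_offset_delta for s in cohort.subjects])
    meq = np.array([s.meq_score for s in cohort.subjects])
    dlmo = np.array([s.true_dlmo for s in cohort.subjects])
    bedtime = np.array([
        np.mean([b - 24.0 * i for i, (b, _) in enumerate(s.activity.rest_intervals)])
        for s in cohort.subjects])
    assert np.corrcoef(delta, meq)[0, 1] > 0
    assert np.corrcoef(delta, dlmo)[0, 1] < 0
    assert np.corrcoef(delta, bedtime)[0, 1] < 0
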