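"""Synthetic-data generator: schedules, rendering, reports, corpora."""

import numpy as np
import pytest

from cardiofm.channels import CANONICAL_CHANNELS
from cardiofm.synth import (CLASS_NAMES, Corpus, GeneratorConfig, LEAD_MIX,
                            attach_report, generate_corpus,
                            render_record, sample_beat_schedule)


class TestBeatSchedule:
    def test_regular_zero_jitter_is_equally_spaced(self):
        cfg = GeneratorConfig(duration=10.0, regular_jitter_cv=0.0)
        beats = sample_beat_schedule(cfg, 0, 60.0, np.random.default_rng(0))
        in_window = beats[beats < 10.0]
        assert len(in_window) == 10
        np.testing.assert_allclose(np.diff(beats), 1.0, atol=1e-12)

    def test_regular_rr_cv_below_5_percent(self):
        cfg = GeneratorConfig(duration=60.0)
        rng = np.random.default_rng(1)
        rr = np.concatenate([np.diff(sample_beat_schedule(cfg, 0, 70.0, rng))
                             for _ in range(20)])   # ~1,000 intervals
        assert len(rr) > 900
        assert rr.std() / rr.mean() < 0.05

    def test_irregular_cv_exceeds_regular_with_high_probability(self):
        cfg = GeneratorConfig(duration=30.0)
        rng = np.random.default_rng(2)
        wins = 0
        for _ in range(100):
            rr_reg = np.diff(sample_beat_schedule(cfg, 0, 75.0, rng))
            rr_irr = np.diff(sample_beat_schedule(cfg, 1, 75.0, rng))
            cv = lambda r: r.std() / r.mean()
            wins += cv(rr_irr) > cv(rr_reg)
        assert wins >= 99

    def test_beats_strictly_increasing(self):
        cfg = GeneratorConfig(duration=20.0)
        rng = np.random.default_rng(3)
        for label in (0, 1):
            beats = sample_beat_schedule(cfg, label, 90.0, rng)
            assert (np.diff(beats) > 0).all()

    def test_too_short_record_rejected(self):
        cfg = GeneratorConfig(duration=0.5)
        with pytest.raises(ValueError, match="duration"):
            sample_beat_schedule(cfg, 0, 60.0, np.random.default_rng(0))


class TestRenderRecord:
    def _render(self, **kw):
        defaults = dict(duration=4.0, channels=("II",), noise_sd=0.0,
                        wander_amp=0.0, regular_jitter_cv=0.0)
        defaults.update(kw)
        cfg = GeneratorConfig(**defaults)
        rng = np.random.default_rng(4)
        beats = np.array([1.0])
        return cfg, render_record(beats, cfg, kw.get("label", 0), 50.0, 60.0, rng)

    def test_single_beat_yields_single_r_peak(self):
        _, (rec, _) = self._render()
        x = rec.values[0]
        r_amp = x.max()
        # samples above 80% of the R amplitude cluster within one narrow peak
        above = np.nonzero(x > 0.8 * r_amp)[0]
        assert np.ptp(above) <= 5   # <= 50 ms wide at 100 Hz

    def test_abp_pinned_to_drawn_pressures(self):
        _, (rec, tr) = self._render(channels=("PPG",))
        assert tr.abp.max() == tr.sbp
        assert tr.abp.min() == tr.dbp

    def test_irregular_class_suppresses_p_wave(self):
        cfg = GeneratorConfig(duration=4.0, channels=("II",), noise_sd=0.0,
                              wander_amp=0.0)
        rng = np.random.default_rng(5)
        beats = np.array([1.0])
        rec_reg, _ = render_record(beats, cfg, 0, 50.0, 60.0,
                                   np.random.default_rng(5))
        rec_irr, _ = render_record(beats, cfg, 1, 50.0, 60.0,
                                   np.random.default_rng(5))
        # P wave sits ~160 ms before R: window [0.79, 0.89] s
        p_reg = np.abs(rec_reg.values[0][79:90]).max()
        p_irr = np.abs(rec_irr.values[0][79:90]).max()
        assert p_reg > 3 * p_irr

    def test_lead_correlations_follow_mixing_matrix(self):
        cfg = GeneratorConfig(duration=10.0, noise_sd=0.0, wander_amp=0.0,
                              channels=("II", "III", "aVR"))
        beats = np.arange(0.5, 10.0, 1.0)
        rec, _ = render_record(beats, cfg, 0, 50.0, 60.0,
                               np.random.default_rng(6))
        ii, iii, avr = rec.values
        corr = lambda a, b: np.corrcoef(a, b)[0, 1]
        assert corr(ii, iii) > 0.5        # same-sign mixing rows
        assert corr(ii, avr) < -0.5       # aVR row is negated

    def test_unsupported_channel_rejected_in_config(self):
        with pytest.raises(ValueError, match="unsupported"):
            GeneratorConfig(channels=("II", "ABP"))

    def test_covariate_shifts_heart_rate(self):
        corpus = generate_corpus(GeneratorConfig(
            n_records=200, duration=2.0, channels=("II",), seed=10))
        ages = np.array([tr.age for tr in corpus.truths])
        hrs = np.array([tr.heart_rate for tr in corpus.truths])
        assert np.corrcoef(ages, hrs)[0, 1] > 0.2


class TestReports:
    def test_class_keyword_consistency(self):
        rng = np.random.default_rng(7)
        corpus = generate_corpus(GeneratorConfig(
            n_records=300, duration=2.0, channels=("II",), seed=8))
        for tr in corpus.truths:
            if tr.label == 0:
                assert "sinus" in tr.report
                assert "fibrillation" not in tr.report
            else:
                assert "fibrillation" in tr.report
                assert "sinus" not in tr.report

    def test_report_deterministic_under_seed(self):
        from cardiofm.synth import GroundTruth
        tr = GroundTruth(1, CLASS_NAMES[1], np.array([1.0]), 60.0, 0.3,
                         120.0, 80.0, np.zeros(3), 40.0, None)
        r1 = attach_report(tr, np.random.default_rng(12))
        r2 = attach_report(tr, np.random.default_rng(12))
        assert r1 == r2


class TestCorpus:
    def test_seeded_corpora_are_identical(self):
        cfg = GeneratorConfig(n_records=10, duration=2.0, channels=("II", "PPG"),
                              seed=13)
        c1, c2 = generate_corpus(cfg), generate_corpus(cfg)
        for r1, r2 in zip(c1.records, c2.records):
            np.testing.assert_array_equal(r1.values, r2.values)
        for t1, t2 in zip(c1.truths, c2.truths):
            assert t1.report == t2.report and t1.sbp == t2.sbp

    def test_split_is_disjoint_partition(self):
        corpus = generate_corpus(GeneratorConfig(
            n_records=100, duration=2.0, channels=("II",), seed=14))
        tr, va, te = corpus.split()
        assert len(tr) == 80 and len(va) == 10 and len(te) == 10
        assert not (set(tr) & set(va) or set(tr) & set(te) or set(va) & set(te))
        assert set(tr) | set(va) | set(te) == set(range(100))

    def test_class_mix_within_binomial_bounds(self):
        corpus = generate_corpus(GeneratorConfig(
            n_records=400, duration=2.0, channels=("II",), seed=15))
        n1 = corpus.labels.sum()
        sd = np.sqrt(400 * 0.25)
        assert abs(n1 - 200) <= 3 * sd

    def test_irregular_records_have_higher_rr_cv(self):
        corpus = generate_corpus(GeneratorConfig(
            n_records=60, duration=10.0, channels=("II",), seed=16))
        cv0 = [tr.rr_cv for tr in corpus.truths if tr.label == 0]
        cv1 = [tr.rr_cv for tr in corpus.truths if tr.label == 1]
        assert np.mean(cv1) > 3 * np.mean(cv0)

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            generate_corpus(GeneratorConfig(n_records=0))

    def test_save_load_roundtrip(self, tmp_path):
        corpus = generate_corpus(GeneratorConfig(
            n_records=6, duration=2.0, channels=("II", "PPG"), seed=17))
        corpus.save(tmp_path / "corpus")
        loaded = Corpus.load(tmp_path / "corpus")
        assert len(loaded) == 6
        np.testing.assert_array_equal(loaded.records[3].values,
                                      corpus.records[3].values)
        assert loaded.truths[3].report == corpus.truths[3].report
        assert loaded.manifest["config_hash"] == corpus.manifest["config_hash"]

    def test_manifest_hash_tracks_config(self):
        c1 = generate_corpus(GeneratorConfig(n_records=4, duration=2.0,
                                             channels=("II",), seed=18))
        c2 = generate_corpus(GeneratorConfig(n_records=4, duration=2.0,
                                             channels=("II",), seed=19))
        assert c1.manifest["config_hash"] != c2.manifest["config_hash"]

    def test_mix_matrix_shape(self):
        assert LEAD_MIX.shape == (12, 5)
        assert len(CANONICAL_CHANNELS) == 13
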