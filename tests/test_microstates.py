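"""Tests for GFP, T-AAHC clustering, backfitting, smoothing and parameters."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import preictal as p
from preictal.errors import DegenerateInputError, LengthError, MontageError, ParameterError
from preictal.microstates import MicrostateSequence, _runs

from oracles import run_lengths_oracle


class TestGFP:
    @pytest.mark.parametrize("column,expected", [
        ([5, 5, 5, 5], 0.0),
        ([1, -1], 1.0),
        ([2, 0, -2, 0], np.sqrt(2)),
    ])
    def test_single_sample_values(self, column, expected):
        gfp = p.compute_gfp(np.array(column, dtype=float)[:, None])
        assert gfp.values[0] == pytest.approx(expected)

    def test_single_channel_rejected(self):
        with pytest.raises(DegenerateInputError):
            p.compute_gfp(np.ones((1, 10)))

    def test_nonnegative(self):
        rng = np.random.default_rng(0)
        assert np.all(p.compute_gfp(rng.normal(size=(19, 100))).values >= 0)


class TestGFPPeaks:
    def test_monotone_has_none(self):
        assert p.find_gfp_peaks(p.GFPSeries(np.arange(10.0))).size == 0

    def test_simple_peaks(self):
        peaks = p.find_gfp_peaks(p.GFPSeries(np.array([0, 1, 0, 2, 0.0])))
        assert peaks.tolist() == [1, 3]

    def test_rectified_sinusoid_spacing(self):
        t = np.arange(2500) / 250.0
        gfp = p.GFPSeries(np.abs(np.sin(2 * np.pi * 10 * t)), 250.0)
        peaks = p.find_gfp_peaks(gfp)
        spacing = np.diff(peaks)
        assert np.mean(spacing) == pytest.approx(12.5, rel=0.02)

    def test_too_short(self):
        with pytest.raises(LengthError):
            p.find_gfp_peaks(p.GFPSeries(np.array([1.0, 2.0])))


class TestSpatialCorrelation:
    def test_identical_and_negated(self):
        m = np.array([1.0, -2.0, 0.5, 0.5])
        assert p.spatial_correlation(m, m)[1] == pytest.approx(1.0)
        assert p.spatial_correlation(m, -m) == (pytest.approx(-1.0), pytest.approx(1.0))

    def test_orthogonal_zero_mean_vectors(self):
        r, abs_r = p.spatial_correlation([1, -1, 0, 0], [0, 0, 1, -1])
        assert r == pytest.approx(0.0)
        assert abs_r == pytest.approx(0.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            p.spatial_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_channel_mismatch(self):
        with pytest.raises(MontageError):
            p.spatial_correlation([1.0, 2.0], [1.0, 2.0, 3.0])


def _match_quality(found: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Best |r| of each true template to any found centroid."""
    absr = np.abs(found @ truth.T)
    return absr.max(axis=0)


class TestTAAHC:
    def test_repeated_orthogonal_templates(self, planted_templates):
        maps = np.repeat(planted_templates, 50, axis=0)
        templates = p.taahc_cluster(maps, 4)
        assert np.all(_match_quality(templates.maps, planted_templates) > 1 - 1e-9)
        assert templates.gev == pytest.approx(1.0)

    def test_sign_flip_invariance(self, planted_templates):
        maps = np.repeat(planted_templates, 50, axis=0)
        rng = np.random.default_rng(1)
        signs = rng.choice([-1.0, 1.0], size=maps.shape[0])
        flipped = maps * signs[:, None]
        a = p.taahc_cluster(maps, 4)
        b = p.taahc_cluster(flipped, 4)
        # same subspaces up to sign and order
        match = np.abs(a.maps @ b.maps.T)
        assert np.allclose(match.max(axis=1), 1.0, atol=1e-9)

    def test_noisy_templates_recovered(self, planted_templates):
        rng = np.random.default_rng(2)
        reps = np.repeat(planted_templates, 100, axis=0)
        noise = rng.normal(size=reps.shape)
        noise *= np.linalg.norm(reps) / np.linalg.norm(noise) / np.sqrt(10**(20 / 10))
        templates = p.taahc_cluster(reps + noise, 4)
        assert np.all(_match_quality(templates.maps, planted_templates) >= 0.95)

    def test_k_out_of_range(self, planted_templates):
        with pytest.raises(ParameterError):
            p.taahc_cluster(planted_templates, 0)
        with pytest.raises(ParameterError):
            p.taahc_cluster(planted_templates, 5)

    def test_gev_nondecreasing_in_k(self, noisy_recording):
        rec, _, _ = noisy_recording
        gfp = p.compute_gfp(rec.data)
        peaks = p.find_gfp_peaks(gfp)[:800]
        maps = rec.data[:, peaks].T
        w = gfp.values[peaks] ** 2
        gevs = [p.taahc_cluster(maps, k, weights=w).gev for k in range(2, 7)]
        assert np.all(np.diff(gevs) >= -1e-12)


class TestSelectOptimalK:
    @pytest.mark.parametrize("k_true", [3, 4])
    def test_recovers_planted_k(self, k_true):
        rng = np.random.default_rng(40 + k_true)
        tmpl = p.make_templates(19, k_true, rng=rng)
        spec = p.SyntheticSpec(seed=40 + k_true, k=k_true, snr_db=20.0,
                               oscillations=(), templates=tmpl)
        labels, _ = p.simulate_sequence(spec, 60.0)
        rec = p.render_eeg(labels, spec)
        gfp = p.compute_gfp(rec.data)
        peaks = p.find_gfp_peaks(gfp)
        sub = np.random.default_rng(0).choice(peaks.size, 1000, replace=False)
        k, snaps = p.select_optimal_k(rec.data[:, peaks[sub]].T, (3, 8),
                                      weights=gfp.values[peaks[sub]] ** 2)
        assert k == k_true
        assert set(snaps) == set(range(3, 9))

    def test_degenerate_identical_maps(self):
        maps = np.tile(np.array([1.0, -1.0, 0.5, -0.5, 0.0]), (30, 1))
        with pytest.warns(UserWarning):
            k, _ = p.select_optimal_k(maps, (3, 8))
        assert k == 3


class TestBackfit:
    def test_noise_free_identity(self, clean_recording, planted_templates):
        rec, labels, _ = clean_recording
        templates = p.MicrostateTemplates(planted_templates, 4, 1.0)
        seq = p.backfit(templates, rec.data, sample_rate=rec.sample_rate)
        assert np.all(seq.labels == labels)
        assert np.all(seq.correlations > 1 - 1e-9)

    def test_sign_flip_invariance(self, clean_recording, planted_templates):
        rec, labels, _ = clean_recording
        templates = p.MicrostateTemplates(planted_templates, 4, 1.0)
        seq = p.backfit(templates, -rec.data, sample_rate=rec.sample_rate)
        assert np.all(seq.labels == labels)

    def test_orthogonal_sample_unassigned(self, planted_templates):
        templates = p.MicrostateTemplates(planted_templates[:3], 3, 1.0)
        # the 4th template is orthogonal to the first three by construction
        epoch = np.tile(planted_templates[3][:, None], (1, 10))
        seq = p.backfit(templates, epoch, sample_rate=250.0)
        assert np.all(seq.labels == 0)

    def test_channel_mismatch(self, planted_templates):
        templates = p.MicrostateTemplates(planted_templates, 4, 1.0)
        with pytest.raises(MontageError):
            p.backfit(templates, np.zeros((5, 100)), sample_rate=250.0)


def _seq(labels, rate=250.0, k=4):
    labels = np.asarray(labels, dtype=int)
    return MicrostateSequence(labels, np.ones(labels.size), rate, k)


class TestSmoothing:
    def test_even_short_run_halved(self):
        labels = [1] * 20 + [3] * 6 + [2] * 20
        out = p.smooth_sequence(_seq(labels), 32.0)
        assert out.labels.tolist() == [1] * 23 + [2] * 23

    def test_odd_short_run_ceil_floor(self):
        labels = [1] * 20 + [3] * 5 + [2] * 20
        out = p.smooth_sequence(_seq(labels), 32.0)
        assert out.labels.tolist() == [1] * 23 + [2] * 22

    def test_long_runs_unchanged(self):
        labels = [1] * 8 + [2] * 9 + [3] * 8
        out = p.smooth_sequence(_seq(labels), 32.0)
        assert out.labels.tolist() == labels

    def test_boundary_run_absorbed_by_single_neighbor(self):
        labels = [2] * 3 + [1] * 30
        out = p.smooth_sequence(_seq(labels), 32.0)
        assert out.labels.tolist() == [1] * 33

    def test_unassigned_never_absorbs(self):
        labels = [0] * 20 + [3] * 4 + [0] * 20
        out = p.smooth_sequence(_seq(labels), 32.0)
        assert out.labels.tolist() == labels

    @given(st.lists(st.integers(0, 4), min_size=1, max_size=200))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_never_creates_new_labels(self, labels):
        out = p.smooth_sequence(_seq(labels), 32.0)
        assert set(out.labels.tolist()) <= set(labels) | set()
        assert out.labels.size == len(labels)


class TestParameters:
    def test_single_class_epoch(self):
        pars = p.microstate_parameters(_seq([1] * 750))
        assert pars.mean_duration_ms[0] == pytest.approx(3000.0)
        assert pars.coverage_fraction[0] == pytest.approx(1.0)
        assert pars.occurrence_per_s[0] == pytest.approx(1 / 3)
        assert pars.missing_classes == [2, 3, 4]

    def test_alternating_runs(self):
        labels = ([1] * 25 + [2] * 25) * 15  # 750 samples, 3 s at 250 Hz
        pars = p.microstate_parameters(_seq(labels))
        assert pars.mean_duration_ms[0] == pytest.approx(100.0)
        assert pars.mean_duration_ms[1] == pytest.approx(100.0)
        assert pars.coverage_fraction[:2] == pytest.approx([0.5, 0.5])
        assert pars.occurrence_per_s[:2] == pytest.approx([5.0, 5.0])

    @given(st.lists(st.integers(0, 4), min_size=1, max_size=500))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_coverage_sums_to_one(self, labels):
        pars = p.microstate_parameters(_seq(labels))
        total = pars.coverage_fraction.sum() + pars.unassigned_fraction
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_occurrence_duration_coverage_identity(self):
        rng = np.random.default_rng(3)
        labels = np.repeat(rng.integers(1, 5, 400), rng.integers(5, 40, 400))
        pars = p.microstate_parameters(_seq(labels))
        for c in range(4):
            product = pars.occurrence_per_s[c] * pars.mean_duration_ms[c]
            assert product == pytest.approx(pars.coverage_fraction[c] * 1000.0,
                                            rel=0.02)

    def test_runs_match_oracle(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 5, 300)
        ours = [(lab, length) for lab, _, length in _runs(labels)]
        assert ours == run_lengths_oracle(labels)
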