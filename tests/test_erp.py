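"""Event-related potentials: filtering, baselining, averaging, peaks, and
the ERP-alignment correlation."""

import numpy as np
import pytest

from phasealign import (ERPWave, PAIMap, SynthConfig, compute_erp,
                        erp_alignment_correlation, erp_peak, generate_cohort)
from phasealign.erp import bandpass_zero_phase
from conftest import make_epochset

SFREQ = 500.0


def _epochs(trials, t0=-0.5):
    trials = np.asarray(trials, dtype=float)
    cond = np.array(["SE"] * (len(trials) - 1) + ["UE"], dtype=object)
    return make_epochset(trials[:, None, :], sfreq=SFREQ, t0=t0,
                         condition=cond)


class TestComputeERP:
    def test_constant_trials_vanish(self):
        es = _epochs(np.full((6, 1500), 3.7))
        erp = compute_erp(es, "frontal", "SE")
        assert np.max(np.abs(erp.values)) < 1e-9

    def test_baseline_mean_is_zero(self):
        rng = np.random.default_rng(0)
        es = _epochs(rng.standard_normal((8, 1500)))
        erp = compute_erp(es, "frontal", "SE")
        bmask = (erp.times >= -0.2) & (erp.times <= 0.0)
        assert abs(erp.values[bmask].mean()) < 1e-9

    def test_noise_averages_out_at_sqrt_k(self):
        """Fixed 5 Hz cosine + noise: residual RMS shrinks ~1/sqrt(K)."""
        t = -0.5 + np.arange(1500) / SFREQ
        signal = np.cos(2 * np.pi * 5 * t)
        rng = np.random.default_rng(1)
        rms = {}
        for k in (10, 100, 1000):
            trials = signal + rng.standard_normal((k + 1, 1500))
            erp = compute_erp(_epochs(trials), "frontal", "SE")
            ref = compute_erp(_epochs(np.tile(signal, (2, 1))), "frontal", "SE")
            interior = slice(200, 1300)
            rms[k] = np.sqrt(np.mean(
                (erp.values[interior] - ref.values[interior]) ** 2))
        assert rms[100] < rms[10]
        assert rms[1000] < rms[100]
        # within a factor ~2 of the 1/sqrt(K) law over two decades
        assert rms[1000] < rms[10] / 5.0

    def test_single_trial_identity(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(1500)
        es = _epochs(np.stack([x, np.zeros(1500)]))
        erp = compute_erp(es, "frontal", "SE")
        filt = bandpass_zero_phase(x, SFREQ, (1.0, 8.0))[0]
        bmask = (es.times >= -0.2) & (es.times <= 0.0)
        expected = filt - filt[bmask].mean()
        np.testing.assert_allclose(erp.values, expected, atol=1e-9)

    def test_per_trial_offset_invariance(self):
        rng = np.random.default_rng(3)
        trials = rng.standard_normal((5, 1500))
        offsets = rng.uniform(-30, 30, size=(5, 1))
        a = compute_erp(_epochs(trials), "frontal", "SE")
        b = compute_erp(_epochs(trials + offsets), "frontal", "SE")
        np.testing.assert_allclose(a.values, b.values, atol=1e-7)

    def test_linear_in_trials_and_reorder_invariant(self):
        rng = np.random.default_rng(4)
        trials = rng.standard_normal((4, 1500))
        a = compute_erp(_epochs(trials), "frontal", "SE")
        b = compute_erp(_epochs(trials[[2, 0, 1, 3]]), "frontal", "SE")
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)
        c = compute_erp(_epochs(2.0 * trials), "frontal", "SE")
        np.testing.assert_allclose(c.values, 2.0 * a.values, atol=1e-9)

    def test_baseline_outside_epoch_rejected(self):
        es = _epochs(np.zeros((3, 1500)), t0=0.0)
        with pytest.raises(ValueError, match="baseline"):
            compute_erp(es, "frontal", "SE", baseline_window=(-0.2, -0.1))


class TestERPPeak:
    def _wave(self, values, dt=0.1):
        values = np.asarray(values, dtype=float)
        return ERPWave("P", "frontal", "SE",
                       times=np.arange(values.size) * dt, values=values)

    def test_largest_absolute_deflection(self):
        amp, lat = erp_peak(self._wave([0.0, -3.0, 2.0]), (0.0, 0.3))
        assert amp == -3.0 and lat == pytest.approx(0.1)

    def test_tie_broken_at_window_start(self):
        amp, lat = erp_peak(self._wave([1.5, 1.5, 1.5]), (0.0, 0.3))
        assert amp == 1.5 and lat == 0.0

    def test_injected_transient_recovered(self):
        """A noiseless 4 uV damped transient survives the 1-8 Hz filter
        with at least 3 uV of its peak."""
        cfg = SynthConfig(n_participants=1, n_trials_per_condition=2,
                          noise_sigma=0.0, theta_amp=0.0, early_amp=0.0,
                          gamma_amp=0.0, erp_amplitude=4.0, seed=0)
        cohort, _ = generate_cohort(cfg)
        erp = compute_erp(cohort[0], "frontal", "SE")
        amp, _ = erp_peak(erp, (0.0, 0.5))
        assert abs(amp) >= 3.0

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            erp_peak(self._wave([1.0, 2.0]), (5.0, 6.0))


class TestERPAlignmentCorrelation:
    def _pair(self, pai_series, erp_series, dt=0.01):
        n = len(pai_series)
        times = np.arange(n) * dt
        erp = ERPWave("P", "R-ATN", "SE", times=times,
                      values=np.asarray(erp_series, float))
        pmap = PAIMap("P", "R-ATN", "SE", freqs=np.array([10.0]),
                      times=times, pai=np.asarray(pai_series, float)[None, :],
                      n_epochs=10)
        return erp, pmap

    def test_affine_relation_gives_unit_correlation(self):
        rng = np.random.default_rng(0)
        base = rng.random(50) * 0.5 + 0.2
        erp, pmap = self._pair(0.4 * base + 0.1, base)
        res = erp_alignment_correlation(erp, pmap, window=(0.0, 0.49),
                                        band=(8.0, 12.0))
        assert res.r == pytest.approx(1.0, abs=1e-9)

    def test_independent_series_rarely_correlate(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(40):
            erp, pmap = self._pair(rng.random(100) * 0.8,
                                   rng.standard_normal(100), dt=0.005)
            res = erp_alignment_correlation(erp, pmap, window=(0.0, 0.49),
                                            band=(8.0, 12.0))
            if abs(res.r) < 0.3:
                hits += 1
        assert hits >= 36

    def test_shared_early_reset_drives_positive_correlation(self):
        """The early broadband reset produces both an evoked deflection and
        early phase alignment, so |ERP| and PAI correlate positively."""
        from phasealign.alignment import pai_map_from_tf
        from phasealign.tfr import morlet_decompose

        hits = 0
        n_runs = 10
        for s in range(n_runs):
            cfg = SynthConfig(n_participants=1, n_trials_per_condition=30,
                              seed=500 + s)
            cohort, _ = generate_cohort(cfg)
            es = cohort[0]
            tf = morlet_decompose(es, np.arange(4.0, 21.0), channel="R-ATN",
                                  decim=5)
            pmap = pai_map_from_tf(tf, es.participant_id, "R-ATN", "SE",
                                   es.condition_mask("SE"))
            erp = compute_erp(es, "R-ATN", "SE")
            res = erp_alignment_correlation(erp, pmap, window=(0.0, 0.5),
                                            band=(4.0, 20.0))
            if res.r > 0:
                hits += 1
        assert hits >= 9

    def test_too_few_points_rejected(self):
        erp, pmap = self._pair([0.1, 0.2], [1.0, 2.0])
        with pytest.raises(ValueError):
            erp_alignment_correlation(erp, pmap, window=(0.0, 0.01),
                                      band=(8.0, 12.0))
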