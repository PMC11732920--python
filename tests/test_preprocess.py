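"""Denoising chain and motion QC."""

import numpy as np
import pytest

from cerebgraph import (DenoiseSettings, bandpass_filter, despike_frames,
                        drop_initial_volumes, mean_relative_rms, qc_subject,
                        regress_confounds)

TR = 2.5


def _arrays(n, n_rois=4, rng=None):
    rng = rng or np.random.default_rng(0)
    return (rng.standard_normal((n, n_rois)),
            rng.standard_normal((n, 6)) * 0.01,
            rng.standard_normal((n, 2)))


class TestDropInitialVolumes:
    def test_drops_first_k_rows_synchronously(self):
        ts, mo, nu = _arrays(200)
        t2, m2, n2 = drop_initial_volumes(ts, mo, nu, 5)
        assert t2.shape[0] == m2.shape[0] == n2.shape[0] == 195
        np.testing.assert_array_equal(t2, ts[5:])
        np.testing.assert_array_equal(m2, mo[5:])

    def test_zero_is_identity(self):
        ts, mo, nu = _arrays(10)
        t2, _, _ = drop_initial_volumes(ts, mo, nu, 0)
        np.testing.assert_array_equal(t2, ts)

    def test_dropping_everything_errors(self):
        ts, mo, nu = _arrays(5)
        with pytest.raises(ValueError, match="drop"):
            drop_initial_volumes(ts, mo, nu, 5)


class TestDespike:
    def test_injected_spike_flagged_and_replaced(self, rng):
        # spike at the last frame: exactly one outlying differential
        x = rng.standard_normal((195, 6)) * 0.1
        x[194] += 20.0
        cleaned, n = despike_frames(x, z_thresh=9.0)
        assert n == 1
        clean_mask = np.ones(195, bool)
        clean_mask[194] = False
        np.testing.assert_allclose(cleaned[194], x[clean_mask].mean(axis=0))
        np.testing.assert_array_equal(cleaned[clean_mask], x[clean_mask])

    def test_interior_spike_flags_both_transition_frames(self, rng):
        # an interior one-frame excursion makes both the entering and the
        # leaving differential outlying; both frames are replaced
        x = rng.standard_normal((195, 6)) * 0.1
        x[100] += 20.0
        cleaned, n = despike_frames(x, z_thresh=9.0)
        assert n == 2
        assert np.abs(cleaned[100]).max() < 1.0

    def test_gaussian_noise_is_essentially_never_flagged(self):
        # at z = 9 over 195 frames, flags should be vanishingly rare
        flags = 0
        for seed in range(500):
            x = np.random.default_rng(seed).standard_normal((195, 8))
            _, n = despike_frames(x, 9.0)
            flags += n
        assert flags / (500 * 194) < 0.001

    def test_infinite_threshold_is_identity(self, rng):
        x = rng.standard_normal((50, 3))
        cleaned, n = despike_frames(x, np.inf)
        assert n == 0
        np.testing.assert_array_equal(cleaned, x)

    def test_constant_series_no_flags(self):
        cleaned, n = despike_frames(np.ones((30, 2)), 9.0)
        assert n == 0


class TestBandpass:
    def _amplitude(self, y, freq, n):
        spec = np.abs(np.fft.rfft(y)) * 2 / n
        idx = int(round(freq * n * TR))
        return spec[idx]

    def test_passband_sinusoid_retained(self):
        n = 400
        t = np.arange(n) * TR
        x = np.sin(2 * np.pi * 0.04 * t)[:, None]
        y = bandpass_filter(x, TR, 0.008, 0.09)[:, 0]
        assert self._amplitude(y, 0.04, n) >= 0.9 * self._amplitude(x[:, 0], 0.04, n)

    def test_stopband_sinusoid_suppressed(self):
        n = 400
        t = np.arange(n) * TR
        x = np.sin(2 * np.pi * 0.15 * t)[:, None]
        y = bandpass_filter(x, TR, 0.008, 0.09)[:, 0]
        assert self._amplitude(y, 0.15, n) <= 0.1 * self._amplitude(x[:, 0], 0.15, n)

    def test_constant_column_zeroed(self):
        y = bandpass_filter(np.full((100, 2), 7.3), TR, 0.008, 0.09)
        np.testing.assert_allclose(y, 0.0, atol=1e-10)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(np.zeros((50, 1)), TR, 0.008, 0.3)

    def test_despiking_clean_series_commutes_with_filter(self, rng):
        # a series with no spikes: despike -> filter == filter alone
        x = rng.standard_normal((195, 5))
        despiked, n = despike_frames(x, 9.0)
        assert n == 0
        a = bandpass_filter(despiked, TR, 0.008, 0.09)
        b = bandpass_filter(x, TR, 0.008, 0.09)
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestRegressConfounds:
    def test_timeseries_equal_to_confound_gives_zero_residual(self, rng):
        mo = rng.standard_normal((100, 6))
        nu = rng.standard_normal((100, 2))
        y = mo[:, [2]] * 3.0
        res = regress_confounds(y, mo, nu)
        np.testing.assert_allclose(res, 0.0, atol=1e-10)

    def test_zero_confounds_demean_only(self, rng):
        y = rng.standard_normal((80, 3)) + 5.0
        with pytest.warns(UserWarning):
            res = regress_confounds(y, np.zeros((80, 6)), np.zeros((80, 2)))
        np.testing.assert_allclose(res, y - y.mean(axis=0), atol=1e-10)

    def test_residuals_orthogonal_to_regressors(self, rng):
        ts, mo, nu = _arrays(150, 5, rng)
        res = regress_confounds(ts, mo, nu)
        design = np.column_stack([np.ones(150), mo, nu])
        inner = design.T @ res
        scale = np.linalg.norm(design) * np.linalg.norm(res)
        assert np.abs(inner).max() / scale < 1e-8

    def test_projection_is_idempotent(self, rng):
        ts, mo, nu = _arrays(120, 4, rng)
        once = regress_confounds(ts, mo, nu)
        twice = regress_confounds(once, mo, nu)
        np.testing.assert_allclose(once, twice, atol=1e-10)

    def test_denoising_recovers_truth_better_than_raw(self):
        # leakage of known confounds should be removed by regression
        from cerebgraph import CohortConfig, ParcellationSpec, simulate_subject
        cfg = CohortConfig(
            n_volumes=500, parcellation=ParcellationSpec("p4", tuple("abcd")),
            affected_rois=("a",), base_correlation=0.5, correlation_spread=0.0,
            subject_spread=0.0, edge_attenuation=0.0, attenuation_subject_sd=0.0,
            confound_loadings={"motion": 1.0, "wm": 1.0, "csf": 1.0},
            noise_sd=0.1, seed=9,
        )
        rec = simulate_subject(cfg, "control", np.random.default_rng(9))
        truth = 0.5
        raw = np.corrcoef(rec.timeseries, rowvar=False)
        res = regress_confounds(rec.timeseries, rec.motion, rec.nuisance)
        den = np.corrcoef(res, rowvar=False)
        iu = np.triu_indices(4, 1)
        assert np.abs(den[iu] - truth).mean() < np.abs(raw[iu] - truth).mean()


class TestMotionQC:
    def test_static_trace_zero_rms(self):
        assert mean_relative_rms(np.zeros((50, 6))) == 0.0

    def test_unit_step_translation(self):
        mo = np.zeros((11, 6))
        mo[:, 0] = np.arange(11)  # +1 mm per frame along x
        assert mean_relative_rms(mo) == pytest.approx(1 / np.sqrt(3))

    def test_homogeneity(self, rng):
        mo = rng.standard_normal((40, 6))
        assert mean_relative_rms(2 * mo) == pytest.approx(2 * mean_relative_rms(mo))

    def test_high_rms_excludes(self):
        mo = np.zeros((100, 6))
        mo[1::2, 0] = 0.45  # alternating steps -> mean relative RMS ~ 0.26
        rep = qc_subject(mo, DenoiseSettings(), "s1")
        assert rep.excluded
        assert any("RMS" in r for r in rep.exclusion_reasons)
        assert not any("translation" in r for r in rep.exclusion_reasons)

    def test_single_large_displacement_excludes(self):
        mo = np.zeros((100, 6))
        mo[50, 1] = 2.5
        rep = qc_subject(mo, DenoiseSettings(), "s2")
        assert rep.excluded
        assert any("translation" in r for r in rep.exclusion_reasons)

    def test_rotation_limit_checked_separately(self):
        mo = np.zeros((100, 6))
        mo[10, 4] = 2.2  # degrees
        rep = qc_subject(mo, DenoiseSettings(), "s3")
        assert rep.excluded
        assert any("rotation" in r for r in rep.exclusion_reasons)

    def test_still_subject_included(self):
        rep = qc_subject(np.zeros((100, 6)), DenoiseSettings(), "s4")
        assert not rep.excluded
        assert rep.exclusion_reasons == []

    @pytest.mark.parametrize("scale", [1.5, 3.0, 10.0])
    def test_scaling_up_never_rescues_an_excluded_subject(self, rng, scale):
        mo = rng.standard_normal((60, 6)) * 0.2
        before = qc_subject(mo, DenoiseSettings(), "s")
        after = qc_subject(mo * scale, DenoiseSettings(), "s")
        if before.excluded:
            assert after.excluded

    def test_boundary_rms_excluded_at_threshold(self):
        # the exclusion rule is >= 0.20, not > 0.20
        step = 0.20 * np.sqrt(3)
        mo = np.zeros((3, 6))
        mo[1, 0] = step
        mo[2, 0] = 2 * step
        rep = qc_subject(mo, DenoiseSettings(), "s")
        assert rep.mean_relative_rms == pytest.approx(0.20)
        assert rep.excluded
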