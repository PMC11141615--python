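"""DDM: windowing convention, spectra, ISF, relaxation-time extraction."""

import numpy as np
import pytest
from scipy.special import j0

from conftest import BALLISTIC_SPEED_UM_S, BROWNIAN_D_UM2_S
from mtswarm.ddm import (
    DDMWindow,
    ISFEstimate,
    extract_windows,
    fit_initial_relaxation,
    isf,
    relaxation_trace,
    structure_function,
    _nearest_bin,
)
from mtswarm.errors import ValidationError


def dummy_frames(n, side=8, seed=0):
    return np.random.default_rng(seed).random((n, side, side))


class TestWindowing:
    @pytest.mark.parametrize("n_frames, expected", [(180, 155), (26, 1), (40, 15)])
    def test_window_count_convention(self, n_frames, expected):
        wins = extract_windows(
            dummy_frames(n_frames), frame_interval_s=1.0, pixel_size_um=0.5
        )
        assert len(wins) == expected
        assert all(w.window_len == 25 for w in wins)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValidationError):
            extract_windows(dummy_frames(25), frame_interval_s=1.0, pixel_size_um=0.5)

    def test_midpoint_time_is_thirteenth_frame(self):
        wins = extract_windows(
            dummy_frames(30), frame_interval_s=60.0, pixel_size_um=0.5
        )
        for w in wins:
            assert w.T_min == pytest.approx(w.start_frame + 12)

    def test_array_input_requires_calibration(self):
        with pytest.raises(ValidationError):
            extract_windows(dummy_frames(30))


class TestStructureFunction:
    def test_static_movie_has_zero_structure_function(self):
        frame = np.random.default_rng(1).random((32, 32))
        window = DDMWindow(np.repeat(frame[None], 25, axis=0), 0, 1.0, 0.5)
        sf = structure_function(window)
        assert np.all(sf.D == 0.0)

    def test_pure_noise_is_flat_in_lag(self):
        frames = np.random.default_rng(2).normal(100.0, 10.0, (25, 64, 64))
        sf = structure_function(DDMWindow(frames, 0, 1.0, 0.5))
        band = slice(10, 26)
        d_band = sf.D[:, band].mean(axis=1)  # mid-band average per lag
        assert np.max(np.abs(d_band - d_band.mean())) / d_band.mean() < 0.05

    def test_parseval_consistency_every_lag(self):
        frames = np.random.default_rng(3).random((10, 32, 32)) * 50
        window = DDMWindow(frames, 0, 1.0, 0.5)
        sf = structure_function(window)
        weights = sf.counts / sf.counts.sum()
        for li, lag in enumerate(range(1, 10)):
            diffs = frames[lag:] - frames[:-lag] if lag else None
            msd = np.mean([(d**2).mean() for d in diffs])
            spectral = float(sf.D[li] @ weights)
            assert abs(spectral - msd) / msd < 1e-3

    def test_translating_pattern_nulls_at_full_phase_wrap(self):
        # sinusoid moving at v: D ∝ sin²(q·v·Δt/2), first zero at q·v·Δt = 2π
        side, px = 64, 0.5
        m = 4
        kx = 2 * np.pi * m / (side * px)
        v = 2 * np.pi / (kx * 4.0)  # μm/s -> full wrap at lag 4 s
        x = np.arange(side) * px
        frames = np.stack(
            [np.tile(np.sin(kx * (x - v * t)), (side, 1)) for t in range(25)]
        )
        sf = structure_function(DDMWindow(frames, 0, 1.0, px))
        qi = _nearest_bin(sf.q_um, kx)
        assert sf.D[1, qi] > 0  # lag 2 s: maximal dephasing
        assert sf.D[3, qi] < 1e-9 * sf.D[1, qi]  # lag 4 s: q·v·Δt = 2π, first zero
        # intermediate lags follow the sin² phase law
        assert sf.D[0, qi] / sf.D[1, qi] == pytest.approx(
            np.sin(kx * v * 1 / 2) ** 2 / np.sin(kx * v * 2 / 2) ** 2, rel=1e-6
        )

    def test_nonfinite_pixels_rejected(self):
        frames = dummy_frames(25, 16)
        frames[3, 0, 0] = np.nan
        with pytest.raises(ValidationError):
            structure_function(DDMWindow(frames, 0, 1.0, 0.5))


class TestISF:
    def test_isf_is_anchored_at_one(self):
        frames = np.random.default_rng(4).normal(50, 5, (25, 32, 32))
        est = isf(structure_function(DDMWindow(frames, 0, 1.0, 0.5)))
        assert np.all(est.F[0, est.usable] == 1.0)

    def test_too_few_lags_rejected(self):
        frames = dummy_frames(3, 16)
        sf = structure_function(DDMWindow(frames, 0, 1.0, 0.5))
        with pytest.raises(ValidationError):
            isf(sf)

    def test_brownian_isf_matches_exponential(self, brownian_benchmark):
        frames = brownian_benchmark.channel("green")
        est_F, q_grid, lag_s = None, None, None
        n_avg = 0
        for s in range(0, 30, 5):
            wnd = DDMWindow(frames[s : s + 25], s, 0.5, 0.5)
            est = isf(structure_function(wnd))
            if est_F is None:
                est_F = np.zeros_like(est.F)
                q_grid, lag_s = est.q_um, est.lag_s
            est_F += est.F
            n_avg += 1
        est_F /= n_avg
        band = [qi for qi, q in enumerate(q_grid)
                if 0.2 <= BROWNIAN_D_UM2_S * q * q * 0.5 <= 0.8]
        assert len(band) >= 4
        for qi in band:
            for li in range(1, 4):
                expected = np.exp(-BROWNIAN_D_UM2_S * q_grid[qi] ** 2 * lag_s[li])
                assert abs(est_F[li, qi] - expected) < 0.1

    def test_ballistic_isf_matches_bessel(self, ballistic_movie):
        frames = ballistic_movie.channel("green")
        v = BALLISTIC_SPEED_UM_S
        est_F, q_grid, lag_s = None, None, 0
        n_avg = 0
        for s in range(0, 20, 4):
            wnd = DDMWindow(frames[s : s + 25], s, 0.5, 0.5)
            est = isf(structure_function(wnd))
            if est_F is None:
                est_F = np.zeros_like(est.F)
                q_grid, lag_s = est.q_um, est.lag_s
            est_F += est.F
            n_avg += 1
        est_F /= n_avg
        band = [qi for qi, q in enumerate(q_grid) if 0.6 <= q * v * 0.5 <= 1.0]
        assert len(band) >= 4
        for qi in band:
            q = q_grid[qi]
            for li in range(1, 4):
                x = q * v * lag_s[li]
                if x < 2.4:  # before the first zero of J0
                    assert abs(est_F[li, qi] - j0(x)) < 0.1


def synthetic_isf(F_values, lag_s=(0.0, 1.0, 2.0, 3.0)):
    F = np.asarray(F_values, dtype=float)[:, None]
    return ISFEstimate(
        q_um=np.array([1.0]),
        lag_s=np.asarray(lag_s, dtype=float),
        F=F,
        A=np.array([1.0]),
        B=np.array([0.0]),
        usable=np.array([True]),
    )


class TestRelaxationFit:
    def test_exact_exponential_recovers_generator_tau(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        est = synthetic_isf(np.exp(-t / 2.0), t)
        assert fit_initial_relaxation(est, 1.0) == pytest.approx(2.0, rel=1e-6)

    def test_slow_exponential_is_recovered_by_extrapolation(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        est = synthetic_isf(np.exp(-t / 8.0), t)  # no 1/e crossing within range
        assert fit_initial_relaxation(est, 1.0) == pytest.approx(8.0, rel=1e-3)

    def test_constant_isf_is_flagged_nondecaying(self):
        est = synthetic_isf([1.0, 1.0, 1.0, 1.0])
        assert fit_initial_relaxation(est, 1.0) == np.inf

    def test_unusable_bin_propagates_nan(self):
        est = synthetic_isf([1.0, 0.5, 0.3, 0.2])
        est.usable[0] = False
        assert np.isnan(fit_initial_relaxation(est, 1.0))

    def test_nearest_bin_ties_resolve_to_lower_q(self):
        grid = np.array([0.0, 1.0, 2.0, 3.0])
        assert _nearest_bin(grid, 1.5) == 1
        assert _nearest_bin(grid, 1.6) == 2


class TestRelaxationTrace:
    def test_wavelength_validation(self, ballistic_movie):
        with pytest.raises(ValidationError):
            relaxation_trace(ballistic_movie, wavelengths_um=(100.0,))
        with pytest.raises(ValidationError):
            relaxation_trace(ballistic_movie, wavelengths_um=(0.5,))

    def test_fast_path_agrees_with_per_window_computation(self, ballistic_movie):
        wl = 4.0
        rt = relaxation_trace(ballistic_movie, wavelengths_um=(wl,), block=16)
        frames = ballistic_movie.channel("green")
        wnd = DDMWindow(frames[0:25], 0, 0.5, 0.5)
        est = isf(structure_function(wnd))
        tau_direct = fit_initial_relaxation(est, 2 * np.pi / wl)
        row = rt.per_window
        row = row[(row.channel == "green") & (row.window == 0)]
        assert row.tau_s.iloc[0] == pytest.approx(tau_direct, rel=1e-9)

    def test_stationary_ballistic_movie_gives_flat_trace(self, ballistic_movie):
        rt = relaxation_trace(ballistic_movie, wavelengths_um=(4.0,), block=16)
        for ch in ("green", "magenta"):
            tau = rt.per_window[rt.per_window.channel == ch].tau_s.to_numpy()
            tau = tau[np.isfinite(tau)]
            half = len(tau) // 2
            a, b = tau[:half].mean(), tau[half:].mean()
            assert abs(a - b) / ((a + b) / 2) < 0.1

    def test_progressive_sticking_raises_filament_scale_tau(self, sticking_movie):
        from scipy.stats import spearmanr

        movie, _log = sticking_movie
        rt = relaxation_trace(movie, wavelengths_um=(6.1,), block=16)
        for ch in ("green", "magenta"):
            g = rt.blocked[rt.blocked.channel == ch]
            rho = spearmanr(g.T_min, g.tau_s).statistic
            assert rho > 0.8
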