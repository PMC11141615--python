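"""Windowed differential dynamic microscopy (DDM) analysis.

DDM extracts ensemble dynamics from a movie without tracking: the image
structure function

    D(q, Δt) = ⟨ |FFT2[ I(t+Δt) − I(t) ]|² ⟩_t   (radially averaged over q̂)

relates to the intermediate scattering function F(q, Δt) through

    D(q, Δt) = A(q) · (1 − F(q, Δt)) + B(q),

where A(q) is twice the static signal power and B(q) the camera noise
floor.  F decays on a time scale τ(q) characteristic of motion at length
scale 2π/q: exp(−D₀q²Δt) for Brownian tracers, the Bessel function
J₀(q·v·Δt) for isotropically oriented ballistic motion.

The windowed variant slides a 25-frame window across the movie (start
indices 0 … N−26, i.e. N−25 windows; a 180-frame movie yields 155), assigns
each window the elapsed time T of its midpoint frame, extracts τ at the q
bins nearest the requested wavelengths from the first four lags of F, and
block-averages τ over every 16 consecutive windows.  The τ(T) trajectories
at a filament-scale and a swarm-scale wavelength are the dynamic order
parameters of the assembly/disassembly process.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ValidationError
from .stack import CHANNELS, MovieStack

__all__ = [
    "DDMWindow",
    "StructureFunction",
    "ISFEstimate",
    "RelaxationTrace",
    "extract_windows",
    "structure_function",
    "isf",
    "fit_initial_relaxation",
    "relaxation_trace",
    "DEFAULT_WAVELENGTHS_UM",
]

DEFAULT_WINDOW_LEN = 25
DEFAULT_BLOCK = 16
#: Filament-scale and swarm-scale probe wavelengths (μm).
DEFAULT_WAVELENGTHS_UM = (6.1, 46.7)
#: Number of initial ISF points (lag 0 included) entering the τ fit.
N_FIT_POINTS = 4


@dataclass(frozen=True)
class DDMWindow:
    """A block of consecutive frames with its calibration.

    ``T_min`` is the elapsed time of the window's midpoint frame
    (index ``start_frame + (len-1)//2``; the 13th frame of a 25-frame
    window)."""

    frames: np.ndarray  # (window_len, H, W)
    start_frame: int
    frame_interval_s: float
    pixel_size_um: float

    @property
    def window_len(self) -> int:
        return self.frames.shape[0]

    @property
    def T_min(self) -> float:
        mid = self.start_frame + (self.window_len - 1) // 2
        return mid * self.frame_interval_s / 60.0


@dataclass
class StructureFunction:
    """Radially averaged spectral power of frame differences.

    ``D`` has shape (n_lags, n_q); ``lag_s`` excludes lag 0 (D(q,0)=0 by
    construction and is not stored).  ``counts`` gives the number of Fourier
    modes in each radial bin, so the count-weighted mean of D over q equals
    the spatial mean-square frame difference (Parseval).  ``static_power``
    is the radially averaged time-mean single-frame power in the same
    normalization, used for amplitude estimation.
    """

    q_um: np.ndarray        # (n_q,) radial bin centers, μm^-1
    lag_s: np.ndarray       # (n_lags,) in seconds, lags 1..window_len-1
    D: np.ndarray           # (n_lags, n_q)
    counts: np.ndarray      # (n_q,) modes per bin
    static_power: np.ndarray  # (n_q,)


@dataclass
class ISFEstimate:
    """Intermediate scattering function with its amplitude/noise split.

    ``F`` has shape (n_lags+1, n_q); row 0 is anchored at exactly 1.
    ``usable`` marks q bins with positive estimated amplitude.
    """

    q_um: np.ndarray
    lag_s: np.ndarray       # (n_lags+1,) including 0
    F: np.ndarray
    A: np.ndarray
    B: np.ndarray
    usable: np.ndarray


@dataclass
class RelaxationTrace:
    """Per-window and block-averaged τ(T) tables."""

    per_window: pd.DataFrame
    blocked: pd.DataFrame


def extract_windows(
    movie: MovieStack | np.ndarray,
    window_len: int = DEFAULT_WINDOW_LEN,
    channel: str = "green",
    frame_interval_s: float | None = None,
    pixel_size_um: float | None = None,
) -> list[DDMWindow]:
    """Overlapping windows at start indices 0 … n_frames − window_len − 1.

    The convention reserves one trailing frame: a movie of N frames yields
    N − window_len windows (180 frames → 155), each window's elapsed time
    being that of its midpoint frame.
    """
    if isinstance(movie, MovieStack):
        frames = movie.channel(channel)
        frame_interval_s = movie.frame_interval_s
        pixel_size_um = movie.pixel_size_um
    else:
        frames = np.asarray(movie)
        if frame_interval_s is None or pixel_size_um is None:
            raise ValidationError(
                "frame_interval_s and pixel_size_um are required for array input"
            )
    n = frames.shape[0]
    if n < window_len + 1:
        raise ValidationError(
            f"movie has {n} frames; at least {window_len + 1} are required"
        )
    return [
        DDMWindow(frames[s : s + window_len], s, frame_interval_s, pixel_size_um)
        for s in range(n - window_len)
    ]


def _radial_bins(shape: tuple[int, int], pixel_size_um: float):
    """Radial bin index per Fourier mode and the bin-center q grid."""
    H, W = shape
    if H != W:
        raise ValidationError("frames must be square (pad beforehand)")
    qx = 2 * np.pi * np.fft.fftfreq(W, d=pixel_size_um)
    qy = 2 * np.pi * np.fft.fftfreq(H, d=pixel_size_um)
    qmag = np.hypot(qy[:, None], qx[None, :])
    dq = 2 * np.pi / (W * pixel_size_um)
    idx = np.round(qmag / dq).astype(np.int64)
    n_bins = idx.max() + 1
    counts = np.bincount(idx.ravel(), minlength=n_bins)
    q_centers = np.arange(n_bins) * dq
    return idx.ravel(), counts, q_centers


def _radial_mean(power_flat: np.ndarray, idx: np.ndarray, counts: np.ndarray) -> np.ndarray:
    return np.bincount(idx, weights=power_flat, minlength=counts.size) / np.maximum(counts, 1)


def structure_function(window: DDMWindow, pixel_size: float | None = None) -> StructureFunction:
    """Image structure function of one window.

    For each lag Δt ∈ {1 … window_len−1} frames, the squared modulus of the
    2-D spectrum of every valid frame difference within the window is
    averaged over start times and radially averaged into q bins one
    Fourier-grid spacing wide.  The normalization ``|FFT|²/N_pix`` makes the
    count-weighted q-average of D equal the spatial mean-square difference.
    """
    frames = np.asarray(window.frames, dtype=np.float64)
    if not np.all(np.isfinite(frames)):
        raise ValidationError("frames contain non-finite pixels")
    pixel_size = pixel_size if pixel_size is not None else window.pixel_size_um
    L, H, W = frames.shape
    idx, counts, q_centers = _radial_bins((H, W), pixel_size)
    npix = H * W

    fhat = np.fft.fft2(frames)
    static = np.zeros(q_centers.size)
    for t in range(L):
        static += _radial_mean((np.abs(fhat[t]) ** 2).ravel() / npix, idx, counts)
    static /= L

    D = np.zeros((L - 1, q_centers.size))
    for lag in range(1, L):
        acc = np.zeros(q_centers.size)
        n_pairs = L - lag
        for t in range(n_pairs):
            diff = fhat[t + lag] - fhat[t]
            acc += _radial_mean((np.abs(diff) ** 2).ravel() / npix, idx, counts)
        D[lag - 1] = acc / n_pairs

    lag_s = np.arange(1, L) * window.frame_interval_s
    return StructureFunction(q_centers, lag_s, D, counts, static)


def _estimate_amplitude_noise(
    sf: StructureFunction, mode: str = "static"
) -> tuple[np.ndarray, np.ndarray]:
    """Split D into signal amplitude A(q) and noise floor B(q).

    ``B`` is the median of D over the top 10% of q (where camera noise
    dominates the spectrum).  ``A`` comes either from twice the static
    spectral power minus B (``mode="static"``, the default: exact for
    statistically stationary fields and usable even when F has not decayed
    within the window) or from the large-lag plateau of D
    (``mode="plateau"``, valid only when F reaches ~0 inside the window).
    This split is isolated here so alternative schemes can be swapped in.
    """
    n_q = sf.q_um.size
    hi = sf.q_um >= 0.9 * sf.q_um.max()
    B = float(np.median(sf.D[:, hi])) if hi.any() else 0.0
    if mode == "static":
        A = 2.0 * sf.static_power - B
    elif mode == "plateau":
        tail = sf.D[-max(1, sf.D.shape[0] // 3):]
        A = tail.mean(axis=0) - B
        fallback = 2.0 * sf.static_power - B
        A = np.where(A > 0, A, fallback)
    else:
        raise ValidationError(f"unknown amplitude mode {mode!r}")
    return A, np.full(n_q, B)


def isf(sf: StructureFunction, amplitude_mode: str = "static") -> ISFEstimate:
    """Intermediate scattering function ``F = 1 − (D − B)/A``.

    ``F(q, 0)`` is set to exactly 1.  Bins with non-positive estimated
    amplitude are flagged unusable and excluded from fitting.
    """
    if sf.lag_s.size < 3:
        raise ValidationError("at least 3 lags are required to estimate the ISF")
    A, B = _estimate_amplitude_noise(sf, amplitude_mode)
    usable = A > 0
    n_lags, n_q = sf.D.shape
    F = np.ones((n_lags + 1, n_q))
    with np.errstate(divide="ignore", invalid="ignore"):
        F[1:] = 1.0 - (sf.D - B[None, :]) / A[None, :]
    F[:, ~usable] = np.nan
    F[0, :] = 1.0
    lag_s = np.concatenate([[0.0], sf.lag_s])
    return ISFEstimate(sf.q_um, lag_s, F, A, B, usable)


def _fit_anchored_exponential(t: np.ndarray, F: np.ndarray) -> float:
    """Least-squares rate of exp(−rate·t) through the points; 0 if flat."""
    f_pos = np.clip(F, 1e-6, None)
    r0 = max(1e-6, float(-np.log(f_pos[-1]) / t[-1])) if t[-1] > 0 else 1e-6

    def resid(r):
        return np.exp(-r[0] * t) - F

    sol = least_squares(resid, np.array([r0]), bounds=(0.0, np.inf))
    return float(sol.x[0])


def fit_initial_relaxation(isf_est: ISFEstimate, q: float) -> float:
    """Initial relaxation time τ (s) at the q bin nearest ``q`` (μm⁻¹).

    The first four ISF points (lag 0, F = 1, included) are fitted with an
    anchored exponential.  τ is the time at which the ISF decays to 1/e:
    log-linear interpolation between the bracketing measured lags when the
    data cross 1/e within the fitted range, extrapolation with the fitted
    exponential otherwise.  Non-decaying data give ``inf``; an unusable q
    bin gives NaN.
    """
    qi = _nearest_bin(isf_est.q_um, q)
    if not isf_est.usable[qi]:
        return float("nan")
    t = isf_est.lag_s[:N_FIT_POINTS]
    F = isf_est.F[:N_FIT_POINTS, qi]
    if t.size < N_FIT_POINTS or not np.all(np.isfinite(F)):
        return float("nan")

    target = np.exp(-1.0)
    below = np.flatnonzero(F <= target)
    if below.size and below[0] > 0:
        k = below[0]
        f0, f1 = F[k - 1], F[k]
        if f0 > 0 and f1 > 0:
            frac = (np.log(f0) + 1.0) / (np.log(f0) - np.log(f1))
        else:  # non-positive ISF value: fall back to linear interpolation
            frac = (f0 - target) / (f0 - f1)
        return float(t[k - 1] + frac * (t[k] - t[k - 1]))

    rate = _fit_anchored_exponential(t, F)
    if rate * t[-1] < 1e-4:  # no measurable decay within the fitted range
        return float("inf")
    return 1.0 / rate


def _nearest_bin(q_grid: np.ndarray, q: float) -> int:
    """Bin with minimal |q_bin − q|; ties resolve toward lower q."""
    d = np.abs(q_grid - q)
    return int(np.argmin(d))  # argmin takes the first (lower-q) minimum on ties


def _pair_profiles(frames: np.ndarray, pixel_size_um: float, max_lag: int):
    """Radial power profiles of every frame pair up to ``max_lag`` plus the
    per-frame static profiles — the shared fast path for windowed analysis."""
    n = frames.shape[0]
    idx, counts, q_centers = _radial_bins(frames.shape[1:], pixel_size_um)
    npix = frames.shape[1] * frames.shape[2]
    fhat = np.fft.fft2(frames.astype(np.float64))
    static = np.empty((n, q_centers.size))
    for t in range(n):
        static[t] = _radial_mean((np.abs(fhat[t]) ** 2).ravel() / npix, idx, counts)
    pair = {}
    for lag in range(1, max_lag + 1):
        prof = np.empty((n - lag, q_centers.size))
        for t in range(n - lag):
            diff = fhat[t + lag] - fhat[t]
            prof[t] = _radial_mean((np.abs(diff) ** 2).ravel() / npix, idx, counts)
        pair[lag] = prof
    return q_centers, counts, static, pair


def relaxation_trace(
    movie: MovieStack,
    wavelengths_um: Sequence[float] = DEFAULT_WAVELENGTHS_UM,
    window_len: int = DEFAULT_WINDOW_LEN,
    block: int = DEFAULT_BLOCK,
    amplitude_mode: str = "static",
) -> RelaxationTrace:
    """τ(T) at the q bins nearest each requested wavelength, per channel.

    Per window, τ is extracted from the first four ISF lags; the per-window
    values are then block-averaged over every ``block`` consecutive windows
    (a trailing partial block is kept), with non-finite τ values excluded
    from the block means.
    """
    fov = movie.data.shape[-1] * movie.pixel_size_um
    for wl in wavelengths_um:
        if wl > fov:
            raise ValidationError(
                f"wavelength {wl} μm exceeds the field of view ({fov:.3g} μm)"
            )
        if wl < 2 * movie.pixel_size_um:
            raise ValidationError(
                f"wavelength {wl} μm is below the Nyquist limit "
                f"({2 * movie.pixel_size_um:.3g} μm)"
            )

    rows = []
    for channel in CHANNELS:
        frames = movie.channel(channel)
        n = frames.shape[0]
        if n < window_len + 1:
            raise ValidationError(
                f"movie has {n} frames; at least {window_len + 1} are required"
            )
        max_lag = window_len - 1
        q_centers, counts, static, pair = _pair_profiles(
            frames, movie.pixel_size_um, max_lag
        )
        n_windows = n - window_len
        for s in range(n_windows):
            D = np.empty((max_lag, q_centers.size))
            for lag in range(1, max_lag + 1):
                D[lag - 1] = pair[lag][s : s + window_len - lag].mean(axis=0)
            sf = StructureFunction(
                q_centers,
                np.arange(1, window_len) * movie.frame_interval_s,
                D,
                counts,
                static[s : s + window_len].mean(axis=0),
            )
            est = isf(sf, amplitude_mode)
            T = (s + (window_len - 1) // 2) * movie.frame_interval_s / 60.0
            for wl in wavelengths_um:
                q_req = 2 * np.pi / wl
                tau = fit_initial_relaxation(est, q_req)
                qi = _nearest_bin(q_centers, q_req)
                rows.append(
                    {
                        "channel": channel,
                        "wavelength_um": wl,
                        "q_um_inv": q_centers[qi],
                        "window": s,
                        "T_min": T,
                        "tau_s": tau,
                        "usable": bool(np.isfinite(tau)),
                    }
                )
    per_window = pd.DataFrame(rows)

    blocked_rows = []
    for (channel, wl), grp in per_window.groupby(["channel", "wavelength_um"], sort=False):
        grp = grp.sort_values("window")
        for b0 in range(0, len(grp), block):
            chunk = grp.iloc[b0 : b0 + block]
            tau = chunk["tau_s"].to_numpy()
            finite = np.isfinite(tau)
            blocked_rows.append(
                {
                    "channel": channel,
                    "wavelength_um": wl,
                    "block": b0 // block,
                    "T_min": chunk["T_min"].mean(),
                    "tau_s": float(tau[finite].mean()) if finite.any() else float("nan"),
                    "n_windows": len(chunk),
                    "n_usable": int(finite.sum()),
                }
            )
    return RelaxationTrace(per_window, pd.DataFrame(blocked_rows))
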