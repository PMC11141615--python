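"""Two-channel pixel colocalization: threshold, classify, ratio, trace.

The statistic is deliberately simple and implemented exactly as defined:
each channel of a frame is thresholded at the mean plus the (population)
standard deviation of its own brightness distribution; a pixel strictly
above both thresholds is *white* (W), above only one is *green* (G) or
*magenta* (M), otherwise background.  The colocalization ratio
``W / (M + G + W)`` is the order parameter for cross-population bundling:
it rises as the two filament populations co-localize and falls when they
separate.  Pixels exactly at a threshold count as background (strict
inequality); an all-background frame has an undefined ratio, reported as
NaN, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .stack import MovieStack

__all__ = [
    "Thresholds",
    "PixelClassCounts",
    "compute_threshold",
    "classify_pixels",
    "colocalization_ratio",
    "trace",
]


@dataclass(frozen=True)
class Thresholds:
    """Per-channel intensity thresholds; ``degenerate`` flags a constant
    channel whose SD was zero."""

    green: float
    magenta: float
    degenerate: bool = False


@dataclass(frozen=True)
class PixelClassCounts:
    """Four-way pixel classification counts of one frame."""

    M: int
    G: int
    W: int
    background: int

    @property
    def total(self) -> int:
        return self.M + self.G + self.W + self.background


def compute_threshold(image: np.ndarray) -> tuple[float, bool]:
    """Mean + population SD of all pixel intensities in one channel.

    Returns ``(threshold, degenerate)``; ``degenerate`` is set for a
    constant image, whose threshold equals the constant itself.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValidationError("cannot threshold an empty image")
    sd = float(image.std())  # population (divide-by-N) SD
    return float(image.mean()) + sd, sd == 0.0


def classify_pixels(
    green: np.ndarray, magenta: np.ndarray, thr: Thresholds
) -> PixelClassCounts:
    """Classify every pixel of a frame pair as W, G, M, or background.

    "Exceeds" is strict: a pixel exactly at a threshold does not count as
    signal in that channel.
    """
    green = np.asarray(green)
    magenta = np.asarray(magenta)
    if green.shape != magenta.shape:
        raise ValidationError(
            f"channel shapes differ: {green.shape} vs {magenta.shape}"
        )
    g_hot = green > thr.green
    m_hot = magenta > thr.magenta
    w = int(np.count_nonzero(g_hot & m_hot))
    g = int(np.count_nonzero(g_hot & ~m_hot))
    m = int(np.count_nonzero(m_hot & ~g_hot))
    return PixelClassCounts(M=m, G=g, W=w, background=green.size - w - g - m)


def colocalization_ratio(counts: PixelClassCounts) -> float:
    """``W / (M + G + W)``; NaN when no pixel is above threshold in either
    channel (the ratio is undefined for an all-background frame)."""
    denom = counts.M + counts.G + counts.W
    if denom == 0:
        return float("nan")
    return counts.W / denom


def trace(
    movie: MovieStack,
    fixed_thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Per-frame colocalization trace of a two-channel movie.

    Thresholds are recomputed per channel per frame (the snapshot rule);
    passing ``fixed_thresholds`` instead applies one threshold pair to every
    frame, the mode used for linker-titration comparisons where a common
    intensity scale across images is wanted.

    Returns a DataFrame with columns frame, time_min, M, G, W, background,
    ratio.
    """
    rows = []
    times = movie.frame_times_min
    green_stack = movie.channel("green")
    magenta_stack = movie.channel("magenta")
    for k in range(movie.n_frames):
        if fixed_thresholds is None:
            tg, dg = compute_threshold(green_stack[k])
            tm, dm = compute_threshold(magenta_stack[k])
            thr = Thresholds(tg, tm, dg or dm)
        else:
            thr = fixed_thresholds
        counts = classify_pixels(green_stack[k], magenta_stack[k], thr)
        rows.append(
            {
                "frame": k,
                "time_min": times[k],
                "M": counts.M,
                "G": counts.G,
                "W": counts.W,
                "background": counts.background,
                "ratio": colocalization_ratio(counts),
            }
        )
    return pd.DataFrame(rows)
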