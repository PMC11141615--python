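"""Two-channel calibrated movie container with TIFF round-tripping."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import ValidationError

__all__ = ["MovieStack", "CHANNELS"]

#: Fixed channel order of every stack.
CHANNELS = ("green", "magenta")


@dataclass
class MovieStack:
    """A T x C x H x W intensity stack with physical calibration.

    ``data`` holds non-negative intensities (photon-count scale); channel 0
    is green, channel 1 magenta.  ``pixel_size_um`` is the pixel pitch in
    micrometres and ``frame_interval_s`` the time between frames in seconds.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 or self.data.shape[1] != len(CHANNELS):
            raise ValidationError(
                f"stack must have shape (T, {len(CHANNELS)}, H, W), got {self.data.shape}"
            )
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValidationError("pixel size and frame interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s / 60.0

    def channel(self, name: str) -> np.ndarray:
        """The (T, H, W) sub-stack of one channel, by name or index."""
        if isinstance(name, str):
            if name not in CHANNELS:
                raise ValidationError(f"unknown channel {name!r}; expected one of {CHANNELS}")
            idx = CHANNELS.index(name)
        else:
            idx = int(name)
        return self.data[:, idx]

    def to_tiff(self, path: str | Path, extra_metadata: dict | None = None) -> None:
        """Write a 16-bit TCYX TIFF plus a JSON calibration sidecar.

        ``extra_metadata`` (e.g. the generator's seed and parameters) is
        merged into both the embedded description and the sidecar.
        """
        path = Path(path)
        arr = np.clip(np.round(self.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
        meta = {
            "axes": "TCYX",
            "pixel_size_um": self.pixel_size_um,
            "frame_interval_s": self.frame_interval_s,
            "channels": list(CHANNELS),
            **(extra_metadata or {}),
        }
        tifffile.imwrite(path, arr, metadata=meta, description=json.dumps(meta))
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_tiff(
        cls,
        path: str | Path,
        pixel_size_um: float | None = None,
        frame_interval_s: float | None = None,
    ) -> "MovieStack":
        """Load a stack written by :meth:`to_tiff` (or any TCYX/ TYX TIFF).

        Calibration is taken from the JSON sidecar or embedded description;
        explicit arguments override.  A missing calibration with no override
        raises a :class:`ValidationError` naming the flags to pass.
        """
        path = Path(path)
        try:
            arr = tifffile.imread(path)
        except Exception as exc:
            raise ValidationError(f"cannot read TIFF {path}: {exc}") from exc

        meta: dict = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        else:
            try:
                with tifffile.TiffFile(path) as tf:
                    desc = tf.pages[0].description
                if desc:
                    meta = json.loads(desc)
            except Exception:
                meta = {}

        pixel = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
        interval = (
            frame_interval_s if frame_interval_s is not None else meta.get("frame_interval_s")
        )
        if pixel is None or interval is None:
            raise ValidationError(
                f"{path} carries no calibration; pass pixel_size_um / frame_interval_s "
                "(CLI: --pixel-size and --frame-interval)"
            )

        arr = np.asarray(arr)
        if arr.ndim == 3:  # single channel: not a valid two-channel movie
            raise ValidationError(
                f"{path} is single-channel; two-channel (TCYX) input is required"
            )
        if arr.ndim != 4:
            raise ValidationError(f"{path}: expected 4-D TCYX data, got shape {arr.shape}")
        return cls(arr.astype(np.float64), float(pixel), float(interval))
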