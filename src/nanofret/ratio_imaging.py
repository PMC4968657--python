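"""Pixel-wise acceptor/donor ratio images and intensity-modulated pseudocolor.

The ratio image divides the acceptor channel by the donor channel pixel by
pixel, keeping only pixels where both channels clear an intensity floor (by
default the pre-injection background mean plus two standard deviations). The
pseudocolor rendering encodes the ratio as hue on a blue (low FRET, carriers
disintegrated) to red (high FRET, carriers intact) scale, and the summed
two-channel intensity as brightness, so that dark regions carry no spurious
color. With the default display range taken from the calibration endpoints,
hue maps directly onto integrity extremes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
from matplotlib.colors import hsv_to_rgb
from scipy.ndimage import median_filter

from .calibration import CalibrationParams, DEFAULT_CALIBRATION, ratio_from_integrity
from .image_io import ACCEPTOR, DONOR, ChannelFrame

__all__ = [
    "RatioImage",
    "RatioImagingError",
    "compute_ratio_image",
    "default_intensity_floor",
    "default_display_range",
    "render_pseudocolor",
    "save_png",
]


class RatioImagingError(ValueError):
    """Invalid ratio-imaging input."""


@dataclass
class RatioImage:
    """Pixel-wise A/D values with a validity mask.

    Ratios are defined (and > 0) only where ``valid`` is True; invalid pixels
    hold NaN. ``display_range`` is the (min, max) ratio window used for
    pseudocolor hue mapping.
    """

    ratio: np.ndarray
    valid: np.ndarray
    display_range: Tuple[float, float]
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ratio.shape != self.valid.shape:
            raise RatioImagingError("ratio and validity mask must share a shape")
        lo, hi = self.display_range
        if not (hi > lo):
            raise RatioImagingError(f"degenerate display range {self.display_range}")
        if np.any(self.ratio[self.valid] <= 0):
            raise RatioImagingError("valid pixels must have ratio > 0")


def default_intensity_floor(pre_injection: ChannelFrame, n_sigma: float = 2.0) -> float:
    """Background mean + n_sigma * SD estimated from a pre-injection frame."""
    data = pre_injection.data.astype(float)
    return float(data.mean() + n_sigma * data.std())


def default_display_range(params: CalibrationParams = DEFAULT_CALIBRATION) -> Tuple[float, float]:
    """A/D ratios at the calibration extremes: E/(1-E) at 0% and 100% integrity."""
    e0 = ratio_from_integrity(params, 0.0)
    e100 = ratio_from_integrity(params, 100.0)
    return e0 / (1.0 - e0), e100 / (1.0 - e100)


def compute_ratio_image(
    acceptor: ChannelFrame,
    donor: ChannelFrame,
    intensity_floor: float,
    display_range: Optional[Tuple[float, float]] = None,
    median3: bool = False,
) -> RatioImage:
    """Pixel-wise acceptor/donor division above an intensity floor.

    Pixels where either channel falls below ``intensity_floor`` (or the donor is
    zero) are marked invalid. ``median3`` applies a 3x3 median filter to both
    channels before division (off by default; the raw channels are divided
    as acquired).
    """
    if acceptor.channel != ACCEPTOR or donor.channel != DONOR:
        raise RatioImagingError(
            f"channel tags must be ({ACCEPTOR}, {DONOR}), got "
            f"({acceptor.channel}, {donor.channel})"
        )
    if acceptor.shape != donor.shape:
        raise RatioImagingError(
            f"frame shapes differ: {acceptor.shape} vs {donor.shape}"
        )
    if not np.isclose(acceptor.time_h, donor.time_h):
        raise RatioImagingError(
            f"frames are from different timepoints: {acceptor.time_h} vs {donor.time_h} h"
        )
    a = acceptor.data.astype(float)
    d = donor.data.astype(float)
    if median3:
        a = median_filter(a, size=3)
        d = median_filter(d, size=3)
    floor = max(float(intensity_floor), 0.0)
    valid = (a >= floor) & (d >= floor) & (a > 0) & (d > 0)
    ratio = np.full(a.shape, np.nan, dtype=float)
    np.divide(a, d, out=ratio, where=valid)
    if display_range is None:
        display_range = default_display_range()
    return RatioImage(
        ratio=ratio,
        valid=valid,
        display_range=display_range,
        source={
            "time_h": acceptor.time_h,
            "subject": acceptor.subject,
            "intensity_floor": floor,
            "median3": median3,
        },
    )


def render_pseudocolor(
    ratio_image: RatioImage,
    donor: ChannelFrame,
    acceptor: ChannelFrame,
    brightness_norm: Optional[float] = None,
) -> np.ndarray:
    """Intensity-modulated pseudocolor RGB (float in [0, 1]).

    Hue encodes the ratio linearly over the display range, blue (low) to red
    (high); brightness is the summed two-channel intensity normalized by its
    99th percentile (or an explicit ``brightness_norm``) and clipped to [0, 1].
    Invalid pixels are black.
    """
    if donor.shape != ratio_image.ratio.shape or acceptor.shape != ratio_image.ratio.shape:
        raise RatioImagingError("frames and ratio image must share a shape")
    lo, hi = ratio_image.display_range
    frac = np.clip((ratio_image.ratio - lo) / (hi - lo), 0.0, 1.0)
    frac = np.where(ratio_image.valid, frac, 0.0)
    hue = (1.0 - frac) * (240.0 / 360.0)  # 240 deg = blue, 0 deg = red

    total = donor.data.astype(float) + acceptor.data.astype(float)
    if brightness_norm is None:
        visible = total[ratio_image.valid]
        if visible.size == 0:
            brightness_norm = np.inf  # all-invalid image renders black
        else:
            brightness_norm = float(np.percentile(visible, 99))
    value = np.clip(total / brightness_norm, 0.0, 1.0) if brightness_norm > 0 else np.zeros_like(total)
    value = np.where(ratio_image.valid, value, 0.0)

    hsv = np.stack([hue, np.ones_like(hue), value], axis=-1)
    return hsv_to_rgb(hsv)


def save_png(rgb: np.ndarray, path: Union[str, Path]) -> Path:
    """Write an RGB float image in [0, 1] as 8-bit PNG."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, (np.clip(rgb, 0, 1) * 255).astype(np.uint8))
    return path
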