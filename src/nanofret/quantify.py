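"""ROI quantification: background correction, proximity ratio, integrity time courses.

The in vivo readout chain per region and timepoint is

    ROI mean per channel -> subtract the matched pre-injection ROI mean
    -> E = A/(A + D) -> invert the calibration law -> integrity %.

Background correction uses the pre-injection frame of the *same* region, never a
global background; corrections that come out non-positive are flagged as
insufficient signal and the affected record is dropped rather than allowed to
produce a negative ratio. With replicate subjects, the subject-level means are
the unit of analysis and dispersion is the standard error of the mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CalibrationParams, IN_RANGE, integrity_from_ratio
from .image_io import ACCEPTOR, DONOR, ChannelFrame, ImageIOError, Manifest, RoiSet

__all__ = [
    "RoiMeasurement",
    "TimeCourse",
    "QuantifyError",
    "UndefinedRatioError",
    "roi_mean",
    "background_correct",
    "proximity_ratio",
    "integrity_timecourse",
    "intensity_timecourse",
    "compare_groups",
    "INSUFFICIENT_SIGNAL",
]

INSUFFICIENT_SIGNAL = "insufficient_signal"


class QuantifyError(ValueError):
    """Invalid quantification input."""


class UndefinedRatioError(QuantifyError):
    """A + D = 0: the proximity ratio is undefined."""


def roi_mean(frame: ChannelFrame, rois: RoiSet, region: str) -> Tuple[float, int]:
    """Mean intensity of a delimited region and its pixel count."""
    if tuple(rois.mask.shape) != tuple(frame.shape):
        raise QuantifyError(
            f"ROI mask shape {rois.mask.shape} does not match frame shape {frame.shape}"
        )
    mask = rois.region_mask(region)
    n = int(mask.sum())
    if n == 0:
        raise QuantifyError(f"region {region!r} contains no pixels")
    return float(frame.data[mask].mean()), n


def background_correct(raw: float, pre_injection: float) -> Tuple[float, bool]:
    """Subtract the matched pre-injection ROI mean.

    Returns ``(corrected, flagged)``; non-positive corrections clamp to 0 and are
    flagged as insufficient signal.
    """
    if raw < 0 or pre_injection < 0:
        raise QuantifyError("intensities must be >= 0")
    corrected = raw - pre_injection
    if corrected <= 0:
        return 0.0, True
    return corrected, False


def proximity_ratio(acceptor_corrected: float, donor_corrected: float) -> float:
    """E = A / (A + D) from background-corrected channel means."""
    if acceptor_corrected < 0 or donor_corrected < 0:
        raise QuantifyError("corrected intensities must be >= 0")
    total = acceptor_corrected + donor_corrected
    if total <= 0:
        raise UndefinedRatioError("A + D = 0: proximity ratio undefined")
    return acceptor_corrected / total


@dataclass
class RoiMeasurement:
    """One (region, time, channel) ROI record through background correction."""

    region: str
    time_h: float
    channel: str
    raw_mean: float
    background_mean: float
    corrected_mean: float
    n_pixels: int
    flagged: bool = False


@dataclass
class TimeCourse:
    """Ordered (time, value, sem, n) records of one quantity in one region."""

    region: str
    quantity: str  # "ratio" | "integrity" | "intensity"
    data: pd.DataFrame  # columns: time_h, value, sem, n, flags

    def __post_init__(self) -> None:
        t = self.data["time_h"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise QuantifyError("time course times must be strictly increasing")
        v = self.data["value"].to_numpy(dtype=float)
        if self.quantity == "integrity" and (np.any(v < 0) or np.any(v > 100)):
            raise QuantifyError("integrity values must lie in [0, 100]")
        if self.quantity == "ratio" and (np.any(v <= 0) or np.any(v >= 1)):
            raise QuantifyError("ratio values must lie in (0, 1)")

    @property
    def times(self) -> np.ndarray:
        return self.data["time_h"].to_numpy(dtype=float)

    @property
    def values(self) -> np.ndarray:
        return self.data["value"].to_numpy(dtype=float)

    def value_at(self, time_h: float) -> float:
        match = self.data[np.isclose(self.data["time_h"], time_h)]
        if match.empty:
            raise QuantifyError(f"no record at t = {time_h} h for region {self.region!r}")
        return float(match["value"].iloc[0])

    def to_frame(self) -> pd.DataFrame:
        out = self.data.copy()
        out.insert(0, "quantity", self.quantity)
        out.insert(0, "region", self.region)
        return out


def _roi_measurement(
    manifest: Manifest, rois: RoiSet, region: str, t: float, channel: str, pre_mean: float
) -> RoiMeasurement:
    frame = manifest.load_frame(t, channel)
    raw, n = roi_mean(frame, rois, region)
    corrected, flagged = background_correct(raw, pre_mean)
    return RoiMeasurement(
        region=region,
        time_h=t,
        channel=channel,
        raw_mean=raw,
        background_mean=pre_mean,
        corrected_mean=corrected,
        n_pixels=n,
        flagged=flagged,
    )


def _subject_integrity(
    manifest: Manifest, rois: RoiSet, region: str, calibration: CalibrationParams
) -> Dict[float, Tuple[float, str]]:
    """Per-timepoint (integrity, flag) for one subject, skipping dead records."""
    t0 = manifest.times[0]
    pre = {
        ch: roi_mean(manifest.load_frame(t0, ch), rois, region)[0] for ch in (DONOR, ACCEPTOR)
    }
    out: Dict[float, Tuple[float, str]] = {}
    for t in manifest.times[1:]:
        meas = {
            ch: _roi_measurement(manifest, rois, region, t, ch, pre[ch])
            for ch in (DONOR, ACCEPTOR)
        }
        a = meas[ACCEPTOR].corrected_mean
        d = meas[DONOR].corrected_mean
        if a + d <= 0:  # both channels flagged: no carrier signal at all
            continue
        ratio = proximity_ratio(a, d)
        integrity, range_flag = integrity_from_ratio(calibration, ratio)
        flags = [] if range_flag == IN_RANGE else [range_flag]
        if meas[ACCEPTOR].flagged or meas[DONOR].flagged:
            flags.append(INSUFFICIENT_SIGNAL)
        out[t] = (integrity, "|".join(flags))
    return out


def _aggregate(
    per_subject: List[Dict[float, Tuple[float, str]]], region: str, quantity: str
) -> TimeCourse:
    times = sorted({t for subj in per_subject for t in subj})
    rows = []
    for t in times:
        vals = [subj[t][0] for subj in per_subject if t in subj]
        flags = sorted({f for subj in per_subject if t in subj for f in subj[t][1].split("|") if f})
        n = len(vals)
        if n == 0:
            continue
        sem = float(stats.sem(vals)) if n > 1 else float("nan")
        rows.append(
            {"time_h": t, "value": float(np.mean(vals)), "sem": sem, "n": n, "flags": "|".join(flags)}
        )
    if not rows:
        raise QuantifyError(f"no usable records for region {region!r}")
    return TimeCourse(region=region, quantity=quantity, data=pd.DataFrame(rows))


def integrity_timecourse(
    manifests: Union[Manifest, Sequence[Manifest]],
    calibration: CalibrationParams,
    rois: Optional[RoiSet] = None,
    regions: Optional[Sequence[str]] = None,
) -> Dict[str, TimeCourse]:
    """Full pipeline per region: ROI means -> background correction -> E -> integrity.

    ``manifests`` may be a single subject or a list of replicate subjects; with
    replicates the reported value is the subject mean and ``sem`` the standard
    error over subjects. Requires a pre-injection timepoint (t = 0) per manifest.
    """
    if isinstance(manifests, Manifest):
        manifests = [manifests]
    if not manifests:
        raise QuantifyError("at least one manifest is required")
    for m in manifests:
        if m.times[0] != 0:
            raise ImageIOError("manifest lacks the pre-injection timepoint 0")
    if rois is None:
        roisets = [m.load_rois() for m in manifests]
    else:
        roisets = [rois] * len(manifests)
    if regions is None:
        regions = roisets[0].regions
    out: Dict[str, TimeCourse] = {}
    for region in regions:
        per_subject = [
            _subject_integrity(m, rs, region, calibration)
            for m, rs in zip(manifests, roisets)
        ]
        if not any(per_subject):
            continue  # e.g. donor-only acceptor never rises above background
        out[region] = _aggregate(per_subject, region, "integrity")
    if not out:
        raise QuantifyError("no region produced a usable integrity time course")
    return out


def intensity_timecourse(
    manifests: Union[Manifest, Sequence[Manifest]],
    region: str,
    channel: str = DONOR,
    rois: Optional[RoiSet] = None,
) -> TimeCourse:
    """Background-corrected ROI intensity over time (e.g. for clearance fits)."""
    if isinstance(manifests, Manifest):
        manifests = [manifests]
    per_subject: List[Dict[float, Tuple[float, str]]] = []
    for m in manifests:
        rs = rois if rois is not None else m.load_rois()
        t0 = m.times[0]
        pre = roi_mean(m.load_frame(t0, channel), rs, region)[0]
        series: Dict[float, Tuple[float, str]] = {}
        for t in m.times[1:]:
            meas = _roi_measurement(m, rs, region, t, channel, pre)
            series[t] = (meas.corrected_mean, INSUFFICIENT_SIGNAL if meas.flagged else "")
        per_subject.append(series)
    return _aggregate(per_subject, region, "intensity")


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float], equal_var: bool = True
) -> Tuple[float, float]:
    """Two-sample two-sided t-test (Student by default, Welch via equal_var=False)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise QuantifyError("each group needs n >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)
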