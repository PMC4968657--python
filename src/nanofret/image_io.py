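"""Readers and writers for frames, ROI masks, manifests and time-course tables.

Conventions owned here: pixel coordinates are 0-based, row-major, origin at the
top-left; ROI masks share the frame grid exactly (no resampling); time is in
hours everywhere; wavelength is advisory metadata. Each TIFF travels with a JSON
sidecar (``<name>.json``) carrying channel/time/subject tags, which keeps the
metadata independent of TIFF tag dialects. All writers are atomic
(write-to-temp, then rename).
"""

from __future__ import annotations

import json
import os
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ChannelFrame",
    "RoiSet",
    "Manifest",
    "FrameRecord",
    "ImageIOError",
    "DONOR",
    "ACCEPTOR",
    "CHANNEL_WAVELENGTH_NM",
    "read_frame",
    "write_frame",
    "read_roiset",
    "write_roiset",
    "read_manifest",
    "write_manifest",
    "read_timecourse_csv",
    "write_timecourse_csv",
]

DONOR = "donor"
ACCEPTOR = "acceptor"
#: Nominal emission-filter wavelengths of the two NIR channels.
CHANNEL_WAVELENGTH_NM = {DONOR: 700, ACCEPTOR: 820}


class ImageIOError(IOError):
    """Malformed or missing image/mask/manifest data."""


@dataclass
class ChannelFrame:
    """One background-inclusive 2-D intensity grid for a single channel.

    ``data`` holds counts (non-negative), uint16 for quantized acquisitions or
    float32 for noiseless synthetic frames.
    """

    data: np.ndarray
    channel: str
    time_h: float
    subject: str = ""
    wavelength_nm: Optional[int] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ImageIOError(
                f"frame must be a non-empty 2-D grid, got shape {self.data.shape}"
            )
        if self.channel not in (DONOR, ACCEPTOR):
            raise ImageIOError(
                f"channel must be '{DONOR}' or '{ACCEPTOR}', got {self.channel!r}"
            )
        if np.any(self.data < 0):
            raise ImageIOError("frame intensities must be non-negative")
        if self.wavelength_nm is None:
            self.wavelength_nm = CHANNEL_WAVELENGTH_NM[self.channel]

    @property
    def shape(self):
        return self.data.shape


@dataclass
class RoiSet:
    """Label mask plus label-to-region-name mapping.

    ``provenance`` records whether the delimitation was manual or synthetic.
    Label 0 is reserved for unassigned pixels.
    """

    mask: np.ndarray
    names: Dict[int, str]
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 2:
            raise ImageIOError("ROI mask must be 2-D")
        present = set(np.unique(self.mask).tolist()) - {0}
        unknown = {int(k) for k in self.names} - present
        if unknown:
            raise ImageIOError(f"names table labels absent from mask: {sorted(unknown)}")

    def region_mask(self, region: str) -> np.ndarray:
        for label, name in self.names.items():
            if name == region:
                return self.mask == int(label)
        raise ImageIOError(f"unknown region {region!r}; have {sorted(self.names.values())}")

    @property
    def regions(self) -> List[str]:
        return sorted(self.names.values())


def _atomic_write_bytes(path: Path, payload: bytes) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(payload)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_write_text(path: Path, text: str) -> None:
    _atomic_write_bytes(path, text.encode("utf-8"))


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(tiff_path.suffix + ".json")


def write_frame(frame: ChannelFrame, path: Union[str, Path]) -> Path:
    """Write a frame as grayscale TIFF plus JSON metadata sidecar (atomically)."""
    path = Path(path)
    data = frame.data
    if data.dtype not in (np.uint16, np.float32):
        if np.issubdtype(data.dtype, np.integer):
            if data.max(initial=0) > np.iinfo(np.uint16).max:
                raise ImageIOError("integer frame exceeds 16-bit range")
            data = data.astype(np.uint16)
        else:
            data = data.astype(np.float32)
    import io as _io

    buf = _io.BytesIO()
    tifffile.imwrite(buf, data, photometric="minisblack")
    _atomic_write_bytes(path, buf.getvalue())
    meta = {
        "channel": frame.channel,
        "time_h": frame.time_h,
        "subject": frame.subject,
        "wavelength_nm": frame.wavelength_nm,
    }
    _atomic_write_text(_sidecar_path(path), json.dumps(meta, indent=2))
    return path


def read_frame(path: Union[str, Path]) -> ChannelFrame:
    """Read a TIFF frame and its JSON sidecar back into a :class:`ChannelFrame`."""
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"frame file not found: {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ImageIOError(f"missing metadata sidecar for frame: {sidecar}")
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # tifffile raises assorted types on truncation
        raise ImageIOError(f"malformed TIFF {path}: {exc}") from exc
    if data.ndim == 3:
        raise ImageIOError(
            f"{path} is multi-channel (shape {data.shape}); channels must be separate files"
        )
    if data.dtype == np.uint8:
        warnings.warn(f"{path}: 8-bit frame promoted to 16-bit", stacklevel=2)
        data = data.astype(np.uint16)
    meta = json.loads(sidecar.read_text())
    return ChannelFrame(
        data=data,
        channel=meta["channel"],
        time_h=float(meta["time_h"]),
        subject=meta.get("subject", ""),
        wavelength_nm=meta.get("wavelength_nm"),
    )


def write_roiset(rois: RoiSet, mask_path: Union[str, Path], names_path: Union[str, Path]) -> None:
    """Write the label mask as 8-bit TIFF and the names table as JSON."""
    mask_path, names_path = Path(mask_path), Path(names_path)
    if rois.mask.max(initial=0) > 255:
        raise ImageIOError("label mask exceeds 8-bit label range")
    import io as _io

    buf = _io.BytesIO()
    tifffile.imwrite(buf, rois.mask.astype(np.uint8), photometric="minisblack")
    _atomic_write_bytes(mask_path, buf.getvalue())
    record = {
        "provenance": rois.provenance,
        "names": {str(k): v for k, v in rois.names.items()},
    }
    _atomic_write_text(names_path, json.dumps(record, indent=2))


def read_roiset(
    mask_path: Union[str, Path],
    names_path: Union[str, Path],
    expect_shape=None,
) -> RoiSet:
    mask_path, names_path = Path(mask_path), Path(names_path)
    if not mask_path.exists():
        raise ImageIOError(f"ROI mask not found: {mask_path}")
    if not names_path.exists():
        raise ImageIOError(f"ROI names table not found: {names_path}")
    try:
        mask = tifffile.imread(mask_path)
    except Exception as exc:
        raise ImageIOError(f"malformed ROI mask {mask_path}: {exc}") from exc
    record = json.loads(names_path.read_text())
    names = {int(k): str(v) for k, v in record["names"].items()}
    if expect_shape is not None and tuple(mask.shape) != tuple(expect_shape):
        raise ImageIOError(
            f"ROI mask shape {mask.shape} does not match frame shape {tuple(expect_shape)}"
        )
    return RoiSet(mask=mask, names=names, provenance=record.get("provenance", "unknown"))


@dataclass
class FrameRecord:
    """One manifest entry: where a frame lives and what it is."""

    path: str
    time_h: float
    channel: str
    subject: str = ""


@dataclass
class Manifest:
    """Index of a generated or acquired time series on disk.

    Paths are stored relative to the manifest file's directory. Times must be
    strictly increasing and include the pre-injection time 0.
    """

    scenario: str
    times: List[float]
    frames: List[FrameRecord]
    roi_mask: str
    roi_names: str
    seed: Optional[int] = None
    root: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        times = list(self.times)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ImageIOError("manifest times must be strictly increasing")
        if not times or times[0] != 0:
            raise ImageIOError("manifest must include the pre-injection time 0")

    def frame_path(self, record: FrameRecord) -> Path:
        return self.root / record.path

    def find(self, time_h: float, channel: str) -> FrameRecord:
        for rec in self.frames:
            if rec.channel == channel and np.isclose(rec.time_h, time_h):
                return rec
        raise ImageIOError(f"no frame for t={time_h} h, channel={channel}")

    def load_frame(self, time_h: float, channel: str) -> ChannelFrame:
        rec = self.find(time_h, channel)
        path = self.frame_path(rec)
        if not path.exists():
            raise ImageIOError(f"manifest names missing frame file: {path} (t={rec.time_h}, {rec.channel})")
        return read_frame(path)

    def load_rois(self) -> RoiSet:
        shape = self.load_frame(self.times[0], DONOR).shape
        return read_roiset(self.root / self.roi_mask, self.root / self.roi_names, expect_shape=shape)


def write_manifest(manifest: Manifest, path: Union[str, Path]) -> Path:
    path = Path(path)
    record = {
        "scenario": manifest.scenario,
        "times": list(manifest.times),
        "seed": manifest.seed,
        "roi_mask": manifest.roi_mask,
        "roi_names": manifest.roi_names,
        "frames": [
            {"path": f.path, "time_h": f.time_h, "channel": f.channel, "subject": f.subject}
            for f in manifest.frames
        ],
    }
    _atomic_write_text(path, json.dumps(record, indent=2))
    return path


def read_manifest(path: Union[str, Path]) -> Manifest:
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"manifest not found: {path}")
    record = json.loads(path.read_text())
    return Manifest(
        scenario=record["scenario"],
        times=[float(t) for t in record["times"]],
        frames=[FrameRecord(**f) for f in record["frames"]],
        roi_mask=record["roi_mask"],
        roi_names=record["roi_names"],
        seed=record.get("seed"),
        root=path.parent,
    )


TIMECOURSE_COLUMNS = ["region", "quantity", "time_h", "value", "sem", "n", "flags"]


def write_timecourse_csv(frame: pd.DataFrame, path: Union[str, Path]) -> Path:
    """Write a time-course table (region, quantity, time_h, value, sem, n, flags)."""
    missing = [c for c in TIMECOURSE_COLUMNS if c not in frame.columns]
    if missing:
        raise ImageIOError(f"time-course table missing columns: {missing}")
    path = Path(path)
    _atomic_write_text(path, frame[TIMECOURSE_COLUMNS].to_csv(index=False))
    return path


def read_timecourse_csv(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"time-course file not found: {path}")
    frame = pd.read_csv(path)
    missing = [c for c in TIMECOURSE_COLUMNS if c not in frame.columns]
    if missing:
        raise ImageIOError(f"time-course file missing columns: {missing}")
    for (_, _), group in frame.groupby(["region", "quantity"]):
        t = group["time_h"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ImageIOError("time-course times must be strictly increasing per region")
    return frame
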