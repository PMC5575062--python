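"""Calibrated stack, ROI, and result-table I/O.

Conventions fixed here once, because ImageJ ROI exports are ambiguous
across import paths:

* coordinates are 0-based ``(x, y) = (column, row)``, pixel-center;
* ROI interchange is plain JSON, not the binary ImageJ ROI format;
* calibration priority is explicit argument > TIFF resolution tags >
  error — never a silent default.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

ROI_KINDS = ("neurite_axis", "neck", "growthcone_outline")


@dataclass
class TimeLapseStack:
    """A calibrated T x H x W grayscale time-lapse.

    Parameters
    ----------
    data : ndarray, shape (T, H, W)
        Nonnegative intensities; a 2-D array is promoted to T=1.
    pixel_size_um : float
        Lateral calibration, micrometres per pixel.
    frame_interval_s : float
        Seconds between consecutive frames.
    channel_name : str
        Free-text channel label ("actin", "ebc", "marker", ...).
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channel_name: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError(f"stack must be T x H x W, got shape {self.data.shape}")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("calibration must be strictly positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self):
        return self.data.shape

    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame, starting at t=0."""
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class LineRoi:
    """Polyline or polygon ROI in 0-based pixel-center (x, y) coordinates.

    ``kind`` distinguishes the three geometries the analysis uses: a line
    along the neurite axis (kymograph source), a short line across the
    neurite at the growth-cone neck (comet counting), and a closed
    growth-cone outline (area/intensity measurement).
    """

    points: list = field(default_factory=list)
    width_px: int = 1
    label: str = ""
    kind: str = "neurite_axis"

    def __post_init__(self):
        pts = [tuple(float(c) for c in p) for p in self.points]
        if len(pts) < 2:
            raise ValueError("LineRoi needs at least 2 points")
        for a, b in zip(pts, pts[1:]):
            if a == b:
                raise ValueError("consecutive ROI points must be distinct")
        if self.width_px < 1 or self.width_px % 2 == 0:
            raise ValueError("ROI width must be a positive odd integer")
        if self.kind not in ROI_KINDS:
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        self.points = pts

    def length_px(self) -> float:
        p = np.asarray(self.points)
        return float(np.sum(np.hypot(*(np.diff(p, axis=0).T))))


def frames_for_duration(duration_s: float, interval_s: float) -> int:
    """Number of frames acquired in ``duration_s`` at ``interval_s`` spacing.

    The frame at t=0 is counted, so a 5-minute acquisition at 2-second
    intervals yields floor(300/2)+1 = 151 frames.
    """
    if duration_s <= 0 or interval_s <= 0:
        raise ValueError("duration and interval must be positive")
    return int(np.floor(duration_s / interval_s)) + 1


def write_stack(stack: TimeLapseStack, path) -> None:
    """Write a multi-page grayscale TIFF with calibration in its tags.

    Pixel size goes into the resolution tags (pixels per micrometre) and
    the frame interval into ImageJ-style metadata, so a round trip
    through :func:`read_stack` needs no explicit calibration.
    """
    data = stack.data
    if data.dtype == np.float64:
        data = data.astype(np.float32)
    res = 1.0 / stack.pixel_size_um
    tifffile.imwrite(
        str(path),
        data,
        imagej=True,
        resolution=(res, res),
        metadata={
            "unit": "um",
            "finterval": stack.frame_interval_s,
            "axes": "TYX",
        },
    )


def read_stack(path, pixel_size_um: float | None = None,
               frame_interval_s: float | None = None,
               channel_name: str = "") -> TimeLapseStack:
    """Read a multi-page grayscale TIFF as a calibrated stack.

    Calibration resolution order: explicit arguments win, then TIFF
    resolution tags / ImageJ metadata; if neither source supplies a
    value the read fails rather than guessing.
    """
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(
                f"{path}: expected grayscale pages, got array of shape {data.shape}"
            )
        if pixel_size_um is None:
            page = tf.pages[0]
            tag = page.tags.get("XResolution")
            if tag is not None:
                num, den = tag.value
                if num > 0:
                    pixel_size_um = den / num
        if frame_interval_s is None and tf.imagej_metadata:
            fi = tf.imagej_metadata.get("finterval")
            if fi:
                frame_interval_s = float(fi)
    if pixel_size_um is None:
        raise ValueError(f"{path}: no pixel size in TIFF tags and none supplied")
    if frame_interval_s is None:
        raise ValueError(f"{path}: no frame interval in metadata and none supplied")
    return TimeLapseStack(data, pixel_size_um, frame_interval_s, channel_name)


def write_roi(rois: list[LineRoi], path) -> None:
    payload = [
        {
            "label": r.label,
            "kind": r.kind,
            "width_px": r.width_px,
            "points": [list(p) for p in r.points],
        }
        for r in rois
    ]
    with open(path, "w") as fh:
        json.dump({"coordinate_convention": "0-based, (x, y), pixel-center",
                   "rois": payload}, fh, indent=2)


def read_roi(path) -> list[LineRoi]:
    """Read ROIs from JSON; width defaults to 1 when omitted."""
    with open(path) as fh:
        doc = json.load(fh)
    entries = doc["rois"] if isinstance(doc, dict) else doc
    return [
        LineRoi(
            points=e["points"],
            width_px=int(e.get("width_px", 1)),
            label=e.get("label", ""),
            kind=e.get("kind", "neurite_axis"),
        )
        for e in entries
    ]


def result_table(rows: list[dict]) -> pd.DataFrame:
    """Validate and assemble a long-format measurement table.

    Every numeric measurement must carry a nonempty ``units`` string;
    unitless quantities must say so explicitly (e.g. "sigma", "count").
    """
    df = pd.DataFrame(rows)
    if len(df) and ("units" not in df.columns or df["units"].astype(str).eq("").any()
                    or df["units"].isna().any()):
        raise ValueError("every measurement row must carry nonempty units")
    return df


def log(msg: str, *, verbose: bool = True) -> None:
    if verbose:
        print(f"[gcflow] {msg}", file=sys.stderr)
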