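"""Growth-cone delineation and intensity tracing.

Two measurement modes coexist, matching the two procedures used on real
data: a manual polygon outline whose enclosed mean intensity is read
from a single frame or projection, and an automated per-frame mean
auto-threshold (pixels strictly brighter than the crop mean) that
follows the dynamic growth cone through all frames of a time-lapse and
retrieves the *original* channel intensities at the thresholded
coordinates — never the thresholded values themselves.

The strict ``> mean`` cutoff means a constant crop yields an empty mask
(flagged degenerate) rather than a full one: a constant crop contains
no growth cone. By default only the largest 8-connected component is
kept, so stray bright speckles outside the cone do not contaminate the
trace; the unfiltered behavior is available via ``keep_largest=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .io import LineRoi, TimeLapseStack


@dataclass
class GrowthConeTrace:
    label: str
    per_frame_mask_coords: list            # per frame: (N,2) array of (row, col)
    mean_intensity: np.ndarray             # per-frame mean of the original channel (NaN = degenerate)
    degenerate: np.ndarray                 # bool per frame
    summary_intensity: float               # mean over non-degenerate frames


def mean_threshold_mask(crop: np.ndarray, keep_largest: bool = True):
    """Pixels strictly brighter than the crop mean.

    Returns ``(mask, degenerate)``: a boolean mask the shape of the crop
    and a flag set when no pixel exceeds the mean (constant crop).
    With ``keep_largest`` only the largest 8-connected component survives.
    """
    crop = np.asarray(crop, dtype=float)
    if crop.size == 0:
        raise ValueError("empty crop")
    mask = crop > crop.mean()
    if not mask.any():
        return mask, True
    if keep_largest:
        lab = measure.label(mask, connectivity=2)
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        mask = lab == sizes.argmax()
    return mask, False


def trace_growthcone(stack: TimeLapseStack, crop_roi,
                     measure_channel: TimeLapseStack | None = None, *,
                     keep_largest: bool = True, label: str = "") -> GrowthConeTrace:
    """Segment the growth cone per frame and read out original intensities.

    Parameters
    ----------
    stack : segmentation channel (e.g. the marker/Drebrin channel).
    crop_roi : (x, y, w, h) rectangle containing the growth cone.
    measure_channel : channel whose intensities are retrieved at the
        thresholded coordinates; defaults to the segmentation channel.

    Degenerate frames (empty mask) are excluded from the summary mean
    and reported; more than 50% degenerate frames is a failure.
    """
    if measure_channel is None:
        measure_channel = stack
    if measure_channel.shape != stack.shape:
        raise ValueError("segmentation and measurement stacks must be co-registered")
    x, y, w, h = (int(v) for v in crop_roi)
    T, H, W = stack.shape
    if x < 0 or y < 0 or x + w > W or y + h > H or w < 1 or h < 1:
        raise ValueError(f"crop {crop_roi} outside image of shape {(H, W)}")
    coords_per_frame = []
    means = np.full(T, np.nan)
    degen = np.zeros(T, dtype=bool)
    for t in range(T):
        crop = stack.data[t, y:y + h, x:x + w]
        mask, bad = mean_threshold_mask(crop, keep_largest=keep_largest)
        degen[t] = bad
        rc = np.argwhere(mask)
        rc_global = rc + [y, x]
        coords_per_frame.append(rc_global)
        if not bad:
            means[t] = float(measure_channel.data[t, rc_global[:, 0], rc_global[:, 1]].mean())
    if degen.mean() > 0.5:
        raise ValueError(f"segmentation failed: {int(degen.sum())}/{T} degenerate frames")
    summary = float(np.nanmean(means))
    return GrowthConeTrace(label=label, per_frame_mask_coords=coords_per_frame,
                           mean_intensity=means, degenerate=degen,
                           summary_intensity=summary)


def polygon_mask(shape, vertices) -> np.ndarray:
    """Even-odd point-in-polygon test on pixel centers.

    ``vertices`` are (x, y) pixel-center coordinates of a closed polygon
    (closing edge implied). A pixel belongs to the mask when a ray from
    its center crosses the polygon boundary an odd number of times.
    """
    vs = np.asarray(vertices, dtype=float)
    if vs.shape[0] < 3:
        raise ValueError("polygon needs at least 3 vertices")
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    px, py = xx.astype(float), yy.astype(float)
    inside = np.zeros(shape, dtype=bool)
    n = len(vs)
    for i in range(n):
        x0, y0 = vs[i]
        x1, y1 = vs[(i + 1) % n]
        crosses = ((y0 > py) != (y1 > py))
        with np.errstate(divide="ignore", invalid="ignore"):
            x_int = x0 + (py - y0) * (x1 - x0) / (y1 - y0)
        inside ^= crosses & (px < x_int)
    return inside


def manual_region_mean(frame: np.ndarray, outline) -> float:
    """Mean original intensity inside a manually drawn polygon outline."""
    if isinstance(outline, LineRoi):
        vertices = outline.points
    else:
        vertices = outline
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("expected a single frame or projection")
    mask = polygon_mask(frame.shape, vertices)
    if not mask.any():
        raise ValueError("polygon encloses no pixel centers")
    return float(frame[mask].mean())
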