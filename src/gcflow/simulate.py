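"""Synthetic growth-cone time-lapse and kinetics generator.

Every quantification stage in this package (kymograph velocimetry, EB3
comet counting, coverage, intensity tracing, kinetic fitting) is
validated by parameter recovery on data produced here, because the
microscopy videos the procedures were designed for are not deposited
anywhere. The generator therefore emulates the statistical structure
those procedures assume:

* neurites with a shaft and a terminal growth cone, carrying F-actin
  speckles that advect tipward-to-base (retrograde) at a configured
  µm/min speed;
* EB3 comets born at the growth-cone neck at a Poisson rate, moving
  anterogradely (base-to-tip) until they reach the tip or die;
* a diffuse marker channel (Drebrin-like) filling the growth-cone
  footprint at a per-neurite intensity;
* acquisition of 5 min at one frame per 2 s (151 frames), Gaussian PSF,
  and Poisson + Gaussian noise.

All randomness flows from explicit integer seeds; identical config and
seed give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io import LineRoi, TimeLapseStack, frames_for_duration
from .kinetics import KineticTrace
from .kymograph import Kymograph


# Treadmilling-speed condition means (µm/min) used as group-comparison
# simulation presets: control vs microtubule-depolymerized (nocodazole)
# vs microtubule-stabilized (taxol), as mean ± SEM with n = 10 cells.
TREADMILL_CONDITIONS = {
    "control": {"mean": 4.7258, "sem": 0.1918, "n": 10},
    "nocodazole": {"mean": 1.6522, "sem": 0.1183, "n": 10},
    "taxol": {"mean": 5.7273, "sem": 0.2150, "n": 10},
}


@dataclass
class NeuriteSpec:
    """Geometry and dynamics of one synthetic neurite.

    The neurite is a straight shaft from ``base_xy`` to ``tip_xy`` with a
    disk-shaped growth cone of ``growthcone_radius_px`` at the tip; the
    neck sits where the shaft meets the cone. ``flow_speed_um_min`` is the
    ground-truth retrograde F-actin speed, ``comet_rate_per_min`` the
    Poisson intensity of EB3 comets entering the neck, and
    ``marker_intensity`` the diffuse marker level of this growth cone.
    """

    base_xy: tuple = (20.0, 100.0)
    tip_xy: tuple = (120.0, 100.0)
    shaft_width_px: float = 5.0
    growthcone_radius_px: float = 9.0
    flow_speed_um_min: float = 4.7
    speckle_density: float = 1.5          # speckles / µm²
    speckle_lifetime_s: float = 30.0
    comet_rate_per_min: float = 4.0
    comet_speed_um_min: float = 8.0
    marker_intensity: float = 100.0
    speckle_intensity: float = 120.0
    comet_intensity: float = 150.0
    comet_lifetime_s: float = 12.0
    label: str = "n1"

    def __post_init__(self):
        if self.flow_speed_um_min < 0 or self.comet_rate_per_min < 0:
            raise ValueError("rates and speeds must be nonnegative")
        if tuple(self.base_xy) == tuple(self.tip_xy):
            raise ValueError("tip must differ from base")

    @property
    def length_px(self) -> float:
        return math.hypot(self.tip_xy[0] - self.base_xy[0],
                          self.tip_xy[1] - self.base_xy[1])

    @property
    def neck_arc_px(self) -> float:
        """Arc-length position of the growth-cone neck, from the base."""
        return self.length_px - self.growthcone_radius_px


@dataclass
class SceneConfig:
    """Full description of one synthetic acquisition."""

    image_shape: tuple = (200, 200)       # (H, W)
    pixel_size_um: float = 0.16
    frame_interval_s: float = 2.0
    duration_s: float = 300.0
    neurites: list = field(default_factory=lambda: [NeuriteSpec()])
    psf_sigma_px: float = 1.0
    noise_gaussian_sd: float = 2.0
    noise_poisson_scale: float = 5.0      # photons per intensity unit; 0 = off
    background_level: float = 10.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0 or self.duration_s <= 0:
            raise ValueError("calibration and duration must be positive")

    @property
    def n_frames(self) -> int:
        return frames_for_duration(self.duration_s, self.frame_interval_s)


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    neurites: list                        # NeuriteSpec per neurite
    comet_events: dict                    # label -> list of (birth_s, neck_crossing_s)
    footprints: dict                      # label -> HxW bool growth-cone mask
    axis_rois: dict                       # label -> LineRoi, base -> tip order
    neck_rois: dict                       # label -> LineRoi across the neck
    pixel_size_um: float = 0.16
    frame_interval_s: float = 2.0


def _unit(vx, vy):
    n = math.hypot(vx, vy)
    return vx / n, vy / n


def _splat(frame: np.ndarray, x: float, y: float, amp: float, sigma: float) -> None:
    """Add one Gaussian point source at sub-pixel position (x, y)."""
    h, w = frame.shape
    r = int(math.ceil(3 * sigma))
    x0, x1 = int(math.floor(x)) - r, int(math.floor(x)) + r + 1
    y0, y1 = int(math.floor(y)) - r, int(math.floor(y)) + r + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return
    xs = np.arange(x0c, x1c) - x
    ys = np.arange(y0c, y1c) - y
    g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sigma ** 2))
    frame[y0c:y1c, x0c:x1c] += amp * g


def _footprint_masks(spec: NeuriteSpec, shape) -> tuple[np.ndarray, np.ndarray]:
    """(full neurite footprint, growth-cone-only footprint) boolean masks."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    bx, by = spec.base_xy
    tx, ty = spec.tip_xy
    ux, uy = _unit(tx - bx, ty - by)
    # arc-length and lateral offset of every pixel center
    s = (xx - bx) * ux + (yy - by) * uy
    u = -(xx - bx) * uy + (yy - by) * ux
    shaft = (s >= 0) & (s <= spec.neck_arc_px) & (np.abs(u) <= spec.shaft_width_px / 2)
    cone = (xx - tx) ** 2 + (yy - ty) ** 2 <= spec.growthcone_radius_px ** 2
    return shaft | cone, cone


def _check_inside(spec: NeuriteSpec, shape) -> None:
    h, w = shape
    pts = [spec.base_xy, spec.tip_xy]
    r = spec.growthcone_radius_px
    tx, ty = spec.tip_xy
    for x, y in pts:
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(f"neurite {spec.label!r}: endpoint ({x}, {y}) outside image {shape}")
    if tx - r < 0 or tx + r >= w or ty - r < 0 or ty + r >= h:
        raise ValueError(f"neurite {spec.label!r}: growth cone exceeds image bounds")


def simulate_timelapse(config: SceneConfig):
    """Render the three-channel synthetic acquisition.

    Returns
    -------
    channels : dict of str -> TimeLapseStack
        "actin" (retrograde speckles), "ebc" (EB3-comet puncta), and
        "marker" (diffuse growth-cone fill).
    truth : GroundTruth
    """
    n_frames = config.n_frames
    if n_frames < 1:
        raise ValueError("zero frames")
    h, w = config.image_shape
    rng = np.random.default_rng(config.rng_seed)
    px = config.pixel_size_um
    dt = config.frame_interval_s
    ideal = {name: np.zeros((n_frames, h, w), dtype=np.float64)
             for name in ("actin", "ebc", "marker")}

    comet_events: dict[str, list] = {}
    footprints: dict[str, np.ndarray] = {}
    axis_rois: dict[str, LineRoi] = {}
    neck_rois: dict[str, LineRoi] = {}

    for spec in config.neurites:
        _check_inside(spec, (h, w))
        full_fp, cone_fp = _footprint_masks(spec, (h, w))
        footprints[spec.label] = cone_fp
        bx, by = spec.base_xy
        ux, uy = _unit(spec.tip_xy[0] - bx, spec.tip_xy[1] - by)
        L = spec.length_px
        neck = spec.neck_arc_px

        axis_rois[spec.label] = LineRoi(
            points=[list(spec.base_xy), list(spec.tip_xy)],
            label=spec.label, kind="neurite_axis")
        # neck line perpendicular to the axis, spanning the shaft width + margin
        half = spec.shaft_width_px / 2 + 2
        nx, ny = bx + ux * neck, by + uy * neck
        neck_rois[spec.label] = LineRoi(
            points=[[nx + uy * half, ny - ux * half],
                    [nx - uy * half, ny + ux * half]],
            label=spec.label, kind="neck")

        # --- actin speckles: steady-state population with Poisson turnover
        v_px_s = spec.flow_speed_um_min / 60.0 / px        # retrograde, px/s
        area_um2 = full_fp.sum() * px ** 2
        n_ss = spec.speckle_density * area_um2
        tau = spec.speckle_lifetime_s
        births = []
        if n_ss > 0:
            # initial population, ages already exponential
            n0 = rng.poisson(n_ss)
            births += [(-rng.exponential(tau), ) for _ in range(n0)]
            # turnover births during the movie
            nb = rng.poisson(n_ss / tau * config.duration_s)
            births += [(rng.uniform(0, config.duration_s), ) for _ in range(nb)]
        speckles = []
        for (t0,) in births:
            s0 = rng.uniform(0, L)
            u0 = rng.uniform(-spec.shaft_width_px / 2, spec.shaft_width_px / 2)
            life = rng.exponential(tau)
            speckles.append((t0, s0, u0, t0 + life))

        # --- EB3 comets: Poisson births at the shaft side of the neck
        rate_s = spec.comet_rate_per_min / 60.0
        vc_px_s = spec.comet_speed_um_min / 60.0 / px
        events = []
        comets = []
        if rate_s > 0:
            n_c = rng.poisson(rate_s * config.duration_s)
            t_births = np.sort(rng.uniform(0, config.duration_s, size=n_c))
            for tb in t_births:
                s0 = neck - 1.0                             # born at the shaft side of the neck
                u0 = rng.uniform(-spec.shaft_width_px / 3, spec.shaft_width_px / 3)
                life = rng.exponential(spec.comet_lifetime_s)
                t_tip = tb + (L - s0) / vc_px_s if vc_px_s > 0 else np.inf
                t_die = min(tb + life, t_tip)
                t_cross = tb + (neck - s0) / vc_px_s if vc_px_s > 0 else tb
                comets.append((tb, s0, u0, t_die))
                # a comet born at the neck has entered by construction
                events.append((float(tb), float(t_cross)))
        comet_events[spec.label] = events

        # --- render ideal frames
        for ti in range(n_frames):
            t = ti * dt
            fa = ideal["actin"][ti]
            fe = ideal["ebc"][ti]
            for (t0, s0, u0, t1) in speckles:
                if not (t0 <= t < t1):
                    continue
                s = s0 - v_px_s * (t - t0)
                if s < 0 or s > L:
                    continue
                x = bx + ux * s - uy * u0
                y = by + uy * s + ux * u0
                _splat(fa, x, y, spec.speckle_intensity, 0.7)
            for (tb, s0, u0, t_die) in comets:
                if not (tb <= t < t_die):
                    continue
                s = s0 + vc_px_s * (t - tb)
                if s > L:
                    continue
                x = bx + ux * s - uy * u0
                y = by + uy * s + ux * u0
                _splat(fe, x, y, spec.comet_intensity, 0.9)
        if spec.marker_intensity != 0:
            ideal["marker"][:, cone_fp] += spec.marker_intensity

    channels = {}
    for name, stack in ideal.items():
        out = np.empty_like(stack)
        for ti in range(n_frames):
            frame = gaussian_filter(stack[ti], config.psf_sigma_px) + config.background_level
            if config.noise_poisson_scale > 0:
                frame = rng.poisson(np.maximum(frame, 0) * config.noise_poisson_scale
                                    ) / config.noise_poisson_scale
            if config.noise_gaussian_sd > 0:
                frame = frame + rng.normal(0, config.noise_gaussian_sd, frame.shape)
            out[ti] = frame
        channels[name] = TimeLapseStack(out, px, dt, channel_name=name)

    truth = GroundTruth(neurites=list(config.neurites), comet_events=comet_events,
                        footprints=footprints, axis_rois=axis_rois,
                        neck_rois=neck_rois, pixel_size_um=px, frame_interval_s=dt)
    return channels, truth


def simulate_kymograph(slope_px_per_frame: float, n_tracks: int,
                       kymo_shape: tuple = (100, 151), line_intensity: float = 50.0,
                       noise_sd: float = 0.0, rng_seed: int = 0, *,
                       sample_spacing_um: float = 0.1, frame_interval_s: float = 2.0,
                       offsets=None, track_sigma: float = 0.8):
    """Paint straight anti-aliased tracks of a known slope on a D x T canvas.

    This is the direct fixture for the slope estimators: each track is a
    Gaussian-profile line d(t) = d0 + slope * t. Negative slopes move
    toward the line start (retrograde by the package convention).

    Returns the kymograph and the ground-truth track endpoints as
    ((d_start, t_start), (d_end, t_end)) pairs in (distance px, frame).
    """
    D, T = kymo_shape
    if D < 2 or T < 2:
        raise ValueError("kymograph shape must be at least 2 x 2")
    if n_tracks < 0:
        raise ValueError("n_tracks must be nonnegative")
    rng = np.random.default_rng(rng_seed)
    data = np.zeros((D, T), dtype=np.float64)
    endpoints = []
    if n_tracks > 0:
        # intercept range guaranteeing each track a minimum visible span
        min_span = 10 if T > 20 else 2
        a = abs(slope_px_per_frame)
        if a > 0 and (D - 1) / a < 2:
            raise ValueError(
                f"slope {slope_px_per_frame} px/frame crosses the image in under "
                "2 frames; no visible track possible")
        if offsets is None:
            if slope_px_per_frame < 0:
                lo, hi = a * min_span, (D - 1) + a * (T - 1 - min_span)
            elif slope_px_per_frame > 0:
                lo, hi = -a * (T - 1 - min_span), (D - 1) - a * min_span
            else:
                lo, hi = 0.0, D - 1.0
            if hi < lo:
                lo = hi = (lo + hi) / 2
            d0s = rng.uniform(lo, hi, size=n_tracks)
        else:
            d0s = np.asarray(offsets, dtype=float)
            if len(d0s) != n_tracks:
                raise ValueError("offsets length must equal n_tracks")
        cols = np.arange(T)
        rows = np.arange(D)
        for d0 in d0s:
            d = d0 + slope_px_per_frame * cols
            visible = (d >= 0) & (d <= D - 1)
            if visible.sum() < 2:
                raise ValueError(
                    f"slope {slope_px_per_frame} px/frame puts the track outside the image")
            prof = np.exp(-(rows[:, None] - d[None, :]) ** 2 / (2 * track_sigma ** 2))
            prof[:, ~visible] = 0.0
            data += line_intensity * prof
            tv = cols[visible]
            endpoints.append(((float(d[tv[0]]), int(tv[0])),
                              (float(d[tv[-1]]), int(tv[-1]))))
    if noise_sd > 0:
        data += rng.normal(0, noise_sd, data.shape)
    kymo = Kymograph(data=data, sample_spacing_um=sample_spacing_um,
                     frame_interval_s=frame_interval_s, source_roi="synthetic")
    return kymo, endpoints


def simulate_comet_kymograph(rate_per_min: float, window_s: float = 300.0,
                             n_rows: int = 96, frame_interval_s: float = 2.0,
                             amplitude: float = 50.0, noise_sd: float = 10.0,
                             rng_seed: int = 0, *, sample_spacing_um: float = 0.16,
                             spot_sigma_px: float = 1.0, spot_sigma_frames: float = 1.0):
    """Counting-line kymograph fixture: Poisson comet crossings as spots.

    Each comet crossing the counting line paints a compact Gaussian spot
    at (its lateral position, its crossing frame); crossing times are a
    homogeneous Poisson process and lateral positions are uniform along
    the line (drawn wide so independent crossings rarely coincide).

    Returns the kymograph and the ground-truth events as an (n, 2) array
    of (time_s, row_px).
    """
    if rate_per_min < 0:
        raise ValueError("rate must be nonnegative")
    rng = np.random.default_rng(rng_seed)
    T = frames_for_duration(window_s, frame_interval_s)
    n = rng.poisson(rate_per_min / 60.0 * window_s)
    times = np.sort(rng.uniform(0, window_s, size=n))
    margin = min(4.0, n_rows / 4)
    rows_ev = rng.uniform(margin, n_rows - margin, size=n)
    data = np.zeros((n_rows, T), dtype=np.float64)
    rows = np.arange(n_rows)
    cols = np.arange(T)
    for t_ev, d_ev in zip(times, rows_ev):
        c_ev = t_ev / frame_interval_s
        g = np.exp(-(rows[:, None] - d_ev) ** 2 / (2 * spot_sigma_px ** 2)) * \
            np.exp(-(cols[None, :] - c_ev) ** 2 / (2 * spot_sigma_frames ** 2))
        data += amplitude * g
    if noise_sd > 0:
        data += rng.normal(0, noise_sd, data.shape)
    kymo = Kymograph(data=data, sample_spacing_um=sample_spacing_um,
                     frame_interval_s=frame_interval_s, source_roi="synthetic_neck")
    events = np.column_stack([times, rows_ev]) if n else np.empty((0, 2))
    return kymo, events


def resolvable_events(events: np.ndarray, res_px: float = 3.0,
                      res_frames: float = 3.0, frame_interval_s: float = 2.0
                      ) -> np.ndarray:
    """Merge ground-truth crossings closer than the fixture's resolution.

    Two comets arriving within ``res_frames`` frames at lateral positions
    within ``res_px`` of each other render as one unresolvable spot; a
    "distinct spot" counter cannot and should not separate them. Greedy
    merge in time order; returns the surviving (time_s, row_px) events.
    """
    if len(events) == 0:
        return events
    kept: list = []
    for t, d in events:
        if any(abs(t - kt) <= res_frames * frame_interval_s and abs(d - kd) <= res_px
               for kt, kd in kept):
            continue
        kept.append((t, d))
    return np.asarray(kept)


def simulate_coverage_scene(target_fraction: float, radius_px: int = 30,
                            image_hw: tuple = (96, 96), n_frames: int = 5,
                            noise_sd: float = 2.0, rng_seed: int = 0,
                            pixel_size_um: float = 0.16, frame_interval_s: float = 2.0):
    """Two-channel scene whose EB3 mask covers a known fraction of the
    reference (F-actin/Drebrin) growth-cone footprint.

    The reference channel fills a disk; the EB3 channel fills the part of
    that disk below the x-quantile chosen so the bright-pixel ratio equals
    ``target_fraction`` exactly on the noiseless masks.
    """
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must be in (0, 1]")
    h, w = image_hw
    rng = np.random.default_rng(rng_seed)
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = h / 2, w / 2
    disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px ** 2
    xs = np.sort(xx[disk])
    cut = xs[min(int(round(target_fraction * disk.sum())), disk.sum() - 1)]
    sub = disk & (xx <= cut)
    true_fraction = sub.sum() / disk.sum()

    ref = np.full((n_frames, h, w), 10.0)
    ebc = np.full((n_frames, h, w), 10.0)
    ref[:, disk] += 200.0
    ebc[:, sub] += 150.0
    ref += rng.normal(0, noise_sd, ref.shape)
    ebc += rng.normal(0, noise_sd, ebc.shape)

    pad = radius_px + 6
    region = LineRoi(points=[[cx - pad, cy - pad], [cx + pad, cy - pad],
                             [cx + pad, cy + pad], [cx - pad, cy + pad]],
                     label="gc", kind="growthcone_outline")
    ref_stack = TimeLapseStack(ref, pixel_size_um, frame_interval_s, "ref")
    ebc_stack = TimeLapseStack(ebc, pixel_size_um, frame_interval_s, "ebc")
    return ref_stack, ebc_stack, region, float(true_fraction)


@dataclass
class KineticSimConfig:
    """Ground truth for one synthetic pyrene polymerization trace.

    The noiseless curve is y0 + (ymax - y0) * (1 - exp(-ln2 *
    ((t - lag)/(t_half - lag))^h)) for t >= lag and y0 before, which
    passes through (t_half, (y0+ymax)/2) exactly for any shape
    exponent h (``hill_or_rate``; h = 1 is the plain lagged
    exponential the fitter assumes).
    """

    y0: float = 0.0
    ymax: float = 1.0
    t_half_s: float = 302.2
    hill_or_rate: float = 1.0
    lag_s: float = 30.0
    noise_sd: float = 0.02
    sampling_interval_s: float = 10.0
    duration_s: float = 1800.0
    rng_seed: int = 0

    def __post_init__(self):
        if not (self.ymax > self.y0 >= 0):
            raise ValueError("need ymax > y0 >= 0")
        if not (self.t_half_s > self.lag_s >= 0):
            raise ValueError("need t_half_s > lag_s >= 0")


def kinetic_curve(t, config: KineticSimConfig) -> np.ndarray:
    """Noiseless saturating curve of the generator's parametrization."""
    t = np.asarray(t, dtype=float)
    tau = np.maximum(t - config.lag_s, 0.0) / (config.t_half_s - config.lag_s)
    rise = 1.0 - np.exp(-np.log(2.0) * tau ** config.hill_or_rate)
    return config.y0 + (config.ymax - config.y0) * np.where(t >= config.lag_s, rise, 0.0)


def simulate_kinetic_trace(config: KineticSimConfig, condition_label: str = ""
                           ) -> KineticTrace:
    """Sample a noisy pyrene trace on a regular time grid."""
    if config.sampling_interval_s >= config.duration_s:
        raise ValueError("sampling interval must be shorter than the duration")
    t = np.arange(0.0, config.duration_s + 1e-9, config.sampling_interval_s)
    y = kinetic_curve(t, config)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.rng_seed)
        y = y + rng.normal(0, config.noise_sd, y.shape)
    return KineticTrace(time_s=t, fluorescence=y, condition_label=condition_label)


def simulate_paired_table(n: int, true_r: float, rng_seed: int = 0) -> pd.DataFrame:
    """Sample n paired observations from a bivariate normal with the given
    population correlation; the fixture for the correlation statistics."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(true_r) > 1:
        raise ValueError("|true_r| must be <= 1")
    rng = np.random.default_rng(rng_seed)
    x = rng.normal(0, 1, n)
    e = rng.normal(0, 1, n)
    y = true_r * x + np.sqrt(max(1 - true_r ** 2, 0.0)) * e
    return pd.DataFrame({"x": x, "y": y})
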