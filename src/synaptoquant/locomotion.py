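"""Larval crawling metrics from per-frame tracker tables.

A crawling third-instar larva propels itself by peristaltic waves of muscle
contraction; each wave produces one stride.  The tracker exports, per frame
(12.5 frames/s by default), the animal's centroid, projected area, spine
length (head to tail) and mid-spine width.  The projected area oscillates with
the peristaltic cycle, so the number of waves in a recording is the number of
peaks of the (Savitzky-Golay smoothed) area curve.  Derived metrics:

* traveled distance: summed frame-to-frame centroid displacement (mm),
* stride size: distance / wave count (mm per wave),
* stride duration: recording time / wave count (s per wave).

Tracks where the larva burrowed into the agar (sustained area collapse) or
escaped the arena are flagged for exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .exceptions import ValidationError

__all__ = [
    "LarvaTrack",
    "StrideMetrics",
    "LocomotionConfig",
    "smooth_area",
    "count_peristaltic_waves",
    "traveled_distance",
    "stride_metrics",
    "body_dimensions",
    "qc_exclude",
    "analyze_track",
]

DEFAULT_FPS = 12.5
DEFAULT_RECORDING_TIME = 120.0  # s


@dataclass
class LarvaTrack:
    """Per-frame time series for one larva (internal unit: mm)."""

    frame_times: np.ndarray
    centroid_xy: np.ndarray  # shape (n, 2)
    area: np.ndarray
    spine_length: np.ndarray
    width: np.ndarray
    larva_id: str = "larva"
    qc_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.centroid_xy = np.asarray(self.centroid_xy, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        self.spine_length = np.asarray(self.spine_length, dtype=float)
        self.width = np.asarray(self.width, dtype=float)
        n = self.frame_times.size
        if n < 1:
            raise ValidationError("track must contain at least one frame")
        if self.centroid_xy.shape != (n, 2):
            raise ValidationError("centroid_xy must have shape (n_frames, 2)")
        for name in ("area", "spine_length", "width"):
            if getattr(self, name).shape != (n,):
                raise ValidationError(f"{name} must have length n_frames")
        if n >= 2:
            dt = np.diff(self.frame_times)
            if np.any(np.abs(dt - dt[0]) > 1e-9):
                raise ValidationError("frame spacing must be constant within 1e-9 s")
        if np.any(~np.isfinite(self.area)) or np.any(self.area <= 0):
            raise ValidationError("area must be finite and > 0 in every frame")

    @property
    def n_frames(self) -> int:
        return self.frame_times.size

    @property
    def dt(self) -> float:
        if self.n_frames < 2:
            raise ValidationError("frame spacing undefined for a single frame")
        return float(self.frame_times[1] - self.frame_times[0])

    @property
    def fps(self) -> float:
        return 1.0 / self.dt

    @property
    def recording_time(self) -> float:
        """Total recorded time, n_frames * dt (s)."""
        return self.n_frames * self.dt


@dataclass
class StrideMetrics:
    """Distance, wave count and per-wave stride metrics for one track.

    ``stride_size * n_waves`` reproduces ``distance`` and
    ``stride_duration * n_waves`` reproduces ``recording_time`` by
    construction.  With zero waves the per-wave metrics are undefined (NaN)
    and flagged, not raised.
    """

    distance: float
    n_waves: int
    recording_time: float
    stride_size: float
    stride_duration: float
    undefined: bool


@dataclass
class LocomotionConfig:
    """Tunables of the crawling analysis.

    The tracker itself is not part of this package; pixel-to-mm conversion is
    assumed done (or supply ``scale_mm_per_px`` at read time).  Savitzky-Golay
    defaults: 11-frame window (~0.9 s at 12.5 fps), polynomial order 3.  Peaks
    must exceed a prominence of ``prominence_iqr_factor`` times the
    interquartile range of the smoothed series (robust to amplitude scale),
    with a noise-adaptive floor of ``noise_prominence_factor`` times the
    measurement-noise SD estimated from the smoothing residual, so that a
    non-crawling larva's residual noise does not count as waves.
    """

    fps: float = DEFAULT_FPS
    recording_time: float | None = None  # default: track.recording_time
    sg_window: int = 11
    sg_polyorder: int = 3
    prominence_iqr_factor: float = 0.25
    noise_prominence_factor: float = 4.0
    arena_bounds: tuple[float, float, float, float] | None = None  # xmin, xmax, ymin, ymax
    burrow_area_fraction: float = 0.5
    burrow_min_duration: float = 2.0  # s


def smooth_area(
    area: np.ndarray | LarvaTrack, window: int = 11, polyorder: int = 3
) -> np.ndarray:
    """Savitzky-Golay smoothing of the area series (length-preserving)."""
    series = area.area if isinstance(area, LarvaTrack) else np.asarray(area, dtype=float)
    if window % 2 == 0 or window <= polyorder or window > series.size:
        raise ValidationError(
            f"window ({window}) must be odd, greater than polyorder ({polyorder}) "
            f"and no longer than the series ({series.size})"
        )
    return savgol_filter(series, window_length=window, polyorder=polyorder)


def count_peristaltic_waves(
    smoothed: np.ndarray,
    prominence_iqr_factor: float = 0.25,
    min_prominence: float | None = None,
) -> int:
    """Number of peristaltic waves = number of peaks of the smoothed area curve.

    A peak counts when its prominence exceeds ``prominence_iqr_factor`` times
    the interquartile range of the series, or ``min_prominence`` if that is
    larger.  A constant series has no peaks.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    if smoothed.size < 3:
        raise ValidationError("need at least 3 samples to count peaks")
    q75, q25 = np.percentile(smoothed, [75, 25])
    prom = prominence_iqr_factor * (q75 - q25)
    if min_prominence is not None:
        prom = max(prom, min_prominence)
    if prom <= 0:
        prom = np.finfo(float).tiny  # constant series -> no peaks anyway
    peaks, _ = find_peaks(smoothed, prominence=prom)
    return int(peaks.size)


def estimate_noise_sd(raw: np.ndarray, smoothed: np.ndarray) -> float:
    """Robust (MAD-based) SD of the high-frequency residual raw - smoothed.

    The peristaltic oscillation survives the Savitzky-Golay filter almost
    unchanged, so the residual is dominated by frame-to-frame measurement
    noise; its scale calibrates the peak-prominence floor.
    """
    resid = np.asarray(raw, dtype=float) - np.asarray(smoothed, dtype=float)
    return 1.4826 * float(np.median(np.abs(resid - np.median(resid))))


def traveled_distance(track: LarvaTrack) -> float:
    """Total path length: sum of successive Euclidean centroid displacements (mm)."""
    if track.n_frames < 2:
        raise ValidationError("need at least 2 frames to compute a distance")
    bad = np.flatnonzero(~np.isfinite(track.centroid_xy).all(axis=1))
    if bad.size:
        raise ValidationError(f"non-finite centroid coordinates at frames {bad.tolist()[:20]}")
    steps = np.diff(track.centroid_xy, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def stride_metrics(
    track: LarvaTrack, n_waves: int, recording_time: float | None = None
) -> StrideMetrics:
    """Per-wave stride metrics; zero waves yields flagged NaN metrics."""
    if n_waves < 0:
        raise ValidationError("n_waves must be >= 0")
    distance = traveled_distance(track)
    rec = track.recording_time if recording_time is None else float(recording_time)
    if n_waves == 0:
        return StrideMetrics(
            distance=distance,
            n_waves=0,
            recording_time=rec,
            stride_size=float("nan"),
            stride_duration=float("nan"),
            undefined=True,
        )
    return StrideMetrics(
        distance=distance,
        n_waves=int(n_waves),
        recording_time=rec,
        stride_size=distance / n_waves,
        stride_duration=rec / n_waves,
        undefined=False,
    )


def body_dimensions(track: LarvaTrack) -> dict:
    """Time-averaged spine length (head to tail) and mid-spine width, in mm."""
    return {
        "mean_length": float(track.spine_length.mean()),
        "mean_width": float(track.width.mean()),
    }


def qc_exclude(
    track: LarvaTrack,
    arena_bounds: tuple[float, float, float, float],
    burrow_area_fraction: float = 0.5,
    burrow_min_duration: float = 2.0,
) -> dict:
    """Flag tracks to exclude: larva escaped the arena or burrowed into the agar.

    * escaped: the centroid leaves ``(xmin, xmax, ymin, ymax)`` at any frame.
    * burrowed (proxy): the projected area stays below
      ``burrow_area_fraction`` of its median for longer than
      ``burrow_min_duration`` seconds — a larva digging in shrinks or loses
      its visible silhouette.
    """
    xmin, xmax, ymin, ymax = arena_bounds
    x, y = track.centroid_xy[:, 0], track.centroid_xy[:, 1]
    escaped = bool(np.any((x < xmin) | (x > xmax) | (y < ymin) | (y > ymax)))

    low = track.area < burrow_area_fraction * np.median(track.area)
    burrowed = False
    if low.any() and track.n_frames >= 2:
        min_frames = int(np.ceil(burrow_min_duration / track.dt))
        run = 0
        for flag in low:
            run = run + 1 if flag else 0
            if run > min_frames:
                burrowed = True
                break
    return {"escaped": escaped, "burrowed": burrowed}


def analyze_track(track: LarvaTrack, config: LocomotionConfig | None = None) -> dict:
    """Full per-larva analysis; returns one flat record ready for a CSV row."""
    cfg = config or LocomotionConfig()
    smoothed = smooth_area(track, window=cfg.sg_window, polyorder=cfg.sg_polyorder)
    n_waves = count_peristaltic_waves(
        smoothed,
        prominence_iqr_factor=cfg.prominence_iqr_factor,
        min_prominence=cfg.noise_prominence_factor * estimate_noise_sd(track.area, smoothed),
    )
    metrics = stride_metrics(track, n_waves, recording_time=cfg.recording_time)
    dims = body_dimensions(track)
    flags = dict(track.qc_flags)
    if cfg.arena_bounds is not None:
        flags.update(
            qc_exclude(
                track,
                cfg.arena_bounds,
                burrow_area_fraction=cfg.burrow_area_fraction,
                burrow_min_duration=cfg.burrow_min_duration,
            )
        )
    return {
        "larva_id": track.larva_id,
        "distance_mm": metrics.distance,
        "n_waves": metrics.n_waves,
        "stride_size_mm": metrics.stride_size,
        "stride_duration_s": metrics.stride_duration,
        "mean_length_mm": dims["mean_length"],
        "mean_width_mm": dims["mean_width"],
        "qc": ";".join(k for k, v in sorted(flags.items()) if v) or "pass",
    }
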