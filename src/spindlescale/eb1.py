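"""Plus-end comet track filtering, growth-speed and partition statistics.

Tracks are retained when their duration, median quality and start/end frames
fall inside the documented acceptance windows (duration 2-4 s, median
quality 200-600, both ends within the configurable frame window). Growth
speed is path length over elapsed time; half-spindle profiles yield the
percentage of summed signal in the pole half (normalized distance 0-0.5);
per-cell comet statistics partition retained tracks into astral and spindle
bulk compartments.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateDataError, ValidationError
from .records import CometTrack, HalfSpindleProfile


@dataclass(frozen=True)
class TrackFilterRules:
    """Retention rules for comet tracks.

    Defaults follow the tracking protocol: duration within 2-4 s, median
    quality within 200-600, track start and end within frames 0-30. The
    frame window is a parameter because recordings can be longer than the
    default window.
    """

    min_duration: float = 2.0
    max_duration: float = 4.0
    quality_range: tuple[float, float] = (200.0, 600.0)
    start_end_window: tuple[int, int] = (0, 30)

    def __post_init__(self):
        if not 0 < self.min_duration < self.max_duration:
            raise ValidationError("require 0 < min_duration < max_duration")
        if self.quality_range[0] >= self.quality_range[1]:
            raise ValidationError("quality_range must be increasing")
        if self.start_end_window[0] > self.start_end_window[1]:
            raise ValidationError("start_end_window must be non-empty")


@dataclass(frozen=True)
class CometStats:
    """Per-cell comet statistics.

    ``astral_bulk_ratio`` is None when no bulk comets were counted (the
    ratio is undefined, not zero). ``pole_signal_fraction`` is populated
    only when a half-spindle profile was analysed alongside the tracks.
    """

    mean_speed: float
    n_tracks: int
    astral_count: int
    bulk_count: int
    astral_bulk_ratio: float | None
    comets_per_volume: float
    pole_signal_fraction: float | None = None


def _first_failing_rule(track: CometTrack, rules: TrackFilterRules) -> str | None:
    if not rules.min_duration <= track.duration <= rules.max_duration:
        return "duration"
    if track.quality is not None:
        med_q = float(np.median(track.quality))
        if not rules.quality_range[0] <= med_q <= rules.quality_range[1]:
            return "quality"
    lo, hi = rules.start_end_window
    if not (lo <= track.start_frame <= hi and lo <= track.end_frame <= hi):
        return "window"
    return None


def filter_tracks(
    tracks: Sequence[CometTrack],
    rules: TrackFilterRules = TrackFilterRules(),
) -> tuple[list[CometTrack], list[tuple[CometTrack, str]]]:
    """Split tracks into (kept, rejected-with-reason).

    A track is kept iff its duration lies in [min, max], its median quality
    lies in the quality range (tracks without quality scores pass this rule)
    and both its first and last frame indices lie in the window. Each
    rejected track carries the first rule it failed, in the order duration,
    quality, window. Idempotent: filtering a kept set keeps all of it.
    """
    kept, rejected = [], []
    for track in tracks:
        reason = _first_failing_rule(track, rules)
        if reason is None:
            kept.append(track)
        else:
            rejected.append((track, reason))
    return kept, rejected


def track_speed(track: CometTrack) -> float:
    """Growth speed of one track: path length / elapsed time (µm·s⁻¹).

    Path length sums frame-to-frame displacements; elapsed time spans the
    first to last position, ``(n_frames - 1) * frame_interval``. Comets grow
    near-ballistically, so path length and end-to-end displacement differ
    little; path length is used as the more general definition.
    """
    elapsed = (track.n_frames - 1) * track.frame_interval
    if elapsed <= 0:
        raise DegenerateDataError("zero-duration track has no defined speed")
    steps = np.diff(track.positions, axis=0)
    return float(np.sum(np.linalg.norm(steps, axis=1)) / elapsed)


def mean_growth_speed(tracks: Sequence[CometTrack]) -> float:
    """Per-cell growth speed: mean over the cell's retained tracks."""
    if len(tracks) == 0:
        raise ValidationError("need at least one retained track")
    return float(np.mean([track_speed(t) for t in tracks]))


def per_cell_speeds(tracks: Sequence[CometTrack]) -> dict[str, float]:
    """Group tracks by cell and return each cell's mean growth speed."""
    by_cell: dict[str, list[CometTrack]] = defaultdict(list)
    for t in tracks:
        by_cell[t.cell_id].append(t)
    return {cell: mean_growth_speed(ts) for cell, ts in sorted(by_cell.items())}


def pole_signal_fraction(profile: HalfSpindleProfile) -> float:
    """Percent of summed profile intensity in the pole half (distance 0-0.5).

    Trapezoidal integrals over [0, 0.5] and [0, 1]; the 0.5 boundary value is
    obtained by linear interpolation when it is not a sample point. A zero
    total integral raises :class:`DegenerateDataError`.
    """
    x, y = profile.distance, profile.intensity
    total = np.trapezoid(y, x)
    if total <= 0:
        raise DegenerateDataError("zero total profile integral")
    # integrate exactly up to 0.5 on the piecewise-linear profile
    if 0.5 < x[0] or 0.5 > x[-1]:
        raise ValidationError("profile must span the 0.5 midpoint")
    xx = np.union1d(x, [0.5])
    yy = np.interp(xx, x, y)
    sel = xx <= 0.5
    pole = np.trapezoid(yy[sel], xx[sel])
    return float(100.0 * pole / total)


def comet_partition(
    tracks: Sequence[CometTrack],
    cell_volume: float,
    sample_frames: Sequence[int] | None = None,
    pole_fraction: float | None = None,
) -> CometStats:
    """Per-cell comet statistics from a cell's retained tracks.

    Counts tracks per compartment label, the astral:bulk ratio (undefined —
    ``None`` — when no bulk comets exist) and the comet number per unit cell
    volume. With ``sample_frames``, the per-volume count emulates manual
    counting at a few reference frames: tracks alive at each sample frame are
    counted and the counts averaged; otherwise all retained tracks count.
    """
    if cell_volume <= 0:
        raise ValidationError("cell_volume must be positive")
    astral = sum(1 for t in tracks if t.compartment == "astral")
    bulk = sum(1 for t in tracks if t.compartment == "bulk")
    ratio = astral / bulk if bulk > 0 else None
    if sample_frames is None:
        total = float(len(tracks))
    else:
        counts = [
            sum(1 for t in tracks if t.start_frame <= f <= t.end_frame)
            for f in sample_frames
        ]
        total = float(np.mean(counts)) if counts else 0.0
    speed = mean_growth_speed(tracks) if len(tracks) else 0.0
    return CometStats(
        mean_speed=speed,
        n_tracks=len(tracks),
        astral_count=astral,
        bulk_count=bulk,
        astral_bulk_ratio=ratio,
        comets_per_volume=total / cell_volume,
        pole_signal_fraction=pole_fraction,
    )
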