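"""Domain record types shared by the generator and the analysis modules.

Each record is a validated frozen dataclass. Validation happens at
construction so that any list of records downstream code receives already
satisfies the documented invariants (e.g. ``0 < V_spindle < V_cell``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class CellRecord:
    """Morphometry and state of one mitotic cell.

    Volumes in µm³, lengths in µm, mass density in mg·ml⁻¹.
    ``n_astral_true`` is generator-only ground truth (``None`` for real data).
    """

    cell_id: str
    state_label: str
    time_bin_h: float
    V_cell: float
    V_spindle: float
    spindle_length: float
    spindle_width: float
    V_centrosome: float
    mass_density: float
    mean_tubulin_signal: float
    n_astral_true: int | None = None

    def __post_init__(self):
        if not 0 < self.V_spindle < self.V_cell:
            raise ValidationError(
                f"{self.cell_id}: require 0 < V_spindle ({self.V_spindle:.3g}) "
                f"< V_cell ({self.V_cell:.3g})"
            )
        if not 0 < self.V_centrosome < self.V_spindle:
            raise ValidationError(
                f"{self.cell_id}: require 0 < V_centrosome ({self.V_centrosome:.3g}) "
                f"< V_spindle ({self.V_spindle:.3g})"
            )
        if self.mass_density <= 0:
            raise ValidationError(f"{self.cell_id}: mass_density must be positive")
        if self.time_bin_h < 0:
            raise ValidationError(f"{self.cell_id}: time_bin_h must be >= 0")
        if self.spindle_length <= 0 or self.spindle_width <= 0:
            raise ValidationError(f"{self.cell_id}: spindle axes must be positive")
        if self.n_astral_true is not None and self.n_astral_true < 0:
            raise ValidationError(f"{self.cell_id}: n_astral_true must be >= 0")


@dataclass(frozen=True, eq=False)
class FrapTrace:
    """One photobleaching recovery acquisition.

    The default acquisition layout is 3 pre-bleach frames at 1 s per frame, a
    1 s bleach gap, then 35 post-bleach frames at 1 s per frame.
    ``bleach_index`` is the index of the first post-bleach frame within the
    arrays (pre-bleach frames occupy ``0 .. bleach_index-1``).
    """

    frame_times: np.ndarray
    bleach_roi: np.ndarray
    control_roi: np.ndarray
    bleach_index: int
    t_half_true: float | None = None

    def __post_init__(self):
        times = _as_float_array(self.frame_times, "frame_times")
        bleach = _as_float_array(self.bleach_roi, "bleach_roi")
        control = _as_float_array(self.control_roi, "control_roi")
        object.__setattr__(self, "frame_times", times)
        object.__setattr__(self, "bleach_roi", bleach)
        object.__setattr__(self, "control_roi", control)
        if not (len(times) == len(bleach) == len(control)):
            raise ValidationError("frame_times, bleach_roi, control_roi lengths differ")
        if np.any(np.diff(times) <= 0):
            raise ValidationError("frame_times must be strictly increasing")
        if np.any(bleach < 0) or np.any(control < 0):
            raise ValidationError("ROI intensities must be non-negative")
        if not 0 < self.bleach_index < len(times):
            raise ValidationError("bleach_index must split the trace into pre and post")

    @property
    def n_pre(self) -> int:
        return self.bleach_index

    @property
    def n_post(self) -> int:
        return len(self.frame_times) - self.bleach_index


@dataclass(frozen=True, eq=False)
class CometTrack:
    """One plus-end comet trajectory: (x, y) positions at a fixed frame rate.

    ``start_frame`` is the video frame index of the first position. The track
    duration used for filtering counts every imaged frame:
    ``n_frames * frame_interval``.
    """

    cell_id: str
    track_id: str
    positions: np.ndarray
    frame_interval: float = 0.4
    quality: np.ndarray | None = None
    compartment: str = "bulk"
    start_frame: int = 0

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValidationError("positions must be an (n, 2) array")
        if pos.shape[0] < 2:
            raise ValidationError("a track needs at least 2 positions")
        if not np.all(np.isfinite(pos)):
            raise ValidationError("positions contain non-finite values")
        object.__setattr__(self, "positions", pos)
        if self.frame_interval <= 0:
            raise ValidationError("frame_interval must be positive")
        if self.quality is not None:
            q = _as_float_array(self.quality, "quality")
            if len(q) != pos.shape[0]:
                raise ValidationError("quality must have one value per frame")
            object.__setattr__(self, "quality", q)
        if self.compartment not in ("astral", "bulk"):
            raise ValidationError("compartment must be 'astral' or 'bulk'")
        if self.start_frame < 0:
            raise ValidationError("start_frame must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def duration(self) -> float:
        """Acquisition span in s: every imaged frame counts one interval."""
        return self.n_frames * self.frame_interval

    @property
    def end_frame(self) -> int:
        return self.start_frame + self.n_frames - 1


@dataclass(frozen=True, eq=False)
class HalfSpindleProfile:
    """A pole-to-equator summed-intensity profile, both axes in [0, 1].

    Distance 0 is the spindle pole, distance 1 the equator. Both axes are
    min-max normalized.
    """

    distance: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        d = _as_float_array(self.distance, "distance")
        i = _as_float_array(self.intensity, "intensity")
        object.__setattr__(self, "distance", d)
        object.__setattr__(self, "intensity", i)
        if len(d) != len(i):
            raise ValidationError("distance and intensity lengths differ")
        if len(d) < 2:
            raise ValidationError("a profile needs at least 2 samples")
        if np.any(np.diff(d) <= 0):
            raise ValidationError("distance must be strictly increasing")
        for name, arr in (("distance", d), ("intensity", i)):
            if arr.min() < -1e-12 or arr.max() > 1 + 1e-12:
                raise ValidationError(f"{name} must be min-max normalized to [0, 1]")


@dataclass(frozen=True)
class BlotDataset:
    """A quantitative immunoblot: tubulin standards plus whole-lysate lanes.

    ``standards`` are (loaded tubulin mass in ng, band signal) pairs.
    ``lysate_lanes`` are (loaded total protein in µg, band signal, Coomassie
    total-protein signal from the replica gel) triples.
    """

    standards: tuple[tuple[float, float], ...]
    lysate_lanes: tuple[tuple[float, float, float], ...]

    def __post_init__(self):
        standards = tuple((float(m), float(s)) for m, s in self.standards)
        lanes = tuple((float(l), float(s), float(c)) for l, s, c in self.lysate_lanes)
        object.__setattr__(self, "standards", standards)
        object.__setattr__(self, "lysate_lanes", lanes)
        if len(standards) < 2:
            raise ValidationError("need at least 2 tubulin standards")
        masses = [m for m, _ in standards]
        if len(set(masses)) < 2:
            raise ValidationError("standards must span at least 2 distinct masses")
        if any(m <= 0 for m in masses) or any(s < 0 for _, s in standards):
            raise ValidationError("standard masses must be positive, signals >= 0")
        for load, signal, coomassie in lanes:
            if load <= 0:
                raise ValidationError("lane loads must be positive")
            if signal < 0 or coomassie < 0:
                raise ValidationError("lane signals must be >= 0")


@dataclass(frozen=True, eq=False)
class Lineage:
    """Division times (s) of one tracked cell family, strictly increasing."""

    division_times: np.ndarray

    def __post_init__(self):
        t = _as_float_array(self.division_times, "division_times")
        object.__setattr__(self, "division_times", t)
        if len(t) >= 2 and np.any(np.diff(t) <= 0):
            raise ValidationError("division_times must be strictly increasing")


@dataclass(frozen=True)
class RIMeasurement:
    """Cell-averaged raw refractive index in the x10,000 integer convention.

    ``ri_raw`` is the voxel-averaged refractive index scaled by 10,000 (the
    tomogram export convention); ``ri_medium`` is the refractometer value for
    the imaging medium of that experiment.
    """

    ri_raw: float
    ri_medium: float

    def __post_init__(self):
        if self.ri_raw <= 0:
            raise ValidationError("ri_raw must be positive")
        if not 1.30 <= self.ri_medium <= 1.40:
            raise ValidationError("ri_medium outside the plausible range 1.30-1.40")
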