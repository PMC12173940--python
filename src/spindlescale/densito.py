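"""Refractive-index to mass-density conversion and blot densitometry.

Cellular mass density (dry mass per volume, mg·ml⁻¹) follows from the cell-
averaged refractive index through the protein refraction increment
(0.19 ml·g⁻¹)::

    rho = ((ri_raw / 10,000 - ri_medium) * 1,000) / 0.19

where ``ri_raw`` is the tomogram's voxel-averaged refractive index in the
x10,000 integer export convention and ``ri_medium`` the per-experiment
refractometer reading of the imaging medium.

Quantitative immunoblots are calibrated with a least-squares line through
purified-tubulin standards; lysate-lane band signals are back-calculated to
tubulin mass and expressed as a percentage of the Coomassie-corrected total
protein load.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, ValidationError
from .records import BlotDataset, RIMeasurement

#: Protein refraction increment, ml·g⁻¹.
REFRACTION_INCREMENT = 0.19


def mass_density_from_ri(
    ri_raw: float | np.ndarray,
    ri_medium: float,
    refraction_increment: float = REFRACTION_INCREMENT,
) -> float | np.ndarray:
    """Convert a raw (x10,000) refractive index to mass density (mg·ml⁻¹).

    Linear in ``ri_raw``; a voxel average below the medium RI yields a
    negative density, which is returned as-is so callers can flag it (a cell
    mask that dips below the medium indicates a segmentation problem, not a
    physical density).
    """
    ri_raw = np.asarray(ri_raw, dtype=float)
    if np.any(ri_raw <= 0):
        raise ValidationError("ri_raw must be positive")
    if not 1.30 <= ri_medium <= 1.40:
        raise ValidationError("ri_medium outside the plausible range 1.30-1.40")
    rho = ((ri_raw / 10000.0 - ri_medium) * 1000.0) / refraction_increment
    return float(rho) if rho.ndim == 0 else rho


def densities_from_measurements(
    measurements: Sequence[RIMeasurement],
) -> np.ndarray:
    """Vectorized conversion of :class:`RIMeasurement` records."""
    return np.array([
        mass_density_from_ri(m.ri_raw, m.ri_medium) for m in measurements
    ])


def average_masked_ri(
    voxel_values: Sequence[float] | np.ndarray,
    mask: Sequence[bool] | np.ndarray,
) -> float:
    """Arithmetic mean of raw RI voxel values inside a 3D cell mask."""
    values = np.asarray(voxel_values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValidationError("voxel_values and mask shapes differ")
    if not mask.any():
        raise ValidationError("mask selects no voxels")
    return float(values[mask].mean())


@dataclass(frozen=True)
class CalibrationCurve:
    """Least-squares line through the tubulin standards: signal per ng."""

    slope: float
    intercept: float
    r_squared: float

    def mass_from_signal(self, signal: float | np.ndarray):
        """Back-calculate loaded tubulin mass (ng) from a band signal."""
        out = (np.asarray(signal, dtype=float) - self.intercept) / self.slope
        return float(out) if out.ndim == 0 else out


def fit_calibration(
    standards: Sequence[tuple[float, float]],
) -> CalibrationCurve:
    """Ordinary least squares calibration line through (ng, signal) pairs."""
    if len(standards) < 2:
        raise ValidationError("need at least 2 standards")
    masses = np.array([m for m, _ in standards], dtype=float)
    signals = np.array([s for _, s in standards], dtype=float)
    if np.all(masses == masses[0]):
        raise DegenerateDataError("standards with identical masses cannot calibrate")
    res = stats.linregress(masses, signals)
    if res.slope <= 0:
        raise DegenerateDataError("non-positive calibration slope: invalid blot")
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


@dataclass(frozen=True)
class TubulinQuantification:
    """Tubulin mass fraction of total protein, per lane and averaged."""

    fraction_percent: float
    per_lane_percent: tuple[float, ...]
    flagged_lanes: tuple[int, ...]
    calibration: CalibrationCurve


def quantify_tubulin_fraction(
    blot: BlotDataset,
    coomassie_correction: bool = True,
) -> TubulinQuantification:
    """Tubulin as a percentage of total cellular protein mass.

    Per lane: ``tubulin_ng = (signal - intercept) / slope`` from the
    calibration line; ``fraction = 100 * tubulin_ng / (load_µg * 1,000 *
    correction)``. The Coomassie correction rescales each lane's nominal
    load by its Coomassie signal relative to the blot-wide signal-per-µg
    (unweighted mean over lanes), compensating uneven loading. Lanes whose
    back-calculated mass is negative are flagged and excluded from the
    (unweighted) average.
    """
    calibration = fit_calibration(blot.standards)
    loads = np.array([l for l, _, _ in blot.lysate_lanes])
    signals = np.array([s for _, s, _ in blot.lysate_lanes])
    coomassie = np.array([c for _, _, c in blot.lysate_lanes])

    if coomassie_correction:
        per_ug = coomassie / loads
        expectation = per_ug.mean()
        if expectation <= 0:
            raise DegenerateDataError("zero Coomassie signal: cannot normalize")
        correction = (coomassie / (expectation * loads))
    else:
        correction = np.ones_like(loads)

    tubulin_ng = calibration.mass_from_signal(signals)
    fractions = 100.0 * tubulin_ng / (loads * 1000.0 * correction)
    flagged = tuple(int(i) for i in np.nonzero(tubulin_ng < 0)[0])
    usable = [f for i, f in enumerate(fractions) if i not in flagged]
    if not usable:
        raise DegenerateDataError("all lanes flagged: no usable quantification")
    return TubulinQuantification(
        fraction_percent=float(np.mean(usable)),
        per_lane_percent=tuple(float(f) for f in fractions),
        flagged_lanes=flagged,
        calibration=calibration,
    )
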