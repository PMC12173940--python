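"""FRAP trace preprocessing and exponential recovery fitting.

Raw bleach-ROI signals are corrected for acquisition photobleaching with a
control ROI (ratio correction, control rescaled to its pre-bleach mean) and
min-max normalized. Post-bleach frames, re-zeroed at the first post-bleach
frame, are then fit to ``A (1 - exp(-t/tau)) + C`` by nonlinear least
squares; the recovery half-time is ``t_half = tau * ln 2``.

Because time re-zeroing and min-max normalization are affine in t and in
intensity respectively, they change A and C but leave tau — and therefore
the half-time — invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import DegenerateDataError, FitError, ValidationError
from .records import FrapTrace

#: Fits with tau beyond this multiple of the post-bleach observation window
#: are refused as non-identifiable.
MAX_TAU_WINDOW_RATIO = 10.0

#: Fits with tau beyond this fraction of the window are kept but flagged as
#: weakly constrained.
TAU_QC_WINDOW_FRACTION = 0.75


@dataclass(frozen=True, eq=False)
class CorrectedTrace:
    """A bleach-corrected, min-max normalized trace ready for fitting."""

    frame_times: np.ndarray
    intensity: np.ndarray
    bleach_index: int

    @property
    def post_times(self) -> np.ndarray:
        return self.frame_times[self.bleach_index:]

    @property
    def post_intensity(self) -> np.ndarray:
        return self.intensity[self.bleach_index:]


@dataclass(frozen=True)
class FrapFit:
    """Fitted exponential recovery parameters (normalized intensity units).

    ``well_constrained`` is a QC flag: False when the fitted time constant
    is comparable to the observation window (tau beyond
    :data:`TAU_QC_WINDOW_FRACTION` of it), where the plateau — and hence the
    half-time — is largely extrapolated.
    """

    A: float
    tau: float
    C: float
    t_half: float
    residual_rms: float
    well_constrained: bool = True

    def __post_init__(self):
        if self.tau <= 0:
            raise ValidationError("tau must be positive")
        if self.A < 0:
            raise ValidationError("A must be non-negative")
        if not math.isclose(self.t_half, self.tau * math.log(2),
                            rel_tol=1e-12):
            raise ValidationError("t_half must equal tau * ln 2")


def preprocess_trace(
    trace: FrapTrace,
    normalize_over: str = "full",
) -> CorrectedTrace:
    """Bleach-correct and normalize a raw FRAP trace.

    The bleach ROI is divided pointwise by the control ROI rescaled to its
    pre-bleach mean (removing the shared acquisition-photobleaching decay),
    then min-max normalized. ``normalize_over`` selects whether the min-max
    span covers the ``"full"`` trace (default) or only the ``"post"`` bleach
    frames. A corrected trace with (numerically) zero range raises
    :class:`DegenerateDataError`.
    """
    if normalize_over not in ("full", "post"):
        raise ValidationError("normalize_over must be 'full' or 'post'")
    control = trace.control_roi
    if np.any(control <= 0):
        raise ValidationError("control ROI must be strictly positive")
    pre_mean = control[: trace.bleach_index].mean()
    corrected = trace.bleach_roi / (control / pre_mean)
    span_vals = (corrected if normalize_over == "full"
                 else corrected[trace.bleach_index:])
    lo, hi = float(span_vals.min()), float(span_vals.max())
    if hi - lo < 1e-12 * max(1.0, abs(hi)):
        raise DegenerateDataError(
            "corrected trace has zero range; min-max normalization undefined"
        )
    normalized = (corrected - lo) / (hi - lo)
    return CorrectedTrace(
        frame_times=trace.frame_times.copy(),
        intensity=normalized,
        bleach_index=trace.bleach_index,
    )


def _recovery(t, A, tau, C):
    return A * (1.0 - np.exp(-t / tau)) + C


def fit_recovery(times: np.ndarray, normalized: np.ndarray) -> FrapFit:
    """Fit the exponential recovery to post-bleach samples.

    ``times`` are the post-bleach frame times (any origin; they are re-zeroed
    at the first frame), ``normalized`` the corrected intensities.
    Initialization: ``A0 = plateau - first``, ``C0 = first``, ``tau0`` the
    time at which the curve first passes half way to the plateau. Fits whose
    tau exceeds 10x the observation window are refused (non-identifiable on
    this window); non-convergence raises :class:`FitError` with diagnostics.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(normalized, dtype=float)
    if len(t) != len(y):
        raise ValidationError("times and intensities must have equal length")
    if len(t) < 5:
        raise ValidationError("need at least 5 post-bleach samples")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")
    t = t - t[0]
    window = float(t[-1])

    first = float(y[0])
    plateau = float(np.mean(y[-max(3, len(y) // 5):]))
    A0 = max(plateau - first, 1e-6)
    C0 = first
    half_level = C0 + A0 / 2.0
    above = np.nonzero(y >= half_level)[0]
    tau0 = float(t[above[0]]) if len(above) and t[above[0]] > 0 else window / 5.0

    p0 = (A0, tau0, C0)
    try:
        popt, _ = optimize.curve_fit(
            _recovery, t, y, p0=p0,
            bounds=((0.0, 1e-9, -np.inf), (np.inf, np.inf, np.inf)),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError("recovery fit did not converge",
                       {"p0": p0, "message": str(exc)}) from exc
    A, tau, C = (float(v) for v in popt)
    if tau > MAX_TAU_WINDOW_RATIO * window:
        raise FitError(
            f"tau = {tau:.3g} s exceeds {MAX_TAU_WINDOW_RATIO:.0f}x the "
            f"{window:.3g} s observation window; recovery not identifiable",
            {"p0": p0, "tau": tau, "window": window},
        )
    resid = y - _recovery(t, *popt)
    return FrapFit(
        A=A, tau=tau, C=C, t_half=tau * math.log(2),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        well_constrained=tau <= TAU_QC_WINDOW_FRACTION * window,
    )


def fit_trace(trace: FrapTrace, normalize_over: str = "full") -> FrapFit:
    """Preprocess a raw trace and fit its post-bleach recovery."""
    corrected = preprocess_trace(trace, normalize_over=normalize_over)
    return fit_recovery(corrected.post_times, corrected.post_intensity)


def mean_half_time(traces, normalize_over: str = "full"):
    """Fit every trace; return (mean t_half, s.d., per-trace fits).

    The per-condition half-time reported by the pipeline is the mean over
    cells, matching how the recovery statistics are summarized.
    """
    fits = [fit_trace(tr, normalize_over=normalize_over) for tr in traces]
    halves = np.array([f.t_half for f in fits])
    return float(halves.mean()), float(halves.std(ddof=1)), fits
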