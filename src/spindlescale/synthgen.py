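"""Seeded synthetic-data generators for every pipeline stage.

The generators emulate the statistical structure of the study's imaging
data — two-state mitotic cell populations with published volume and density
moments, a spindle-proportional-to-cell-volume law with a state-specific
subscaling factor and log-normal noise, saturating centrosome scaling,
exponential FRAP recovery under acquisition photobleaching, constant-velocity
plus-end comet tracks, pole-weighted half-spindle intensity profiles,
calibration-blot tables and cell-family division lineages.

Every generator takes an explicit integer ``seed`` and is deterministic
under fixed ``(params, n, seed)``.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from . import cpapmodel
from .errors import ValidationError
from .params import StateParams
from .records import (
    BlotDataset,
    CellRecord,
    CometTrack,
    FrapTrace,
    HalfSpindleProfile,
    Lineage,
    RIMeasurement,
)

#: Sharpness of the soft-min used to cap centrosome volume; large values make
#: the cap nearly hard while keeping the volume law smooth near the limit.
_SOFTCAP_SHARPNESS = 12.0

#: Fluorescence gain converting tubulin concentration (mg·ml⁻¹) to the
#: arbitrary mean cellular tubulin signal.
_TUBULIN_SIGNAL_GAIN = 100.0

#: Spindle pole-to-pole length over width for the ellipsoidal shape proxy.
_SPINDLE_ASPECT = 1.4


def _require_count(n: int, name: str = "n"):
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValidationError(f"{name} must be a positive integer, got {n!r}")


def _truncated_normal(rng, mean, sd, n, lower=None):
    """Normal(mean, sd) truncated at max(0, mean - 3 sd) (or ``lower``)."""
    if sd == 0:
        return np.full(n, float(mean))
    lo = max(0.0, mean - 3.0 * sd) if lower is None else lower
    a = (lo - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n,
                               random_state=rng)


def _soft_cap(x: np.ndarray, cap: float | None) -> np.ndarray:
    """Smooth minimum of ``x`` and ``cap`` via a p-norm soft-min.

    Close to the identity well below the cap (<3% reduction at 0.8 cap for
    the default sharpness) and asymptotically equal to ``cap`` above it.
    """
    if cap is None:
        return x
    k = _SOFTCAP_SHARPNESS
    return (x**-k + cap**-k) ** (-1.0 / k)


def generate_cell_population(
    params: StateParams,
    n: int,
    seed: int,
    model: "cpapmodel.ModelParams | None" = None,
) -> list[CellRecord]:
    """Draw ``n`` mitotic cell records for one state.

    Cell volume follows a truncated normal with the state's published
    moments. Spindle volume is proportional to cell volume — reduced by the
    state's subscaling factor — with multiplicative log-normal noise.
    Centrosome volume is a fixed fraction of cell volume, soft-capped where
    the state defines an upper limit. Mass density is an independent
    truncated normal. The astral-count ground truth ``n_astral_true`` is a
    Poisson draw around the limiting-component forward model.
    """
    _require_count(n)
    if model is None:
        model = cpapmodel.model_params_for_state(params)
    rng = np.random.default_rng(seed)

    V_cell = _truncated_normal(rng, params.cell_volume_mean,
                               params.cell_volume_sd, n)
    eps = (rng.normal(0.0, params.scaling_noise_sd, n)
           if params.scaling_noise_sd > 0 else np.zeros(n))
    s_g = params.spindle_fraction * (1.0 - params.subscaling_factor)
    V_spindle = s_g * V_cell * np.exp(eps)
    # Guard: the log-normal tail must never produce a spindle that fills the
    # cell; resample-free clip at 90% of cell volume (astronomically rare at
    # the default noise level).
    V_spindle = np.minimum(V_spindle, 0.9 * V_cell)

    eta = (rng.normal(0.0, params.centrosome_noise_sd, n)
           if params.centrosome_noise_sd > 0 else np.zeros(n))
    V_centrosome = _soft_cap(params.centrosome_fraction * V_cell * np.exp(eta),
                             params.centrosome_cap)
    V_centrosome = np.minimum(V_centrosome, 0.9 * V_spindle)

    rho = _truncated_normal(rng, params.mass_density_mean,
                            params.mass_density_sd, n)

    time_bins = np.asarray(params.time_bins_h, dtype=float)
    t_bin = rng.choice(time_bins, size=n)

    mean_N = cpapmodel.mechanistic_astral_mean(V_cell, V_spindle, model)
    n_astral = rng.poisson(np.clip(mean_N, 0.0, None))

    signal = (_TUBULIN_SIGNAL_GAIN * cpapmodel.TUBULIN_MASS_FRACTION * rho
              * np.exp(rng.normal(0.0, 0.05, n)))

    # Prolate-ellipsoid shape proxy: V = (pi/6) L W^2 with fixed aspect L/W.
    width = np.cbrt(6.0 * V_spindle / (math.pi * _SPINDLE_ASPECT))
    length = _SPINDLE_ASPECT * width

    label = params.state_label
    return [
        CellRecord(
            cell_id=f"{label}-{i:05d}",
            state_label=label,
            time_bin_h=float(t_bin[i]),
            V_cell=float(V_cell[i]),
            V_spindle=float(V_spindle[i]),
            spindle_length=float(length[i]),
            spindle_width=float(width[i]),
            V_centrosome=float(V_centrosome[i]),
            mass_density=float(rho[i]),
            mean_tubulin_signal=float(signal[i]),
            n_astral_true=int(n_astral[i]),
        )
        for i in range(n)
    ]


def generate_frap_traces(
    params: StateParams,
    n: int,
    seed: int,
    n_pre: int = 3,
    n_post: int = 35,
    frame_interval: float = 1.0,
    bleach_gap: float = 1.0,
    bleach_depth: float = 0.6,
    acquisition_decay_rate: float = 0.004,
    noise_sd: float = 0.02,
    plateau: float = 1.0,
) -> list[FrapTrace]:
    """Draw ``n`` photobleaching recovery traces.

    Layout: ``n_pre`` pre-bleach frames, a ``bleach_gap`` with no frame, then
    ``n_post`` post-bleach frames. The underlying recovery is
    ``A (1 - exp(-t/tau)) + C`` with per-trace half-time drawn from a
    positive-truncated normal around the state's ``frap_t_half``; the bleach
    removes ``bleach_depth`` of the plateau signal. Both ROIs decay with a
    shared mono-exponential acquisition-photobleaching rate; i.i.d. Gaussian
    noise of ``noise_sd`` (relative to the plateau) is added per frame.
    """
    _require_count(n)
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    if not 0 < bleach_depth <= 1:
        raise ValidationError("bleach_depth must lie in (0, 1]")
    if acquisition_decay_rate < 0:
        raise ValidationError("acquisition_decay_rate must be non-negative")
    rng = np.random.default_rng(seed)

    pre_times = np.arange(n_pre) * frame_interval
    post_times = (pre_times[-1] + bleach_gap
                  + np.arange(1, n_post + 1) * frame_interval)
    times = np.concatenate([pre_times, post_times])

    traces = []
    for i in range(n):
        t_half = float(_truncated_normal(rng, params.frap_t_half,
                                         params.frap_t_half_sd, 1,
                                         lower=1e-3)[0])
        tau = t_half / math.log(2)
        C = plateau * (1.0 - bleach_depth)
        A = plateau - C  # full recovery towards the pre-bleach plateau
        t_rel = post_times - post_times[0] + frame_interval  # time since bleach end
        ideal = np.concatenate([
            np.full(n_pre, plateau),
            A * (1.0 - np.exp(-t_rel / tau)) + C,
        ])
        decay = np.exp(-acquisition_decay_rate * times)
        bleach_roi = ideal * decay
        control_roi = plateau * decay
        if noise_sd > 0:
            bleach_roi = bleach_roi + rng.normal(0.0, noise_sd, len(times))
            control_roi = control_roi + rng.normal(0.0, noise_sd, len(times))
        traces.append(FrapTrace(
            frame_times=times.copy(),
            bleach_roi=np.clip(bleach_roi, 0.0, None),
            control_roi=np.clip(control_roi, 1e-6, None),
            bleach_index=n_pre,
            t_half_true=t_half,
        ))
    return traces


def generate_comet_tracks(
    params: StateParams,
    n_cells: int,
    tracks_per_cell: int,
    seed: int,
    frame_interval: float = 0.4,
    duration_range_s: tuple[float, float] = (1.2, 4.8),
    astral_odds: float = 0.25,
    video_frames: int = 150,
    quality_mean: float = 400.0,
    quality_sd: float = 120.0,
) -> list[CometTrack]:
    """Draw straight-line plus-end comet tracks for ``n_cells`` cells.

    Per-track growth speed is a positive-truncated normal around the state's
    comet speed. Track durations are uniform over ``duration_range_s``, which
    deliberately spans beyond the 2-4 s retention window so that duration
    filtering has work to do. ``astral_odds`` is the probability of the
    astral compartment label; per-frame quality is Gaussian around
    ``quality_mean``.
    """
    _require_count(n_cells, "n_cells")
    _require_count(tracks_per_cell, "tracks_per_cell")
    if duration_range_s[0] <= 0 or duration_range_s[1] <= duration_range_s[0]:
        raise ValidationError("duration_range_s must be an increasing positive pair")
    if not 0 <= astral_odds <= 1:
        raise ValidationError("astral_odds must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    tracks = []
    for c in range(n_cells):
        cell_id = f"{params.state_label}-cell-{c:04d}"
        for t in range(tracks_per_cell):
            speed = float(_truncated_normal(rng, params.comet_speed_mean,
                                            params.comet_speed_sd, 1,
                                            lower=0.0)[0])
            duration = float(rng.uniform(*duration_range_s))
            n_frames = max(2, int(round(duration / frame_interval)))
            start = int(rng.integers(0, max(1, video_frames - n_frames + 1)))
            theta = float(rng.uniform(0.0, 2.0 * math.pi))
            origin = rng.uniform(-5.0, 5.0, size=2)
            step = speed * frame_interval * np.array([math.cos(theta),
                                                      math.sin(theta)])
            positions = origin + np.outer(np.arange(n_frames), step)
            quality = rng.normal(quality_mean, quality_sd, n_frames)
            compartment = "astral" if rng.random() < astral_odds else "bulk"
            tracks.append(CometTrack(
                cell_id=cell_id,
                track_id=f"{cell_id}-tr{t:04d}",
                positions=positions,
                frame_interval=frame_interval,
                quality=np.clip(quality, 0.0, None),
                compartment=compartment,
                start_frame=start,
            ))
    return tracks


def _profile_components(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-mass pole-peaked and equator-weighted profile components."""
    return 3.0 * (1.0 - x) ** 2, 3.0 * x**2


def _normalized_pole_share(w: float, x: np.ndarray) -> float:
    """Pole-half integral share of the min-max normalized mixture."""
    g_pole, g_eq = _profile_components(x)
    m = w * g_pole + (1.0 - w) * g_eq
    m = m - m.min()
    total = np.trapezoid(m, x)
    if total <= 0:
        return 0.5
    half = np.trapezoid(np.where(x <= 0.5, m, 0.0), x)
    return float(half / total)


def _solve_mixture_weight(target: float, x: np.ndarray) -> float:
    """Mixture weight whose *normalized* profile has the target pole share."""
    lo_share = _normalized_pole_share(0.0, x)
    hi_share = _normalized_pole_share(1.0, x)
    if not lo_share < target < hi_share:
        raise ValidationError(
            f"pole_fraction_mean {target:.3f} outside the attainable range "
            f"({lo_share:.3f}, {hi_share:.3f}) of the profile mixture"
        )
    from scipy.optimize import brentq

    return float(brentq(lambda w: _normalized_pole_share(w, x) - target,
                        0.0, 1.0, xtol=1e-10))


def generate_half_spindle_profiles(
    params: StateParams,
    n: int,
    seed: int,
    n_points: int = 101,
    noise_sd: float = 0.02,
) -> list[HalfSpindleProfile]:
    """Draw ``n`` pole-to-equator intensity profiles.

    Each profile is a two-component mixture — a pole-peaked and an
    equator-weighted quadratic — whose weight is solved so that, after the
    min-max normalization the profile convention requires, the expected
    integral share over the pole half (distance 0-0.5) equals the state's
    ``pole_fraction_mean``. Gaussian intensity noise is added before the
    final normalization.
    """
    _require_count(n)
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, 1.0, n_points)
    w = _solve_mixture_weight(params.pole_fraction_mean, x)
    g_pole, g_eq = _profile_components(x)
    base = w * g_pole + (1.0 - w) * g_eq

    profiles = []
    for _ in range(n):
        y = base + (rng.normal(0.0, noise_sd, n_points) if noise_sd > 0 else 0.0)
        y = y - y.min()
        rng_span = y.max()
        if rng_span <= 0:  # pragma: no cover - flat profile only at w=0.5, noise 0
            y = np.full_like(y, 0.5)
        else:
            y = y / rng_span
        profiles.append(HalfSpindleProfile(distance=x.copy(), intensity=y))
    return profiles


def generate_blot_dataset(
    true_tubulin_percent: float,
    standards_ng: list[float] | tuple[float, ...] = (25.0, 50.0, 100.0),
    lane_loads_ug: list[float] | tuple[float, ...] = (4.0, 2.0, 1.0),
    noise_cv: float = 0.0,
    seed: int = 0,
    slope_signal_per_ng: float = 20.0,
    coomassie_per_ug: float = 500.0,
) -> BlotDataset:
    """Build a synthetic quantitative immunoblot.

    Standard band signals are linear in loaded tubulin mass; lysate band
    signals are linear in the tubulin contained in each total-protein load at
    the given true mass percentage; Coomassie total-protein signals are
    proportional to load. ``noise_cv`` applies independent multiplicative
    log-normal noise to every band.
    """
    if not 0 < true_tubulin_percent < 100:
        raise ValidationError("true_tubulin_percent must lie in (0, 100)")
    if len(standards_ng) < 2:
        raise ValidationError("need at least 2 tubulin standards")
    if noise_cv < 0:
        raise ValidationError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)

    def jitter():
        if noise_cv == 0:
            return 1.0
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        return float(rng.lognormal(-sigma**2 / 2.0, sigma))

    standards = tuple(
        (float(ng), slope_signal_per_ng * float(ng) * jitter())
        for ng in standards_ng
    )
    lanes = []
    for load in lane_loads_ug:
        tubulin_ng = float(load) * 1000.0 * true_tubulin_percent / 100.0
        lanes.append((
            float(load),
            slope_signal_per_ng * tubulin_ng * jitter(),
            coomassie_per_ug * float(load) * jitter(),
        ))
    return BlotDataset(standards=standards, lysate_lanes=tuple(lanes))


def generate_lineages(
    mean_cycle_s: float,
    sd_s: float,
    total_duration_s: float,
    n_families: int,
    seed: int,
) -> list[Lineage]:
    """Draw division-time lineages with i.i.d. truncated-normal intercycle
    intervals accumulated until ``total_duration_s``."""
    if mean_cycle_s <= 0 or sd_s < 0 or total_duration_s <= 0:
        raise ValidationError("cycle mean/duration must be positive, sd >= 0")
    if total_duration_s < mean_cycle_s:
        # A recording shorter than one cycle yields empty-interval lineages.
        pass
    _require_count(n_families, "n_families")
    rng = np.random.default_rng(seed)

    lineages = []
    for _ in range(n_families):
        times = [0.0]
        while True:
            interval = float(_truncated_normal(rng, mean_cycle_s, sd_s, 1,
                                               lower=1e-6)[0])
            nxt = times[-1] + interval
            if nxt > total_duration_s:
                break
            times.append(nxt)
        lineages.append(Lineage(division_times=np.array(times)))
    return lineages


def generate_ri_measurements(
    params: StateParams,
    n: int,
    seed: int,
    ri_medium: float = 1.337,
    refraction_increment: float = 0.19,
) -> list[RIMeasurement]:
    """Synthesize cell-averaged raw refractive indices for a state.

    Per-cell mass density is drawn from the state's truncated normal and
    mapped to the x10,000 integer raw-RI convention through the inverse of
    the density conversion (``ri_raw = round((ri_medium + rho * 0.19/1000) *
    10,000)``), emulating the tomogram export quantization.
    """
    _require_count(n)
    rng = np.random.default_rng(seed)
    rho = _truncated_normal(rng, params.mass_density_mean,
                            params.mass_density_sd, n)
    ri_raw = np.rint((ri_medium + rho * refraction_increment / 1000.0) * 10000.0)
    return [RIMeasurement(ri_raw=float(r), ri_medium=ri_medium) for r in ri_raw]
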