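"""Limiting-component model of astral microtubule number.

The model links cell volume, spindle volume and cytoplasmic tubulin to the
number of astral microtubules through a centrosomal regulator (CPAP) that is
inhibited by soluble tubulin:

1.  Tubulin mass balance. The total tubulin concentration ``c_tot`` (mg·ml⁻¹,
    numerically identical to fg·µm⁻³) is split between polymer in the spindle
    bulk (``rho_poly`` per unit spindle volume) and the free pool::

        c_free = (c_tot * V_cell - rho_poly * V_spindle) / V_cell

2.  CPAP liberation. Free tubulin binds CPAP with half-inhibition constant
    ``K_d`` (single-site equilibrium, tubulin in excess), so the free CPAP
    fraction is ``f_free = K_d / (K_d + c_free)``. A more dilute cytoplasm
    (lower ``c_tot``) means less free tubulin and therefore more free CPAP.

3.  Astral number. Centrosomal nucleation capacity saturates with cell
    volume; the astral microtubule count follows a Michaelis-Menten curve in
    cell volume whose plateau is proportional to the free CPAP amount::

        N(V) = N_sat * V / (K_V + V),   N_sat = alpha * cpap_total * f_free

Counting astral microtubules from morphometry inverts the observation that
the total microtubule (comet) number per cell volume ``n_V`` is constant:
``N_astral = n_V * V_cell - lambda_bulk * V_spindle``, with ``lambda_bulk``
the bulk microtubule number per unit spindle volume.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import integrate, optimize, stats

from .errors import DegenerateDataError, FitError, ValidationError
from .params import StateParams, state_defaults
from .records import CellRecord

#: Tubulin share of total protein mass, as quantified by immunoblot (~1.5%).
TUBULIN_MASS_FRACTION = 0.015

#: Polymer tubulin mass per unit spindle volume (mg·ml⁻¹). Calibration
#: parameter; must stay below c_tot / spindle_fraction for mass balance.
DEFAULT_RHO_POLY = 1.5

#: CPAP-tubulin half-inhibition concentration (mg·ml⁻¹). Free parameter.
DEFAULT_KD = 0.3

#: CPAP copies per cell (arbitrary count units). Free parameter; together
#: with alpha it sets the astral-count scale (ESC plateau ~ 60).
DEFAULT_CPAP_TOTAL = 420.0

#: Astral microtubules nucleated per free CPAP unit.
DEFAULT_ALPHA = 1.0

#: Half-saturation cell volume of centrosomal nucleation (µm³); the astral
#: count levels off above roughly twice this volume.
DEFAULT_KV = 1500.0

#: Total microtubule (comet) number per unit cell volume (µm⁻³), shared by
#: all states. Frozen from the self-consistency relation
#: n_V = (E[N_astral] + lambda_bulk * E[V_spindle]) / E[V_cell]
#: evaluated for the ESC defaults with lambda_bulk = 0.30 (docs/methods.md).
DEFAULT_N_V = 0.07555

#: Bulk microtubule number per unit spindle volume (µm⁻³), per state. The
#: ESC value is the chosen anchor; other states are frozen from the same
#: consistency relation at the shared n_V so that the total comet number per
#: cell volume is state-independent.
DEFAULT_LAMBDA_BULK = {
    "ESC": 0.30,
    "DIF": 0.36580,
    "ISO": 0.28710,
    "HYPO": 0.34346,
    "DMSO": 0.30,
    "CCB02": 0.19237,
}

#: Cell-volume bin edges (µm³) for saturation-curve fitting: 500 µm³ bins
#: across the full sampled volume range, so the high-volume bins constrain
#: the plateau.
MODEL_BIN_EDGES = tuple(float(e) for e in range(500, 5500, 500))

#: Effective K_d multiplier per state. CCB02 competitively displaces tubulin
#: from CPAP, modelled as a larger effective half-inhibition constant.
KD_SCALE = {"CCB02": 5.0}


@dataclass(frozen=True)
class ModelParams:
    """Constants of the CPAP-tubulin limiting-component model.

    Units: concentrations in mg·ml⁻¹ (≡ fg·µm⁻³), volumes in µm³, counts
    dimensionless. ``n_V`` and ``lambda_bulk`` are number densities (µm⁻³).
    """

    c_tot: float
    rho_poly: float = DEFAULT_RHO_POLY
    K_d: float = DEFAULT_KD
    cpap_total: float = DEFAULT_CPAP_TOTAL
    n_V: float = DEFAULT_N_V
    lambda_bulk: float = DEFAULT_LAMBDA_BULK["ESC"]
    alpha: float = DEFAULT_ALPHA
    K_V: float = DEFAULT_KV

    def __post_init__(self):
        for name in ("c_tot", "rho_poly", "K_d", "cpap_total", "n_V",
                     "lambda_bulk", "alpha", "K_V"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")

    def with_overrides(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


def model_params_for_state(state: StateParams | str, **overrides) -> ModelParams:
    """Default :class:`ModelParams` for a cell state.

    ``c_tot`` is derived from the state's mass density via the measured
    tubulin share of protein mass (1.5%), e.g. 0.015 x 140 = 2.1 mg·ml⁻¹ for
    ESCs. ``lambda_bulk`` comes from the per-state consistency table.
    """
    if isinstance(state, str):
        state = state_defaults(state)
    fields = dict(
        c_tot=TUBULIN_MASS_FRACTION * state.mass_density_mean,
        lambda_bulk=DEFAULT_LAMBDA_BULK.get(state.state_label,
                                            DEFAULT_LAMBDA_BULK["ESC"]),
        K_d=DEFAULT_KD * KD_SCALE.get(state.state_label, 1.0),
    )
    fields.update(overrides)
    return ModelParams(**fields)


def free_tubulin_concentration(
    V_cell: float | np.ndarray,
    V_spindle: float | np.ndarray,
    params: ModelParams,
) -> np.ndarray | float:
    """Free tubulin concentration from the cellular tubulin mass balance.

    ``c_free = (c_tot * V_cell - rho_poly * V_spindle) / V_cell``, clipped at
    zero. A violated mass balance (more polymer than total tubulin) is
    clipped rather than propagated; callers that need to exclude such records
    should check admissibility first (see :func:`estimate_astral_counts`).
    """
    V_cell = np.asarray(V_cell, dtype=float)
    V_spindle = np.asarray(V_spindle, dtype=float)
    if np.any(V_cell <= 0):
        raise ValidationError("V_cell must be positive")
    if np.any(V_spindle < 0) or np.any(V_spindle >= V_cell):
        raise ValidationError("require 0 <= V_spindle < V_cell")
    c_free = (params.c_tot * V_cell - params.rho_poly * V_spindle) / V_cell
    out = np.clip(c_free, 0.0, None)
    return float(out) if out.ndim == 0 else out


def cpap_free_fraction(c_free, K_d: float):
    """Fraction of CPAP not inhibited by soluble tubulin.

    Single-site binding equilibrium with tubulin in excess:
    ``f = K_d / (K_d + c_free)``; 1 with no free tubulin, 1/2 at ``c_free ==
    K_d``, and approaches 0 under saturating inhibition.
    """
    c_free = np.asarray(c_free, dtype=float)
    if K_d <= 0:
        raise ValidationError("K_d must be positive")
    if np.any(c_free < 0):
        raise ValidationError("c_free must be non-negative")
    f = K_d / (K_d + c_free)
    return float(f) if f.ndim == 0 else f


def predict_astral_count(
    V_cell,
    f_free,
    fit: "SaturationFit | None" = None,
    params: ModelParams | None = None,
):
    """Astral microtubule number predicted at cell volume ``V_cell``.

    With a :class:`SaturationFit`, evaluates the fitted curve scaled to the
    supplied free-CPAP fraction relative to the fit's reference (``f_free``
    multiplies the plateau). With :class:`ModelParams`, the plateau is
    computed mechanistically as ``alpha * cpap_total * f_free``. The curve is
    strictly increasing in V and bounded by the plateau.
    """
    V = np.asarray(V_cell, dtype=float)
    if np.any(V <= 0):
        raise ValidationError("V_cell must be positive")
    f = np.asarray(f_free, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise ValidationError("f_free must lie in [0, 1]")
    if (fit is None) == (params is None):
        raise ValidationError("supply exactly one of fit= or params=")
    if fit is not None:
        n_sat = fit.N_sat * f
        K_V = fit.K_V
    else:
        n_sat = params.alpha * params.cpap_total * f
        K_V = params.K_V
    out = n_sat * V / (K_V + V)
    return float(out) if out.ndim == 0 else out


def mechanistic_astral_mean(records_V_cell, records_V_spindle,
                            params: ModelParams):
    """Compose the full mechanistic chain into an expected astral count.

    mass balance -> CPAP liberation -> saturating nucleation. This is the
    generator's forward model; per-cell ground truth adds Poisson noise.
    """
    c_free = free_tubulin_concentration(records_V_cell, records_V_spindle, params)
    f_free = cpap_free_fraction(c_free, params.K_d)
    return predict_astral_count(records_V_cell, f_free, params=params)


def admissible(record: CellRecord, params: ModelParams) -> bool:
    """Mass-balance admissibility: total microtubules cover the bulk demand
    and polymer mass does not exceed total tubulin mass."""
    return (
        params.n_V * record.V_cell >= params.lambda_bulk * record.V_spindle
        and params.c_tot * record.V_cell >= params.rho_poly * record.V_spindle
    )


@dataclass(frozen=True, eq=False)
class AstralEstimates:
    """Morphometric astral-count estimates for a set of records.

    ``estimate`` is floored at zero; ``raw`` is the unfloored linear
    estimate. ``admissible`` flags records passing the mass-balance check
    (only those should enter fits). The raw estimator is mean-unbiased for
    the generator ground truth by the density-consistency calibration;
    flooring and admissibility masking select against cells whose spindle
    holds an above-average share of the microtubule budget, so the floored,
    masked values carry a positive selection bias on noisy single cells.
    """

    estimate: np.ndarray
    raw: np.ndarray
    admissible: np.ndarray


def estimate_astral_counts(
    records: Sequence[CellRecord],
    params: ModelParams,
) -> AstralEstimates:
    """Per-cell astral count estimates from morphometry.

    Rests on the constancy of the total microtubule number per cell volume:
    ``N_astral = n_V * V_cell - lambda_bulk * V_spindle``, floored at zero.
    Records failing the mass-balance admissibility check are flagged and
    should be excluded from fits.
    """
    if len(records) == 0:
        empty = np.empty(0)
        return AstralEstimates(empty, empty.copy(), np.empty(0, dtype=bool))
    V = np.array([r.V_cell for r in records])
    Vs = np.array([r.V_spindle for r in records])
    raw = params.n_V * V - params.lambda_bulk * Vs
    mask = np.array([admissible(r, params) for r in records])
    return AstralEstimates(np.clip(raw, 0.0, None), raw, mask)


@dataclass(frozen=True, eq=False)
class SaturationFit:
    """Result of fitting N(V) = N_sat * V / (K_V + V).

    ``N_sat`` is the predicted saturation value (plateau count), ``K_V`` the
    half-saturation cell volume. ``covariance`` is the 2x2 covariance of
    (N_sat, K_V); ``identifiable`` is False when the data do not constrain
    ``K_V`` (e.g. flat counts).
    """

    N_sat: float
    K_V: float
    residual_rms: float
    covariance: np.ndarray
    identifiable: bool = True

    def __post_init__(self):
        if self.N_sat <= 0 or self.K_V <= 0:
            raise ValidationError("N_sat and K_V must be positive")
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (2, 2):
            raise ValidationError("covariance must be 2x2")
        object.__setattr__(self, "covariance", cov)

    def __call__(self, V):
        V = np.asarray(V, dtype=float)
        out = self.N_sat * V / (self.K_V + V)
        return float(out) if out.ndim == 0 else out


def _mm(V, n_sat, K_V):
    return n_sat * V / (K_V + V)


def fit_saturation_curve(
    bin_centers: Sequence[float],
    mean_counts: Sequence[float],
    count_sds: Sequence[float] | None = None,
    n_starts: int = 5,
) -> SaturationFit:
    """Weighted nonlinear least squares of the saturating count curve.

    Initialization: ``N_sat0 = 1.2 x max(count)``, ``K_V0`` the bin center
    whose count is nearest half of that; a deterministic multistart over
    ``n_starts`` jittered initializations keeps the best residual. ``K_V``
    running into its bounds (far outside the sampled volume range) marks the
    fit non-identifiable.
    """
    V = np.asarray(bin_centers, dtype=float)
    y = np.asarray(mean_counts, dtype=float)
    if V.ndim != 1 or len(V) != len(y):
        raise ValidationError("bin_centers and mean_counts must be equal-length 1-D")
    if len(V) < 3:
        raise ValidationError("need at least 3 bins to fit the saturation curve")
    if np.any(V <= 0):
        raise ValidationError("bin centers must be positive volumes")
    if np.any(y <= 0):
        raise ValidationError("mean counts must be positive")
    sigma = None
    if count_sds is not None:
        sigma = np.asarray(count_sds, dtype=float)
        if len(sigma) != len(V) or np.any(sigma <= 0):
            raise ValidationError("count_sds must be positive, one per bin")

    n_sat0 = 1.2 * float(y.max())
    K_V0 = float(V[np.argmin(np.abs(y - n_sat0 / 2))])
    lo, hi = (1e-9, 1e-9), (np.inf, 1e4 * V.max())
    jitter_rng = np.random.default_rng(0)  # deterministic multistart
    starts = [(n_sat0, K_V0)]
    starts += [
        (n_sat0 * float(jitter_rng.uniform(0.5, 2.0)),
         K_V0 * float(jitter_rng.uniform(0.3, 3.0)))
        for _ in range(max(0, n_starts - 1))
    ]

    best = None
    diagnostics = {"starts": starts, "errors": []}
    for p0 in starts:
        try:
            popt, pcov = optimize.curve_fit(
                _mm, V, y, p0=p0, sigma=sigma, absolute_sigma=sigma is not None,
                bounds=(lo, hi), maxfev=20000,
            )
        except (RuntimeError, optimize.OptimizeWarning) as exc:  # pragma: no cover
            diagnostics["errors"].append(str(exc))
            continue
        resid = y - _mm(V, *popt)
        rms = float(np.sqrt(np.mean(resid**2)))
        if best is None or rms < best[2]:
            best = (popt, pcov, rms)
    if best is None:
        raise FitError("saturation fit did not converge from any start",
                       diagnostics)
    popt, pcov, rms = best
    n_sat, K_V = float(popt[0]), float(popt[1])
    # K_V pushed far outside the sampled range (or its uncertainty swamps the
    # estimate): the plateau alone is constrained, not the half-saturation.
    kv_err = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.inf
    identifiable = (
        V.min() / 50 < K_V < 50 * V.max() and np.isfinite(kv_err)
        and kv_err < 10 * K_V
    )
    return SaturationFit(
        N_sat=n_sat, K_V=K_V, residual_rms=rms, covariance=np.asarray(pcov),
        identifiable=identifiable,
    )


def fit_state_counts(
    records: Sequence[CellRecord],
    params: ModelParams,
    edges: Sequence[float],
    min_bin_n: int = 5,
    use_true_counts: bool = False,
) -> tuple[SaturationFit, dict]:
    """Bin astral-count estimates by cell volume and fit the saturation curve.

    Convenience wrapper used by the pipeline: takes per-cell astral counts —
    directly counted ones stored in ``n_astral_true`` when
    ``use_true_counts``, otherwise the morphometric estimates — groups them
    into the supplied cell-volume bins, and fits bin means weighted by the
    bin standard errors. The fit abscissa is each bin's empirical mean cell
    volume (not the geometric bin center), which avoids attenuation bias in
    sparsely populated edge bins. Returns the fit and a per-bin summary.

    Note the morphometric estimator is linear in (V_cell, V_spindle): it
    preserves the population-mean astral count but not the count's curvature
    against cell volume, so saturation fitting should use counted astral
    microtubules where available.
    """
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValidationError("edges must be strictly increasing")
    if use_true_counts:
        kept = [r for r in records if r.n_astral_true is not None]
        counts = np.array([float(r.n_astral_true) for r in kept])
    else:
        estimates = estimate_astral_counts(records, params)
        mask = estimates.admissible
        kept = [r for r, m in zip(records, mask) if m]
        counts = estimates.estimate[mask]
    V = np.array([r.V_cell for r in kept])

    centers, means, sds, ns = [], [], [], []
    for lo_e, hi_e in zip(edges[:-1], edges[1:]):
        sel = (V >= lo_e) & (V < hi_e)
        if sel.sum() < min_bin_n:
            continue
        vals = counts[sel]
        centers.append(float(V[sel].mean()))
        means.append(float(vals.mean()))
        sds.append(float(vals.std(ddof=1) / np.sqrt(len(vals))))
        ns.append(int(sel.sum()))
    if len(centers) < 3:
        raise DegenerateDataError("fewer than 3 populated volume bins")
    sds = [max(s, 1e-9) for s in sds]
    fit = fit_saturation_curve(centers, means, sds)
    summary = {"bin_mean_volumes": centers, "means": means, "sems": sds, "n": ns}
    return fit, summary


def consistent_comet_density(state: StateParams, params: ModelParams) -> float:
    """Comet number density n_V implied by the state's forward model.

    Evaluates ``(E[N_astral] + lambda_bulk * E[V_spindle]) / E[V_cell]`` by
    quadrature over the state's truncated-normal cell-volume law, with the
    spindle at its state-mean volume fraction. Used once to freeze
    :data:`DEFAULT_N_V` and the per-state ``lambda_bulk`` table.
    """
    mu, sd = state.cell_volume_mean, state.cell_volume_sd
    lo = max(0.0, mu - 3 * sd)
    a = (lo - mu) / sd
    dist = stats.truncnorm(a, np.inf, loc=mu, scale=sd)
    s_eff = (state.spindle_fraction * (1 - state.subscaling_factor)
             * np.exp(state.scaling_noise_sd**2 / 2))

    def integrand(v):
        return mechanistic_astral_mean(v, s_eff * v, params) * dist.pdf(v)

    E_N, _ = integrate.quad(integrand, lo, mu + 8 * sd, limit=200)
    E_V = dist.mean()
    return float((E_N + params.lambda_bulk * s_eff * E_V) / E_V)


def consistent_bulk_density(state: StateParams, params: ModelParams,
                            n_V: float) -> float:
    """lambda_bulk that keeps the total comet density at ``n_V`` for a state."""
    mu, sd = state.cell_volume_mean, state.cell_volume_sd
    lo = max(0.0, mu - 3 * sd)
    a = (lo - mu) / sd
    dist = stats.truncnorm(a, np.inf, loc=mu, scale=sd)
    s_eff = (state.spindle_fraction * (1 - state.subscaling_factor)
             * np.exp(state.scaling_noise_sd**2 / 2))

    def integrand(v):
        return mechanistic_astral_mean(v, s_eff * v, params) * dist.pdf(v)

    E_N, _ = integrate.quad(integrand, lo, mu + 8 * sd, limit=200)
    E_V = dist.mean()
    return float((n_V * E_V - E_N) / (s_eff * E_V))
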