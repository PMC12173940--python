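# Methods

This note documents the models, the synthetic-data generator and the
numerical choices behind `spindlescale`. Units throughout: volumes µm³,
lengths µm, mass densities mg ml⁻¹ (numerically identical to fg µm⁻³),
times s, speeds µm s⁻¹.

## Cell states and the generator

A `StateParams` bundle describes one experimental condition. Two kinds of
fields coexist:

* **Published population moments** — mitotic cell volume (ESC 2,719 ± 567;
  DIF 1,942 ± 424), cellular mass density (ESC 140 ± 12; DIF 125 ± 11;
  isosmotic control 118 ± 10; hypo-osmotic 112 ± 9), FRAP half-time
  (ESC 11.1 ± 4.6; DIF 9.7 ± 5.8 s), comet growth speed (ESC 0.26 ± 0.034;
  DIF 0.26 ± 0.031), and the DIF spindle subscaling factor 0.24.
* **Calibration parameters** — quantities the study shows only as figure
  distributions. Their defaults are fixed once, documented here, and not
  revisited: spindle volume fraction 0.20 of cell volume in the reference
  state; centrosome volume fraction 1.0×10⁻³ (ESC) and 1.4×10⁻³ (DIF, and
  the perturbations that raise centrosomal nucleation); pole signal
  fraction 0.55 (ESC-like) / 0.62 (DIF-like); log-scale scaling noise
  (below); hypo-osmotic cell swelling (+14% volume) and the CCB02/DMSO
  state definitions.

**Cell volume** is truncated normal (truncation at max(0, mean − 3 s.d.)),
matching the printed moments without heavy tails. **Spindle volume** is
linear through the origin with multiplicative log-normal noise,
`V_spindle = s·(1 − subscaling)·V_cell·exp(ε)`, ε ~ N(0, σ). Applying the
subscaling factor uniformly makes every volume bin's expected median
deficit equal the factor. σ = 0.2171 is calibrated once by a bisection
sweep so that the pooled default two-state population (1,084 + 2,920
cells) shows a Spearman rank correlation of 0.80 between spindle and cell
volume — the correlation is a pooled-scatter statistic, so the calibration
targets the pooled population; the ESC-only correlation at this noise is
≈ 0.68.

**Centrosome volume** is a fixed fraction of cell volume with log-normal
noise (σ = 0.25), soft-capped for states whose centrosomes approach an
upper limit (ESC-like states) via a p-norm soft-minimum
`(x⁻ᵏ + cap⁻ᵏ)^(−1/k)` with sharpness k = 12. The cap asymptote sits at
fraction × 3,500 µm³ so that the volume law is still near-linear at the
~3,000 µm³ onset of saturation; a lower asymptote suppresses the
population median and inflates the DIF:ESC occupancy fold beyond the
1.4-fold the generator is meant to emulate.

**FRAP traces** follow the acquisition layout (3 pre-bleach frames at 1 s,
1 s bleach, 35 post-bleach frames at 1 s): plateau, bleach to 40% of the
plateau, recovery `A(1 − e^(−t/τ)) + C` with per-trace t½ drawn truncated-
normal around the state mean, a shared mono-exponential acquisition-
photobleaching decay on both ROIs (rate 0.004 s⁻¹) and Gaussian intensity
noise (default s.d. 0.02 of the plateau).

**Comet tracks** are straight lines at per-track truncated-normal speed;
durations are uniform on 1.2–4.8 s so the 2–4 s retention filter has both
kinds of rejects; start frames are uniform over a 150-frame video, so the
0–30 frame window also rejects. Track duration counts every imaged frame
(`n_frames × Δt`); growth speed divides the summed path length by the
first-to-last elapsed time (`(n_frames − 1) × Δt`) — the per-step
displacement of a track at speed v is exactly v·Δt.

**Half-spindle profiles** mix a pole-peaked and an equator-weighted
quadratic, `w·3(1−x)² + (1−w)·3x²`. Because the profile convention
min-max normalizes intensities, the mixture weight is solved (Brent) so
that the share of the *normalized* profile's integral over the pole half
(distance 0–0.5) equals the state's target; attainable targets lie in
roughly (0.09, 0.91).

**Blots** put standard band signals exactly on a line through the origin
and lysate bands at `slope × load × fraction`, with multiplicative
log-normal noise of the given CV on every band (mean-one parameterization,
so noise does not bias the expected signal). **RI measurements** invert
the density conversion and round to the ×10,000 integer convention,
emulating tomogram-export quantization (±0.26 mg ml⁻¹ per count, which is
why density tests carry a 0.03 mg ml⁻¹ allowance on means).

All generators take an explicit seed; the pipeline derives per-stage seeds
from one global seed via `SeedSequence([seed, crc32(key)...])`, keeping
children below 2³¹.

## Analysis conventions

* Volume bins are left-closed right-open; the six default bins start at
  1,000 through 3,500 µm³ in 500-µm³ steps; out-of-range records go to an
  explicit "unbinned" bucket.
* Welch's t-test (two-sided, Satterthwaite df) and Cohen's d with
  (n−1)-weighted pooled s.d.; no multiple-testing correction across bins
  (per-bin tests are reported as such).
* Subscaling profiles report the per-bin percent deficit of test-group
  median spindle volume against the reference; bins with fewer than 5
  records in either group are flagged and excluded from the maximum.
* FRAP fitting uses only post-bleach frames, re-zeroed at the first
  post-bleach frame; bleach correction divides by the control ROI rescaled
  to its pre-bleach mean, then min-max normalizes over the full trace
  (switchable to post-only). Both operations are affine, so τ — and the
  half-time t½ = τ·ln 2 — is invariant under them. Initialization:
  A₀ = plateau − first, C₀ = first, τ₀ = time to half-plateau. Fits with
  τ > 10× the window are refused; fits with τ > 0.75× the window are kept
  but flagged `well_constrained=False`, since the plateau is then largely
  extrapolated. At 2% intensity noise the median half-time error is < 5%;
  at 5% noise it is ~9–10%, which is close to the Cramér–Rao limit of a
  three-parameter exponential on a 35-frame window — no estimator does
  materially better there.
* Pole signal fraction integrates the trapezoid rule over [0, 0.5] (with
  the midpoint interpolated) against the total. Comet partitions count
  retained tracks per compartment; an optional sample-frame mode averages
  the counts of tracks alive at a few reference frames, emulating manual
  counting.
* The blot quantification back-calculates each lane through the standards'
  least-squares line and normalizes by the Coomassie-corrected load; the
  Coomassie correction rescales a lane's nominal load by its total-protein
  signal relative to the blot-wide mean signal per µg. The quantified
  fraction is invariant to any common gain on all signals.

## The limiting-component model

Defaults: `c_tot = 0.015 × ρ_state` (tubulin is 1.5% of protein mass, so
2.1 mg ml⁻¹ for ESC, 1.875 for DIF — a derived default), ρ_poly = 1.5,
K_d = 0.3 mg ml⁻¹, CPAP_tot·α = 420 (sets the astral-count scale,
ESC plateau ≈ 60), K_V = 1,500 µm³ (saturation visible above ~3,000 µm³).
K_d, CPAP_tot, α and the number densities have no published values; they
are free configuration constants. CCB02 is represented as a 5× effective
K_d (tubulin displaced from CPAP); DMSO equals ESC. The mixing volume for
c_free is the whole cell volume.

With spindle volume proportional to cell volume, c_free — and hence
f_free — is volume-independent, so composing mass balance → CPAP
liberation → saturating nucleation yields exactly
`N(V) = α·CPAP_tot·f_free·V/(K_V + V)`: the Michaelis–Menten form with a
free-CPAP-proportional plateau. Dilution lowers c_tot faster than the
(smaller) spindle lowers polymer demand, so f_free(DIF) > f_free(ESC) and
the DIF plateau is higher (≈ 64.9 vs ≈ 60.2 at the defaults).

Comet-number densities are tied together by a consistency relation: with
the total comet density n_V constant across states (as observed), the bulk
density per spindle volume must satisfy
`λ_bulk = (n_V·E[V_cell] − E[N_astral]) / E[V_spindle]`. The ESC bulk
density is anchored at 0.30 µm⁻³; n_V = 0.07555 µm⁻³ and each other
state's λ_bulk follow from the relation by quadrature over the state's
volume law (frozen in `cpapmodel.py`, reproducible via
`consistent_comet_density` / `consistent_bulk_density`).

Two properties of the morphometric astral-count estimator
`N̂ = n_V·V_cell − λ_bulk·V_spindle` deserve emphasis. First, it is linear
in its inputs: when spindle volume is strictly proportional to cell
volume it cannot reproduce the saturating curvature, and its floored,
admissibility-masked version is selection-biased upward (cells whose
spindle drew an above-average share of the microtubule budget are the ones
excluded). The raw (unfloored) estimator is mean-unbiased for the
generator's ground truth by the consistency calibration, and
`estimate_astral_counts` returns raw, floored and flag side by side.
Second, for saturation fitting the pipeline therefore uses per-cell astral
counts themselves (`n_astral_true`, emulating directly counted astral
microtubules), binned in 500-µm³ bins across the full sampled range.

Saturation fits are weighted nonlinear least squares of
`N_sat·V/(K_V + V)` on bin means (weights = bin standard errors), with the
abscissa at each bin's empirical mean volume — geometric bin centers bias
K_V low in sparse edge bins. Initialization N_sat⁰ = 1.2 × max count,
K_V⁰ = the bin nearest half of that, plus a deterministic five-start
jitter; the best residual wins. K_V far outside the sampled range or with
runaway uncertainty marks the fit non-identifiable (flat counts trigger
this). At 2,000 cells per state both parameters are recovered with ~2%
(N_sat) and ~7% (K_V) sampling s.d., unbiased.

## What the generator does and does not emulate

Passing tests show that the analysis code recovers the statistical
structure the generator encodes — published moments in, published
statistics out — under idealized conditions: no segmentation errors, no
drift, straight comet tracks without catastrophes, mono-exponential
photobleaching, single-site CPAP–tubulin binding. Real imaging data add
detection noise, nested experiment effects (the study pools experiments,
as do we), and a spindle-scaling law whose true functional form is
unknown; none of that is probed here.

One diagnostic consequence of the design is worth knowing: the maximum
per-bin median spindle-volume deficit reads ~28–30% on default synthetic
populations even though exactly 24% subscaling is injected. A maximum
over six noisy, unbiased per-bin deficits is upward-biased by ~2 points,
and in the outermost bins the two states sample systematically different
volumes within the same bin (one state's tail against the other's body),
which adds another ~3–4 points. The per-bin deficits in the well-populated
central bins sit at 24–26%.

## Problem sizes

Defaults mirror the study's cell counts (1,084/2,920 morphometry, 31 FRAP
traces, 92/75 comet cells, 158/98 profiles, 60/70/107/96 density cells,
188/182 occupancy cells, 2,000 cells per state for model fits); the whole
pipeline plus test suite runs in well under a minute on one CPU.
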