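import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spindlescale import synthgen
from spindlescale.cpapmodel import (
    MODEL_BIN_EDGES,
    ModelParams,
    consistent_bulk_density,
    consistent_comet_density,
    cpap_free_fraction,
    estimate_astral_counts,
    fit_saturation_curve,
    fit_state_counts,
    free_tubulin_concentration,
    mechanistic_astral_mean,
    model_params_for_state,
    predict_astral_count,
)
from spindlescale.errors import DegenerateDataError, ValidationError
from spindlescale.params import STATE_DEFAULTS


def _mm(V, n_sat, K_V):
    return n_sat * V / (K_V + V)


def _true_plateau(state, model):
    s_eff = (state.spindle_fraction * (1 - state.subscaling_factor)
             * np.exp(state.scaling_noise_sd**2 / 2))
    f = model.K_d / (model.K_d + model.c_tot - model.rho_poly * s_eff)
    return model.alpha * model.cpap_total * f


class TestFreeTubulin:
    def test_no_polymer_returns_total(self):
        m = model_params_for_state("ESC")
        assert free_tubulin_concentration(2000.0, 0.0, m) == pytest.approx(m.c_tot)

    def test_half_spindle_halves_concentration(self):
        m = model_params_for_state("ESC").with_overrides(rho_poly=2.1)
        assert m.c_tot == pytest.approx(2.1)  # 1.5% of 140 mg/ml
        assert free_tubulin_concentration(2000.0, 1000.0, m) == pytest.approx(
            m.c_tot / 2)

    def test_monotone_decreasing_in_spindle_volume(self):
        m = model_params_for_state("ESC")
        V_s = np.linspace(0.0, 1500.0, 200)
        c = free_tubulin_concentration(np.full_like(V_s, 2000.0), V_s, m)
        assert np.all(np.diff(c) < 0)

    def test_spindle_exceeding_cell_rejected(self):
        m = model_params_for_state("ESC")
        with pytest.raises(ValidationError):
            free_tubulin_concentration(1000.0, 1000.0, m)


class TestCpapFraction:
    def test_limits_and_midpoint(self):
        assert cpap_free_fraction(0.0, 0.3) == 1.0
        assert cpap_free_fraction(0.3, 0.3) == 0.5
        assert cpap_free_fraction(1e6 * 0.3, 0.3) < 1e-5

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            cpap_free_fraction(-0.1, 0.3)
        with pytest.raises(ValidationError):
            cpap_free_fraction(0.1, 0.0)


class TestPredictAstralCount:
    def test_half_saturation_and_plateau(self):
        m = model_params_for_state("ESC")
        n_sat = m.alpha * m.cpap_total * 0.2
        assert predict_astral_count(m.K_V, 0.2, params=m) == pytest.approx(n_sat / 2)
        assert predict_astral_count(1e9, 0.2, params=m) == pytest.approx(n_sat,
                                                                        rel=1e-5)

    def test_linear_in_free_cpap(self):
        m = model_params_for_state("ESC")
        V = np.linspace(500, 5000, 50)
        assert np.allclose(predict_astral_count(V, 0.4, params=m),
                           2 * predict_astral_count(V, 0.2, params=m))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        n_sat=st.floats(1.0, 500.0),
        K_V=st.floats(100.0, 5000.0),
        f=st.floats(0.01, 1.0),
    )
    def test_monotone_increasing_and_bounded(self, n_sat, K_V, f):
        m = model_params_for_state("ESC").with_overrides(
            cpap_total=n_sat, alpha=1.0, K_V=K_V)
        V = np.linspace(10.0, 50000.0, 400)
        N = predict_astral_count(V, f, params=m)
        assert np.all(np.diff(N) > 0)
        assert np.all(N < n_sat * f + 1e-9)


class TestEstimates:
    def test_all_microtubules_in_bulk_floors_at_zero(self, esc):
        m = model_params_for_state(esc)
        records = synthgen.generate_cell_population(esc, 5, 1)
        # force lambda_bulk so the bulk demand equals the total supply
        r = records[0]
        forced = m.with_overrides(lambda_bulk=m.n_V * r.V_cell / r.V_spindle)
        out = estimate_astral_counts([r], forced)
        assert out.estimate[0] == pytest.approx(0.0, abs=1e-9)
        assert bool(out.admissible[0]) is True

    def test_inadmissible_record_flagged(self, esc):
        m = model_params_for_state(esc).with_overrides(lambda_bulk=50.0)
        records = synthgen.generate_cell_population(esc, 3, 1)
        out = estimate_astral_counts(records, m)
        assert not out.admissible.any()
        assert np.all(out.estimate == 0.0)
        assert np.all(out.raw < 0.0)

    def test_estimates_unbiased_against_generator_truth(self, esc):
        # generator-inverse oracle: the linear estimator's population mean
        # equals the forward model's by the density-consistency calibration
        m = model_params_for_state(esc)
        records = synthgen.generate_cell_population(esc, 1000, 8, model=m)
        out = estimate_astral_counts(records, m)
        truth = np.array([r.n_astral_true for r in records], dtype=float)
        diff = out.raw - truth
        sem = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 2 * sem

    def test_consistency_relations_reproduce_frozen_defaults(self, esc, dif):
        m_esc = model_params_for_state(esc)
        n_v = consistent_comet_density(esc, m_esc)
        assert n_v == pytest.approx(m_esc.n_V, abs=5e-4)
        m_dif = model_params_for_state(dif)
        lam = consistent_bulk_density(dif, m_dif, m_esc.n_V)
        assert lam == pytest.approx(m_dif.lambda_bulk, abs=5e-3)


class TestSaturationFit:
    def test_exact_recovery_on_noise_free_points(self):
        V = np.array([1250.0, 1750.0, 2250.0, 2750.0, 3250.0, 3750.0])
        y = _mm(V, 60.0, 1500.0)
        fit = fit_saturation_curve(V, y)
        assert fit.N_sat == pytest.approx(60.0, rel=1e-6)
        assert fit.K_V == pytest.approx(1500.0, rel=1e-6)
        assert fit.identifiable

    def test_flat_counts_flagged_non_identifiable(self):
        V = np.array([1250.0, 1750.0, 2250.0, 2750.0, 3250.0, 3750.0])
        fit = fit_saturation_curve(V, np.full(6, 42.0))
        assert not fit.identifiable

    def test_saturating_counts_plateau_within_sampled_range(self, esc):
        # counts that level off above ~3,000 µm³: the fitted curve reaches
        # a large share of its plateau inside the sampled volumes
        m = model_params_for_state(esc)
        records = synthgen.generate_cell_population(esc, 2000, 3, model=m)
        fit, summary = fit_state_counts(records, m, MODEL_BIN_EDGES,
                                        use_true_counts=True)
        v_max = max(summary["bin_mean_volumes"])
        assert fit(v_max) / fit.N_sat > 0.65
        assert fit.identifiable

    def test_parameter_recovery_from_synthetic_populations(self, esc, dif):
        for state in (esc, dif):
            m = model_params_for_state(state)
            records = synthgen.generate_cell_population(state, 2000, 0, model=m)
            fit, _ = fit_state_counts(records, m, MODEL_BIN_EDGES,
                                      use_true_counts=True)
            assert fit.N_sat == pytest.approx(_true_plateau(state, m), rel=0.10)
            assert fit.K_V == pytest.approx(m.K_V, rel=0.10)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValidationError):
            fit_saturation_curve([1000.0, 2000.0], [10.0, 20.0])


class TestMechanisticChain:
    def test_chain_reduces_to_michaelis_menten(self, esc):
        # with spindle volume strictly proportional to cell volume the
        # composed chain is itself a saturating curve; its best
        # Michaelis-Menten approximation deviates < 5% RMS
        m = model_params_for_state(esc)
        V = np.linspace(1000.0, 4500.0, 60)
        chain = mechanistic_astral_mean(V, esc.spindle_fraction * V, m)
        fit = fit_saturation_curve(V, chain)
        rel_rms = np.sqrt(np.mean((chain - fit(V)) ** 2)) / chain.mean()
        assert rel_rms < 0.05

    def test_dilution_increases_free_cpap_and_plateau(self, esc, dif):
        m_esc = model_params_for_state(esc)
        m_dif = model_params_for_state(dif)
        V = np.linspace(1200.0, 3200.0, 20)
        f_esc = cpap_free_fraction(
            free_tubulin_concentration(V, esc.spindle_fraction * V, m_esc),
            m_esc.K_d)
        f_dif = cpap_free_fraction(
            free_tubulin_concentration(
                V, dif.spindle_fraction * (1 - dif.subscaling_factor) * V,
                m_dif),
            m_dif.K_d)
        assert np.all(f_dif > f_esc)

    def test_fitted_plateau_ordering_dif_above_esc(self, esc, dif):
        fits = {}
        for state in (esc, dif):
            m = model_params_for_state(state)
            records = synthgen.generate_cell_population(state, 2000, 19, model=m)
            fits[state.state_label], _ = fit_state_counts(
                records, m, MODEL_BIN_EDGES, use_true_counts=True)
        assert fits["DIF"].N_sat > fits["ESC"].N_sat
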