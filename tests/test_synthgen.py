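import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spindlescale import eb1, synthgen
from spindlescale.densito import densities_from_measurements
from spindlescale.errors import ValidationError
from spindlescale.params import StateParams
from spindlescale.scaling import spearman_rho


def _records_equal(a, b):
    return all(ra == rb for ra, rb in zip(a, b)) and len(a) == len(b)


class TestCellPopulation:
    def test_deterministic_under_fixed_seed(self, esc):
        one = synthgen.generate_cell_population(esc, 50, 123)
        two = synthgen.generate_cell_population(esc, 50, 123)
        assert _records_equal(one, two)
        three = synthgen.generate_cell_population(esc, 50, 124)
        assert not _records_equal(one, three)

    def test_esc_mean_volume_matches_published_population(self, esc):
        records = synthgen.generate_cell_population(esc, 1084, 1)
        volumes = np.array([r.V_cell for r in records])
        sem = volumes.std(ddof=1) / np.sqrt(len(volumes))
        assert abs(volumes.mean() - 2719.0) < 2 * sem

    def test_noiseless_proportional_scaling(self, esc):
        params = esc.with_overrides(scaling_noise_sd=0.0, subscaling_factor=0.0)
        records = synthgen.generate_cell_population(params, 10, 7)
        ratios = {round(r.V_spindle / r.V_cell, 12) for r in records}
        assert ratios == {round(params.spindle_fraction, 12)}

    def test_rank_correlation_decreases_with_scaling_noise(self, esc):
        rhos = []
        for noise in (0.05, 0.2171, 0.6):
            records = synthgen.generate_cell_population(
                esc.with_overrides(scaling_noise_sd=noise), 4000, 11)
            rhos.append(spearman_rho([r.V_cell for r in records],
                                     [r.V_spindle for r in records]))
        assert rhos[0] > rhos[1] > rhos[2]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        mean=st.floats(200.0, 5000.0),
        cv=st.floats(0.05, 0.6),
        noise=st.floats(0.0, 0.8),
        sub=st.floats(0.0, 0.9),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_truncation_never_yields_nonpositive_quantities(
            self, mean, cv, noise, sub, seed):
        params = StateParams(
            state_label="ESC",
            cell_volume_mean=mean,
            cell_volume_sd=cv * mean,
            mass_density_mean=130.0,
            mass_density_sd=40.0,
            scaling_noise_sd=noise,
            subscaling_factor=sub,
        )
        records = synthgen.generate_cell_population(params, 40, seed)
        for r in records:
            assert 0 < r.V_spindle < r.V_cell
            assert 0 < r.V_centrosome < r.V_spindle
            assert r.mass_density > 0
            assert r.n_astral_true >= 0

    def test_rejects_nonpositive_n(self, esc):
        with pytest.raises(ValidationError):
            synthgen.generate_cell_population(esc, 0, 1)


class TestFrapTraces:
    def test_default_acquisition_layout(self, esc):
        (trace,) = synthgen.generate_frap_traces(esc, 1, 5)
        assert trace.n_pre == 3
        assert trace.n_post == 35
        assert np.all(trace.bleach_roi >= 0)
        # 1 s frames with a 1 s bleach gap between frame 2 and 3
        assert trace.frame_times[3] - trace.frame_times[2] == pytest.approx(2.0)

    def test_control_constant_without_acquisition_decay(self, esc):
        (trace,) = synthgen.generate_frap_traces(
            esc, 1, 5, acquisition_decay_rate=0.0, noise_sd=0.0)
        assert np.allclose(trace.control_roi, trace.control_roi[0])

    def test_half_recovery_time_on_noiseless_curve(self, esc):
        # t_half = tau * ln 2: with tau = 1 s the noiseless recovery passes
        # half way to the plateau at exactly 0.6931 s after the bleach
        t_half = float(np.log(2))
        params = esc.with_overrides(frap_t_half=t_half, frap_t_half_sd=0.0)
        (trace,) = synthgen.generate_frap_traces(
            params, 1, 3, acquisition_decay_rate=0.0, noise_sd=0.0,
            frame_interval=t_half / 4, bleach_gap=0.0,
        )
        post = trace.bleach_roi[trace.bleach_index:]
        t_post = (trace.frame_times[trace.bleach_index:]
                  - trace.frame_times[trace.bleach_index - 1])
        # the bleach removes 60% of the plateau: recovery starts at 0.4
        floor, plateau = 0.4, 1.0
        half_idx = np.argmin(np.abs(t_post - t_half))
        assert t_post[half_idx] == pytest.approx(t_half, abs=1e-9)
        expected = floor + (plateau - floor) * 0.5
        assert post[half_idx] == pytest.approx(expected, abs=1e-9)

    def test_negative_noise_rejected(self, esc):
        with pytest.raises(ValidationError):
            synthgen.generate_frap_traces(esc, 1, 5, noise_sd=-0.1)


class TestCometTracks:
    def test_fixed_speed_gives_expected_per_frame_displacement(self, esc):
        params = esc.with_overrides(comet_speed_mean=0.26, comet_speed_sd=0.0)
        (track,) = synthgen.generate_comet_tracks(params, 1, 1, 9)
        steps = np.linalg.norm(np.diff(track.positions, axis=0), axis=1)
        assert np.allclose(steps, 0.26 * 0.4)

    def test_zero_speed_track_is_static(self, esc):
        params = esc.with_overrides(comet_speed_mean=0.0, comet_speed_sd=0.0)
        (track,) = synthgen.generate_comet_tracks(params, 1, 1, 9)
        assert np.allclose(track.positions, track.positions[0])

    def test_population_speed_centred_on_state_mean(self, esc):
        tracks = synthgen.generate_comet_tracks(esc, 92, 30, 2)
        kept, _ = eb1.filter_tracks(tracks)
        speeds = eb1.per_cell_speeds(kept)
        grand = np.mean(list(speeds.values()))
        assert grand == pytest.approx(0.26, abs=0.01)


class TestProfiles:
    def test_mean_pole_fraction_recovers_target(self, esc):
        params = esc.with_overrides(pole_fraction_mean=0.60)
        profiles = synthgen.generate_half_spindle_profiles(params, 100, 21)
        fractions = [eb1.pole_signal_fraction(p) / 100 for p in profiles]
        assert np.mean(fractions) == pytest.approx(0.60, abs=0.02)

    def test_axes_normalized(self, esc):
        (profile,) = synthgen.generate_half_spindle_profiles(esc, 1, 3)
        assert profile.distance[0] == 0.0 and profile.distance[-1] == 1.0
        assert profile.intensity.min() == pytest.approx(0.0)
        assert profile.intensity.max() == pytest.approx(1.0)

    def test_unattainable_target_rejected(self, esc):
        with pytest.raises(ValidationError):
            synthgen.generate_half_spindle_profiles(
                esc.with_overrides(pole_fraction_mean=0.95), 1, 3)


class TestBlotAndLineages:
    def test_noise_free_blot_encodes_exact_fraction(self):
        blot = synthgen.generate_blot_dataset(1.5, noise_cv=0.0, seed=0)
        # standards lie exactly on a line through the origin
        masses = np.array([m for m, _ in blot.standards])
        signals = np.array([s for _, s in blot.standards])
        assert np.allclose(signals / masses, signals[0] / masses[0])
        slope = signals[0] / masses[0]
        for load, band, _ in blot.lysate_lanes:
            assert band / slope == pytest.approx(load * 1000 * 0.015)

    def test_fewer_than_two_standards_rejected(self):
        with pytest.raises(ValidationError):
            synthgen.generate_blot_dataset(1.5, standards_ng=[50.0], seed=0)

    def test_deterministic_division_clock(self):
        lineages = synthgen.generate_lineages(
            mean_cycle_s=36000.0, sd_s=0.0, total_duration_s=144000.0,
            n_families=5, seed=4)
        for lin in lineages:
            intervals = np.diff(lin.division_times)
            assert np.allclose(intervals, 36000.0)
            assert 3 <= len(intervals) <= 4

    def test_short_recording_gives_empty_interval_lineage(self):
        (lin,) = synthgen.generate_lineages(36000.0, 0.0, 1000.0, 1, 4)
        assert len(lin.division_times) == 1

    def test_interval_mean_recovered_at_large_n(self):
        # long recordings so the stopping rule's length bias (families with
        # shorter cycles fit more divisions before the cutoff) is negligible
        lineages = synthgen.generate_lineages(36000.0, 7200.0, 4.0e6, 30, 8)
        intervals = np.concatenate([np.diff(l.division_times) for l in lineages])
        sem = intervals.std(ddof=1) / np.sqrt(len(intervals))
        assert abs(intervals.mean() - 36000.0) < 2 * sem + 7200.0**2 / 4.0e6


class TestRISynthesis:
    def test_density_round_trip_through_ri(self, esc):
        measurements = synthgen.generate_ri_measurements(esc, 60, 31)
        rho = densities_from_measurements(measurements)
        sem = rho.std(ddof=1) / np.sqrt(len(rho))
        assert abs(rho.mean() - 140.0) < 2 * sem + 0.03  # 0.03: RI quantization

    def test_raw_values_are_integer_convention(self, esc):
        measurements = synthgen.generate_ri_measurements(esc, 5, 31)
        for m in measurements:
            assert m.ri_raw == round(m.ri_raw)
            assert m.ri_raw / 10000.0 > m.ri_medium
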