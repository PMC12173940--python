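import numpy as np
import pytest
from scipy import stats

from spindlescale import scaling, synthgen
from spindlescale.errors import DegenerateDataError, ValidationError
from spindlescale.records import CellRecord, Lineage
from spindlescale.scaling import (
    BinSummary,
    DEFAULT_BIN_EDGES,
    UNBINNED,
    bin_by_cell_volume,
    compare_groups,
    fold_change_vs_control,
    intermitotic_times,
    occupancy,
    spearman_rho,
    subscaling_profile,
    summarize_bins,
)


def _record(v_cell, v_spindle=None, v_centrosome=None, label="ESC"):
    v_spindle = v_spindle if v_spindle is not None else 0.2 * v_cell
    v_centrosome = v_centrosome if v_centrosome is not None else 0.01 * v_spindle
    return CellRecord(
        cell_id=f"c{v_cell:.0f}",
        state_label=label,
        time_bin_h=0.0,
        V_cell=v_cell,
        V_spindle=v_spindle,
        spindle_length=10.0,
        spindle_width=7.0,
        V_centrosome=v_centrosome,
        mass_density=140.0,
        mean_tubulin_signal=100.0,
    )


class TestBinning:
    @pytest.mark.parametrize(
        "volume,expected",
        [
            (2499.0, (2000.0, 2500.0)),  # interior assignment
            (2500.0, (2500.0, 3000.0)),  # left-closed right-open boundary
            (900.0, UNBINNED),           # below the binned range
            (4000.0, UNBINNED),          # the last edge is exclusive
        ],
    )
    def test_boundary_convention(self, volume, expected):
        binned = bin_by_cell_volume([_record(volume)], DEFAULT_BIN_EDGES)
        holders = [k for k, v in binned.items() if v]
        assert holders == [expected]

    def test_binning_is_a_partition(self, esc):
        records = synthgen.generate_cell_population(esc, 300, 17)
        binned = bin_by_cell_volume(records, DEFAULT_BIN_EDGES)
        total = sum(len(v) for v in binned.values())
        assert total == len(records)
        ids = [r.cell_id for bucket in binned.values() for r in bucket]
        assert len(set(ids)) == len(records)

    def test_unsorted_edges_rejected(self):
        with pytest.raises(ValidationError):
            bin_by_cell_volume([_record(2000.0)], [1000.0, 900.0, 2000.0])


class TestCompareGroups:
    def test_hand_computed_effect_size(self):
        # means 2 and 4, pooled sd exactly 1
        res = compare_groups([1.0, 2.0, 3.0], [3.0, 4.0, 5.0])
        assert res.cohens_d == pytest.approx(-2.0, abs=1e-12)

    def test_identical_samples(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == 0.0
        assert res.p_two_sided == pytest.approx(1.0)
        assert res.cohens_d == 0.0

    def test_degenerate_zero_variance(self):
        res = compare_groups([2.0, 2.0], [2.0, 2.0])
        assert (res.t_statistic, res.p_two_sided, res.cohens_d) == (0.0, 1.0, 0.0)
        with pytest.raises(DegenerateDataError):
            compare_groups([2.0, 2.0], [3.0, 3.0])

    def test_matches_textbook_formulas(self, rng):
        # independent oracle: Welch t, Satterthwaite df, two-sided p from the
        # t distribution, and (n-1)-weighted pooled-sd Cohen's d, written out
        for _ in range(1000):
            n_a, n_b = rng.integers(3, 12, size=2)
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), n_a)
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), n_b)
            va, vb = a.var(ddof=1), b.var(ddof=1)
            se2 = va / n_a + vb / n_b
            t = (a.mean() - b.mean()) / np.sqrt(se2)
            df = se2**2 / ((va / n_a) ** 2 / (n_a - 1) + (vb / n_b) ** 2 / (n_b - 1))
            p = 2 * stats.t.sf(abs(t), df)
            s_pooled = np.sqrt(((n_a - 1) * va + (n_b - 1) * vb) / (n_a + n_b - 2))
            d = (a.mean() - b.mean()) / s_pooled
            res = compare_groups(a, b)
            assert res.t_statistic == pytest.approx(t, abs=1e-10)
            assert res.df_welch == pytest.approx(df, abs=1e-10)
            assert res.p_two_sided == pytest.approx(p, abs=1e-10)
            assert res.cohens_d == pytest.approx(d, abs=1e-10)

    def test_type_one_error_rate(self, rng):
        # under the null, p < 0.05 in 5% +/- 1% of replicates
        reps, n = 10000, 50
        a = rng.normal(size=(reps, n))
        b = rng.normal(size=(reps, n))
        p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        # cross-check a subsample against compare_groups itself
        for i in range(0, reps, 1000):
            assert compare_groups(a[i], b[i]).p_two_sided == pytest.approx(p[i])
        assert np.mean(p < 0.05) == pytest.approx(0.05, abs=0.01)


class TestSpearman:
    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=60)
        y = rng.normal(size=60)
        base = spearman_rho(x, y)
        assert spearman_rho(x**3, y) == pytest.approx(base, abs=1e-12)
        assert spearman_rho(x, np.exp(y)) == pytest.approx(base, abs=1e-12)

    def test_perfect_monotone_relations(self):
        x = np.array([-2.0, -1.0, 0.5, 1.5, 3.0])
        assert spearman_rho(x, x**3) == pytest.approx(1.0)
        assert spearman_rho(x, -x) == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateDataError):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSubscalingProfile:
    def _summary(self, median, n=50, lo=1000.0, hi=1500.0):
        return BinSummary(lo, hi, n, median, median * 0.9, median * 1.1)

    def test_hand_computed_deficit(self):
        ref = [self._summary(250.0)]
        test = [self._summary(190.0)]
        profile = subscaling_profile(ref, test)
        assert profile.deficits_percent[0] == pytest.approx(24.0)
        assert profile.max_deficit_percent == pytest.approx(24.0)

    def test_self_comparison_is_zero(self, esc):
        records = synthgen.generate_cell_population(esc, 500, 23)
        bins = summarize_bins(bin_by_cell_volume(records))
        profile = subscaling_profile(bins, bins)
        assert all(d == pytest.approx(0.0) for d in profile.deficits_percent
                   if not np.isnan(d))

    def test_low_count_bins_flagged_and_excluded(self):
        ref = [self._summary(250.0, n=50), self._summary(250.0, n=3,
                                                         lo=1500.0, hi=2000.0)]
        test = [self._summary(200.0, n=50), self._summary(100.0, n=30,
                                                          lo=1500.0, hi=2000.0)]
        profile = subscaling_profile(ref, test, min_n=5)
        assert profile.flagged == (False, True)
        assert profile.max_deficit_percent == pytest.approx(20.0)

    def test_mismatched_edges_rejected(self):
        with pytest.raises(ValidationError):
            subscaling_profile([self._summary(250.0)],
                               [self._summary(250.0, lo=2000.0, hi=2500.0)])


class TestOccupancyAndFolds:
    def test_arithmetic(self):
        assert occupancy(10.0, 1000.0) == pytest.approx(1.0)
        assert occupancy(0.0, 1000.0) == 0.0
        with pytest.raises(ValidationError):
            occupancy(1100.0, 1000.0)

    def test_fold_change_identity_and_doubling(self, rng):
        control = rng.uniform(1.0, 3.0, 40)
        assert fold_change_vs_control(control, control).median_fold == pytest.approx(1.0)
        assert fold_change_vs_control(2 * control, control).median_fold == pytest.approx(2.0)

    def test_density_fold_hypo_below_iso(self):
        from spindlescale.params import STATE_DEFAULTS
        iso = synthgen.generate_cell_population(STATE_DEFAULTS["ISO"], 107, 5)
        hypo = synthgen.generate_cell_population(STATE_DEFAULTS["HYPO"], 96, 6)
        fold = fold_change_vs_control([r.mass_density for r in hypo],
                                      [r.mass_density for r in iso])
        # state means 112 vs 118 -> expected ratio ~0.949
        assert fold.median_fold < 1.0
        assert fold.median_fold == pytest.approx(112.0 / 118.0, abs=0.03)

    def test_zero_control_median_rejected(self):
        with pytest.raises(DegenerateDataError):
            fold_change_vs_control([1.0], [0.0, 0.0, 0.0])


class TestIntermitoticTimes:
    def test_successive_differences(self):
        hours = 3600.0
        out = intermitotic_times(Lineage(np.array([0.0, 10.0, 25.0]) * hours))
        assert np.allclose(out / hours, [10.0, 15.0])

    def test_single_event_yields_empty(self):
        assert len(intermitotic_times(Lineage(np.array([5.0])))) == 0
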