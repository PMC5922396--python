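"""Descriptive stats, Mann-Whitney against brute-force enumeration,
correlations, ROC cut-off optimality, and ELISA quantification."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctcev.biomarkers import (
    BiomarkerError,
    ElisaPlate,
    ElisaQcError,
    correlate,
    describe,
    elisa_quantify,
    mann_whitney,
    roc_cutoff,
)
from ctcev.simulate.elisa import ElisaSimParams, four_pl, generate_elisa_plate


class TestDescribe:
    def test_single_value(self):
        s = describe([5])
        assert (s.median, s.iqr, s.min, s.max) == (5, 0, 5, 5)

    def test_linear_interpolation_quantiles(self):
        s = describe([1, 2, 3, 4])
        assert s.median == 2.5
        assert s.p25 == 1.75
        assert s.p75 == 3.25
        assert s.iqr == 1.5

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(size=31)
        assert describe(v).to_dict() == describe(rng.permutation(v)).to_dict()

    def test_errors(self):
        with pytest.raises(BiomarkerError):
            describe([])
        with pytest.raises(BiomarkerError):
            describe([1.0, np.nan])


def brute_force_mw(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all label assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    n = len(x)

    def u_stat(xs, ys):
        return sum((xi < yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    observed = u_stat(x, y)
    m = len(pooled)
    us = []
    for idx in itertools.combinations(range(m), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(m) if i not in idx]
        us.append(u_stat(xs, ys))
    us = np.array(us)
    mean_u = us.mean()
    p = np.mean(np.abs(us - mean_u) >= abs(observed - mean_u) - 1e-12)
    return observed, float(p)


class TestMannWhitney:
    def test_separated_groups_match_brute_force(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        bu, bp = brute_force_mw([1, 2, 3], [4, 5, 6])
        assert u == bu == 9
        assert p == pytest.approx(bp)  # two-sided 2/20
        # one-sided exact tail is 1/20
        from scipy import stats

        one_sided = stats.mannwhitneyu([1, 2, 3], [4, 5, 6], alternative="less", method="exact")
        assert one_sided.pvalue == pytest.approx(0.05)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_small_samples_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.permutation(20)[:6].tolist()
        y = rng.permutation(np.arange(20, 40))[:5].tolist()
        u, p = mann_whitney(x, y)
        bu, bp = brute_force_mw(x, y)
        assert u == bu
        assert p == pytest.approx(bp)

    def test_identical_samples_symmetric(self):
        u, p = mann_whitney([1, 2], [1, 2])
        assert u == 2  # n*m/2 with half-counted ties
        assert p == pytest.approx(1.0)

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(1)
        _, p = mann_whitney(rng.normal(0, 1, 200), rng.normal(2, 1, 200))
        assert p < 1e-3

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_u_statistics_sum_to_nm(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 10, size=rng.integers(1, 12))
        y = rng.integers(0, 10, size=rng.integers(1, 12))
        u_xy, _ = mann_whitney(x, y)
        u_yx, _ = mann_whitney(y, x)
        assert u_xy + u_yx == pytest.approx(len(x) * len(y))

    def test_empty_rejected(self):
        with pytest.raises(BiomarkerError):
            mann_whitney([], [1])


class TestCorrelate:
    def test_monotone_series(self):
        assert correlate([1, 2, 3, 7], [2, 9, 11, 30])[0] == pytest.approx(1.0)
        assert correlate([1, 2, 3, 7], [30, 11, 9, 2])[0] == pytest.approx(-1.0)

    def test_hand_computed_spearman(self):
        rho, _ = correlate([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)

    def test_pearson_on_ranks_equals_spearman(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=50), rng.normal(size=50)
        from scipy.stats import rankdata

        rho_s, _ = correlate(x, y, "spearman")
        rho_p, _ = correlate(rankdata(x), rankdata(y), "pearson")
        assert rho_s == pytest.approx(rho_p)

    def test_errors(self):
        with pytest.raises(BiomarkerError):
            correlate([1, 1, 1], [1, 2, 3])
        with pytest.raises(BiomarkerError):
            correlate([1, 2], [1, 2])


class TestRocCutoff:
    def test_perfectly_separated_values(self):
        # short survivors (died early) carry high values; long survivors low
        values = np.array([1, 2, 3, 4, 5, 6, 7, 10, 11, 12, 13, 14])
        times = np.array([30.0, 28, 26, 25, 24, 22, 20, 2, 3, 4, 5, 6])
        events = np.array([1, 0, 0, 1, 0, 1, 1, 1, 1, 1, 1, 1])
        res = roc_cutoff(values, times, events)
        assert res.cutoff == 10
        assert res.min_abs_diff == 0
        sens = res.sensitivity[np.flatnonzero(res.thresholds == 10)][0]
        spec = res.specificity[np.flatnonzero(res.thresholds == 10)][0]
        assert sens == spec == 1.0
        assert res.auc == pytest.approx(1.0)

    def test_cutoff_globally_minimizes_abs_diff(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = 60
            values = rng.integers(0, 15, n).astype(float)
            times = rng.exponential(12, n)
            events = rng.integers(0, 2, n)
            try:
                res = roc_cutoff(values, times, events)
            except BiomarkerError:
                continue
            # exhaustive re-scan
            from ctcev.survival import km_fit

            median = km_fit(times, events).median
            keep = (times >= median) | (events == 1)
            short = ((times < median) & (events == 1))[keep]
            v = values[keep]
            best = min(
                abs(np.mean(v[short] >= t) - np.mean(v[~short] < t))
                for t in np.unique(v)
            )
            assert res.min_abs_diff == pytest.approx(best)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        n = 80
        values = rng.uniform(1, 10, n)
        times = rng.exponential(12 / values, n)  # higher value, shorter survival
        events = np.ones(n)
        a = roc_cutoff(values, times, events)
        b = roc_cutoff(np.exp(values), times, events)
        assert a.auc == pytest.approx(b.auc)

    def test_null_auc_near_half_over_repetitions(self):
        rng = np.random.default_rng(5)
        aucs = []
        for _ in range(50):
            n = 100
            values = rng.permutation(n).astype(float)
            times = rng.exponential(12, n)
            aucs.append(roc_cutoff(values, times, np.ones(n)).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    def test_censored_before_median_are_excluded(self):
        values = np.array([1, 2, 3, 4, 10, 11, 12, 13, 5.0, 6.0])
        times = np.array([30, 28, 26, 25, 2, 3, 4, 5, 1.0, 1.5])
        events = np.array([1, 1, 1, 1, 1, 1, 1, 1, 0, 0])
        res = roc_cutoff(values, times, events)
        assert res.n_excluded == 2
        assert res.n_short + res.n_long == 8

    def test_errors(self):
        with pytest.raises(BiomarkerError):
            roc_cutoff([1, 2, 3], [1, 2, 3], [1, 1, 1])  # n < 10
        # median never reached: all censored
        with pytest.raises(BiomarkerError):
            roc_cutoff(np.arange(12), np.arange(1, 13), np.zeros(12))


class TestElisa:
    def test_node_interpolation_is_exact(self):
        plate, _ = generate_elisa_plate(ElisaSimParams(noise_sd=0.0))
        conc4, abs4 = plate.standards[3]
        plate.samples = {"node": (abs4, abs4)}
        out = elisa_quantify(plate, model="interp")
        assert out.concentration[0] == pytest.approx(conc4)

    def test_duplicates_equal_single_well(self):
        plate, _ = generate_elisa_plate(ElisaSimParams(seed=1))
        a = plate.samples["s2"][0]
        plate.samples = {"dup": (a, a), "single_equiv": (a, a)}
        out = elisa_quantify(plate)
        assert out.concentration[0] == pytest.approx(out.concentration[1])

    def test_round_trip_recovery_within_5pct_mid_range(self):
        plate, truth = generate_elisa_plate(ElisaSimParams(seed=2))
        out = elisa_quantify(plate).set_index("sample")
        for name, true_conc in truth.items():
            if 100 <= true_conc <= 2000:  # mid-range of the standards
                assert out.loc[name, "concentration"] == pytest.approx(true_conc, rel=0.05)

    def test_monotone_conversion(self):
        plate, _ = generate_elisa_plate(ElisaSimParams(seed=3))
        grid = np.linspace(0.3, 2.8, 30)
        plate.samples = {f"g{i}": (a + plate.blank, a + plate.blank) for i, a in enumerate(grid)}
        out = elisa_quantify(plate)
        conc = out.concentration.to_numpy()
        ok = ~np.isnan(conc)
        assert (np.diff(conc[ok]) >= 0).all()

    def test_out_of_range_flagged_not_extrapolated(self):
        plate, _ = generate_elisa_plate(ElisaSimParams(seed=4))
        top = max(a for _, a in plate.standards)
        plate.samples = {"high": (top + 1.0, top + 1.0)}
        out = elisa_quantify(plate)
        assert out.flag[0] == "out_of_range"
        assert np.isnan(out.concentration[0])

    def test_qc_failure_raises(self):
        plate, _ = generate_elisa_plate(ElisaSimParams(seed=5))
        wells, _ = plate.qc_low
        plate.qc_low = (wells, (2000.0, 3000.0))  # declared range far from truth
        with pytest.raises(ElisaQcError):
            elisa_quantify(plate)

    def test_standards_must_increase(self):
        plate, _ = generate_elisa_plate(ElisaSimParams(seed=6))
        plate.standards[1] = (plate.standards[0][0], plate.standards[1][1])
        with pytest.raises(BiomarkerError):
            elisa_quantify(plate)

    def test_four_pl_curve_shape(self):
        a, d, c, b = 0.05, 3.0, 500.0, 1.2
        assert four_pl(c, a, d, c, b) == pytest.approx((a + d) / 2)
        assert four_pl(1e-9, a, d, c, b) == pytest.approx(a, abs=1e-6)
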