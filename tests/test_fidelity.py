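import numpy as np
import pytest

from kdeknn import (
    DataError,
    density_coverage,
    ks_battery,
    moment_comparison,
    shift_report,
)


def brute_force_density_coverage(real, synthetic, k):
    """O(N^2 + N*Q) double loop, the test oracle."""
    n, q = real.shape[0], synthetic.shape[0]
    radii = []
    for i in range(n):
        dists = sorted(
            np.sqrt(((real[i] - real[j]) ** 2).sum()) for j in range(n) if j != i
        )
        radii.append(dists[k - 1])
    density = 0
    covered = 0
    for i in range(n):
        hit = False
        for j in range(q):
            if np.sqrt(((synthetic[j] - real[i]) ** 2).sum()) <= radii[i]:
                density += 1
                hit = True
        covered += hit
    return density / (k * q), covered / n


class TestKSBattery:
    def test_identical_columns(self):
        x = np.random.default_rng(0).standard_normal((40, 3))
        res = ks_battery(x, x.copy())
        assert (res.table["statistic"] == 0).all()
        np.testing.assert_allclose(res.table["p_value"], 1.0)

    def test_disjoint_supports(self):
        rng = np.random.default_rng(1)
        real = rng.random((50, 1))
        res = ks_battery(real, real + 10)
        assert res.table["statistic"].iloc[0] == 1.0
        assert res.table["p_value"].iloc[0] < 1e-10

    def test_hand_stepped_cdfs(self):
        real = np.array([[1.0], [2.0], [3.0], [4.0]])
        syn = np.array([[1.5], [2.5], [3.5], [4.5]])
        res = ks_battery(real, syn)
        assert res.table["statistic"].iloc[0] == pytest.approx(0.25)

    def test_mean_p_value_is_feature_mean(self):
        rng = np.random.default_rng(2)
        res = ks_battery(rng.standard_normal((30, 4)), rng.standard_normal((30, 4)))
        assert res.mean_p_value == pytest.approx(res.table["p_value"].mean())

    def test_null_calibration(self):
        """Same-distribution columns give roughly uniform p-values."""
        rng = np.random.default_rng(3)
        real = rng.standard_normal((300, 200))
        syn = rng.standard_normal((300, 200))
        res = ks_battery(real, syn)
        assert 0.4 < res.mean_p_value < 0.6


class TestDensityCoverage:
    def test_synthetic_equals_real_coverage_one(self):
        x = np.random.default_rng(0).standard_normal((30, 3))
        density, coverage = density_coverage(x, x.copy(), k=5)
        assert coverage == 1.0

    def test_hand_case_density_above_one(self):
        density, coverage = density_coverage(
            np.array([[0.0], [2.0]]), np.array([[1.0]]), k=1
        )
        assert density == pytest.approx(2.0)
        assert coverage == 1.0

    def test_far_synthetic_gives_zero(self):
        x = np.random.default_rng(1).standard_normal((20, 2))
        density, coverage = density_coverage(x, x + 100.0, k=3)
        assert density == 0.0 and coverage == 0.0

    def test_n_must_exceed_k(self):
        with pytest.raises(DataError):
            density_coverage(np.zeros((5, 1)), np.zeros((3, 1)), k=5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        real = rng.standard_normal((40, 3))
        syn = rng.standard_normal((35, 3)) * 1.5
        ours = density_coverage(real, syn, k=4)
        oracle = brute_force_density_coverage(real, syn, k=4)
        assert ours[0] == pytest.approx(oracle[0])
        assert ours[1] == pytest.approx(oracle[1])

    def test_translation_invariance(self):
        rng = np.random.default_rng(9)
        real = rng.standard_normal((30, 2))
        syn = rng.standard_normal((25, 2))
        shift = np.array([7.0, -3.0])
        assert density_coverage(real, syn, 3) == density_coverage(
            real + shift, syn + shift, 3
        )


class TestMoments:
    def test_hand_values(self):
        x = np.array([[1.0], [2.0], [3.0]])
        table = moment_comparison(x, x.copy())
        assert table["real_mean"].iloc[0] == pytest.approx(2.0)
        assert table["real_var"].iloc[0] == pytest.approx(1.0)
        assert table["real_mean"].iloc[0] == table["synthetic_mean"].iloc[0]

    def test_ci_halfwidth(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)[:, None]
        x = (x - x.mean()) / x.std(ddof=1)  # force s = 1 exactly
        table = moment_comparison(x, x.copy())
        assert table["real_ci_halfwidth"].iloc[0] == pytest.approx(0.196)


class TestShiftReport:
    def test_identical_cohorts(self):
        x = np.arange(1.0, 4.0)[:, None]
        table = shift_report(x, x.copy())
        assert table["U"].iloc[0] == pytest.approx(4.5)  # n1*n2/2
        assert table["p_adjusted"].iloc[0] == pytest.approx(1.0)
        assert not table["significant"].iloc[0]

    def test_fully_separated_cohorts(self):
        a = np.array([[1.0], [2.0], [3.0]])
        b = np.array([[10.0], [11.0], [12.0]])
        table = shift_report(a, b)
        assert table["U"].iloc[0] == 0.0  # min(U1, U2) convention

    def test_bonferroni_is_min_one_d_times_p(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((40, 6))
        b = rng.standard_normal((40, 6)) + rng.normal(0, 0.5, 6)
        table = shift_report(a, b)
        np.testing.assert_allclose(
            table["p_adjusted"], np.minimum(1.0, 6 * table["p_value"])
        )
        # monotone in the raw p
        order = table.sort_values("p_value")
        assert order["p_adjusted"].is_monotonic_increasing

    def test_missing_cells_dropped_pairwise(self):
        a = np.array([[1.0], [np.nan], [3.0], [2.0]])
        b = np.array([[1.5], [2.5], [np.nan], [3.5]])
        table = shift_report(a, b)  # simply must run on the observed values
        assert np.isfinite(table["p_value"].iloc[0])

    def test_empty_feature_rejected(self):
        with pytest.raises(DataError):
            shift_report(np.full((3, 1), np.nan), np.ones((3, 1)))

    def test_null_calibration_and_flag_rate(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal((150, 200))
        b = rng.standard_normal((150, 200))
        table = shift_report(a, b)
        assert 0.4 < table["p_value"].mean() < 0.6
        # raw p < 0.05 occurs at roughly the nominal rate; Bonferroni kills all
        raw_flags = (table["p_value"] < 0.05).sum()
        assert 2 <= raw_flags <= 25
        assert table["significant"].sum() <= 1
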