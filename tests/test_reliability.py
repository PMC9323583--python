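import numpy as np
import pytest

from conftest import brute_force_icc
from fdretina.errors import DegenerateInputError, InputError
from fdretina.reliability import (
    bland_altman,
    cicchetti_label,
    cv,
    format_proportion,
    icc,
    normality_check,
    paired_t,
    summarize,
)
from fdretina.synthetic import (
    VarianceComponentsParams,
    simulate_measurement_table,
)


class TestICC:
    def test_identical_raters_give_one(self):
        y = np.column_stack([np.arange(1.0, 7.0)] * 3)
        for model in ("ICC_1_1", "ICC_2_1", "ICC_3_1"):
            assert icc(y, model).estimate == pytest.approx(1.0)

    def test_rater_offset_distinguishes_consistency_from_agreement(self):
        y = np.array([[1.0, 11.0], [2.0, 12.0], [3.0, 13.0], [4.0, 14.0]])
        assert icc(y, "ICC_3_1").estimate == pytest.approx(1.0)
        assert icc(y, "ICC_2_1").estimate < 1.0

    @pytest.mark.parametrize("model", ["ICC_1_1", "ICC_2_1", "ICC_3_1"])
    def test_matches_brute_force_anova_oracle(self, model, rng):
        for _ in range(50):
            y = rng.normal(size=(10, 3))
            assert icc(y, model).estimate == pytest.approx(
                brute_force_icc(y, model), abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        y = rng.normal(size=(12, 3))
        n, k = y.shape
        frame = pd.DataFrame({
            "targets": np.repeat(np.arange(n), k),
            "raters": np.tile(np.arange(k), n),
            "ratings": y.ravel(),
        })
        ref = pingouin.intraclass_corr(frame, targets="targets",
                                       raters="raters", ratings="ratings")
        for model, pg_type in [("ICC_1_1", "ICC(1,1)"), ("ICC_2_1", "ICC(A,1)"),
                               ("ICC_3_1", "ICC(C,1)")]:
            row = ref[ref["Type"] == pg_type].iloc[0]
            res = icc(y, model)
            assert res.estimate == pytest.approx(row["ICC"], abs=1e-8)
            lo, hi = row["CI95"]  # pingouin rounds bounds to 2 decimals
            assert res.ci_low == pytest.approx(lo, abs=6e-3)
            assert res.ci_high == pytest.approx(hi, abs=6e-3)

    def test_ci_brackets_estimate(self, rng):
        for _ in range(20):
            y = rng.normal(size=(8, 2)) + rng.normal(size=(8, 1)) * 2
            for model in ("ICC_1_1", "ICC_2_1", "ICC_3_1"):
                res = icc(y, model)
                assert res.ci_low <= res.estimate <= res.ci_high

    def test_parameter_recovery(self):
        for true, sigma_s in [(0.1, 1.0 / 3.0), (0.5, 1.0), (0.9, 3.0)]:
            ests = []
            for seed in range(100):
                table = simulate_measurement_table(VarianceComponentsParams(
                    mu=0.0, sigma_subject=sigma_s, sigma_observer=0.0,
                    sigma_error=1.0, n_subjects=200, n_raters=2, seed=seed))
                ests.append(icc(table, "ICC_2_1").estimate)
            assert abs(np.mean(ests) - true) <= 0.05

    def test_long_format_input(self):
        table = simulate_measurement_table(VarianceComponentsParams(
            mu=1.7, sigma_subject=0.05, sigma_observer=0.01,
            sigma_error=0.01, n_subjects=10, n_raters=2, seed=0))
        wide = table.pivot(index="participant_id", columns="rater_id",
                           values="value").to_numpy()
        assert icc(table, "ICC_2_1").estimate == pytest.approx(
            icc(wide, "ICC_2_1").estimate)

    def test_missing_cells_rejected(self):
        table = simulate_measurement_table(VarianceComponentsParams(
            mu=0, sigma_subject=1, sigma_observer=0, sigma_error=1,
            n_subjects=5, n_raters=2, seed=0))
        with pytest.raises(InputError):
            icc(table.iloc[:-1], "ICC_2_1")

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            icc(np.ones((5, 2)), "ICC_2_1")

    def test_unknown_model_rejected(self):
        with pytest.raises(InputError):
            icc(np.random.default_rng(0).normal(size=(5, 2)), "ICC_9_9")


class TestCV:
    def test_identical_repeats_zero(self):
        assert cv([[2.0, 2.0], [3.0, 3.0]]).cv_percent == 0.0

    def test_single_subject_hand_computed(self):
        # SD = sqrt(2), mean = 2 -> 70.71%
        res = cv([[1.0, 3.0]])
        assert res.cv_percent == pytest.approx(100 * np.sqrt(2) / 2, abs=1e-10)
        assert res.cv_percent == pytest.approx(70.71, abs=0.005)

    def test_constant_offset_decreases_cv(self):
        base = [[1.0, 2.0], [2.0, 4.0]]
        shifted = [[v + 10 for v in g] for g in base]
        assert cv(shifted).cv_percent < cv(base).cv_percent

    def test_overall_aggregation(self):
        values = [1.0, 2.0, 3.0, 4.0]
        res = cv([values], aggregation="overall")
        expected = np.std(values, ddof=1) / np.mean(values) * 100
        assert res.cv_percent == pytest.approx(expected)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(InputError):
            cv([[-1.0, 1.0]])


class TestBlandAltman:
    def test_equal_series(self):
        x = np.array([1.0, 2.0, 3.0])
        res = bland_altman(x, x)
        assert res.bias == 0.0
        assert res.loa_low == res.loa_high == 0.0

    def test_constant_offset(self):
        x = np.array([1.0, 2.0, 3.0])
        res = bland_altman(x, x + 2.0)
        assert res.bias == pytest.approx(-2.0)
        assert res.sd_diff == 0.0

    def test_hand_computed_toy_case(self):
        res = bland_altman([1.0, 2.0, 3.0], [2.0, 2.0, 5.0])
        assert res.bias == pytest.approx(-1.0)
        assert res.sd_diff == pytest.approx(1.0)
        assert res.loa_low == pytest.approx(-2.96)
        assert res.loa_high == pytest.approx(0.96)

    def test_pairs_carry_mean_and_difference(self):
        res = bland_altman([1.0, 2.0, 3.0], [2.0, 2.0, 5.0])
        means, diffs = zip(*res.pairs)
        assert means == (1.5, 2.0, 4.0)
        assert diffs == (-1.0, 0.0, -2.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            bland_altman([1.0, 2.0, 3.0], [1.0, 2.0])

    def test_limit_coverage_near_95_percent(self, rng):
        d = rng.normal(0.1, 1.0, size=10000)
        res = bland_altman(d, np.zeros_like(d))
        inside = ((d >= res.loa_low) & (d <= res.loa_high)).mean()
        assert 0.94 <= inside <= 0.96


class TestPairedT:
    def test_zero_mean_difference(self):
        x = np.array([1.0, 0.0, 1.0, 2.0])
        y = x - np.array([1.0, -1.0, 0.0, 0.0])
        t, p = paired_t(x, y)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_systematic_shift_significant(self, rng):
        x = rng.normal(size=30)
        y = x + 1.0 + rng.normal(0, 0.01, size=30)
        _, p = paired_t(x, y)
        assert p < 0.001

    def test_antisymmetry(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        t1, p1 = paired_t(x, y)
        t2, p2 = paired_t(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])


class TestNormalityCheck:
    def test_type_i_control_on_normal_draws(self):
        rejections = 0
        for seed in range(100):
            v = np.random.default_rng(seed).normal(size=500)
            _, p = normality_check(v)
            rejections += p <= 0.01
        assert rejections <= 2

    def test_power_on_exponential_draws(self):
        rejections = 0
        for seed in range(100):
            v = np.random.default_rng(seed).exponential(size=500)
            _, p = normality_check(v)
            rejections += p < 0.01
        assert rejections >= 95

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateInputError):
            normality_check(np.ones(10))

    def test_n_out_of_range_rejected(self):
        with pytest.raises(InputError):
            normality_check([1.0, 2.0])


class TestCicchettiLabel:
    @pytest.mark.parametrize("value,label", [
        (0.722, "good"), (0.828, "excellent"),
        (0.651, "good"), (0.363, "poor"),
        (0.40, "fair"), (0.60, "good"), (0.75, "excellent"),
        (0.39, "poor"), (0.59, "fair"), (0.74, "good"), (1.0, "excellent"),
    ])
    def test_bands(self, value, label):
        assert cicchetti_label(value) == label

    def test_monotone_non_decreasing(self):
        order = ["poor", "fair", "good", "excellent"]
        grid = np.linspace(-1.0, 1.0, 201)
        ranks = [order.index(cicchetti_label(v)) for v in grid]
        assert all(a <= b for a, b in zip(ranks, ranks[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            cicchetti_label(1.5)


class TestSummaries:
    def test_mean_sd_range_format(self):
        res = summarize([1.0, 2.0, 3.0])
        assert res["mean"] == 2.0
        assert res["sd"] == 1.0
        assert res["formatted"] == "2 ± 1 (1–3)"

    def test_constant_series_sd_zero(self):
        assert summarize([4.0, 4.0, 4.0])["sd"] == 0.0

    def test_proportion_formatting(self):
        pct, formatted = format_proportion(29, 43)
        assert pct == 67.44
        assert formatted == "29 (67.44)"
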