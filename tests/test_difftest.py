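import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylrescue.difftest import (
    NO_SHRINKAGE,
    ShrinkagePrior,
    call_degs,
    call_dmrs,
    estimate_prior,
    expression_summary,
    moderated_two_sample_test,
)
from methylrescue.io_formats import SampleSheet, ValidationError


class TestModeratedTest:
    def test_identical_groups_give_null_result(self):
        a = np.array([0.1, 0.2, 0.3])
        t, p = moderated_two_sample_test(a, a.copy(), NO_SHRINKAGE)
        assert t == 0 and p == pytest.approx(1.0)

    def test_equals_classical_t_without_shrinkage(self):
        # spec worked example plus random instances, 10 significant figures
        a = np.array([0.10, 0.12, 0.11])
        b = np.array([0.30, 0.28, 0.29])
        t, p = moderated_two_sample_test(a, b, NO_SHRINKAGE)
        ref = stats.ttest_ind(b, a, equal_var=True)
        assert t == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

        rng = np.random.default_rng(0)
        for _ in range(25):
            x = rng.normal(size=rng.integers(2, 6))
            y = rng.normal(size=rng.integers(2, 6))
            t, p = moderated_two_sample_test(x, y, NO_SHRINKAGE)
            ref = stats.ttest_ind(y, x, equal_var=True)
            assert t == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_infinite_prior_df_fixes_variance(self):
        a = np.array([0.1, 0.2, 0.3])
        b = np.array([0.5, 0.6, 0.4])
        prior = ShrinkagePrior(d0=math.inf, s0_sq=0.04)
        t, _ = moderated_two_sample_test(a, b, prior)
        delta = b.mean() - a.mean()
        assert t == pytest.approx(delta / (0.2 * math.sqrt(2 / 3)))

    def test_zero_variance_degenerate(self):
        a = np.array([1.0, 1.0])
        b = np.array([2.0, 2.0])
        with pytest.warns(UserWarning):
            t, p = moderated_two_sample_test(a, b, NO_SHRINKAGE)
        assert p == 0.0
        with pytest.warns(UserWarning):
            _, p_eq = moderated_two_sample_test(a, a.copy(), NO_SHRINKAGE)
        assert p_eq == 1.0

    def test_monotone_in_effect_size(self):
        rng = np.random.default_rng(1)
        base_a = rng.normal(0, 0.1, size=3)
        prior = ShrinkagePrior(d0=4.0, s0_sq=0.01)
        stats_out = []
        for shift in [0.0, 0.1, 0.2, 0.4]:
            b = base_a + shift  # same residuals, growing mean difference
            t, _ = moderated_two_sample_test(base_a, b, prior)
            stats_out.append(abs(t))
        assert all(x <= y for x, y in zip(stats_out, stats_out[1:]))

    def test_type_i_error_calibrated_under_null(self):
        rng = np.random.default_rng(1234)
        n_features = 10_000
        a = rng.normal(0.0, 0.05, size=(n_features, 3))
        b = rng.normal(0.0, 0.05, size=(n_features, 3))
        s_sq = (
            ((a - a.mean(1, keepdims=True)) ** 2).sum(1) + ((b - b.mean(1, keepdims=True)) ** 2).sum(1)
        ) / 4
        prior = estimate_prior(s_sq, df=4)
        _, p = moderated_two_sample_test(a, b, prior)
        rate = float((p < 0.05).mean())
        assert abs(rate - 0.05) <= 0.015


class TestEstimatePrior:
    def test_identical_variances_give_infinite_df(self):
        prior = estimate_prior(np.full(100, 0.01), df=4)
        assert math.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.01, rel=1e-6)

    def test_too_few_features_disable_shrinkage(self):
        prior = estimate_prior(np.array([0.01, 0.02, 0.03, 0.02, 0.01]), df=4)
        assert prior.d0 == 0.0

    def test_recovers_known_hierarchical_truth(self):
        # sigma_g^2 ~ s0^2 * d0 / chisq(d0); s_g^2 | sigma_g^2 ~ sigma_g^2 chisq(d)/d
        rng = np.random.default_rng(7)
        d0_true, s0_true, d = 4.0, 0.02, 4
        n = 5000
        sigma_sq = s0_true * d0_true / rng.chisquare(d0_true, size=n)
        s_sq = sigma_sq * rng.chisquare(d, size=n) / d
        prior = estimate_prior(s_sq, df=d)
        assert abs(prior.d0 - d0_true) <= 1.0
        assert abs(prior.s0_sq - s0_true) / s0_true <= 0.20


def _matrix(rows: dict, samples: list[str]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=samples)


SHEET6 = SampleSheet({f"y{i}": "young" for i in range(3)} | {f"o{i}": "old" for i in range(3)})
COLS6 = SHEET6.samples


class TestCallDmrs:
    def _bins(self, rng, n=60):
        # null bins around 0.5 with small noise plus three crafted bins
        rows = {f"b{i}": rng.normal(0.5, 0.01, 6) for i in range(n)}
        rows["big_shift"] = np.array([0.50, 0.51, 0.49, 0.65, 0.66, 0.64])  # delta 0.15, tight
        rows["noisy_shift"] = np.array([0.30, 0.70, 0.50, 0.45, 0.75, 0.55])  # delta 0.15-ish, huge spread
        rows["small_shift"] = np.array([0.50, 0.51, 0.49, 0.58, 0.59, 0.57])  # delta 0.08 < 0.1
        return _matrix(rows, COLS6)

    def test_threshold_logic(self):
        calls = call_dmrs(self._bins(np.random.default_rng(2)), SHEET6, "young", "old")
        calls = calls.set_index("feature_id")
        big = calls.loc["big_shift"]
        assert big["significant"] and big["direction"] == "hyper" and big["p_value"] < 0.05
        assert not calls.loc["noisy_shift"]["significant"]  # p too large
        small = calls.loc["small_shift"]
        assert small["p_value"] < 0.05 and not small["significant"]  # fails |delta| > 0.1

    def test_unknown_group_rejected(self):
        with pytest.raises(ValidationError, match="unknown group"):
            call_dmrs(self._bins(np.random.default_rng(3)), SHEET6, "young", "elderly")

    def test_invariant_under_within_group_relabeling(self):
        m = self._bins(np.random.default_rng(4))
        shuffled = m[["y2", "y0", "y1", "o1", "o2", "o0"]]
        shuffled.columns = COLS6
        a = call_dmrs(m, SHEET6, "young", "old")
        b = call_dmrs(shuffled, SHEET6, "young", "old")
        pd.testing.assert_frame_equal(a, b)

    def test_hypo_direction(self):
        rng = np.random.default_rng(5)
        rows = {f"b{i}": rng.normal(0.5, 0.01, 6) for i in range(30)}
        rows["drop"] = np.array([0.80, 0.81, 0.79, 0.60, 0.61, 0.59])
        calls = call_dmrs(_matrix(rows, COLS6), SHEET6, "young", "old").set_index("feature_id")
        assert calls.loc["drop"]["significant"] and calls.loc["drop"]["direction"] == "hypo"


class TestCallDegs:
    def test_direction_classes(self):
        rng = np.random.default_rng(6)
        rows = {f"g{i}": np.abs(rng.normal(5, 1, 6)) for i in range(30)}
        rows["up"] = np.array([1.0, 1.1, 0.9, 4.0, 4.2, 3.9])
        rows["down"] = np.array([4.0, 4.2, 3.9, 1.0, 1.1, 0.9])
        rows["flat"] = np.array([2.0, 2.1, 1.9, 2.0, 2.1, 1.9])
        rows["silent"] = np.zeros(6)
        calls = call_degs(_matrix(rows, COLS6), SHEET6, "young", "old").set_index("feature_id")
        assert "silent" not in calls.index  # all-zero genes are skipped
        assert calls.loc["up"]["significant"] and calls.loc["up"]["direction"] == "ODEG"
        assert calls.loc["down"]["significant"] and calls.loc["down"]["direction"] == "UDEG"
        assert not calls.loc["flat"]["significant"]


class TestExpressionSummary:
    def test_floor_counts_and_log2fc(self):
        sheet = SampleSheet({"y1": "young", "y2": "young", "o1": "old", "o2": "old"})
        fpkm = _matrix(
            {"gA": [0.5, 0.5, 2.0, 2.0], "gB": [2.0, 2.0, 2.0, 2.0], "gC": [2.0, 2.0, 8.0, 8.0]},
            ["y1", "y2", "o1", "o2"],
        )
        counts, ma = expression_summary(fpkm, sheet, "young", "old", fpkm_floor=1.0)
        assert counts["young"] == 2 and counts["old"] == 3  # gA only clears the floor in old
        ma = ma.set_index("gene_id")
        assert ma.loc["gB", "log2_fold_change"] == pytest.approx(0.0)
        assert ma.loc["gC", "log2_fold_change"] == pytest.approx(2.0)
        assert ma.loc["gC", "mean_expression"] == pytest.approx(5.0)
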