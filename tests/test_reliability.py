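"""ICC (three models, F-based CIs), classification, correlations, shares."""
import itertools

import numpy as np
import pytest
from scipy import stats

from mapssn.errors import (InsufficientDataError, MapsSNError,
                           UndefinedStatisticError)
from mapssn.reliability_stats import (classify_icc, concordance, correlate,
                                      crossing_type_shares, icc)


def anova_icc_oracle(x, model):
    """Independent sums-of-squares computation, written from the ANOVA
    definitions with explicit loops (no shared code with the implementation)."""
    n, k = len(x), len(x[0])
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(x[i][j] for j in range(k)) / k for i in range(n)]
    col = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ss_total = sum((x[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_rows = k * sum((m - grand) ** 2 for m in row)
    ss_cols = n * sum((m - grand) ** 2 for m in col)
    msr = ss_rows / (n - 1)
    msw = (ss_total - ss_rows) / (n * (k - 1))
    mse = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    msc = ss_cols / (k - 1)
    if model == "one_way":
        denom = msr + (k - 1) * msw
        return (msr - msw) / denom if denom else 0.0
    if model == "two_way_consistency":
        denom = msr + (k - 1) * mse
        return (msr - mse) / denom if denom else 0.0
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    return (msr - mse) / denom if denom else 0.0


class TestICC:
    def test_perfect_agreement_is_one(self):
        x = np.array([[1, 1], [2, 2], [3, 3], [5, 5]], dtype=float)
        for model in ("one_way", "two_way_agreement", "two_way_consistency"):
            res = icc(x, model=model)
            assert res.icc == pytest.approx(1.0)
            assert res.classification == "excellent"

    def test_constant_shift_distinguishes_models(self):
        base = np.array([1.0, 4.0, 2.0, 6.0, 3.0])
        x = np.column_stack([base, base + 5.0])
        assert icc(x, model="two_way_consistency").icc == pytest.approx(1.0)
        assert icc(x, model="two_way_agreement").icc < 1.0

    @pytest.mark.parametrize("model", ["one_way", "two_way_agreement",
                                       "two_way_consistency"])
    def test_matches_anova_oracle_on_worked_matrix(self, model):
        x = np.array([[9, 2], [1, 10], [8, 8], [2, 6], [7, 6], [4, 2]],
                     dtype=float)
        res = icc(x, model=model)
        assert res.icc == pytest.approx(anova_icc_oracle(x.tolist(), model),
                                        abs=1e-10)

    @pytest.mark.parametrize("model", ["one_way", "two_way_agreement",
                                       "two_way_consistency"])
    def test_exhaustive_small_matrix_sweep(self, model):
        # every 3-target x 2-rater matrix with entries in 0..3
        for flat in itertools.product(range(4), repeat=6):
            x = np.array(flat, dtype=float).reshape(3, 2)
            if np.ptp(x.mean(axis=1)) == 0:
                continue  # zero between-target variance: 0-by-convention
            res = icc(x, model=model)
            assert res.icc == pytest.approx(
                anova_icc_oracle(x.tolist(), model), abs=1e-10), flat

    def test_zero_between_target_variance_reports_zero(self):
        x = np.array([[1, 2], [1, 2], [1, 2]], dtype=float)
        with pytest.warns(UserWarning, match="zero between-target"):
            res = icc(x)
        assert res.icc == 0.0

    def test_missing_rows_dropped(self):
        x = np.array([[1, 1], [2, np.nan], [3, 3], [4, 4]])
        with pytest.warns(UserWarning, match="missing"):
            res = icc(x)
        assert res.n_targets == 3

    def test_too_few_targets_rejected(self):
        with pytest.raises(InsufficientDataError):
            icc(np.array([[1.0, 2.0]]))

    def test_ci_brackets_estimate_and_allows_negative_lower(self, rng):
        truth = rng.normal(0, 2, 8)
        x = np.column_stack([truth + rng.normal(0, 1, 8),
                             truth + rng.normal(0, 1, 8)])
        for model in ("one_way", "two_way_agreement", "two_way_consistency"):
            res = icc(x, model=model)
            lo, hi = res.ci95
            assert lo <= res.icc <= hi
            assert res.icc <= 1.0
        # tiny samples with weak signal can produce negative lower bounds
        noisy = np.column_stack([rng.normal(0, 1, 4), rng.normal(0, 1, 4)])
        res = icc(noisy, model="two_way_agreement")
        assert res.ci95[0] < res.icc  # reported as computed, not truncated

    def test_against_pingouin_cross_check(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        mapping = {"one_way": "ICC(1,1)", "two_way_agreement": "ICC(A,1)",
                   "two_way_consistency": "ICC(C,1)"}
        for trial in range(5):
            truth = rng.normal(0, 2, 10)
            x = np.column_stack([truth + rng.normal(0, 1, 10),
                                 truth + rng.normal(0.3, 1, 10)])
            df = pd.DataFrame({
                "targets": np.repeat(np.arange(10), 2),
                "raters": np.tile(["A", "B"], 10),
                "scores": x.ravel()})
            ref = pingouin.intraclass_corr(df, targets="targets",
                                           raters="raters", ratings="scores")
            ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
            for model, code in mapping.items():
                res = icc(x, model=model)
                row = ref[ref.Type == code].iloc[0]
                assert res.icc == pytest.approx(row.ICC, abs=1e-9)
                assert res.ci95 == pytest.approx(tuple(row[ci_col]), abs=2e-2)


class TestClassification:
    @pytest.mark.parametrize("value,expected", [
        (0.80, "excellent"), (0.75, "excellent"),
        (0.74, "good"), (0.60, "good"),
        (0.59, "fair"), (0.40, "fair"),
        (0.39, "poor"), (-0.2, "poor"), (1.0, "excellent"),
    ])
    def test_cicchetti_bands(self, value, expected):
        assert classify_icc(value) == expected

    def test_monotone_step_function(self):
        order = {"poor": 0, "fair": 1, "good": 2, "excellent": 3}
        grid = np.arange(-0.5, 1.001, 0.01)
        cats = [order[classify_icc(v)] for v in grid]
        assert all(a <= b for a, b in zip(cats, cats[1:]))

    def test_above_one_rejected(self):
        with pytest.raises(MapsSNError):
            classify_icc(1.2)


class TestCorrelate:
    def test_identity_and_reflection(self):
        x = [1.0, 3.0, 2.0, 5.0, 4.0]
        r, p = correlate(x, x)
        assert r == pytest.approx(1.0)
        r, _ = correlate(x, [-v for v in x])
        assert r == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_spearman_ties_average_ranks(self):
        r, _ = correlate([1, 2, 2, 3], [1, 2, 2, 3], method="spearman")
        assert r == pytest.approx(1.0)

    def test_recovery_of_generating_correlation(self, rng):
        # 12-point samples at rho = 0.9: replicate mean near the target
        rho, reps, n = 0.9, 1000, 12
        cov = [[1.0, rho], [rho, 1.0]]
        rs = []
        for _ in range(reps):
            z = rng.multivariate_normal([0, 0], cov, size=n)
            rs.append(correlate(z[:, 0], z[:, 1])[0])
        assert np.mean(rs) == pytest.approx(rho, abs=0.02)

    def test_type_one_error_rate_near_nominal(self, rng):
        reps, n = 2000, 12
        hits = 0
        for _ in range(reps):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            _, p = correlate(x, y)
            hits += p < 0.05
        assert 0.03 <= hits / reps <= 0.07


class TestConcordanceTable:
    def test_identical_sides_give_unit_correlation(self, rng):
        import pandas as pd
        vals = rng.normal(10, 2, 12)
        paired = pd.DataFrame({
            "school_id": [f"S{i:02d}" for i in range(12)],
            "grand_score_odd": vals, "grand_score_even": vals,
            "crossing_score_odd": vals, "crossing_score_even": vals,
        })
        table = concordance(paired).set_index("measure")
        assert table.loc["grand_score", "r"] == pytest.approx(1.0)

    def test_crossing_measure_has_no_side_correlation(self, rng):
        import pandas as pd
        vals = rng.normal(10, 2, 12)
        paired = pd.DataFrame({
            "school_id": [f"S{i:02d}" for i in range(12)],
            "crossing_score_odd": vals, "crossing_score_even": vals,
        })
        table = concordance(paired).set_index("measure")
        assert table.loc["crossing_score", "r"] is None or \
            np.isnan(table.loc["crossing_score", "r"])

    def test_designated_measures_use_spearman(self, rng):
        import pandas as pd
        paired = pd.DataFrame({
            "school_id": [f"S{i:02d}" for i in range(12)],
            "bicycle_facilities_odd": rng.normal(1, 0.5, 12),
            "bicycle_facilities_even": rng.normal(1, 0.5, 12),
            "grand_score_odd": rng.normal(15, 2, 12),
            "grand_score_even": rng.normal(15, 2, 12),
        })
        table = concordance(paired).set_index("measure")
        assert table.loc["bicycle_facilities", "method"] == "spearman"
        assert table.loc["grand_score", "method"] == "pearson"


class TestCrossingTypeShares:
    def test_published_tally_reproduced(self):
        df = crossing_type_shares([516, 224, 15, 12])
        assert list(df.share_pct_rounded) == [67.3, 29.2, 2.0, 1.6]
        assert list(df.ways) == [3, 4, 5, 6]

    def test_degenerate_and_uniform_tallies(self):
        assert list(crossing_type_shares([10, 0, 0, 0]).share_pct_rounded) == \
            [100.0, 0.0, 0.0, 0.0]
        assert list(crossing_type_shares([1, 1, 1, 1]).share_pct_rounded) == \
            [25.0] * 4

    def test_exact_shares_sum_to_100(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 500, size=4)
            if counts.sum() == 0:
                continue
            df = crossing_type_shares(list(counts))
            assert df.share_pct.sum() == pytest.approx(100.0, abs=1e-12)
            assert abs(df.share_pct_rounded.sum() - 100.0) <= 0.2

    def test_empty_tally_rejected(self):
        with pytest.raises(MapsSNError):
            crossing_type_shares([0, 0])
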