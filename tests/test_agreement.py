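"""ICC(2,1), qualitative bands, difference summaries, report assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tunnelmetrics as tm
from tunnelmetrics.agreement import read_ratings_csv


def icc_a1_oracle(x):
    """Definitional two-way ANOVA ICC(2,1) from raw sums of squares,
    computed with explicit loops (independent of the implementation)."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(x[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(x[i, j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((r - grand) ** 2 for r in row)
    ssc = n * sum((c - grand) ** 2 for c in col)
    sst = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC21:
    def test_identical_columns_give_one(self):
        x = np.column_stack([[5, 7, 9, 11.0]] * 2)
        res = tm.icc_2_1(x)
        assert res.icc == pytest.approx(1.0, abs=1e-12)

    def test_known_small_table_vs_hand_anova(self):
        x = np.array([[5, 6], [7, 8], [9, 10], [11, 12.0]])
        res = tm.icc_2_1(x)
        assert abs(res.icc - icc_a1_oracle(x)) < 1e-10
        assert res.icc == pytest.approx(0.930, abs=1e-3)

    def test_random_tables_match_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            x = rng.normal(6, 2, size=(20, 3)) + rng.normal(0, 1, size=(20, 1))
            res = tm.icc_2_1(x)
            assert abs(res.icc - icc_a1_oracle(x)) < 1e-10
            assert res.ci_low <= res.icc <= res.ci_high

    def test_matches_pingouin_reference(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(21)
        for _ in range(25):
            x = rng.normal(6, 2, size=(20, 3)) + rng.normal(0, 1, size=(20, 1))
            res = tm.icc_2_1(x)
            long = pd.DataFrame({
                "subject": np.repeat(np.arange(20), 3),
                "rater": np.tile(np.arange(3), 20),
                "score": x.ravel(),
            })
            ref = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                           ratings="score")
            row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
            assert abs(res.icc - row["ICC"]) < 1e-8
            assert abs(res.ci_low - row["CI95"][0]) < 6e-3  # pingouin rounds its CI
            assert abs(res.ci_high - row["CI95"][1]) < 6e-3

    def test_all_equal_cells_defined_as_perfect(self):
        with pytest.warns(UserWarning, match="identical"):
            res = tm.icc_2_1(np.full((5, 2), 6.0))
        assert (res.icc, res.ci_low, res.ci_high) == (1.0, 1.0, 1.0)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            tm.icc_2_1(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            tm.icc_2_1(np.zeros((5, 1)))
        bad = np.ones((5, 2))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            tm.icc_2_1(bad)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 10_000), shift=st.floats(-100, 100))
    def test_shift_invariance_property(self, seed, shift):
        rng = np.random.default_rng(seed)
        x = rng.normal(7, 1.5, size=(10, 1)) + rng.normal(0, 0.5, size=(10, 3))
        base = tm.icc_2_1(x)
        moved = tm.icc_2_1(x + shift)
        assert moved.icc == pytest.approx(base.icc, abs=1e-8)
        assert base.ci_low <= base.icc <= base.ci_high

    def test_invariant_to_subject_order_and_shift(self):
        rng = np.random.default_rng(3)
        x = rng.normal(7, 1.5, size=(12, 2)) + rng.normal(0, 0.8, size=(12, 1))
        base = tm.icc_2_1(x).icc
        perm = rng.permutation(12)
        assert tm.icc_2_1(x[perm]).icc == pytest.approx(base, abs=1e-12)
        assert tm.icc_2_1(x + 100.0).icc == pytest.approx(base, abs=1e-9)

    def test_single_rater_bias_lowers_absolute_agreement(self):
        rng = np.random.default_rng(9)
        subject = rng.normal(7, 1.5, size=(15, 1))
        x = subject + rng.normal(0, 0.2, size=(15, 2))
        biased = x.copy()
        biased[:, 1] += 1.0
        assert tm.icc_2_1(biased).icc < tm.icc_2_1(x).icc

    def test_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(5)

        def median_width(n, trials=30):
            widths = []
            for _ in range(trials):
                subj = rng.normal(7, 1.5, size=(n, 1))
                x = subj + rng.normal(0, 0.5, size=(n, 2))
                res = tm.icc_2_1(x)
                widths.append(res.ci_high - res.ci_low)
            return np.median(widths)

        assert median_width(40) < median_width(10)


class TestClassification:
    @pytest.mark.parametrize("icc,expected", [
        (0.899, "excellent"),
        (0.745, "fair_to_good"),
        (-0.004, "poor"),
        (0.75, "fair_to_good"),   # boundary belongs to fair_to_good
        (0.40, "fair_to_good"),
        (0.399, "poor"),
        (0.751, "excellent"),
    ])
    def test_bands(self, icc, expected):
        assert tm.classify_icc(icc).value == expected


class TestDifferenceSummary:
    def test_identical_series(self):
        d = tm.difference_summary([5, 6, 7], [5, 6, 7])
        assert d.mean_diff_mm == 0.0 and d.sd_diff_mm == 0.0

    def test_constant_offset(self):
        d = tm.difference_summary(np.array([5, 6, 7]) + 0.3, [5, 6, 7])
        assert d.mean_diff_mm == pytest.approx(0.3, abs=1e-12)
        assert d.sd_diff_mm == pytest.approx(0.0, abs=1e-12)

    def test_two_point_hand_computation(self):
        d = tm.difference_summary([5.2, 6.9], [5.0, 7.0])
        diffs = np.array([0.2, -0.1])
        assert d.mean_diff_mm == pytest.approx(diffs.mean(), abs=1e-12)
        # sample SD, n-1 denominator
        assert d.sd_diff_mm == pytest.approx(
            np.sqrt(((diffs - diffs.mean()) ** 2).sum() / 1), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            tm.difference_summary([1, 2], [1, 2, 3])


class TestAgreementReport:
    def _frame(self, values_by_method, ids):
        rows = [{"tunnel_id": i, "method": m, "diameter_mm": v}
                for m, vals in values_by_method.items() for i, v in zip(ids, vals)]
        return pd.DataFrame(rows)

    def test_perfect_measurements(self):
        ids = [f"t{i}" for i in range(6)]
        truths = dict(zip(ids, [5.0, 6.0, 6.5, 7.0, 8.0, 9.0]))
        frame = self._frame({"cylinder_fit": list(truths.values()),
                             "ct2d": list(truths.values())}, ids)
        report = tm.agreement_report(frame, truths)
        assert len(report) == 2
        assert (report.icc == 1.0).all()
        assert (report.mean_diff_mm == 0.0).all()

    def test_repeats_add_intra_rater_columns(self):
        ids = [f"t{i}" for i in range(6)]
        vals = [5.1, 6.2, 6.4, 7.1, 7.9, 8.8]
        truths = dict(zip(ids, [5.0, 6.0, 6.5, 7.0, 8.0, 9.0]))
        frame = self._frame({"ct2d": vals}, ids)
        repeats = self._frame({"ct2d": [v + 0.05 for v in vals]}, ids)
        report = tm.agreement_report(frame, truths, repeats=repeats)
        assert "intra_icc" in report.columns
        assert report.loc[0, "intra_icc"] > 0.9

    def test_failed_method_yields_error_row(self):
        ids = [f"t{i}" for i in range(4)]
        truths = dict(zip(ids, [5.0, 6.0, 7.0, 8.0]))
        frame = self._frame({"wall_thickness": [np.nan] * 4,
                             "ct2d": [5.1, 6.1, 7.1, 8.1]}, ids)
        report = tm.agreement_report(frame, truths).set_index("method")
        assert "error" in report.columns
        assert isinstance(report.loc["wall_thickness", "error"], str)
        assert report.loc["ct2d", "icc"] > 0.9


class TestRatingsIO:
    def test_long_csv_pivots(self, tmp_path):
        path = tmp_path / "ratings.csv"
        pd.DataFrame({
            "tunnel_id": ["a", "a", "b", "b", "c", "c"],
            "rater": ["m1", "m2"] * 3,
            "value_mm": [5.0, 5.1, 6.0, 6.2, 7.0, 6.9],
        }).to_csv(path, index=False)
        wide = read_ratings_csv(path)
        assert wide.shape == (3, 2)
        res = tm.icc_2_1(wide)
        assert res.icc > 0.9
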