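"""Error summaries, the paired user test, and survey summarization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from arguide.datasets import patient_survey, surgeon_survey
from arguide.evaluation import (SurveyTable, distance_error_correlation, paired_user_test,
                                summarize_errors, survey_summary, error_boxplot)


def frame(errors, **cols):
    n = len(errors)
    base = {"case": ["C1"] * n, "user": [1] * n, "rep": [1] * n,
            "target": list(range(n)), "error_mm": errors,
            "distance_to_marker_mm": list(np.linspace(10, 60, n))}
    base.update(cols)
    return pd.DataFrame(base)


class TestSummarize:
    def test_constant_errors_zero_sd(self):
        s = summarize_errors(frame([2.0] * 10))
        r = s.row(case="C1")
        assert r.sd_mm == 0.0 and r.mean_mm == 2.0 and r.n == 10

    def test_quartiles_match_sorting_oracle(self, rng):
        e = rng.gamma(2.0, 1.0, 10)
        s = summarize_errors(frame(list(e)))
        r = s.row(case="C1")
        q1, med, q3 = np.percentile(np.sort(e), [25, 50, 75])
        assert np.isclose(r.q1_mm, q1) and np.isclose(r.median_mm, med) and np.isclose(r.q3_mm, q3)
        assert r.q1_mm <= r.median_mm <= r.q3_mm
        assert np.isclose(r.whisker_high_mm, r.mean_mm + 1.5 * r.sd_mm)

    def test_permutation_invariant(self, rng):
        e = list(rng.gamma(2.0, 1.0, 12))
        a = summarize_errors(frame(e)).table
        perm = list(rng.permutation(e))
        b = summarize_errors(frame(perm)).table
        pd.testing.assert_frame_equal(a, b)

    def test_group_by_case_one_row_per_phantom(self, rng):
        dfs = [frame(list(rng.gamma(2, 1, 8)), case=[f"C{i}"] * 8) for i in range(6)]
        s = summarize_errors(pd.concat(dfs, ignore_index=True), ("case",))
        assert len(s.table) == 6
        assert sorted(s.table["case"]) == [f"C{i}" for i in range(6)]

    def test_tukey_whisker_mode(self, rng):
        s = summarize_errors(frame(list(rng.gamma(2, 1, 20))), whisker="iqr")
        r = s.row(case="C1")
        assert np.isclose(r.whisker_high_mm, r.q3_mm + 1.5 * (r.q3_mm - r.q1_mm))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_errors(pd.DataFrame(columns=["error_mm"]))

    def test_boxplot_builds(self, rng):
        s = summarize_errors(frame(list(rng.gamma(2, 1, 15))))
        ax = error_boxplot(s)
        assert ax.get_ylabel() == "Error (mm)"


class TestPairedUserTest:
    def test_identical_vectors(self):
        t, p = paired_user_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_matches_hand_formula(self, rng):
        """t = mean(d) / (sd(d)/sqrt(n)) on a worked 5-pair example."""
        u1 = np.array([2.1, 1.8, 2.5, 3.0, 2.2])
        u2 = np.array([2.0, 2.1, 2.3, 2.8, 2.6])
        d = u1 - u2
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        t, p = paired_user_test(u1, u2)
        assert abs(t - t_hand) < 1e-10
        from scipy import stats

        assert abs(p - 2 * stats.t.sf(abs(t_hand), len(d) - 1)) < 1e-10

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_user_test([1, 2], [1, 2, 3])

    def test_null_pvalues_uniform(self, rng):
        """Under the null, p-values are U[0,1] (KS sanity at 1000 reps)."""
        from scipy import stats

        ps = []
        for _ in range(1000):
            a = rng.normal(2.0, 0.5, 6)
            b = rng.normal(2.0, 0.5, 6)
            ps.append(paired_user_test(a, b)[1])
        d, p_ks = stats.kstest(ps, "uniform")
        assert p_ks > 0.05


class TestDistanceCorrelation:
    def test_constant_errors_flagged(self):
        rho, p, defined = distance_error_correlation(frame([1.5] * 8))
        assert not defined and rho == 0.0

    def test_linear_construction(self):
        d = np.linspace(5, 100, 30)
        df = frame(list(0.05 * d))
        df["distance_to_marker_mm"] = d
        rho, p, defined = distance_error_correlation(df)
        assert defined and rho > 0.999

    def test_too_few_distances(self):
        df = frame([1.0, 2.0])
        df["distance_to_marker_mm"] = [5.0, 5.0]
        with pytest.raises(ValueError):
            distance_error_correlation(df)


class TestSurvey:
    def test_all_fives(self):
        t = SurveyTable(["q1", "q2"], ["r1", "r2", "r3"], np.full((2, 3), 5))
        s = survey_summary(t)
        assert (s["question_means"] == 5.0).all()
        assert (s["respondent_means"] == 5.0).all()
        assert s["overall"] == 5.0

    def test_surgeon_question_one(self):
        """Scores 5,4,5,5,3,5 average to 4.5 after half-up rounding."""
        s = survey_summary(surgeon_survey())
        assert s["question_means"].iloc[0] == 4.5

    def test_patient_question_one(self):
        s = survey_summary(patient_survey())
        assert s["question_means"].iloc[0] == 3.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SurveyTable(["q"], ["r"], np.array([[6]]))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.lists(st.integers(1, 5), min_size=2, max_size=6),
                    min_size=1, max_size=8).filter(lambda r: len({len(x) for x in r}) == 1))
    def test_means_bounded_by_scores(self, scores):
        arr = np.array(scores)
        t = SurveyTable([f"q{i}" for i in range(arr.shape[0])],
                        [f"r{j}" for j in range(arr.shape[1])], arr)
        s = survey_summary(t)
        assert s["question_means"].min() >= arr.min() - 0.05
        assert s["question_means"].max() <= arr.max() + 0.05

    def test_csv_roundtrip(self, tmp_path):
        t = surgeon_survey()
        t.to_csv(tmp_path / "s.csv")
        t2 = SurveyTable.from_csv(tmp_path / "s.csv")
        assert np.array_equal(t.scores, t2.scores)
        assert t.questions == t2.questions
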