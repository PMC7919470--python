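"""Summary statistics, user-effect testing, and survey summarization.

Error summaries follow the reporting conventions of phantom accuracy
studies: mean ± sample standard deviation (n−1), median and quartiles
per grouping (per case, per user), with box-plot whiskers at ±1.5
standard deviations around the mean (an alternative Tukey 1.5·IQR mode
is available).  The user effect is assessed with a two-sided paired
t-test on per-condition means; spatial error structure with the Spearman
rank correlation between target-to-marker distance and error, the
signature of lever-arm (rotational) error growth away from the reference
marker.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .phantom import TrialResult, trials_to_dataframe

__all__ = ["ErrorSummary", "SurveyTable", "summarize_errors", "paired_user_test",
           "distance_error_correlation", "survey_summary", "error_boxplot"]


# ----------------------------------------------------------------------
# error summaries
# ----------------------------------------------------------------------

@dataclass
class ErrorSummary:
    """Grouped error statistics as a tidy table (one row per group)."""

    table: pd.DataFrame
    group_by: tuple[str, ...]

    def __getitem__(self, col):
        return self.table[col]

    def row(self, **keys) -> pd.Series:
        t = self.table
        for k, v in keys.items():
            t = t[t[k] == v]
        if len(t) != 1:
            raise KeyError(f"keys {keys} select {len(t)} rows")
        return t.iloc[0]


def _as_dataframe(trials) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        return trials
    return trials_to_dataframe(list(trials))


def summarize_errors(trials, group_by=("case",), whisker: str = "sd") -> ErrorSummary:
    """Per-group mean, sample sd, median, quartiles and whisker bounds.

    ``trials`` is a list of :class:`~arguide.phantom.TrialResult` or an
    equivalent long-format DataFrame with an ``error_mm`` column.
    ``whisker='sd'`` places whiskers at mean ± 1.5·sd (the figure
    convention used here); ``whisker='iqr'`` uses Tukey fences.
    """
    df = _as_dataframe(trials)
    if df.empty:
        raise ValueError("no trial data to summarize")
    if isinstance(group_by, str):
        group_by = (group_by,)
    group_by = tuple(group_by)
    if whisker not in ("sd", "iqr"):
        raise ValueError("whisker must be 'sd' or 'iqr'")

    def agg(g: pd.Series) -> pd.Series:
        e = g.to_numpy(dtype=float)
        mean = e.mean()
        sd = e.std(ddof=1) if len(e) > 1 else 0.0
        q1, med, q3 = np.percentile(e, [25, 50, 75])
        if whisker == "sd":
            lo, hi = mean - 1.5 * sd, mean + 1.5 * sd
        else:
            iqr = q3 - q1
            lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        return pd.Series({"n": len(e), "mean_mm": mean, "sd_mm": sd, "median_mm": med,
                          "q1_mm": q1, "q3_mm": q3, "whisker_low_mm": lo, "whisker_high_mm": hi})

    out = df.groupby(list(group_by), sort=True)["error_mm"].apply(agg).unstack().reset_index()
    out["n"] = out["n"].astype(int)
    return ErrorSummary(out, group_by)


def paired_user_test(u1, u2) -> tuple[float, float]:
    """Two-sided paired t-test on matched per-condition means.

    Null hypothesis: no systematic difference between the two users.
    Identical vectors (zero variance of differences) report ``(0.0, 1.0)``.
    """
    a = np.asarray(u1, dtype=float).ravel()
    b = np.asarray(u2, dtype=float).ravel()
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        return np.inf * np.sign(d.mean()), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def distance_error_correlation(trials) -> tuple[float, float, bool]:
    """Spearman rank correlation between target-to-marker distance and error.

    Returns ``(rho, p_value, defined)``; ``defined`` is False when either
    variable is constant (correlation undefined, rho reported as 0).
    """
    df = _as_dataframe(trials)
    d = df["distance_to_marker_mm"].to_numpy(dtype=float)
    e = df["error_mm"].to_numpy(dtype=float)
    if len(np.unique(d)) < 3:
        raise ValueError("need at least 3 targets with distinct distances")
    if np.allclose(e, e[0]) or np.allclose(d, d[0]):
        return 0.0, np.nan, False
    rho, p = stats.spearmanr(d, e)
    return float(rho), float(p), True


# ----------------------------------------------------------------------
# surveys
# ----------------------------------------------------------------------

def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SurveyTable:
    """5-point Likert survey: one row per question, one column per respondent."""

    questions: list[str]
    respondents: list[str]
    scores: np.ndarray  # (n_questions, n_respondents) ints in 1..5

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=int)
        if self.scores.shape != (len(self.questions), len(self.respondents)):
            raise ValueError("score matrix shape does not match labels")
        if ((self.scores < 1) | (self.scores > 5)).any():
            raise ValueError("Likert scores must be integers in [1, 5]")

    @classmethod
    def from_csv(cls, path) -> "SurveyTable":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index), [str(c) for c in df.columns], df.to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame(self.scores, index=self.questions, columns=self.respondents) \
            .to_csv(path, index_label="question")


def survey_summary(table: SurveyTable, decimals: int = 1) -> dict:
    """Per-question and per-respondent mean scores, rounded half-up.

    Returns a dict with ``question_means`` and ``respondent_means``
    (pandas Series) plus the ``overall`` mean of all individual scores,
    each rounded half-up to ``decimals`` (matching printed score tables).
    """
    s = table.scores.astype(float)
    qm = pd.Series([_round_half_up(v, decimals) for v in s.mean(axis=1)],
                   index=table.questions, name="mean_score")
    rm = pd.Series([_round_half_up(v, decimals) for v in s.mean(axis=0)],
                   index=table.respondents, name="mean_score")
    return {"question_means": qm, "respondent_means": rm,
            "overall": _round_half_up(s.mean(), decimals)}


# ----------------------------------------------------------------------
# plotting
# ----------------------------------------------------------------------

def error_boxplot(summary: ErrorSummary, ax=None, ylabel: str = "Error (mm)"):
    """Box plot of grouped errors from an :class:`ErrorSummary`.

    Boxes span Q1-Q3 with the median line; whiskers use the summary's
    precomputed bounds (±1.5 sd by default).
    """
    import matplotlib

    if ax is None:
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(1.2 * len(summary.table) + 2, 4))
    t = summary.table
    labels = t[list(summary.group_by)].astype(str).agg("/".join, axis=1)
    bxp = [
        {"label": lab, "med": r.median_mm, "q1": r.q1_mm, "q3": r.q3_mm,
         "whislo": max(r.whisker_low_mm, 0.0), "whishi": r.whisker_high_mm, "fliers": []}
        for lab, (_, r) in zip(labels, t.iterrows())
    ]
    ax.bxp(bxp, showfliers=False)
    ax.set_ylabel(ylabel)
    ax.tick_params(axis="x", rotation=45)
    return ax
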