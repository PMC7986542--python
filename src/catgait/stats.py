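"""Group comparisons and effect-size-based parameter ranking.

Parameters are ranked between the uninjured and injured groups with a
Welch t test (no equal-variance assumption) on per-animal means; all
parameters with p below the selection threshold (default 0.01, applied to
the unadjusted p value) enter the discriminant fit, with Cohen's d (pooled
SD form) reported alongside.  Two-group score comparisons use the same
Welch test; three or more groups use a one-way ANOVA followed by pairwise
pooled-variance t tests with Bonferroni correction.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

#: significance stars at the conventional thresholds
STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return ""


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def welch_t_test(a, b) -> WelchResult:
    """Two-sided Welch t test.

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b) with
    Welch-Satterthwaite degrees of freedom.  Conventions for degenerate
    input: both variances zero with equal means -> t = 0, p = 1; zero
    variances with unequal means is an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t_test needs at least 2 observations per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchResult(t=0.0, df=float(na + nb - 2), p=1.0)
        raise ValueError("both samples have zero variance but different means")
    se2a, se2b = va / na, vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2a + se2b)
    df = (se2a + se2b) ** 2 / (
        se2a**2 / (na - 1) + se2b**2 / (nb - 1)
    )
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(p))


def cohens_d(a, b) -> float:
    """Cohen's d with the pooled standard deviation, (n-1)-weighted."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


def rank_and_select(
    data: pd.DataFrame,
    groups,
    uninjured_label,
    injured_label,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Welch-test ranking of candidate parameters on per-animal vectors.

    ``data`` holds one row per animal (parameter columns only) and
    ``groups`` the parallel group labels.  Returns one row per parameter,
    sorted ascending by p, with columns t, df, p, cohens_d, n_uninjured,
    n_injured and the boolean ``selected`` = (p < p_threshold).
    Parameters missing for an entire group are excluded and logged.
    """
    groups = pd.Series(list(groups)).reset_index(drop=True)
    data = data.reset_index(drop=True)
    a_mask = (groups == uninjured_label).values
    b_mask = (groups == injured_label).values
    if a_mask.sum() < 2 or b_mask.sum() < 2:
        raise ValueError("both groups need at least 2 animals")
    records = []
    for name in data.columns:
        a = data.loc[a_mask, name].dropna().to_numpy(float)
        b = data.loc[b_mask, name].dropna().to_numpy(float)
        if a.size < 2 or b.size < 2:
            logger.warning("parameter %r missing for (almost) a whole group; excluded", name)
            continue
        res = welch_t_test(a, b)
        try:
            d = cohens_d(a, b)
        except ValueError:
            d = 0.0
        records.append(
            {
                "parameter": name,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "cohens_d": d,
                "n_uninjured": a.size,
                "n_injured": b.size,
                "selected": res.p < p_threshold,
            }
        )
    out = pd.DataFrame.from_records(records).sort_values("p", kind="mergesort")
    return out.reset_index(drop=True)


@dataclass
class ComparisonReport:
    """One-way ANOVA plus Bonferroni-corrected pairwise comparisons."""

    kind: str
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame
    group_summary: pd.DataFrame


def oneway_anova_bonferroni(groups: dict, alpha: float = 0.05) -> ComparisonReport:
    """One-way ANOVA over >=3 groups with Bonferroni-corrected post hocs.

    Pairwise comparisons use pooled-variance two-sample t tests; adjusted
    p = min(1, raw p x number of pairs).  Two groups are a contract error —
    use :func:`welch_t_test`.
    """
    if len(groups) < 3:
        raise ValueError("need >=3 groups; for two groups use welch_t_test")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    f, p = sps.f_oneway(*arrays.values())
    pairs = list(itertools.combinations(arrays, 2))
    m = len(pairs)
    rows = []
    for g1, g2 in pairs:
        t, raw = sps.ttest_ind(arrays[g1], arrays[g2], equal_var=True)
        adj = min(1.0, float(raw) * m)
        rows.append(
            {
                "group_1": g1,
                "group_2": g2,
                "mean_diff": float(arrays[g1].mean() - arrays[g2].mean()),
                "t": float(t),
                "p_raw": float(raw),
                "p_adjusted": adj,
                "significant": adj < alpha,
                "stars": significance_stars(adj),
            }
        )
    summary = pd.DataFrame(
        {
            "group": list(arrays),
            "n": [v.size for v in arrays.values()],
            "mean": [v.mean() for v in arrays.values()],
            "sd": [v.std(ddof=1) for v in arrays.values()],
        }
    )
    return ComparisonReport(
        kind="oneway_anova_bonferroni",
        f_statistic=float(f),
        p_value=float(p),
        pairwise=pd.DataFrame(rows),
        group_summary=summary,
    )


class ParameterRanker(BaseEstimator):
    """Feature selector: Welch-test ranking between two designated groups.

    sklearn-style wrapper over :func:`rank_and_select`.  ``fit`` expects
    per-animal feature vectors ``X`` (DataFrame) and group labels ``y``.

    Attributes
    ----------
    results_ : DataFrame sorted by p with t, df, p, cohens_d, selected.
    selected_ : list of selected parameter names.
    """

    def __init__(self, uninjured_label="uninjured", injured_label="injured",
                 p_threshold: float = 0.01):
        self.uninjured_label = uninjured_label
        self.injured_label = injured_label
        self.p_threshold = p_threshold

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.results_ = rank_and_select(
            X, y, self.uninjured_label, self.injured_label, self.p_threshold
        )
        self.selected_ = list(self.results_.loc[self.results_["selected"], "parameter"])
        return self

    def get_support(self) -> np.ndarray:
        return np.array([c in self.selected_ for c in self.feature_names_in_])

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.selected_]
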