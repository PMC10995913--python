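"""Group comparisons and clinical associations.

The analysis conventions: group differences in continuous individual
measures (total outlier count, mean regional z) and associations with
clinical scores use ordinary least squares adjusting for age and sex,
reporting the Wald t and two-sided p for the predictor of interest.
Distribution-shaped quantities (per-participant Hamming medians, regional
outlier indicators) are compared with Mann-Whitney U tests; regional
tests are corrected with Benjamini-Hochberg FDR.

Group indicators are coded 1 for the first-listed group and 0 for the
second, so a negative coefficient means the first group has lower values —
matching the convention of reporting "PD versus DLB" contrasts with DLB
as the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import DataError, ParameterError, SingularityError

__all__ = [
    "AssociationResult",
    "RankTestResult",
    "adjusted_regression",
    "group_contrast",
    "mann_whitney",
    "fdr_adjust",
    "composite_cognitive_score",
    "flag_extreme_participants",
]


@dataclass(frozen=True)
class AssociationResult:
    """OLS result for a single predictor, adjusted for covariates."""

    predictor: str
    beta: float
    se: float
    t: float
    p: float
    n: int
    covariates: tuple[str, ...] = ("age", "sex")


@dataclass(frozen=True)
class RankTestResult:
    """Mann-Whitney U result (U convention: 0 <= U <= n1*n2)."""

    U: float
    p: float
    n1: int
    n2: int
    q: float | None = None
    method: str = "exact"


def adjusted_regression(
    outcome, predictor, age, sex, *, predictor_name: str = "predictor"
) -> AssociationResult:
    """OLS of ``outcome`` on ``[1, predictor, age, sex]``; Wald test for
    the predictor coefficient.

    Rows with missing values in any column are dropped.  Raises
    :class:`SingularityError` when the design is rank deficient, naming
    the collinear columns.
    """
    df = pd.DataFrame(
        {"outcome": np.asarray(outcome, float), predictor_name: np.asarray(predictor, float),
         "age": np.asarray(age, float), "sex": np.asarray(sex, float)}
    ).dropna()
    n = len(df)
    if n <= 4:
        raise DataError(f"need more observations than parameters (n={n})")
    if df[predictor_name].nunique() < 2:
        raise DataError(f"predictor {predictor_name!r} is constant")
    X = sm.add_constant(df[[predictor_name, "age", "sex"]], has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = df[[predictor_name, "age", "sex"]].corr().abs()
        np.fill_diagonal(corr.to_numpy(), 0.0)
        pairs = [
            f"{a}~{b}"
            for a in corr.index
            for b in corr.columns
            if a < b and corr.loc[a, b] > 0.999
        ]
        raise SingularityError(f"design matrix is rank deficient; collinear columns: {pairs or 'constant column'}")
    fit = sm.OLS(df["outcome"], X).fit()
    return AssociationResult(
        predictor=predictor_name,
        beta=float(fit.params[predictor_name]),
        se=float(fit.bse[predictor_name]),
        t=float(fit.tvalues[predictor_name]),
        p=float(fit.pvalues[predictor_name]),
        n=n,
    )


def group_contrast(
    df: pd.DataFrame, outcome: str, groups: tuple[str, str], *, group_col: str = "group"
) -> AssociationResult:
    """Age/sex-adjusted group difference in ``outcome``.

    ``groups = (a, b)`` codes ``a`` as 1 and ``b`` (the reference) as 0.
    """
    a, b = groups
    sub = df[df[group_col].isin(groups)]
    if sub[group_col].nunique() < 2:
        raise DataError(f"contrast {a} vs {b}: one of the groups is empty")
    indicator = (sub[group_col] == a).astype(float)
    return adjusted_regression(
        sub[outcome], indicator, sub["age"], sub["sex"], predictor_name=f"{a}_vs_{b}"
    )


def mann_whitney(x, y) -> RankTestResult:
    """Two-sided Mann-Whitney U test for the first sample.

    The exact null distribution is used when there are no ties and the
    number of group labelings C(n1+n2, n1) is at most 20,000; otherwise
    the normal approximation with mid-ranks, tie correction and
    continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) == 0 or len(y) == 0:
        raise DataError("Mann-Whitney requires both groups non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    exact = (not has_ties) and comb(len(x) + len(y), len(x)) <= 20_000
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    return RankTestResult(
        U=float(res.statistic), p=float(res.pvalue), n1=len(x), n2=len(y),
        method="exact" if exact else "asymptotic",
    )


def fdr_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the original order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def composite_cognitive_score(
    subtests: pd.DataFrame, control_means: pd.Series, control_sds: pd.Series
) -> pd.Series:
    """Mean of per-subtest z-scores relative to a control reference.

    Each subtest is standardized as ``(score - control_mean) / control_sd``
    and the composite is the mean over the subtests a participant
    completed.  Participants missing every subtest get NaN.
    """
    cols = [c for c in subtests.columns if c in control_means.index]
    if not cols:
        raise DataError("no subtest columns overlap the control reference")
    sds = control_sds[cols]
    if np.any(sds.to_numpy(dtype=float) <= 0):
        raise ParameterError("control SDs must be > 0")
    z = (subtests[cols] - control_means[cols]) / sds
    return z.mean(axis=1, skipna=True)


def flag_extreme_participants(
    counts: pd.Series, groups: pd.Series, *, multiplier: float = 3.0
) -> list:
    """Participants whose count exceeds Q3 + multiplier * IQR within group.

    A reproducible automation of flagging the handful of participants with
    far higher total outlier counts than the rest of their group; the
    pipeline reruns comparisons without them as a sensitivity analysis.
    """
    counts = pd.Series(np.asarray(counts, dtype=float), index=counts.index)
    groups = pd.Series(np.asarray(groups), index=counts.index)
    flagged = []
    for g, idx in groups.groupby(groups).groups.items():
        vals = counts.loc[idx]
        q1, q3 = np.percentile(vals, [25, 75])
        cut = q3 + multiplier * (q3 - q1)
        flagged += list(vals.index[vals > cut])
    return flagged
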