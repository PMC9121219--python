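"""Covariate-adjusted association analysis and cohort comparisons.

Partial Pearson correlations between drawing features and the cognition
score are computed by residualizing both variables on the covariates
(age, sex, years of education) by least squares and correlating the
residuals.  P-values use the t transform with ``n - 2 - k`` degrees of
freedom; confidence intervals use the Fisher z transform with an
``n - 3 - k`` effective sample size.  Multiple testing within a feature
family is handled with the Benjamini-Hochberg step-up rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FEATURE_NAMES

#: Covariates controlled for in the feature-score correlations.
COVARIATES = ("age", "sex", "education_years")


@dataclass(frozen=True)
class PartialCorrelationResult:
    feature_name: str
    r: float
    ci95: tuple[float, float]
    p: float
    p_adjusted: float
    n: int
    k_covariates: int


def partial_correlation(x, y, covariates=None) -> tuple[float, tuple[float, float], float]:
    """Pearson correlation of x and y after removing covariates.

    With an empty covariate set this reduces to the plain Pearson
    correlation with its textbook two-sided p-value.

    Returns ``(r, (ci_low, ci_high), p)``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise ValueError("covariates must have one row per observation")
    k = C.shape[1]
    if n <= k + 3:
        raise ValueError(f"need n > k + 3 observations (n={n}, k={k})")
    design = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix is rank deficient after adding intercept")
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if not (rx.std() > 0 and ry.std() > 0):
        raise ValueError("zero-variance residuals: correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = min(1.0, max(-1.0, r))
    df = n - 2 - k
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    se = 1.0 / np.sqrt(n - 3 - k)
    z = np.arctanh(min(1 - 1e-15, max(-1 + 1e-15, r)))
    ci = (float(np.tanh(z - 1.96 * se)), float(np.tanh(z + 1.96 * se)))
    return r, ci, p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted
    return out


def feature_moca_table(records: pd.DataFrame, subset: str = "all",
                       score_col: str = "moca") -> pd.DataFrame:
    """Partial-correlation table between the six features and the score.

    ``subset`` is ``"all"`` or a cohort label; BH adjustment is applied
    within the six-feature family of the chosen subset.  Returns a frame
    with columns feature, n, r, ci_low, ci_high, p, p_bh.
    """
    df = records if subset == "all" else records[records["cohort"] == subset]
    if len(df) < 10:
        raise ValueError(f"need >= 10 records in subset {subset!r} (got {len(df)})")
    C = df.loc[:, list(COVARIATES)].to_numpy(float)
    y = df[score_col].to_numpy(float)
    rows = []
    for name in FEATURE_NAMES:
        r, (lo, hi), p = partial_correlation(df[name].to_numpy(float), y, C)
        rows.append({"feature": name, "n": len(df), "r": r,
                     "ci_low": lo, "ci_high": hi, "p": p})
    table = pd.DataFrame(rows)
    table["p_bh"] = bh_adjust(table["p"].to_numpy())
    return table


def cohort_compare(records: pd.DataFrame,
                   continuous: tuple[str, ...] = ("age", "education_years", "moca"),
                   ) -> pd.DataFrame:
    """Demographic contrasts between the two cohorts.

    Continuous fields use pooled-variance (Student) two-sided t tests;
    the sex split uses a 1-df chi-square test without continuity
    correction.  Returns statistic, df and p per variable.
    """
    names = sorted(records["cohort"].unique())
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 cohorts, found {names}")
    a = records[records["cohort"] == names[0]]
    b = records[records["cohort"] == names[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each cohort needs at least 2 members")
    rows = []
    for col in continuous:
        t, p = sps.ttest_ind(a[col], b[col], equal_var=True)
        rows.append({"variable": col, "test": "t",
                     "statistic": float(t), "df": len(a) + len(b) - 2,
                     "p": float(p)})
    counts = np.array([[int((a["sex"] == 1).sum()), int((a["sex"] == 0).sum())],
                       [int((b["sex"] == 1).sum()), int((b["sex"] == 0).sum())]])
    chi2, p, dof, _ = sps.chi2_contingency(counts, correction=False)
    rows.append({"variable": "sex", "test": "chi2",
                 "statistic": float(chi2), "df": int(dof), "p": float(p)})
    return pd.DataFrame(rows)


def build_records(features: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Join a features table and a metadata table on participant_id."""
    merged = metadata.merge(features, on="participant_id", how="inner",
                            validate="one_to_one")
    required = {"cohort", "moca", *COVARIATES, *FEATURE_NAMES}
    missing = required - set(merged.columns)
    if missing:
        raise ValueError(f"records table missing columns: {sorted(missing)}")
    return merged
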