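"""Clinical rules and outcome statistics.

Implements the progression/recurrence labeling rule (>2 mm growth in at
least one dimension), the resection-extent rule (GTR iff residual < 10% of
original volume), descriptive group comparisons (chi-square / Fisher exact
for categorical, Mann-Whitney U for continuous), Kaplan-Meier /
log-rank progression-free-survival analysis, and univariate → multivariate
Cox proportional-hazards modelling with the p < 0.05 promotion rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .records import CaseRecord, records_to_frame

PROGRESSION_THRESHOLD_MM = 2.0
GTR_RESIDUAL_FRACTION = 0.10


def label_progression(baseline_dims_mm, followup_dims_mm) -> bool:
    """True iff any axis grew by strictly more than 2.0 mm."""
    b = np.asarray(baseline_dims_mm, dtype=float)
    f = np.asarray(followup_dims_mm, dtype=float)
    if b.shape != f.shape:
        raise ValueError("baseline and follow-up must have matching axis counts")
    if np.any(b < 0) or np.any(f < 0):
        raise ValueError("lesion dimensions must be non-negative")
    return bool(np.any(f - b > PROGRESSION_THRESHOLD_MM))


def classify_resection(original_volume_cm3: float, residual_volume_cm3: float) -> str:
    """'GTR' iff residual volume is below 10% of the original, else 'STR'."""
    if original_volume_cm3 <= 0 or residual_volume_cm3 < 0:
        raise ValueError("volumes must be positive (original) / non-negative (residual)")
    if residual_volume_cm3 > original_volume_cm3:
        raise ValueError("residual volume exceeds original volume")
    return "GTR" if residual_volume_cm3 / original_volume_cm3 < GTR_RESIDUAL_FRACTION else "STR"


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def _is_continuous(series: pd.Series) -> bool:
    if series.dtype == bool or series.dtype == object:
        return False
    return series.nunique() > 5


def compare_groups(records, variable: str, group: str = "pr_event"):
    """Two-group comparison of one cohort variable.

    Categorical variables: chi-square test of the contingency table,
    switching to Fisher's exact test when any expected cell count is below
    5 (Fisher only applies to 2×2 tables; larger sparse tables keep
    chi-square with a warning). Continuous variables: two-sided
    Mann-Whitney U. Returns ``(test_name, statistic, p, summary)`` where
    ``summary`` holds median (IQR) per group for continuous variables and
    counts for categorical ones.
    """
    df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
    if variable not in df.columns:
        raise KeyError(variable)
    g = df[group].astype(bool)
    x = df[variable]
    if x.nunique() < 2:
        raise ValueError(f"variable {variable!r} is constant")
    if _is_continuous(x):
        a, b = x[g].astype(float), x[~g].astype(float)
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        summary = {
            grp: f"{np.median(v):.1f} ({np.percentile(v, 25):.1f}, {np.percentile(v, 75):.1f})"
            for grp, v in (("event", a), ("no_event", b))
        }
        return "mann-whitney", float(stat), float(p), summary
    table = pd.crosstab(g, x)
    chi2, p_chi, _, expected = stats.chi2_contingency(table, correction=False)
    summary = {"table": table}
    if (expected < 5).any():
        if table.shape == (2, 2):
            stat, p = stats.fisher_exact(table.to_numpy(), alternative="two-sided")
            return "fisher", float(stat), float(p), summary
        warnings.warn(
            f"{variable}: expected counts < 5 in a {table.shape} table; "
            "Fisher exact unavailable beyond 2x2, keeping chi-square", stacklevel=2)
    return "chi-square", float(chi2), float(p_chi), summary


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def km_logrank(records, group_rule, time_col: str = "time_months",
               event_col: str = "pr_event"):
    """Kaplan-Meier curves per group plus the two-sided log-rank test.

    ``group_rule`` is either a column name (boolean) or a callable mapping
    a cohort-table row to True/False. Returns ``(curves, statistic, p)``
    where ``curves`` maps group label to the fitted survival function
    (DataFrame indexed by time).
    """
    df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
    if callable(group_rule):
        grp = df.apply(group_rule, axis=1).astype(bool)
    else:
        grp = df[group_rule].astype(bool)
    if df[event_col].sum() < 1:
        raise ValueError("log-rank requires at least one event")
    if grp.sum() == 0 or (~grp).sum() == 0:
        raise ValueError("both groups must be nonempty")
    curves = {}
    for label, sel in (("high", grp), ("low", ~grp)):
        km = KaplanMeierFitter(label=label)
        km.fit(df.loc[sel, time_col], df.loc[sel, event_col].astype(bool))
        curves[label] = km.survival_function_
    res = logrank_test(df.loc[grp, time_col], df.loc[~grp, time_col],
                       df.loc[grp, event_col], df.loc[~grp, event_col])
    return curves, float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    """Hazard ratios with Wald 95% CIs, one row per variable."""

    table: pd.DataFrame        # hr, ci_low, ci_high, p
    mode: str                  # 'univariate' | 'multivariate'
    variables: list[str]
    flags: dict                # per-variable convergence warnings, if any


def _fit_one_cox(df: pd.DataFrame, covs: list[str], time_col: str, event_col: str):
    cph = CoxPHFitter()
    flag = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df[[time_col, event_col] + covs], duration_col=time_col,
                    event_col=event_col)
        except Exception as exc:  # non-convergence / separation
            return None, f"fit failed: {exc}"
        msgs = [str(w.message) for w in caught
                if "convergence" in str(w.message).lower()
                or "separation" in str(w.message).lower()]
        if msgs:
            flag = "; ".join(msgs)
    return cph, flag


def cox_fit(records, covariates: list[str], mode: str = "univariate",
            time_col: str = "time_months", event_col: str = "pr_event",
            promote_p: float = 0.05) -> CoxResult:
    """Cox proportional-hazards analysis (Efron tie handling via lifelines).

    ``mode='univariate'`` fits each covariate alone. ``mode='multivariate'``
    first runs the univariate pass and jointly fits exactly those variables
    with univariate p below ``promote_p``. Non-convergence or separation is
    reported in ``flags`` rather than silently dropped.
    """
    df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
    df = df.copy()
    for c in covariates:
        if df[c].dtype == object:   # e.g. resection GTR/STR, hypopituitarism grade
            df[c] = pd.factorize(df[c], sort=True)[0]
        df[c] = df[c].astype(float)
    n_events = int(df[event_col].sum())
    flags: dict[str, str] = {}

    def _rows(cph, covs):
        out = []
        for c in covs:
            out.append({
                "variable": c,
                "hr": float(np.exp(cph.params_[c])),
                "ci_low": float(np.exp(cph.confidence_intervals_.loc[c].iloc[0])),
                "ci_high": float(np.exp(cph.confidence_intervals_.loc[c].iloc[1])),
                "p": float(cph.summary.loc[c, "p"]),
            })
        return out

    uni_rows = []
    for c in covariates:
        cph, flag = _fit_one_cox(df, [c], time_col, event_col)
        if flag:
            flags[c] = flag
        if cph is not None:
            uni_rows.extend(_rows(cph, [c]))
    uni = pd.DataFrame(uni_rows).set_index("variable") if uni_rows else pd.DataFrame()

    if mode == "univariate":
        return CoxResult(uni, "univariate", list(covariates), flags)
    if mode != "multivariate":
        raise ValueError("mode must be 'univariate' or 'multivariate'")

    promoted = [c for c in covariates if c in uni.index and uni.loc[c, "p"] < promote_p]
    if not promoted:
        return CoxResult(pd.DataFrame(), "multivariate", [], flags)
    if n_events < len(promoted):
        warnings.warn(f"only {n_events} events for {len(promoted)} covariates; "
                      "multivariate estimates may be unstable", stacklevel=2)
    cph, flag = _fit_one_cox(df, promoted, time_col, event_col)
    if flag:
        flags["__multivariate__"] = flag
    table = (pd.DataFrame(_rows(cph, promoted)).set_index("variable")
             if cph is not None else pd.DataFrame())
    return CoxResult(table, "multivariate", promoted, flags)
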