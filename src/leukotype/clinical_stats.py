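"""Survival estimation and the categorical/nonparametric tests of the study.

Kaplan–Meier, log-rank and Cox regression are delegated to lifelines (Cox
with Efron tie handling); Kruskal–Wallis comes from scipy with its tie
correction. The r×c Fisher exact test is computed here by full enumeration
of margin-fixed tables under the probability-mass two-sided convention
(the convention of common statistical software: sum the probabilities of
all tables no more probable than the observed one).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, lgamma

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .core_io import CohortError
from .subtype_signatures import bh_adjust  # noqa: F401  (re-exported)


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival curve with right-continuous lookup."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier estimate; ``events`` is 1/True for an observed event."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if (times < 0).any():
        raise CohortError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    sf = kmf.survival_function_.iloc[:, 0]
    return KMCurve(
        times=sf.index.to_numpy(float),
        survival=sf.to_numpy(float),
        at_risk=table["at_risk"].to_numpy(float),
        censor_times=np.sort(times[~events]),
    )


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Log-rank chi-square and p over ≥2 groups (df = groups − 1)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise CohortError("log-rank needs at least 2 groups")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    """Per-covariate hazard ratios with Wald CIs and model log-likelihood."""

    table: pd.DataFrame  # covariate-indexed: hr, ci_lower, ci_upper, p, coef
    log_likelihood: float

    def hr(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hr"])


def cox_fit(times, events, covariates: pd.DataFrame) -> CoxResult:
    """Cox partial-likelihood fit (Efron ties) with Wald 95% CIs."""
    covariates = pd.DataFrame(covariates)
    nunique = covariates.nunique()
    constant = list(nunique.index[nunique <= 1])
    if constant:
        raise CohortError(f"constant covariates: {constant}")
    events = np.asarray(events, dtype=bool)
    if events.sum() < 1:
        raise CohortError("no events observed")
    df = covariates.copy()
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = events.astype(int)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except Exception as err:  # lifelines ConvergenceError and friends
        raise CohortError(f"Cox fit failed: {err}") from err
    summary = cph.summary
    table = pd.DataFrame(
        {
            "coef": summary["coef"],
            "hr": summary["exp(coef)"],
            "ci_lower": summary["exp(coef) lower 95%"],
            "ci_upper": summary["exp(coef) upper 95%"],
            "p": summary["p"],
        }
    )
    return CoxResult(table=table, log_likelihood=float(cph.log_likelihood_))


# ---------------------------------------------------------------------------
# Fisher exact (r×c)
# ---------------------------------------------------------------------------

def _validate_table(table: np.ndarray) -> None:
    if table.ndim != 2 or (table < 0).any():
        raise CohortError("contingency table must be 2-D and nonnegative")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise CohortError("contingency table has an empty margin")


def _log_table_prob(cells, row_sums, col_sums, n) -> float:
    s = sum(lgamma(r + 1) for r in row_sums) + sum(lgamma(c + 1) for c in col_sums)
    s -= lgamma(n + 1) + sum(lgamma(x + 1) for x in cells)
    return s


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for an r×c table (probability-mass rule).

    Enumerates every table with the observed margins and sums the
    probabilities of those no more probable than the observed table. 2×2
    tables shortcut to scipy (same convention).
    """
    arr = np.asarray(table, dtype=int)
    _validate_table(arr)
    if arr.sum() > 10_000:
        raise CohortError("table total exceeds the exact-enumeration bound")
    if arr.shape == (2, 2):
        return float(stats.fisher_exact(arr).pvalue)
    row_sums = arr.sum(axis=1).tolist()
    col_sums = arr.sum(axis=0).tolist()
    n = int(arr.sum())
    lp_obs = _log_table_prob(arr.ravel().tolist(), row_sums, col_sums, n)
    r, c = arr.shape
    total = 0.0

    def fill(row: int, remaining_cols: list[int], cells: list[int]) -> None:
        nonlocal total
        if row == r - 1:
            last = remaining_cols
            if any(x < 0 for x in last):
                return
            lp = _log_table_prob(cells + last, row_sums, col_sums, n)
            if lp <= lp_obs + 1e-9:
                total += exp(lp)
            return

        def fill_row(col: int, left: int, row_cells: list[int]) -> None:
            if col == c - 1:
                if left > remaining_cols[col]:
                    return
                new_cells = row_cells + [left]
                new_rem = [
                    remaining_cols[j] - new_cells[j] for j in range(c)
                ]
                fill(row + 1, new_rem, cells + new_cells)
                return
            for v in range(min(left, remaining_cols[col]) + 1):
                fill_row(col + 1, left - v, row_cells + [v])

        fill_row(0, row_sums[row], [])

    fill(0, col_sums, [])
    return float(min(total, 1.0))


# ---------------------------------------------------------------------------
# Nonparametric tests
# ---------------------------------------------------------------------------

def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and chi-square p."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise CohortError("Kruskal–Wallis needs at least 2 groups")
    if len(np.unique(values)) < 2:
        raise CohortError("all values identical")
    samples = [values[groups == g] for g in uniq]
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


# ---------------------------------------------------------------------------
# Cohort-level survival report helpers
# ---------------------------------------------------------------------------

def km_by_group(times, events, groups) -> dict:
    """KM curves per group plus the joint log-rank test."""
    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    curves = {
        str(g): km_estimate(times[groups == g], events[groups == g])
        for g in np.unique(groups)
    }
    chi2, p = logrank_test(times, events, groups)
    return {"curves": curves, "logrank_chi2": chi2, "logrank_p": p}


def cox_univariate_table(times, events, covariates: pd.DataFrame) -> pd.DataFrame:
    """One single-covariate Cox model per column (the univariate screen)."""
    rows = []
    for col in covariates.columns:
        res = cox_fit(times, events, covariates[[col]])
        rows.append(res.table.loc[col])
    return pd.DataFrame(rows)
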