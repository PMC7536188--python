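"""Survival analysis: Kaplan-Meier, reverse-KM follow-up, Cox models.

Disease-specific survival (DSS) treats death from disease as the event;
deaths from other causes are censored at the death date.  Median follow-up
uses the reverse Kaplan-Meier method (censoring treated as the event).
Cox proportional-hazards models use Efron tie handling and listwise
deletion of records with missing covariates; multivariable models adjust
for stage (I/II vs III/IV), age, decade of diagnosis and residual disease.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

__all__ = [
    "KMResult",
    "CoxResult",
    "km_estimate",
    "median_followup_reverse_km",
    "cox_fit",
    "compare_continuous",
    "logrank",
    "bonferroni",
]


@dataclass
class KMResult:
    """Product-limit survival estimate with Greenwood (log-log) intervals."""

    fitter: KaplanMeierFitter
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        """S(t); right-continuous step function."""
        return float(self.fitter.predict(t))

    def ci_at(self, t: float) -> tuple[float, float]:
        ci = self.fitter.confidence_interval_survival_function_
        idx = ci.index.searchsorted(t, side="right") - 1
        if idx < 0:
            return (1.0, 1.0)
        lo, hi = ci.iloc[idx]
        return float(lo), float(hi)

    @property
    def median(self) -> float:
        """Median survival time; ``inf`` when not reached (open-ended)."""
        return float(self.fitter.median_survival_time_)


def km_estimate(
    times: Sequence[float], events: Sequence[bool], label: str = "KM"
) -> KMResult:
    """Kaplan-Meier product-limit estimator.

    Confidence intervals use the exponential Greenwood (log-log)
    transform.  Raises on empty input.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("no subjects")
    if t.size != e.size:
        raise ValueError("times and events must have equal length")
    if (t < 0).any():
        raise ValueError("times must be non-negative")
    kmf = KaplanMeierFitter(label=label)
    kmf.fit(t, event_observed=e)
    return KMResult(fitter=kmf, n=int(t.size), n_events=int(e.sum()))


def median_followup_reverse_km(
    times: Sequence[float], events: Sequence[bool]
) -> float:
    """Median follow-up by the reverse Kaplan-Meier method.

    The event indicator is inverted so censoring is the event; returns the
    KM median of that curve, ``inf`` when not reached (open-ended).
    """
    e = np.asarray(events, dtype=bool)
    return km_estimate(times, ~e, label="reverse-KM").median


@dataclass
class CoxResult:
    """Cox proportional-hazards fit summary.

    ``summary`` has one row per model term: hazard_ratio, ci_lower,
    ci_upper, p (Wald), with the fitted n and event count attached.
    Terms flagged in ``non_estimable`` hit monotone likelihood (a level
    with no events) and their hazard ratios are not interpretable.
    """

    summary: pd.DataFrame
    n: int
    n_events: int
    non_estimable: tuple[str, ...] = ()

    def hr(self, term: str) -> float:
        return float(self.summary.loc[term, "hazard_ratio"])


def cox_fit(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    group_col: str,
    adjusters: Sequence[str] = (),
    reference: str | None = None,
) -> CoxResult:
    """Fit a Cox model of ``group_col`` with optional adjusters.

    The group factor is dummy-coded against ``reference`` (default: the
    lexicographically first level); numeric adjusters enter linearly,
    categorical adjusters are dummy-coded.  Efron tie handling; listwise
    deletion of rows with missing values in any model column.  A group
    level with no events triggers monotone likelihood: the model is still
    returned but the affected terms are flagged non-estimable.
    """
    cols = [duration_col, event_col, group_col, *adjusters]
    df = data[cols].copy()
    df[event_col] = df[event_col].astype(bool)
    df = df.replace({"missing": np.nan, "": np.nan}).dropna()
    if df.empty:
        raise ValueError("no complete cases for the requested model")

    levels = sorted(df[group_col].astype(str).unique())
    if len(levels) < 2:
        raise ValueError(f"{group_col} must have >= 2 levels after deletion")
    ref = reference if reference is not None else levels[0]
    if ref not in levels:
        raise ValueError(f"reference level {ref!r} not present")

    design = pd.DataFrame(index=df.index)
    term_names: list[str] = []
    non_estimable: list[str] = []
    for lev in levels:
        if lev == ref:
            continue
        term = f"{group_col}[{lev}]"
        design[term] = (df[group_col].astype(str) == lev).astype(float)
        term_names.append(term)
        if df.loc[df[group_col].astype(str) == lev, event_col].sum() == 0 or (
            df.loc[df[group_col].astype(str) == ref, event_col].sum() == 0
        ):
            non_estimable.append(term)
    for adj in adjusters:
        if pd.api.types.is_numeric_dtype(df[adj]):
            design[adj] = df[adj].astype(float)
        else:
            dummies = pd.get_dummies(
                df[adj].astype(str), prefix=adj, drop_first=True, dtype=float
            )
            design = pd.concat([design, dummies], axis=1)

    model = pd.concat(
        [df[[duration_col, event_col]].astype(float), design], axis=1
    )
    cph = CoxPHFitter()  # Efron ties are the lifelines default
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(model, duration_col=duration_col, event_col=event_col)
        raw = cph.summary
        with np.errstate(over="ignore"):  # monotone-likelihood coefs can overflow exp
            summary = pd.DataFrame(
                {
                    "hazard_ratio": np.exp(raw["coef"]),
                    "ci_lower": np.exp(raw["coef lower 95%"]),
                    "ci_upper": np.exp(raw["coef upper 95%"]),
                    "p": raw["p"],
                }
            )
    except ConvergenceError:
        summary = pd.DataFrame(
            np.nan,
            index=list(design.columns),
            columns=["hazard_ratio", "ci_lower", "ci_upper", "p"],
        )
        non_estimable = list(design.columns)
    for term in non_estimable:
        summary.loc[term, ["hazard_ratio", "ci_lower", "ci_upper"]] = np.nan
    return CoxResult(
        summary=summary,
        n=len(model),
        n_events=int(model[event_col].sum()),
        non_estimable=tuple(non_estimable),
    )


def logrank(
    times: Sequence[float],
    events: Sequence[bool],
    groups: Sequence,
) -> float:
    """Log-rank test p-value across groups."""
    from lifelines.statistics import multivariate_logrank_test

    res = multivariate_logrank_test(
        np.asarray(times, float), np.asarray(groups), np.asarray(events, bool)
    )
    return float(res.p_value)


def compare_continuous(
    groups: Mapping[str, Sequence[float]],
    test: str = "mann_whitney",
) -> tuple[float, float]:
    """Two-group comparison of a continuous metric.

    ``mann_whitney`` uses the exact null distribution for small tie-free
    samples and the tie-corrected normal approximation otherwise;
    ``t_test`` is Welch's t.  Returns (statistic, two-sided p).  Two
    identical constant groups give p = 1.
    """
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    (la, a), (lb, b) = groups.items()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("each group needs at least one value")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    if test == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    elif test == "t_test":
        res = stats.ttest_ind(a, b, equal_var=False)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_values: Sequence[float], family: int | None = None) -> list[float]:
    """Bonferroni adjustment: multiply by the family size, cap at 1."""
    m = family if family is not None else len(p_values)
    return [min(float(p) * m, 1.0) for p in p_values]
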