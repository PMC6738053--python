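"""Group comparisons, Kaplan-Meier curves and Cox proportional-hazards models.

Implements the statistical stage of the pipeline: chi-square / Fisher exact
tests for categorical contrasts (Fisher when any expected cell drops below
5), Mann-Whitney U for continuous ones, product-limit survival curves with
k-group log-rank tests, and Cox models with Efron tie handling and Wald 95%
intervals. Multivariable models are built with a univariable screening rule:
every candidate with univariable p strictly below ``alpha`` (default 0.20)
enters the multivariable fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.exceptions import ConvergenceError

from hypoxvasc.synthetic_cohort import design_matrix

ENDPOINTS = {"DSS": ("dss_time", "dss_event"),
             "DFS": ("dfs_time", "dfs_event"),
             "DDFS": ("ddfs_time", "ddfs_event"),
             "raw": ("event_time", "event_observed")}
SCREEN_ALPHA = 0.20  # univariable p strictly below this enters the multivariable model


@dataclass(frozen=True)
class GroupComparison:
    test: str  # chi_square | fisher_exact | mann_whitney
    statistic: float
    p_value: float
    table: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class SurvivalResult:
    """Hazard ratios with Wald 95% CIs and p-values for one Cox model."""

    endpoint: str
    model: str  # univariable | multivariable
    covariates: tuple[str, ...]
    hr: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    p_value: dict[str, float]
    n: int
    n_events: int

    def __post_init__(self) -> None:
        for c in self.covariates:
            lo, hi = self.ci95[c]
            if not (lo <= self.hr[c] <= hi) or self.hr[c] <= 0:
                raise ValueError(f"CI must bracket a positive HR for {c}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": list(self.covariates),
                "hr": [self.hr[c] for c in self.covariates],
                "ci_low": [self.ci95[c][0] for c in self.covariates],
                "ci_high": [self.ci95[c][1] for c in self.covariates],
                "p": [self.p_value[c] for c in self.covariates],
                "model": self.model,
                "endpoint": self.endpoint,
            }
        )


@dataclass(frozen=True)
class KmCurve:
    """Product-limit estimate for one group."""

    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, dtype=float)
        if s.size and (s[0] > 1.0 + 1e-12 or np.any(np.diff(s) > 1e-12)):
            raise ValueError("survival must start at <= 1 and be non-increasing")


def format_p(p: float) -> str:
    """Report-style p formatting: three decimals, '<0.001' below that."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def compare_categorical(
    table, correction: bool = False, fisher_threshold: float = 5.0
) -> GroupComparison:
    """Pearson chi-square (no continuity correction by default), switching to
    Fisher's exact test when any expected cell falls below ``fisher_threshold``
    (2x2 tables only; larger tables always use chi-square)."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need a 2-way contingency table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    expected = stats.contingency.expected_freq(t)
    if t.shape == (2, 2) and (expected < fisher_threshold).any():
        odds, p = stats.fisher_exact(t.astype(int))
        return GroupComparison("fisher_exact", float(odds), float(p), t)
    chi2, p, _, _ = stats.chi2_contingency(t, correction=correction)
    return GroupComparison("chi_square", float(chi2), float(p), t)


def compare_continuous(values_a, values_b) -> GroupComparison:
    """Two-sided Mann-Whitney U: exact enumeration for combined n <= 20
    (without ties), normal approximation with tie correction otherwise."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison("mann_whitney", float(res.statistic), float(min(res.pvalue, 1.0)))


def km_fit(times, events, group_labels=None) -> list[KmCurve]:
    """Kaplan-Meier curves, one per group (single pooled group if labels None)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if group_labels is None:
        group_labels = np.zeros(times.size, dtype=int)
    group_labels = np.asarray(group_labels)
    curves = []
    for g in pd.unique(group_labels):
        sel = group_labels == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel], label=str(g))
        timeline = kmf.survival_function_.index.to_numpy(dtype=float)
        surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
        at_risk = kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy(dtype=float)
        curves.append(KmCurve(str(g), timeline, surv, at_risk))
    return curves


def logrank_test(times, events, group_labels) -> GroupComparison:
    """k-group log-rank test with a chi-square(k-1) p-value.

    Raises when the statistic is undefined (fewer than two groups, or no
    observed events) — the curves themselves remain available via km_fit.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group_labels = np.asarray(group_labels)
    if pd.unique(group_labels).size < 2:
        raise ValueError("log-rank test needs at least two groups")
    if events.sum() == 0:
        raise ValueError("log-rank test undefined with no observed events")
    res = multivariate_logrank_test(times, group_labels, events)
    return GroupComparison("log_rank", float(res.test_statistic), float(res.p_value))


def cox_fit(
    cohort: pd.DataFrame,
    endpoint: str,
    covariates: list[str],
    model: str = "univariable",
) -> SurvivalResult:
    """Cox proportional-hazards fit (Efron ties, Wald 95% CIs).

    ``endpoint`` is one of DSS / DFS / DDFS (columns from derive_endpoints)
    or ``"raw"`` for the simulator's native event columns.
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {sorted(ENDPOINTS)}")
    tcol, ecol = ENDPOINTS[endpoint]
    X = design_matrix(cohort, covariates)
    data = X.copy()
    data["_t"] = cohort[tcol].to_numpy(dtype=float)
    data["_e"] = cohort[ecol].to_numpy(dtype=int)
    n_events = int(data["_e"].sum())
    if n_events < 1:
        raise ValueError(f"no events for endpoint {endpoint}")
    for c in covariates:
        if X[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant; model not identifiable")
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col="_t", event_col="_e")
    except ConvergenceError as exc:
        raise ValueError(
            f"Cox model failed to converge (covariates {covariates}): {exc}"
        ) from exc
    summ = cph.summary
    hr = {c: float(summ.loc[c, "exp(coef)"]) for c in covariates}
    ci = {
        c: (
            float(summ.loc[c, "exp(coef) lower 95%"]),
            float(summ.loc[c, "exp(coef) upper 95%"]),
        )
        for c in covariates
    }
    p = {c: float(summ.loc[c, "p"]) for c in covariates}
    return SurvivalResult(endpoint, model, tuple(covariates), hr, ci, p, len(data), n_events)


def passes_screen(p: float, alpha: float = SCREEN_ALPHA) -> bool:
    """Univariable entry rule: strictly below alpha (p == alpha is excluded)."""
    return p < alpha


def screen_then_fit(
    cohort: pd.DataFrame,
    endpoint: str,
    candidate_covariates: list[str],
    alpha: float = SCREEN_ALPHA,
) -> tuple[list[SurvivalResult], SurvivalResult | None]:
    """Univariable screen at p < ``alpha`` (strict), then one multivariable fit.

    Returns the per-candidate univariable results and the multivariable
    result, or ``None`` for the latter when no candidate passes the screen.
    """
    if not candidate_covariates:
        raise ValueError("need at least one candidate covariate")
    uni = [cox_fit(cohort, endpoint, [c], "univariable") for c in candidate_covariates]
    passed = [r.covariates[0] for r in uni if passes_screen(r.p_value[r.covariates[0]], alpha)]
    multi = cox_fit(cohort, endpoint, passed, "multivariable") if passed else None
    return uni, multi
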