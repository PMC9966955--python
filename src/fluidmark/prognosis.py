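"""Prognostic-index survival stratification.

For a set of marker genes, a Cox proportional-hazards model is fitted to a
cohort's expression and survival outcome; each subject is scored by the
linear predictor, the prognostic index

    PI = beta_1 x_1 + beta_2 x_2 + ... + beta_p x_p,

and the cohort is split into high- and low-risk groups at the median PI.
The groups are compared by the Kaplan–Meier estimator, the log-rank test,
and the hazard ratio exp(beta) of a univariate Cox fit on the group
indicator with a 95% Wald CI. A log-rank p < 0.05 is the conventional
significance cut-off.

The partial-likelihood maximization is delegated to lifelines; the
simulated cohorts have continuous event times, so ties — where tie-handling
conventions would differ — do not arise in practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .simulate import SurvivalCohort

__all__ = [
    "CoxFit",
    "RiskStratification",
    "fit_cox",
    "prognostic_index",
    "stratify",
    "km_curve",
    "logrank_test",
    "hazard_ratio",
    "km_plot",
    "evaluate_prognosis",
]


@dataclass(frozen=True)
class CoxFit:
    betas: dict[str, float]
    log_partial_likelihood: float
    converged: bool


@dataclass(frozen=True)
class RiskStratification:
    pi_scores: pd.Series
    threshold: float
    groups: pd.Series  # "high" / "low"
    logrank_chi2: float
    logrank_p: float
    hazard_ratio: float
    hr_ci: tuple[float, float]


def fit_cox(cohort: SurvivalCohort, genes: Sequence[str]) -> CoxFit:
    """Maximize the Cox partial likelihood over the listed genes.

    Degenerate designs (constant covariates, collinearity, monotone
    likelihood from perfect separation) are flagged ``converged=False``
    instead of returning silent garbage; constant covariates get beta = 0.
    """
    missing = [g for g in genes if g not in cohort.expression.columns]
    if missing:
        raise ValueError(f"genes absent from cohort: {missing}")
    if int(cohort.event.sum()) == 0:
        raise ValueError("cohort has zero events")
    if int(cohort.event.sum()) < 2:
        raise ValueError("need >= 2 events to fit")

    x = cohort.expression[list(genes)]
    constant = [g for g in genes if x[g].nunique() <= 1]
    active = [g for g in genes if g not in constant]
    betas = {g: 0.0 for g in constant}
    if not active:
        return CoxFit(betas=betas, log_partial_likelihood=float("nan"), converged=True)

    df = x[active].copy()
    df["time"] = cohort.time
    df["event"] = cohort.event.astype(int)
    cph = CoxPHFitter()
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, ConvergenceWarning, Exception) as exc:
        if isinstance(exc, (ConvergenceError, ConvergenceWarning)):
            converged = False
            try:  # refit tolerantly to still report the point estimate
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cph.fit(df, duration_col="time", event_col="event")
            except Exception:
                return CoxFit(betas={**betas, **{g: float("nan") for g in active}},
                              log_partial_likelihood=float("nan"), converged=False)
        else:
            raise
    betas.update({g: float(cph.params_[g]) for g in active})
    if any(not np.isfinite(b) for b in betas.values()):
        converged = False
    return CoxFit(betas=betas,
                  log_partial_likelihood=float(cph.log_likelihood_),
                  converged=converged)


def prognostic_index(cohort: SurvivalCohort, betas: Mapping[str, float]) -> pd.Series:
    """PI per subject: the Cox linear predictor sum(beta_i * x_i)."""
    missing = [g for g in betas if g not in cohort.expression.columns]
    if missing:
        raise ValueError(f"genes absent from cohort expression: {missing}")
    for g, b in betas.items():
        if not np.isfinite(b):
            raise ValueError(f"non-finite beta for {g}")
    pi = pd.Series(0.0, index=cohort.expression.index, name="PI")
    for g, b in betas.items():
        pi += b * cohort.expression[g]
    return pi


def stratify(pi_scores: pd.Series, rule: str = "median") -> tuple[pd.Series, float]:
    """Split subjects into high/low risk groups at the median PI.

    High risk is PI >= median; with even n the median is the midpoint of the
    two central order statistics. All-identical scores cannot be stratified.
    """
    if rule != "median":
        raise ValueError(f"unknown stratification rule {rule!r}")
    if len(pi_scores) < 2:
        raise ValueError("need >= 2 subjects to stratify")
    if float(pi_scores.max()) == float(pi_scores.min()):
        raise ValueError("all PI scores identical; no stratification possible")
    threshold = float(np.median(pi_scores.to_numpy()))
    groups = pd.Series(np.where(pi_scores >= threshold, "high", "low"),
                       index=pi_scores.index, name="risk_group")
    return groups, threshold


def km_curve(times: Sequence[float], events: Sequence[bool]) -> pd.DataFrame:
    """Kaplan–Meier product-limit survival curve.

    Returns a frame (time, survival) starting at (0, 1); the curve steps
    down only at observed event times, censored subjects leave the risk set
    without a step.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("empty input")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def logrank_test(
    group_a: tuple[Sequence[float], Sequence[bool]],
    group_b: tuple[Sequence[float], Sequence[bool]],
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square with 1 df, two-sided p)."""
    ta, ea = np.asarray(group_a[0], float), np.asarray(group_a[1], bool)
    tb, eb = np.asarray(group_b[0], float), np.asarray(group_b[1], bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test needs >= 1 event")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def hazard_ratio(
    group_labels: Sequence[str],
    times: Sequence[float],
    events: Sequence[bool],
    reference: str = "low",
) -> tuple[float, tuple[float, float]]:
    """HR (high vs low) from a univariate Cox fit on the group indicator.

    Returns (HR, (ci_low, ci_high)) with a 95% Wald interval. A group with
    no events yields a monotone likelihood; the fit is attempted and any
    non-finite output raised as an error.
    """
    labels = pd.Series(group_labels)
    uniq = set(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 groups, got {sorted(uniq)}")
    ind = (labels != reference).astype(int).to_numpy()
    df = pd.DataFrame({
        "group": ind,
        "time": np.asarray(times, float),
        "event": np.asarray(events, bool).astype(int),
    })
    for g in uniq:
        if df.loc[labels.to_numpy() == g, "event"].sum() == 0:
            raise ValueError(f"group {g!r} has no events; HR unbounded")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    beta = float(cph.params_["group"])
    se = float(cph.standard_errors_["group"])
    z = stats.norm.ppf(0.975)
    return float(np.exp(beta)), (float(np.exp(beta - z * se)), float(np.exp(beta + z * se)))


def km_plot(
    strat: "RiskStratification",
    cohort: SurvivalCohort,
    path: str | None = None,
):
    """Kaplan–Meier curves for the high/low risk groups, annotated with the
    log-rank p and hazard ratio. Returns the matplotlib axes; saves to
    `path` when given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, color in (("high", "tab:red"), ("low", "tab:blue")):
        mask = strat.groups == name
        curve = km_curve(cohort.time[mask], cohort.event[mask])
        ax.step(curve["time"], curve["survival"], where="post",
                color=color, label=f"{name} risk (n={int(mask.sum())})")
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(title=f"log-rank p = {strat.logrank_p:.2e}\nHR = {strat.hazard_ratio:.2f}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax


def evaluate_prognosis(
    cohort: SurvivalCohort,
    genes: Sequence[str],
    rule: str = "median",
) -> RiskStratification:
    """End-to-end: Cox fit -> PI -> median split -> log-rank + HR."""
    fit = fit_cox(cohort, genes)
    pi = prognostic_index(cohort, fit.betas)
    groups, threshold = stratify(pi, rule=rule)
    hi = groups == "high"
    chi2, p = logrank_test(
        (cohort.time[hi], cohort.event[hi]),
        (cohort.time[~hi], cohort.event[~hi]),
    )
    hr, ci = hazard_ratio(groups.to_numpy(), cohort.time.to_numpy(), cohort.event.to_numpy())
    return RiskStratification(pi_scores=pi, threshold=threshold, groups=groups,
                              logrank_chi2=chi2, logrank_p=p,
                              hazard_ratio=hr, hr_ci=ci)
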