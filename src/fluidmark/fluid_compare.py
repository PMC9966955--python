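"""Cross-fluid and cross-diagnosis comparison of protein log2 ratios.

For a protein quantified in both saliva and serum, the per-sample log2
ratios are modeled by an additive two-factor linear model (fluid +
diagnosis, no interaction); the marginal (Type-II) F test for the fluid
factor asks whether the protein's mean log2 ratio differs between fluids
controlling for diagnosis. Within a fluid, select proteins are compared
between the M/N and B/N contrasts by a two-sample t-test. Significance is
assessed at alpha = 0.05 with no multiple-testing adjustment, reflecting
the exploratory screen the pipeline implements.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedRatioSample",
    "AnovaResult",
    "anova_fluid_effect",
    "within_fluid_t_test",
    "cross_fluid_screen",
    "read_samples_tsv",
]


@dataclass(frozen=True)
class PairedRatioSample:
    """One per-sample log2 ratio observation for one protein."""

    protein_id: str
    fluid: str  # saliva | serum
    diagnosis_contrast: str  # B/N | M/N
    sample_id: str
    log2_ratio: float


@dataclass(frozen=True)
class AnovaResult:
    """Marginal fluid-effect test from the additive two-factor model."""

    protein_id: str
    f_fluid: float | None
    p_fluid: float | None
    df: tuple[int, int] | None
    cell_means: dict[tuple[str, str], float]
    status: str  # ok | inestimable

    @property
    def estimable(self) -> bool:
        return self.status == "ok"


def anova_fluid_effect(samples: Sequence[PairedRatioSample]) -> AnovaResult:
    """Type-II F test for the fluid factor, controlling for diagnosis.

    Fits log2_ratio ~ fluid + diagnosis by least squares (handles unbalanced
    cells) and returns the marginal F test for fluid. If either factor has a
    single observed level, or the residual degrees of freedom vanish, the
    test is flagged inestimable rather than returning a number.
    """
    if not samples:
        raise ValueError("samples must be non-empty")
    pids = {s.protein_id for s in samples}
    if len(pids) != 1:
        raise ValueError("samples must all belong to one protein")
    df = pd.DataFrame({
        "fluid": [s.fluid for s in samples],
        "diagnosis": [s.diagnosis_contrast for s in samples],
        "y": [s.log2_ratio for s in samples],
    })
    cell_means = {
        (f, d): float(g["y"].mean())
        for (f, d), g in df.groupby(["fluid", "diagnosis"], sort=True)
    }
    pid = next(iter(pids))
    if df["fluid"].nunique() < 2:
        return AnovaResult(pid, None, None, None, cell_means, "inestimable")

    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    if df["diagnosis"].nunique() < 2:
        model = smf.ols("y ~ C(fluid)", data=df).fit()
        label = "C(fluid)"
    else:
        model = smf.ols("y ~ C(fluid) + C(diagnosis)", data=df).fit()
        label = "C(fluid)"
    if model.df_resid < 1:
        return AnovaResult(pid, None, None, None, cell_means, "inestimable")
    table = anova_lm(model, typ=2)
    f = float(table.loc[label, "F"])
    p = float(table.loc[label, "PR(>F)"])
    dfs = (int(table.loc[label, "df"]), int(model.df_resid))
    if not np.isfinite(f):
        return AnovaResult(pid, None, None, None, cell_means, "inestimable")
    return AnovaResult(pid, f, p, dfs, cell_means, "ok")


def within_fluid_t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sample t-test on log2 ratios (pooled variance by default).

    Returns (t, two-sided p). The Welch variant is available via
    ``equal_var=False``. Both groups need >= 2 values.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if np.isnan(t):  # zero variance in both groups with equal means
        return 0.0, 1.0
    return float(t), float(p)


def cross_fluid_screen(
    samples: Iterable[PairedRatioSample],
    alpha: float = 0.05,
    min_per_fluid: int = 2,
) -> pd.DataFrame:
    """Per-protein fluid-effect screen over all proteins seen in both fluids.

    Returns a frame (protein, F, df1, df2, p, significant) sorted by p;
    proteins not quantified in both fluids with at least ``min_per_fluid``
    samples each are skipped. p-values are unadjusted.
    """
    by_protein: dict[str, list[PairedRatioSample]] = {}
    for s in samples:
        by_protein.setdefault(s.protein_id, []).append(s)

    rows = []
    for pid in sorted(by_protein):
        obs = by_protein[pid]
        counts = pd.Series([s.fluid for s in obs]).value_counts()
        if len(counts) < 2 or counts.min() < min_per_fluid:
            continue
        res = anova_fluid_effect(obs)
        if not res.estimable:
            continue
        rows.append({
            "protein": pid, "F": res.f_fluid,
            "df1": res.df[0], "df2": res.df[1],
            "p": res.p_fluid, "significant": res.p_fluid < alpha,
        })
    out = pd.DataFrame(rows, columns=["protein", "F", "df1", "df2", "p", "significant"])
    return out.sort_values("p", kind="stable").reset_index(drop=True) if len(out) else out


def read_samples_tsv(path: str | Path) -> list[PairedRatioSample]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein", "fluid", "contrast", "sample", "log2_ratio"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        PairedRatioSample(r.protein, r.fluid, r.contrast, r.sample, float(r.log2_ratio))
        for r in df.itertuples(index=False)
    ]
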