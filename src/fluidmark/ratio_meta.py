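"""Inverse-variance pooling of per-run iTRAQ protein ratios.

A protein quantified in several 8-plex iTRAQ runs yields one abundance ratio
per run per diagnosis contrast (B/N, M/N, M/B), each with a variance. The
runs are combined on the log2 scale by an inverse-variance weighted average:

    theta_hat = sum(w_i * y_i) / sum(w_i),   w_i = 1 / (v_i + tau2)

where y_i = log2(ratio_i), v_i is the within-run variance of y_i, and tau2
is the between-run heterogeneity variance — zero for the fixed-effect model,
or the DerSimonian–Laird moment estimate (truncated at zero) for the
random-effects model. The 95% confidence interval is

    theta_hat +/- 1.96 / sqrt(sum(w_i))

and both the estimate and the interval are exponentiated back to the ratio
scale. A protein is called differentially expressed when the ratio-scale CI
excludes 1; direction is up for pooled ratio > 1, down for < 1.

Pooling happens on the log scale because "the CI excludes 1" is only
symmetric and well-behaved for a positive ratio after the log transform.
No multiple-testing adjustment is applied by default (the per-protein 5%
rule); a Benjamini–Hochberg flag is available on :func:`build_differential_table`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fixtures import COMPARISONS, DifferentialRecord, DifferentialTable

__all__ = [
    "RatioObservation",
    "PooledRatio",
    "pool_ratios",
    "call_differential",
    "variance_from_peptides",
    "pool_all",
    "build_differential_table",
    "read_observations_tsv",
    "write_observations_tsv",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class RatioObservation:
    """One protein's ratio in one iTRAQ run for one diagnosis contrast."""

    protein_id: str
    comparison: str
    run_id: str
    ratio: float
    log2_variance: float

    def __post_init__(self):
        if self.ratio <= 0:
            raise ValueError(f"ratio must be positive, got {self.ratio}")
        if self.log2_variance <= 0:
            raise ValueError(f"log2_variance must be positive, got {self.log2_variance}")


@dataclass(frozen=True)
class PooledRatio:
    """Random- or fixed-effect summary of one protein x comparison."""

    protein_id: str
    comparison: str
    pooled_ratio: float
    ci_low: float
    ci_high: float
    tau2: float
    n_runs: int
    weights: Mapping[str, float]
    significant: bool
    direction: str  # up | down | none


def pool_ratios(
    observations: Sequence[RatioObservation],
    method: str = "random",
    tau2: float | None = None,
) -> PooledRatio:
    """Combine one protein's per-run ratios into a pooled summary ratio.

    Parameters
    ----------
    observations
        Non-empty; all must share protein_id and comparison. A single
        observation is returned as-is with its own variance.
    method
        ``"fixed"`` (tau2 = 0) or ``"random"`` (DerSimonian–Laird tau2).
    tau2
        Known between-run variance to use in the random-effects weights
        instead of estimating it (calibration studies); ignored for
        ``"fixed"``.
    """
    if not observations:
        raise ValueError("observations must be non-empty")
    if method not in {"fixed", "random"}:
        raise ValueError(f"unknown method {method!r}")
    proteins = {o.protein_id for o in observations}
    comps = {o.comparison for o in observations}
    if len(proteins) != 1 or len(comps) != 1:
        raise ValueError("observations must all share protein_id and comparison")

    y = np.array([math.log2(o.ratio) for o in observations])
    v = np.array([o.log2_variance for o in observations])
    if np.any(v <= 0):
        raise ValueError("log2_variance must be positive")

    if method == "fixed":
        tau2 = 0.0
    elif tau2 is not None:
        if tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        tau2 = float(tau2)
    elif len(y) > 1:
        tau2 = _dersimonian_laird_tau2(y, v)
    else:
        tau2 = 0.0

    w = 1.0 / (v + tau2)
    w_sum = w.sum()
    theta = float((w * y).sum() / w_sum)
    se = float(1.0 / math.sqrt(w_sum))
    lo, hi = theta - Z_95 * se, theta + Z_95 * se

    pooled = PooledRatio(
        protein_id=next(iter(proteins)),
        comparison=next(iter(comps)),
        pooled_ratio=2.0 ** theta,
        ci_low=2.0 ** lo,
        ci_high=2.0 ** hi,
        tau2=float(tau2),
        n_runs=len(y),
        weights={o.run_id: float(wi / w_sum) for o, wi in zip(observations, w)},
        significant=False,
        direction="none",
    )
    significant, direction = call_differential(pooled)
    return PooledRatio(**{**pooled.__dict__, "significant": significant, "direction": direction})


def _dersimonian_laird_tau2(y: np.ndarray, v: np.ndarray) -> float:
    """DerSimonian–Laird moment estimator of between-run variance, truncated at 0."""
    w = 1.0 / v
    theta_fe = (w * y).sum() / w.sum()
    q = float((w * (y - theta_fe) ** 2).sum())
    df = len(y) - 1
    c = w.sum() - (w ** 2).sum() / w.sum()
    return max(0.0, (q - df) / c)


def call_differential(pooled: PooledRatio) -> tuple[bool, str]:
    """Significance call: the 95% CI excludes 1; direction from the pooled ratio."""
    significant = pooled.ci_low > 1.0 or pooled.ci_high < 1.0
    if not significant:
        return False, "none"
    return True, ("up" if pooled.pooled_ratio > 1.0 else "down")


def variance_from_peptides(peptide_log2_ratios: Sequence[float]) -> float:
    """Per-run variance of the mean log2 ratio from replicate peptide-level ratios.

    Sample variance of the peptide log2 ratios divided by the peptide count
    (the variance of their mean). Needs >= 2 peptides.
    """
    x = np.asarray(peptide_log2_ratios, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 peptide-level ratios to estimate a variance")
    return float(x.var(ddof=1) / x.size)


def pool_all(
    observations: Iterable[RatioObservation],
    method: str = "random",
) -> list[PooledRatio]:
    """Group observations by (protein, comparison) and pool each group."""
    groups: dict[tuple[str, str], list[RatioObservation]] = {}
    for o in observations:
        groups.setdefault((o.protein_id, o.comparison), []).append(o)
    return [pool_ratios(obs, method=method) for key, obs in sorted(groups.items())]


def build_differential_table(
    pooled: Iterable[PooledRatio],
    fluid: str,
    adjust_bh: bool = False,
    alpha: float = 0.05,
) -> DifferentialTable:
    """Assemble pooled results into a significant-protein table.

    One row per protein carrying its three pooled ratios and significance
    flags; proteins significant in no comparison are excluded, mirroring the
    published "significant proteins" table scope. A comparison missing for a
    protein is recorded with ratio 1 and flagged not significant.

    With ``adjust_bh`` the per-protein calls within each comparison are
    re-made on Benjamini–Hochberg-adjusted z-test p-values at level `alpha`
    instead of the raw CI rule.
    """
    by_protein: dict[str, dict[str, PooledRatio]] = {}
    for p in pooled:
        by_protein.setdefault(p.protein_id, {})[p.comparison] = p

    sig_flags: dict[tuple[str, str], bool] = {
        (pid, c): p.significant
        for pid, comps in by_protein.items()
        for c, p in comps.items()
    }
    if adjust_bh:
        from .enrichment import bh_adjust
        from scipy.stats import norm

        for comparison in COMPARISONS:
            keys = [(pid, comparison) for pid in by_protein if comparison in by_protein[pid]]
            if not keys:
                continue
            pvals = []
            for pid, c in keys:
                p = by_protein[pid][c]
                theta = math.log2(p.pooled_ratio)
                se = (math.log2(p.ci_high) - math.log2(p.ci_low)) / (2 * Z_95)
                z = theta / se if se > 0 else math.inf
                pvals.append(2 * norm.sf(abs(z)))
            q = bh_adjust(pvals)
            for key, qi in zip(keys, q):
                sig_flags[key] = qi < alpha

    records = []
    for pid in sorted(by_protein):
        comps = by_protein[pid]
        significant = {c: bool(sig_flags.get((pid, c), False)) for c in COMPARISONS}
        if not any(significant.values()):
            continue
        ratio = {c: (comps[c].pooled_ratio if c in comps else 1.0) for c in COMPARISONS}
        n_runs = max(p.n_runs for p in comps.values())
        records.append(DifferentialRecord(
            accession_id=pid,
            uniprot_id=pid,
            gene_id=pid,
            protein_name=pid,
            ratio=ratio,
            significant=significant,
            runs=n_runs,
            peptides_95=0,
            auc_pct=0.0,
        ))
    return DifferentialTable(fluid=fluid, records=records)


# ---------------------------------------------------------------------------
# TSV interchange with the simulator and the CLI

_OBS_COLUMNS = ["protein", "comparison", "run", "ratio", "log2_var"]


def write_observations_tsv(observations: Iterable[RatioObservation], path: str | Path) -> None:
    df = pd.DataFrame(
        [(o.protein_id, o.comparison, o.run_id, o.ratio, o.log2_variance) for o in observations],
        columns=_OBS_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_observations_tsv(path: str | Path) -> list[RatioObservation]:
    df = pd.read_csv(path, sep="\t", dtype={"protein": str, "comparison": str, "run": str},
                     float_precision="round_trip")
    missing = set(_OBS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        RatioObservation(
            protein_id=row.protein, comparison=row.comparison, run_id=row.run,
            ratio=float(row.ratio), log2_variance=float(row.log2_var),
        )
        for row in df.itertuples(index=False)
    ]
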