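"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators stand in for data the study drew from sources that cannot
be redistributed here: per-run iTRAQ ratio observations (raw MS data were
not deposited), a tumor/normal expression cohort with survival follow-up
(the public breast-carcinoma RNA-Seq cohort), and a protein interactome
(a versioned interaction database). Each generator is deterministic given
its seed and exports the plain-text format the downstream stage reads.

The iTRAQ model is log-normal ratio noise: for protein p in run i,

    log2 ratio = theta_p + u_i + e_i,  u_i ~ N(0, tau^2), e_i ~ N(0, sd^2)

with theta_p the planted log2 fold (0 for null proteins). This is exactly
the two-level model under which random-effects pooling and its CI-excludes-1
call are calibrated. Defaults mirror the study's scale: 8-plex runs, a
within-run log2 SD of 0.3 and mild between-run heterogeneity (tau = 0.1).

Survival cohorts follow a proportional-hazards model with exponential
baseline and independent exponential censoring; tumor/normal expression is
unit-variance Gaussian with a mean shift delta on marker genes in the tumor
class, for which the theoretical AUC is Phi(delta / sqrt(2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ratio_meta import RatioObservation

__all__ = [
    "ItraqSimConfig",
    "SimTruth",
    "CohortSimConfig",
    "SurvivalCohort",
    "simulate_itraq",
    "simulate_survival_cohort",
    "simulate_tumor_normal",
    "simulate_interactome",
    "write_cohort_tsv",
    "read_cohort_tsv",
]


@dataclass
class ItraqSimConfig:
    """Configuration for the per-run iTRAQ ratio generator."""

    n_proteins: int = 1000
    n_runs: int = 8
    frac_differential: float = 0.1
    true_log2_fold: float = 1.0
    within_run_sd: float = 0.3
    between_run_sd: float = 0.1
    min_runs_detected: int = 2
    comparison: str = "M/N"
    seed: int = 0

    def __post_init__(self):
        if self.min_runs_detected > self.n_runs:
            raise ValueError("min_runs_detected must be <= n_runs")
        if self.within_run_sd < 0 or self.between_run_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= self.frac_differential <= 1.0:
            raise ValueError("frac_differential must be in [0, 1]")


@dataclass
class SimTruth:
    """Planted ground truth: which proteins are differential and their ratio."""

    is_differential: dict[str, bool]
    true_ratio: dict[str, float]

    @property
    def differential_ids(self) -> set[str]:
        return {p for p, d in self.is_differential.items() if d}


def simulate_itraq(config: ItraqSimConfig) -> tuple[list[RatioObservation], SimTruth]:
    """Simulate per-run protein ratios under the two-level log-normal model.

    Each protein is detected in a random subset of runs of size between
    ``min_runs_detected`` and ``n_runs``. The exported per-observation
    variance is the within-run variance on the log2 scale (the quantity the
    pooling weights invert); the run effect u_i is the heterogeneity the
    random-effects model estimates as tau^2.
    """
    rng = np.random.default_rng(config.seed)
    n_diff = round(config.frac_differential * config.n_proteins)
    width = len(str(max(config.n_proteins - 1, 1)))
    ids = [f"P{i:0{width}d}" for i in range(config.n_proteins)]
    diff_ids = set(rng.choice(ids, size=n_diff, replace=False).tolist())

    # Variance floor keeps observations valid in the noise-free edge case.
    v = max(config.within_run_sd ** 2, 1e-12)
    observations: list[RatioObservation] = []
    truth = SimTruth(is_differential={}, true_ratio={})
    for pid in ids:
        theta = config.true_log2_fold if pid in diff_ids else 0.0
        truth.is_differential[pid] = pid in diff_ids
        truth.true_ratio[pid] = 2.0 ** theta
        n_det = int(rng.integers(config.min_runs_detected, config.n_runs + 1))
        runs = rng.choice(config.n_runs, size=n_det, replace=False)
        u = rng.normal(0.0, config.between_run_sd, size=n_det)
        e = rng.normal(0.0, config.within_run_sd, size=n_det)
        for j, run in enumerate(sorted(runs.tolist())):
            observations.append(RatioObservation(
                protein_id=pid,
                comparison=config.comparison,
                run_id=f"run{run + 1}",
                ratio=2.0 ** (theta + u[j] + e[j]),
                log2_variance=v,
            ))
    return observations, truth


@dataclass
class CohortSimConfig:
    """Configuration for survival / tumor-normal expression generators."""

    n_subjects: int = 500
    n_genes: int = 5
    true_beta: Sequence[float] = field(default_factory=lambda: [0.5])
    baseline_hazard: float = 0.1
    censor_rate: float = 0.2
    tumor_normal_shift: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if len(self.true_beta) > self.n_genes:
            raise ValueError("true_beta longer than n_genes")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")


@dataclass
class SurvivalCohort:
    """Expression matrix plus right-censored survival outcome per subject."""

    expression: pd.DataFrame  # subjects x genes
    time: pd.Series
    event: pd.Series  # True = death observed, False = censored

    @property
    def genes(self) -> list[str]:
        return list(self.expression.columns)

    def __len__(self) -> int:
        return len(self.expression)


def simulate_survival_cohort(config: CohortSimConfig) -> SurvivalCohort:
    """Proportional-hazards cohort with planted coefficients.

    Expression is N(0,1) per gene; event times are exponential with hazard
    ``baseline_hazard * exp(beta . x)``; censoring is an independent
    exponential whose rate is set so the expected censored fraction is
    approximately ``censor_rate`` (zero rate disables censoring).
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i}" for i in range(config.n_genes)]
    x = rng.standard_normal((config.n_subjects, config.n_genes))
    beta = np.zeros(config.n_genes)
    beta[: len(config.true_beta)] = np.asarray(config.true_beta, dtype=float)

    hazard = config.baseline_hazard * np.exp(x @ beta)
    t_event = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        # For exponential event ~ rate h and censor ~ rate c, P(censored) = c/(c+h);
        # match it at the average hazard.
        c_rate = config.censor_rate / (1 - config.censor_rate) * float(hazard.mean())
        t_cens = rng.exponential(1.0 / c_rate, size=config.n_subjects)
    else:
        t_cens = np.full(config.n_subjects, np.inf)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens

    idx = [f"S{i}" for i in range(config.n_subjects)]
    return SurvivalCohort(
        expression=pd.DataFrame(x, index=idx, columns=genes),
        time=pd.Series(time, index=idx, name="time"),
        event=pd.Series(event, index=idx, name="event"),
    )


def simulate_tumor_normal(
    config: CohortSimConfig,
    n_tumor: int | None = None,
    n_normal: int | None = None,
) -> pd.DataFrame:
    """Two-class expression table with shifted marker genes in the tumor class.

    Genes covered by ``true_beta`` (the markers) are shifted upward by
    ``tumor_normal_shift`` in tumor samples; all genes have unit variance.
    Under this model a marker's theoretical tumor-vs-normal AUC is
    Phi(shift / sqrt(2)). Returns a frame with a boolean ``tumor`` column.
    """
    rng = np.random.default_rng(config.seed)
    if n_tumor is None:
        n_tumor = config.n_subjects // 2
    if n_normal is None:
        n_normal = config.n_subjects - n_tumor
    genes = [f"G{i}" for i in range(config.n_genes)]
    n_markers = max(len(config.true_beta), 1)

    x = rng.standard_normal((n_tumor + n_normal, config.n_genes))
    x[:n_tumor, :n_markers] += config.tumor_normal_shift
    df = pd.DataFrame(x, columns=genes,
                      index=[f"T{i}" for i in range(n_tumor)] + [f"N{i}" for i in range(n_normal)])
    df.insert(0, "tumor", [True] * n_tumor + [False] * n_normal)
    return df


def simulate_interactome(n_nodes: int, n_edges: int, seed: int = 0):
    """Simple undirected Erdos–Renyi-style random graph with exact edge count."""
    import networkx as nx

    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"n_edges={n_edges} exceeds C({n_nodes},2)={max_edges}")
    rng = np.random.default_rng(seed)
    nodes = [f"N{i:04d}" for i in range(n_nodes)]
    g = nx.Graph(name=f"synthetic(seed={seed})")
    g.add_nodes_from(nodes)
    chosen = rng.choice(max_edges, size=n_edges, replace=False)
    pairs = [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)]
    for k in sorted(chosen.tolist()):
        i, j = pairs[k]
        g.add_edge(nodes[i], nodes[j])
    return g


def write_cohort_tsv(cohort: SurvivalCohort, path: str | Path) -> None:
    df = cohort.expression.copy()
    df.insert(0, "event", cohort.event.astype(int))
    df.insert(0, "time", cohort.time)
    df.index.name = "subject"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_cohort_tsv(path: str | Path) -> SurvivalCohort:
    df = pd.read_csv(path, sep="\t", index_col="subject", float_precision="round_trip")
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return SurvivalCohort(
        expression=df.drop(columns=["time", "event"]),
        time=df["time"].astype(float),
        event=df["event"].astype(bool),
    )
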