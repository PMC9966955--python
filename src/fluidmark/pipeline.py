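"""End-to-end pipeline: fixtures -> pooling -> screens -> enrichment -> network -> markers.

Mirrors the analysis order of the study this package re-implements: tally
the packaged differential tables, pool simulated per-run iTRAQ ratios and
call differential proteins, screen proteins for cross-fluid differences,
run over-representation analysis, build a first-neighbor PPI subnetwork,
and evaluate markers by survival stratification and ROC. Every stage writes
plain CSV/TSV/JSON artifacts and contributes to a machine-readable summary
that records the seed, a config hash and package versions, so a run is
reproducible from its report alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import fixtures as fx
from .enrichment import GeneSet, enrichment_frame, ora
from .fluid_compare import PairedRatioSample, cross_fluid_screen
from .ppi import export_network, first_neighbor_network, hub_degrees
from .prognosis import evaluate_prognosis
from .ratio_meta import build_differential_table, pool_all, write_observations_tsv
from .roc import compute_roc
from .simulate import (
    CohortSimConfig,
    ItraqSimConfig,
    simulate_interactome,
    simulate_itraq,
    simulate_survival_cohort,
    simulate_tumor_normal,
    write_cohort_tsv,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with the analysis thresholds."""

    out_dir: str = "fluidmark_out"
    seed: int = 0
    alpha: float = 0.05
    min_fold: float = 2.0
    stratification_rule: str = "median"
    itraq: ItraqSimConfig = field(default_factory=ItraqSimConfig)
    cohort: CohortSimConfig = field(default_factory=CohortSimConfig)
    ppi_nodes: int = 300
    ppi_edges: int = 900
    ppi_n_seeds: int = 20
    n_gene_sets: int = 10
    gene_set_size: int = 30

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # analytic identity only; where outputs land is irrelevant
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


_TOP_LEVEL_KEYS = {
    "out_dir", "seed", "alpha", "min_fold", "stratification_rule",
    "itraq", "cohort", "ppi_nodes", "ppi_edges", "ppi_n_seeds",
    "n_gene_sets", "gene_set_size",
}


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Build a PipelineConfig from a YAML/JSON file or a dict.

    All problems (unknown keys, out-of-range values) are reported together
    in one error, not first-failure. Defaults fill unspecified fields.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    errors: list[str] = []
    unknown = set(raw) - _TOP_LEVEL_KEYS
    if unknown:
        errors.append(f"unknown keys: {sorted(unknown)}")

    def section(name, cls):
        sub = raw.get(name, {})
        if not isinstance(sub, dict):
            errors.append(f"{name}: expected a mapping")
            return cls()
        allowed = set(cls.__dataclass_fields__)
        bad = set(sub) - allowed
        if bad:
            errors.append(f"{name}: unknown keys {sorted(bad)}")
            sub = {k: v for k, v in sub.items() if k in allowed}
        try:
            return cls(**sub)
        except (TypeError, ValueError) as exc:
            errors.append(f"{name}: {exc}")
            return cls()

    itraq = section("itraq", ItraqSimConfig)
    cohort = section("cohort", CohortSimConfig)

    alpha = raw.get("alpha", 0.05)
    if not (isinstance(alpha, (int, float)) and 0 < alpha < 1):
        errors.append(f"alpha: must be in (0, 1), got {alpha!r}")
    min_fold = raw.get("min_fold", 2.0)
    if not (isinstance(min_fold, (int, float)) and min_fold >= 1):
        errors.append(f"min_fold: must be >= 1, got {min_fold!r}")
    rule = raw.get("stratification_rule", "median")
    if rule != "median":
        errors.append(f"stratification_rule: unknown rule {rule!r}")
    for key in ("ppi_nodes", "ppi_edges", "ppi_n_seeds", "n_gene_sets", "gene_set_size", "seed"):
        v = raw.get(key, 0)
        if not isinstance(v, int) or v < 0:
            errors.append(f"{key}: must be a non-negative integer, got {v!r}")

    if errors:
        raise ValueError("invalid pipeline config:\n  - " + "\n  - ".join(errors))

    cfg = PipelineConfig(
        out_dir=str(raw.get("out_dir", "fluidmark_out")),
        seed=int(raw.get("seed", 0)),
        alpha=float(alpha),
        min_fold=float(min_fold),
        stratification_rule=rule,
        itraq=itraq,
        cohort=cohort,
        ppi_nodes=int(raw.get("ppi_nodes", 300)),
        ppi_edges=int(raw.get("ppi_edges", 900)),
        ppi_n_seeds=int(raw.get("ppi_n_seeds", 20)),
        n_gene_sets=int(raw.get("n_gene_sets", 10)),
        gene_set_size=int(raw.get("gene_set_size", 30)),
    )
    logger.info("effective config: %s", asdict(cfg))
    return cfg


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return (and write) the summary report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "fluidmark_version": __version__,
    }

    summary["fixtures"] = _stage("fixtures")(_run_fixtures)(config, out)
    summary["pooling"] = _stage("pooling")(_run_pooling)(config, out)
    summary["fluid_screen"] = _stage("fluid_screen")(_run_fluid_screen)(config, out)
    summary["enrichment"] = _stage("enrichment")(_run_enrichment)(config, out)
    summary["ppi"] = _stage("ppi")(_run_ppi)(config, out)
    summary["survival"] = _stage("survival")(_run_survival)(config, out)
    summary["roc"] = _stage("roc")(_run_roc)(config, out)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _run_fixtures(config: PipelineConfig, out: Path) -> dict:
    res: dict = {}
    for fluid, table in (("saliva", fx.saliva_table()), ("serum", fx.serum_table())):
        entry: dict = {"n_rows": len(table)}
        for comp in fx.COMPARISONS:
            c = fx.count_significant(table, comp)
            entry[comp] = {"significant": c.n_significant, "up": c.n_up, "down": c.n_down}
        tiers = fx.classify_auc_tiers(table)
        entry["auc_tiers"] = {
            "outstanding": tiers.n_outstanding, "excellent": tiers.n_excellent,
            "acceptable": tiers.n_acceptable, "below": tiers.n_below,
        }
        res[fluid] = entry
    saliva = fx.saliva_table()
    res["saliva"]["down_in_BN_and_MN"] = sorted(
        {r.uniprot_id for r in saliva if r.accession_id in
         set(fx.cross_comparison_set(saliva, ["B/N", "M/N"], "down"))})
    res["saliva"]["up_gt2fold_MB"] = sorted(
        {r.uniprot_id for r in saliva if r.accession_id in
         set(fx.cross_comparison_set(saliva, ["M/B"], "up", min_fold=config.min_fold))})
    return res


def _run_pooling(config: PipelineConfig, out: Path) -> dict:
    obs, truth = simulate_itraq(config.itraq)
    write_observations_tsv(obs, out / "ratio_observations.tsv")
    pooled = pool_all(obs, method="random")
    table = build_differential_table(pooled, fluid="saliva")
    table.write_csv(out / "differential_table.csv")
    called = {r.accession_id for r in table}
    planted = truth.differential_ids
    nulls = set(truth.is_differential) - planted
    power = len(called & planted) / len(planted) if planted else float("nan")
    fpr = len(called & nulls) / len(nulls) if nulls else float("nan")
    return {
        "n_proteins": config.itraq.n_proteins,
        "n_called": len(called),
        "power": round(power, 4),
        "false_call_rate": round(fpr, 4),
    }


def _run_fluid_screen(config: PipelineConfig, out: Path) -> dict:
    # Paired saliva/serum log2 ratios: a few proteins get a planted fluid shift.
    rng = np.random.default_rng(config.seed + 1)
    n_prot, n_shift, n_per = 100, 5, 6
    samples = []
    for i in range(n_prot):
        shift = 1.0 if i < n_shift else 0.0
        for fluid in ("saliva", "serum"):
            for contrast in ("B/N", "M/N"):
                for j in range(n_per // 2):
                    y = rng.normal(0.0, 0.2) + (shift if fluid == "serum" else 0.0)
                    samples.append(PairedRatioSample(
                        f"P{i:03d}", fluid, contrast, f"{fluid[:2]}{contrast[0]}{j}", y))
    screen = cross_fluid_screen(samples, alpha=config.alpha)
    screen.to_csv(out / "fluid_screen.csv", index=False)
    flagged = set(screen.loc[screen["significant"], "protein"])
    shifted = {f"P{i:03d}" for i in range(n_shift)}
    return {
        "n_tested": int(len(screen)),
        "n_flagged": len(flagged),
        "true_shift_recovered": len(flagged & shifted),
        "false_flag_rate": round(len(flagged - shifted) / (n_prot - n_shift), 4),
    }


def _run_enrichment(config: PipelineConfig, out: Path) -> dict:
    rng = np.random.default_rng(config.seed + 2)
    universe = [f"P{i:04d}" for i in range(config.itraq.n_proteins)]
    n_query = max(10, config.itraq.n_proteins // 20)
    query = rng.choice(universe, size=n_query, replace=False).tolist()
    sets = []
    for s in range(config.n_gene_sets):
        if s == 0:  # one genuinely enriched set, seeded from the query
            members = (rng.choice(query, size=min(len(query), config.gene_set_size // 2),
                                  replace=False).tolist()
                       + rng.choice(universe, size=config.gene_set_size // 2,
                                    replace=False).tolist())
        else:
            members = rng.choice(universe, size=config.gene_set_size, replace=False).tolist()
        sets.append(GeneSet(f"SET{s:02d}", f"synthetic set {s}", "synthetic",
                            frozenset(members)))
    records = ora(query, sets, universe)
    enrichment_frame(records).to_csv(out / "enrichment.csv", index=False)
    return {
        "n_sets": len(records),
        "n_significant": sum(r.significant for r in records),
        "top_set": records[0].set_id if records else None,
        "top_q": records[0].q_value if records else None,
    }


def _run_ppi(config: PipelineConfig, out: Path) -> dict:
    g = simulate_interactome(config.ppi_nodes, config.ppi_edges, seed=config.seed + 3)
    rng = np.random.default_rng(config.seed + 3)
    seeds = rng.choice(sorted(g.nodes), size=config.ppi_n_seeds, replace=False).tolist()
    regulation = {s: ("up" if rng.random() < 0.5 else "down") for s in seeds}
    sub = first_neighbor_network(g, set(seeds), regulation)
    export_network(sub, out / "subnetwork.sif", format="sif")
    export_network(sub, out / "subnetwork.graphml", format="graphml")
    hubs = hub_degrees(sub)
    return {**sub.summary(), "top_hub": hubs[0][0] if hubs else None,
            "top_hub_degree": hubs[0][1] if hubs else None}


def _run_survival(config: PipelineConfig, out: Path) -> dict:
    cohort = simulate_survival_cohort(config.cohort)
    write_cohort_tsv(cohort, out / "cohort.tsv")
    genes = cohort.genes[: max(len(config.cohort.true_beta), 1)]
    strat = evaluate_prognosis(cohort, genes, rule=config.stratification_rule)
    from .prognosis import km_plot
    km_plot(strat, cohort, path=str(out / "km_plot.png"))
    res = {
        "n_subjects": len(cohort),
        "n_events": int(cohort.event.sum()),
        "logrank_chi2": round(strat.logrank_chi2, 4),
        "logrank_p": float(strat.logrank_p),
        "hazard_ratio": round(strat.hazard_ratio, 4),
        "hr_ci": [round(x, 4) for x in strat.hr_ci],
        "threshold": round(strat.threshold, 4),
        "significant": bool(strat.logrank_p < config.alpha),
    }
    with open(out / "survival.json", "w") as fh:
        json.dump(res, fh, indent=2)
    return res


def _run_roc(config: PipelineConfig, out: Path) -> dict:
    df = simulate_tumor_normal(config.cohort, n_tumor=config.cohort.n_subjects,
                               n_normal=max(config.cohort.n_subjects // 10, 10))
    marker = df.columns[1]  # first gene column carries the planted shift
    res = compute_roc(df[marker].to_numpy(), df["tumor"].to_numpy())
    out_res = {"marker": marker, "auc_pct": round(100 * res.auc, 2), "tier": res.tier,
               "n_pos": res.n_pos, "n_neg": res.n_neg}
    with open(out / "roc.json", "w") as fh:
        json.dump(out_res, fh, indent=2)
    return out_res
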