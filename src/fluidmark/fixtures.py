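"""Differential-protein tables for saliva and serum, and the tallies derived from them.

The packaged fixtures transcribe the published iTRAQ differential tables for
the two biofluids: 110 saliva rows and 56 serum rows, each carrying the three
pooled diagnosis ratios (benign/normal B/N, malignant/normal M/N,
malignant/benign M/B), a per-cell significance flag (the pooled 95% CI
excluded 1), the number of 8-plex runs the protein was seen in, the peptide
count at 95% confidence, and the tumor-vs-normal AUC (percent) from an
external expression cohort.

Counting conventions
--------------------
The counting unit is the table *row* (accession), not the unique protein:
a handful of proteins appear twice under distinct accessions (e.g. two A2MG
isoform rows) and are tallied separately. A significant row counts as
up-regulated when its ratio exceeds 1 and down-regulated below 1.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "COMPARISONS",
    "DifferentialRecord",
    "DifferentialTable",
    "UpDownCount",
    "TierCounts",
    "load_differential_table",
    "saliva_table",
    "serum_table",
    "count_significant",
    "cross_comparison_set",
    "classify_auc_tiers",
]

#: Diagnosis contrasts, in table column order.
COMPARISONS = ("B/N", "M/N", "M/B")

_EXPECTED_ROWS = {"saliva": 110, "serum": 56}

_FIXTURE_FILES = {"saliva": "table1_saliva.csv", "serum": "table2_serum.csv"}

_CSV_COLUMNS = [
    "accession", "uniprot", "gene", "name",
    "ratio_BN", "sig_BN", "ratio_MN", "sig_MN", "ratio_MB", "sig_MB",
    "runs", "peptides95", "auc_pct",
]

_COMPARISON_SUFFIX = {"B/N": "BN", "M/N": "MN", "M/B": "MB"}


class SchemaError(ValueError):
    """Raised when a differential-table file does not match the fixture schema."""


class ParseError(ValueError):
    """Raised when a row of a differential-table file cannot be parsed."""


@dataclass(frozen=True)
class DifferentialRecord:
    """One table row: a protein accession with its three pooled ratios."""

    accession_id: str
    uniprot_id: str
    gene_id: str
    protein_name: str
    ratio: Mapping[str, float]
    significant: Mapping[str, bool]
    runs: int
    peptides_95: int
    auc_pct: float

    def fold(self, comparison: str) -> float:
        """Fold change of `comparison`: max(r, 1/r), always >= 1."""
        r = self.ratio[comparison]
        return max(r, 1.0 / r)


@dataclass
class DifferentialTable:
    """Ordered collection of :class:`DifferentialRecord` for one biofluid."""

    fluid: str
    records: list[DifferentialRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "accession": r.accession_id,
                "uniprot": r.uniprot_id,
                "gene": r.gene_id,
                "name": r.protein_name,
                "ratio_BN": r.ratio["B/N"], "sig_BN": r.significant["B/N"],
                "ratio_MN": r.ratio["M/N"], "sig_MN": r.significant["M/N"],
                "ratio_MB": r.ratio["M/B"], "sig_MB": r.significant["M/B"],
                "runs": r.runs, "peptides95": r.peptides_95,
                "auc_pct": r.auc_pct,
            })
        return pd.DataFrame(rows, columns=_CSV_COLUMNS)

    def write_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        for c in ("sig_BN", "sig_MN", "sig_MB"):
            df[c] = df[c].map({True: "true", False: "false"})
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class UpDownCount:
    comparison: str
    n_significant: int
    n_up: int
    n_down: int


@dataclass(frozen=True)
class TierCounts:
    n_outstanding: int
    n_excellent: int
    n_acceptable: int
    n_below: int

    @property
    def total(self) -> int:
        return self.n_outstanding + self.n_excellent + self.n_acceptable + self.n_below


def _parse_bool(value: str, row_index: int, column: str) -> bool:
    v = str(value).strip().lower()
    if v in {"true", "1", "yes"}:
        return True
    if v in {"false", "0", "no"}:
        return False
    raise ParseError(f"row {row_index}: cannot parse boolean {column}={value!r}")


def load_differential_table(
    path: str | Path,
    fluid: str,
    expect_rows: int | None = None,
) -> DifferentialTable:
    """Load a differential-protein table CSV.

    Parameters
    ----------
    path
        CSV file with the fixture schema (see ``_CSV_COLUMNS``).
    fluid
        ``"saliva"`` or ``"serum"``.
    expect_rows
        Row count to assert; defaults to the published count for the packaged
        fixtures (110 saliva / 56 serum) when `path` is one of them, otherwise
        no assertion.
    """
    if fluid not in _EXPECTED_ROWS:
        raise ValueError(f"unknown fluid {fluid!r}; expected 'saliva' or 'serum'")
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    if list(df.columns) != _CSV_COLUMNS:
        raise SchemaError(
            f"{path}: column set {list(df.columns)} does not match fixture schema {_CSV_COLUMNS}"
        )

    records: list[DifferentialRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            ratio = {c: float(getattr(row, "ratio_" + _COMPARISON_SUFFIX[c])) for c in COMPARISONS}
            significant = {
                c: _parse_bool(getattr(row, "sig_" + _COMPARISON_SUFFIX[c]), i, "sig_" + _COMPARISON_SUFFIX[c])
                for c in COMPARISONS
            }
            rec = DifferentialRecord(
                accession_id=str(row.accession),
                uniprot_id=str(row.uniprot),
                gene_id=str(row.gene),
                protein_name=str(row.name),
                ratio=ratio,
                significant=significant,
                runs=int(row.runs),
                peptides_95=int(row.peptides95),
                auc_pct=float(row.auc_pct),
            )
        except ParseError:
            raise
        except (TypeError, ValueError) as exc:
            raise ParseError(f"row {i}: {exc}") from exc
        if any(r <= 0 for r in rec.ratio.values()):
            raise ParseError(f"row {i}: non-positive ratio")
        if rec.runs < 1:
            raise ParseError(f"row {i}: runs must be >= 1")
        if not 0.0 <= rec.auc_pct <= 100.0:
            raise ParseError(f"row {i}: auc_pct outside [0, 100]")
        records.append(rec)

    accessions = [r.accession_id for r in records]
    if len(set(accessions)) != len(accessions):
        raise SchemaError(f"{path}: duplicate accession ids")
    if expect_rows is not None and len(records) != expect_rows:
        raise SchemaError(f"{path}: expected {expect_rows} rows, found {len(records)}")
    return DifferentialTable(fluid=fluid, records=records)


def _packaged(fluid: str) -> Path:
    res = importlib.resources.files("fluidmark") / "data" / _FIXTURE_FILES[fluid]
    return Path(str(res))


def saliva_table() -> DifferentialTable:
    """The packaged 110-row saliva differential table."""
    return load_differential_table(_packaged("saliva"), "saliva", expect_rows=110)


def serum_table() -> DifferentialTable:
    """The packaged 56-row serum differential table."""
    return load_differential_table(_packaged("serum"), "serum", expect_rows=56)


def count_significant(table: DifferentialTable, comparison: str) -> UpDownCount:
    """Tally significant rows for one comparison, split by direction.

    Up-regulated means ratio > 1, down-regulated ratio < 1.
    """
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}; expected one of {COMPARISONS}")
    sig = [r for r in table if r.significant[comparison]]
    n_up = sum(1 for r in sig if r.ratio[comparison] > 1.0)
    n_down = sum(1 for r in sig if r.ratio[comparison] < 1.0)
    return UpDownCount(comparison=comparison, n_significant=len(sig), n_up=n_up, n_down=n_down)


def cross_comparison_set(
    table: DifferentialTable,
    comparisons: Iterable[str],
    direction: str = "any",
    min_fold: float = 1.0,
) -> list[str]:
    """Accessions significant in *every* listed comparison with the stated direction.

    Parameters
    ----------
    comparisons
        Non-empty subset of {B/N, M/N, M/B}; a row qualifies only if it is
        significant in each of them.
    direction
        ``"up"`` (ratio > 1 in each), ``"down"`` (ratio < 1 in each) or
        ``"any"``.
    min_fold
        Minimum fold change, fold(r) = max(r, 1/r), required in each listed
        comparison. Must be >= 1.
    """
    comparisons = list(comparisons)
    if not comparisons:
        raise ValueError("comparisons must be non-empty")
    unknown = [c for c in comparisons if c not in COMPARISONS]
    if unknown:
        raise ValueError(f"unknown comparisons {unknown}")
    if direction not in {"up", "down", "any"}:
        raise ValueError(f"unknown direction {direction!r}")
    if min_fold < 1.0:
        raise ValueError("min_fold must be >= 1")

    out: list[str] = []
    for rec in table:
        ok = True
        for c in comparisons:
            r = rec.ratio[c]
            if not rec.significant[c]:
                ok = False
            elif direction == "up" and r <= 1.0:
                ok = False
            elif direction == "down" and r >= 1.0:
                ok = False
            elif rec.fold(c) < min_fold:
                ok = False
            if not ok:
                break
        if ok:
            out.append(rec.accession_id)
    return out


def classify_auc_tiers(table: DifferentialTable) -> TierCounts:
    """Bin rows by diagnostic AUC into the standard discrimination tiers.

    Outstanding AUC >= 0.9; excellent [0.8, 0.9); acceptable [0.7, 0.8);
    everything else below. Bins are disjoint and exhaustive.
    """
    counts = [0, 0, 0, 0]
    for rec in table:
        if not 0.0 <= rec.auc_pct <= 100.0:
            raise ValueError(f"auc_pct outside [0, 100] for {rec.accession_id}")
        a = rec.auc_pct / 100.0
        if a >= 0.9:
            counts[0] += 1
        elif a >= 0.8:
            counts[1] += 1
        elif a >= 0.7:
            counts[2] += 1
        else:
            counts[3] += 1
    return TierCounts(*counts)
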