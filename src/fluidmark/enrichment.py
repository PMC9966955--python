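"""Gene-set over-representation analysis (ORA).

Given a query list of significant proteins, a gene-set collection (GMT
format) and a background universe, each set is tested for over-representation
by the one-sided Fisher exact test — the hypergeometric tail probability
P(overlap >= k) with universe size N, set size K and query size n — and
p-values are corrected across the collection by Benjamini–Hochberg. The
universe should be the list of proteins *detected* in the experiment, not
the whole genome: detection bias otherwise inflates enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GeneSet", "EnrichmentRecord", "read_gmt", "ora", "bh_adjust"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    category: str
    members: frozenset[str]


@dataclass(frozen=True)
class EnrichmentRecord:
    set_id: str
    name: str
    k: int  # overlap count
    K: int  # set size within the universe
    n: int  # query size within the universe
    N: int  # universe size
    p_value: float
    q_value: float
    overlap_members: frozenset[str]

    @property
    def significant(self) -> bool:
        return self.q_value < 0.05


def read_gmt(path: str | Path, category: str = "") -> list[GeneSet]:
    """Parse a GMT file: one set per line, tab-separated id, description, members.

    Duplicate members within a line are deduplicated; lines with fewer than
    three fields raise with the offending line number.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            set_id, name, *members = fields
            if set_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            seen.add(set_id)
            sets.append(GeneSet(set_id, name, category, frozenset(m for m in members if m)))
    return sets


def ora(
    query: Iterable[str],
    collection: Sequence[GeneSet],
    universe: Iterable[str],
) -> list[EnrichmentRecord]:
    """One-sided over-representation test of `query` against every set.

    Query members outside the universe are dropped (logged); set members are
    likewise intersected with the universe before testing. BH correction is
    applied across the collection. Records are sorted by (q, p, set_id).
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("universe must be non-empty")
    query_all = set(query)
    query_set = query_all & universe_set
    dropped = len(query_all) - len(query_set)
    if dropped:
        logger.warning("ora: dropped %d query genes absent from the universe", dropped)
    if not query_set:
        logger.warning("ora: empty query after universe intersection")
        return []

    N, n = len(universe_set), len(query_set)
    rows = []
    for gs in collection:
        members = gs.members & universe_set
        K = len(members)
        overlap = members & query_set
        k = len(overlap)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((gs, k, K, overlap, min(p, 1.0)))

    q = bh_adjust([r[4] for r in rows]) if rows else []
    records = [
        EnrichmentRecord(
            set_id=gs.set_id, name=gs.name, k=k, K=K, n=n, N=N,
            p_value=p, q_value=qi, overlap_members=frozenset(overlap),
        )
        for (gs, k, K, overlap, p), qi in zip(rows, q)
    ]
    return sorted(records, key=lambda r: (r.q_value, r.p_value, r.set_id))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in q]


def enrichment_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    """Tabular view of ORA results, suitable for CSV export."""
    return pd.DataFrame([
        {
            "set_id": r.set_id, "name": r.name,
            "k": r.k, "K": r.K, "n": r.n, "N": r.N,
            "p": r.p_value, "q": r.q_value,
            "significant": r.significant,
            "overlap": ";".join(sorted(r.overlap_members)),
        }
        for r in records
    ], columns=["set_id", "name", "k", "K", "n", "N", "p", "q", "significant", "overlap"])
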