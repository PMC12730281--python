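"""Over-representation analysis of a gene list against GMT gene sets.

For each pathway the overlap with the query list is scored with the
hypergeometric upper-tail probability (one-sided Fisher's exact test) given
the background universe, and Benjamini-Hochberg adjustment is applied
across all tested sets. The background defaults to the genes measured on
the platform, per standard ORA practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .omics_io import GeneSetCollection


@dataclass
class EnrichmentRecord:
    """One tested pathway: overlap, p-value, and BH-adjusted p-value."""

    pathway_id: str
    overlap_genes: frozenset
    overlap_size: int
    set_size: int
    query_size: int
    background_size: int
    p_value: float
    adjusted_p: float

    def as_row(self) -> dict:
        return {
            "pathway_id": self.pathway_id,
            "overlap_size": self.overlap_size,
            "set_size": self.set_size,
            "query_size": self.query_size,
            "background_size": self.background_size,
            "p_value": self.p_value,
            "adjusted_p": self.adjusted_p,
            "overlap_genes": ";".join(sorted(self.overlap_genes)),
        }


def run_ora(
    query: Iterable[str],
    background: Iterable[str],
    collection: GeneSetCollection,
    min_set_size: int = 1,
    max_set_size: int | None = None,
) -> list:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Gene sets are intersected with the background before testing, and sets
    whose intersected size falls outside [min_set_size, max_set_size] are
    skipped. The p-value is P(overlap >= observed) under sampling
    ``len(query)`` genes from the background without replacement; BH
    adjustment is applied across the tested sets. Records are returned
    sorted by p-value (ties by pathway_id).
    """
    query = set(query)
    background = set(background)
    if len(background) < 2:
        raise ValueError("background must contain at least 2 genes")
    offenders = sorted(query - background)
    if offenders:
        raise ValueError(f"query genes outside the background: {offenders[:10]}")
    tested = []
    for pid in sorted(collection.sets):
        members = collection.sets[pid] & background
        if len(members) < min_set_size:
            continue
        if max_set_size is not None and len(members) > max_set_size:
            continue
        overlap = members & query
        # upper tail: P(X >= k) for X ~ Hypergeom(M=|bg|, K=|set|, N=|query|)
        p = float(
            hypergeom.sf(len(overlap) - 1, len(background), len(members), len(query))
        )
        tested.append((pid, members, overlap, min(p, 1.0)))
    if not tested:
        return []
    adjusted = multipletests([t[3] for t in tested], method="fdr_bh")[1]
    records = [
        EnrichmentRecord(
            pathway_id=pid,
            overlap_genes=frozenset(overlap),
            overlap_size=len(overlap),
            set_size=len(members),
            query_size=len(query),
            background_size=len(background),
            p_value=p,
            adjusted_p=float(adj),
        )
        for (pid, members, overlap, p), adj in zip(tested, adjusted)
    ]
    records.sort(key=lambda r: (r.p_value, r.pathway_id))
    return records


def top_pathways(records: list, n: int = 10, by: str = "p_value") -> list:
    """The n most-enriched records by raw or adjusted p-value.

    Ties are broken lexicographically by pathway_id; fewer than n records
    are returned as-is.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if by not in ("p_value", "adjusted_p"):
        raise ValueError(f"unknown sort key {by!r}")
    ordered = sorted(records, key=lambda r: (getattr(r, by), r.pathway_id))
    return ordered[:n]


def scatter_table(records: list, by: str = "p_value") -> pd.DataFrame:
    """Scatterplot-ready view: pathway, -log10 p, and overlap ratio
    (overlap size / tested set size)."""
    import numpy as np

    rows = [
        {
            "pathway_id": r.pathway_id,
            "neg_log10_p": float(-np.log10(max(getattr(r, by), 1e-300))),
            "overlap_ratio": r.overlap_size / r.set_size if r.set_size else 0.0,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["pathway_id", "neg_log10_p", "overlap_ratio"])


def enrichment_table(records: list) -> pd.DataFrame:
    """Records as a DataFrame in the canonical enrichment column order."""
    cols = [
        "pathway_id",
        "overlap_size",
        "set_size",
        "query_size",
        "background_size",
        "p_value",
        "adjusted_p",
        "overlap_genes",
    ]
    if not records:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([r.as_row() for r in records], columns=cols)
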