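"""Hypergeometric over-representation analysis against GMT gene-set
collections, with Benjamini-Hochberg FDR.

The over-representation p-value for a query of n genes drawn from a
reference universe of N genes, against a set with K members in the
universe and x in the query, is the upper tail P(X >= x) of
Hypergeometric(N, K, n).  The enrichment ratio is (x/n) / (K/N).
Depletion is not tested.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["GeneSetCollection", "EnrichmentRow", "read_gmt", "ora", "bh_fdr"]


@dataclass(frozen=True)
class GeneSetCollection:
    sets: dict[str, tuple[str, frozenset]]  # set ID -> (description, members)

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("empty gene-set collection")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, tab-separated
    (ID, description, member, member, ...); duplicate members collapse."""
    sets: dict[str, tuple[str, frozenset]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has fewer than 3 fields")
            set_id, desc, *members = fields
            sets[set_id] = (desc, frozenset(m for m in members if m))
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets)


@dataclass(frozen=True)
class EnrichmentRow:
    set_id: str
    description: str
    overlap: int  # x
    query_size: int  # n
    set_size: int  # K, within the reference
    reference_size: int  # N
    enrichment_ratio: float
    p: float
    fdr: float
    significant: bool


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def ora(
    query: Iterable[str],
    reference: Iterable[str],
    sets: GeneSetCollection,
    min_size: int = 5,
    fdr_max: float = 0.1,
    top: int | None = None,
) -> list[EnrichmentRow]:
    """Over-representation of `query` in each set, restricted to `reference`.

    Sets smaller than `min_size` within the reference are dropped before
    testing; rows are BH-adjusted across the tested sets and sorted by p
    (ties broken by larger enrichment ratio, then set ID).  ``top`` keeps
    only the first `top` rows after sorting.
    """
    query_set = set(query)
    ref_set = set(reference)
    if len(ref_set) < 2:
        raise ValueError("reference universe must contain at least 2 genes")
    offenders = query_set - ref_set
    if offenders:
        raise ValueError(f"query genes outside the reference: {sorted(offenders)[:10]}")
    N = len(ref_set)
    n = len(query_set)
    rows = []
    for set_id, (desc, members) in sets.sets.items():
        in_ref = members & ref_set
        K = len(in_ref)
        if K < min_size:
            continue
        x = len(in_ref & query_set)
        p = float(stats.hypergeom.sf(x - 1, N, K, n))
        ratio = (x / n) / (K / N) if n > 0 else 0.0
        rows.append((set_id, desc, x, K, min(max(p, np.nextafter(0, 1)), 1.0), ratio))
    if not rows:
        return []
    fdr = bh_fdr([r[4] for r in rows])
    out = [
        EnrichmentRow(
            set_id=sid,
            description=desc,
            overlap=x,
            query_size=n,
            set_size=K,
            reference_size=N,
            enrichment_ratio=ratio,
            p=p,
            fdr=q,
            significant=q < fdr_max,
        )
        for (sid, desc, x, K, p, ratio), q in zip(rows, fdr)
    ]
    out.sort(key=lambda r: (r.p, -r.enrichment_ratio, r.set_id))
    if top is not None:
        out = out[:top]
    return out
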