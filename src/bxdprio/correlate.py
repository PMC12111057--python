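"""Pearson correlation screens against a focal gene.

Implements the transcriptome-wide co-expression screen (|r| >= 0.3,
p < 0.05, partner mean expression >= 7.1 by default), the gene-trait
panel scan with pairwise-complete handling of sparse phenotypes, and
cross-tissue membership filtering of per-tissue hit lists.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix, TraitTable

__all__ = [
    "CorrelationResult",
    "CorrelateScreenConfig",
    "pearson",
    "correlated_genes",
    "trait_correlations",
    "cross_tissue_membership",
]


@dataclass(frozen=True)
class CorrelationResult:
    partner: str
    r: float
    n: int
    p: float
    partner_mean: Optional[float] = None  # genes only


@dataclass(frozen=True)
class CorrelateScreenConfig:
    """Thresholds of the co-expression screen."""

    r_min: float = 0.3
    p_max: float = 0.05
    mean_min: float = 7.1
    min_tissues: int = 3

    def __post_init__(self) -> None:
        if not (0 <= self.r_min <= 1):
            raise ValueError("r_min must be in [0, 1]")
        if not (0 < self.p_max < 1):
            raise ValueError("p_max must be in (0, 1)")


def pearson(x, y, partner: str = "") -> CorrelationResult:
    """Product-moment correlation with a two-sided t-test p-value.

    Missing values are removed pairwise; the p-value refers
    t = r * sqrt(n - 2) / sqrt(1 - r^2) to Student's t with n - 2 df.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    ok = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[ok], ya[ok]
    n = xa.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(xa, ya)
    r = float(np.clip(res.statistic, -1.0, 1.0))
    p = float(res.pvalue) if abs(r) < 1 else float(res.pvalue)
    return CorrelationResult(partner=partner, r=r, n=int(n), p=max(p, np.nextafter(0, 1)))


def correlated_genes(
    expr: ExpressionMatrix,
    focal: str,
    config: CorrelateScreenConfig = CorrelateScreenConfig(),
) -> list[CorrelationResult]:
    """Partners passing |r| >= r_min, p < p_max and mean >= mean_min.

    The focal gene is excluded from its own list.  Genes that are constant
    or share fewer than 3 complete strains with the focal gene cannot be
    tested and are silently dropped.
    """
    focal_vals = expr.gene_values(focal)
    out: list[CorrelationResult] = []
    means = expr.values.mean(axis=0, skipna=True)
    for gene in expr.genes:
        if gene == focal:
            continue
        if means[gene] < config.mean_min:
            continue
        try:
            res = pearson(focal_vals, expr.values[gene], partner=gene)
        except ValueError:
            continue
        res = CorrelationResult(
            partner=gene, r=res.r, n=res.n, p=res.p, partner_mean=float(means[gene])
        )
        if abs(res.r) >= config.r_min and res.p < config.p_max:
            out.append(res)
    out.sort(key=lambda c: c.p)
    return out


def trait_correlations(
    focal_values: pd.Series, traits: TraitTable
) -> tuple[list[CorrelationResult], list[str]]:
    """Correlate the focal gene with every trait; returns (results, skipped).

    Traits with fewer than 3 complete strain pairs (or constant on the
    complete pairs) are reported as skipped rather than raising.
    """
    if not traits.traits:
        raise ValueError("empty trait table")
    results: list[CorrelationResult] = []
    skipped: list[str] = []
    for trait in traits.traits:
        t = traits.values[trait]
        common = focal_values.index.intersection(t.index)
        try:
            results.append(
                pearson(focal_values.loc[common], t.loc[common], partner=trait)
            )
        except ValueError:
            skipped.append(trait)
    return results, skipped


def cross_tissue_membership(
    lists: Mapping[str, Iterable[str]] | Sequence[Iterable[str]], min_tissues: int
) -> tuple[set[str], dict[frozenset, int]]:
    """Genes present in at least `min_tissues` of the per-tissue hit lists.

    Also returns the full Venn partition: for every non-empty tissue
    combination, the number of genes found in exactly those tissues.
    """
    if isinstance(lists, Mapping):
        named = {str(k): set(v) for k, v in lists.items()}
    else:
        named = {f"list{i + 1}": set(v) for i, v in enumerate(lists)}
    if min_tissues > len(named):
        raise ValueError("min_tissues exceeds the number of supplied lists")
    union: set[str] = set().union(*named.values()) if named else set()
    membership = {g: frozenset(k for k, s in named.items() if g in s) for g in union}
    selected = {g for g, tissues in membership.items() if len(tissues) >= min_tissues}
    partition: dict[frozenset, int] = {}
    for tissues in membership.values():
        partition[tissues] = partition.get(tissues, 0) + 1
    return selected, partition
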