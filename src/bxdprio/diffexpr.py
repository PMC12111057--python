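"""Two-group differential expression with Benjamini-Hochberg FDR.

Per gene: Welch's unequal-variance t-test between case and control
samples, two-sided, BH-adjusted across genes, significant at FDR < 0.1
by default.  An optional empirical-Bayes variance-moderation mode
shrinks per-gene variances toward the pooled average (prior df 4),
giving limma-like behavior at small n; it is a documented variant, not
the default.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrich import bh_fdr
from .ppi import InteractorSet
from .types import ExpressionMatrix

__all__ = ["DETable", "de_test", "overlap_with_interactors"]

VALID_GROUPS = {"case", "control"}


@dataclass
class DETable:
    """Per-gene two-group test results for one comparison."""

    records: pd.DataFrame  # gene, mean_diff, t, p, fdr, significant, direction
    fdr_max: float = 0.1

    def significant_genes(self) -> set[str]:
        return set(self.records.loc[self.records["significant"], "gene"])


def _moderated_welch(case: np.ndarray, ctrl: np.ndarray, prior_df: float, prior_var: float):
    """Welch t with per-group variances shrunk toward the pooled prior."""
    n1, n2 = case.shape[0], ctrl.shape[0]
    v1 = case.var(axis=0, ddof=1)
    v2 = ctrl.var(axis=0, ddof=1)
    d1, d2 = n1 - 1, n2 - 1
    v1 = (d1 * v1 + prior_df * prior_var) / (d1 + prior_df)
    v2 = (d2 * v2 + prior_df * prior_var) / (d2 + prior_df)
    se2 = v1 / n1 + v2 / n2
    t = (case.mean(axis=0) - ctrl.mean(axis=0)) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (d1 + prior_df) + (v2 / n2) ** 2 / (d2 + prior_df))
    p = 2 * stats.t.sf(np.abs(t), df)
    return t, p


def de_test(
    expr: ExpressionMatrix,
    groups: Mapping[str, str] | pd.Series,
    fdr_max: float = 0.1,
    moderated: bool = False,
) -> DETable:
    """Case-vs-control test for every gene.

    `groups` maps each sample ID to "case" or "control" and must cover all
    samples; each group needs at least 3 samples.  Genes with zero
    variance in both groups are reported with t = 0, p = 1.
    """
    labels = pd.Series(groups)
    unknown = set(labels.unique()) - VALID_GROUPS
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    missing = set(expr.strains) - set(labels.index)
    if missing:
        raise ValueError(f"samples without a group label: {sorted(missing)[:5]}")
    labels = labels.loc[expr.strains]
    case_ids = labels.index[labels == "case"]
    ctrl_ids = labels.index[labels == "control"]
    if len(case_ids) < 3 or len(ctrl_ids) < 3:
        raise ValueError("each group needs at least 3 samples")

    case = expr.values.loc[case_ids].to_numpy(dtype=float)
    ctrl = expr.values.loc[ctrl_ids].to_numpy(dtype=float)
    mean_diff = case.mean(axis=0) - ctrl.mean(axis=0)
    flat = (case.var(axis=0, ddof=1) == 0) & (ctrl.var(axis=0, ddof=1) == 0)

    if moderated:
        pooled = np.concatenate([case - case.mean(axis=0), ctrl - ctrl.mean(axis=0)])
        prior_var = float(pooled.var(ddof=2)) or 1e-12
        t, p = _moderated_welch(case, ctrl, prior_df=4.0, prior_var=prior_var)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_ind(case, ctrl, axis=0, equal_var=False)
    t = np.where(flat, 0.0, t)
    p = np.where(flat, 1.0, p)
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    fdr = np.asarray(bh_fdr(p.tolist()))
    records = pd.DataFrame(
        {
            "gene": expr.genes,
            "mean_diff": mean_diff,
            "t": t,
            "p": p,
            "fdr": fdr,
            "significant": fdr < fdr_max,
            "direction": np.where(mean_diff >= 0, "up", "down"),
        }
    )
    return DETable(records=records, fdr_max=fdr_max)


def overlap_with_interactors(
    de_tables: Sequence[DETable], genes: Iterable[str] | InteractorSet
) -> dict[str, bool]:
    """Flag each gene that is significant in ANY of the supplied tables.

    Genes absent from a table count as not significant there.
    """
    if not de_tables:
        raise ValueError("need at least one DE table")
    if isinstance(genes, InteractorSet):
        genes = sorted(genes.members)
    significant: set[str] = set()
    for table in de_tables:
        significant |= table.significant_genes()
    return {g: g in significant for g in genes}
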