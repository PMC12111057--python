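"""Composite 0-5 evidence scoring of the focal gene's interactors.

Four weighted evidence channels are combined per candidate gene:

  * PPI node degree > 1 inside the ego network         -> 1 point
  * correlated with the focal gene (p < 0.05) in any
    of the brain-region expression panels              -> 2 points
  * annotated as autism-related in curated databases   -> 1 point
  * differentially expressed in any case/control set   -> 1 point

Candidates with total >= 4 (80% of the maximum) are selected.  The
scoring universe is the focal gene's primary and secondary interactor
set; genes outside it are not scored.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from . import correlate as _correlate
from .correlate import CorrelateScreenConfig
from .diffexpr import DETable, de_test, overlap_with_interactors
from .eqtl import EqtlCall, classify_eqtl, lmm_scan
from .ppi import InteractorSet, ego_interactors
from .simulate import Cohort

__all__ = [
    "EvidenceComponents",
    "ScoreCard",
    "score_gene",
    "build_components",
    "select_candidates",
    "scorecard_table",
    "run_pipeline",
    "PipelineResult",
]

TISSUE_P_MAX = 0.05
DEGREE_MIN = 2  # degree > 1
SELECT_MIN_TOTAL = 4
MAX_TOTAL = 5


@dataclass(frozen=True)
class EvidenceComponents:
    gene: str
    ppi_degree: int
    n_tissues_correlated: int
    autism_annotated: bool
    differentially_expressed: bool

    def __post_init__(self) -> None:
        if self.ppi_degree < 0 or self.n_tissues_correlated < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class ScoreCard:
    gene: str
    components: EvidenceComponents
    degree_subscore: int  # 0/1
    tissue_subscore: int  # 0/2
    autism_subscore: int  # 0/1
    de_subscore: int  # 0/1
    total: int
    selected: bool


def score_gene(components: EvidenceComponents, min_total: int = SELECT_MIN_TOTAL) -> ScoreCard:
    """Apply the composite scoring rule to one gene's evidence."""
    degree = 1 if components.ppi_degree > 1 else 0
    tissue = 2 if components.n_tissues_correlated >= 1 else 0
    autism = 1 if components.autism_annotated else 0
    de = 1 if components.differentially_expressed else 0
    total = degree + tissue + autism + de
    return ScoreCard(
        gene=components.gene,
        components=components,
        degree_subscore=degree,
        tissue_subscore=tissue,
        autism_subscore=autism,
        de_subscore=de,
        total=total,
        selected=total >= min_total,
    )


def build_components(
    gene: str,
    interactors: InteractorSet,
    tissue_pvalues: Mapping[str, float],
    autism_list: Iterable[str],
    de_flags: Mapping[str, bool],
) -> EvidenceComponents:
    """Assemble the four evidence channels for one interactor gene.

    `tissue_pvalues` maps tissue -> correlation p-value with the focal
    gene (tissues where the gene could not be tested may be omitted);
    `de_flags` is the any-comparison differential-expression disjunction.
    """
    if gene not in interactors.members:
        raise ValueError(
            f"{gene!r} is not a primary or secondary interactor of {interactors.focal!r}"
        )
    n_tissues = sum(1 for p in tissue_pvalues.values() if p < TISSUE_P_MAX)
    return EvidenceComponents(
        gene=gene,
        ppi_degree=interactors.degrees.get(gene, 0),
        n_tissues_correlated=n_tissues,
        autism_annotated=gene in set(autism_list),
        differentially_expressed=bool(de_flags.get(gene, False)),
    )


def select_candidates(
    cards: Sequence[ScoreCard], min_total: int = SELECT_MIN_TOTAL
) -> list[ScoreCard]:
    """Cards with total >= min_total, sorted by total desc then gene symbol."""
    chosen = [c for c in cards if c.total >= min_total]
    chosen.sort(key=lambda c: (-c.total, c.gene))
    return chosen


def scorecard_table(cards: Sequence[ScoreCard]) -> pd.DataFrame:
    """Candidate table: gene, degree, tissue count, autism Y/--, DE Y/--, total."""
    rows = [
        {
            "gene": c.gene,
            "ppi_degree": c.components.ppi_degree,
            "n_tissues_correlated": c.components.n_tissues_correlated,
            "autism_related": "Y" if c.components.autism_annotated else "--",
            "differentially_expressed": "Y" if c.components.differentially_expressed else "--",
            "total_score": c.total,
        }
        for c in cards
    ]
    return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    interactors: InteractorSet
    eqtl_call: Optional[EqtlCall]
    de_tables: list[DETable]
    cards: list[ScoreCard]
    selected: list[ScoreCard]

    def table(self) -> pd.DataFrame:
        return scorecard_table(self.selected)


def run_pipeline(
    cohort: Cohort,
    screen_config: CorrelateScreenConfig = CorrelateScreenConfig(),
    run_eqtl: bool = True,
    min_total: int = SELECT_MIN_TOTAL,
) -> PipelineResult:
    """End-to-end prioritization on a cohort: correlation screens per
    tissue, eQTL classification of the focal gene, ego-network degrees,
    differential expression, and composite scoring of every interactor."""
    focal = cohort.config.focal_gene
    interactors = ego_interactors(cohort.ppi, focal=focal)

    # per-gene, per-tissue correlation p-values with the focal gene
    tissue_p: dict[str, dict[str, float]] = {g: {} for g in interactors.members}
    for tissue, expr in cohort.expression.items():
        focal_vals = expr.gene_values(focal)
        for gene in interactors.members:
            if gene not in expr.values.columns:
                continue
            try:
                res = _correlate.pearson(focal_vals, expr.values[gene], partner=gene)
            except ValueError:
                continue
            tissue_p[gene][tissue] = res.p

    eqtl_call = None
    if run_eqtl:
        first = next(iter(cohort.expression.values()))
        scan = lmm_scan(first.gene_values(focal), cohort.genotypes, loco=True)
        eqtl_call = classify_eqtl(
            scan,
            gene=focal,
            gene_locus=(cohort.config.focal_chromosome, cohort.config.focal_position_mb),
        )

    de_tables = [de_test(expr, groups) for expr, groups in cohort.case_control]
    de_flags = (
        overlap_with_interactors(de_tables, interactors)
        if de_tables
        else {g: False for g in interactors.members}
    )

    cards = [
        score_gene(
            build_components(g, interactors, tissue_p[g], cohort.autism_genes, de_flags),
            min_total=min_total,
        )
        for g in sorted(interactors.members)
    ]
    return PipelineResult(
        interactors=interactors,
        eqtl_call=eqtl_call,
        de_tables=de_tables,
        cards=cards,
        selected=select_candidates(cards, min_total=min_total),
    )
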