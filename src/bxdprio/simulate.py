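"""Synthetic BXD-like cohort generator.

Builds recombinant-inbred (RI) genotypes, multi-tissue expression with a
planted cis-regulated focal gene and co-expressed partners, genetically
correlated traits, a PPI graph with designated primary/secondary
interactors, and two-group case/control expression sets.  Every generator
is a pure function of its configuration and seed, so downstream stages can
be validated against known planted structure without any external data.

Genotypes are simulated as Markov chains along each chromosome.  Map
distances in Mb are converted to centiMorgans at 1 cM/Mb, turned into a
meiotic recombination fraction by Haldane's map function
r = (1 - exp(-2d))/2 (d in Morgans), and expanded for an RI panel fixed by
sibling mating, R = 4r / (1 + 6r).
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .types import ExpressionMatrix, GeneticMap, StrainGenotypes, TraitTable

__all__ = [
    "SimulationConfig",
    "default_map",
    "simulate_ri_genotypes",
    "simulate_expression",
    "simulate_traits",
    "simulate_ppi",
    "simulate_case_control",
    "simulate_cohort",
    "Cohort",
]


def default_map(
    n_chromosomes: int = 19, markers_per_chromosome: int = 10, spacing_mb: float = 10.0
) -> GeneticMap:
    """Evenly spaced desk-scale map: 19 autosomes x 10 markers by default."""
    rows = []
    for c in range(1, n_chromosomes + 1):
        for m in range(markers_per_chromosome):
            rows.append((f"m{c}_{m + 1}", str(c), (m + 1) * spacing_mb))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chromosome", "position_mb"]))


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    cis_effect is in log2 expression units per D allele; noise_sd is the
    residual SD on the same scale; planted correlations are target Pearson
    r values in [-1, 1].
    """

    n_strains: int = 60
    genetic_map: GeneticMap = field(default_factory=default_map)
    focal_gene: str = "Focal1"
    focal_chromosome: str = "11"
    focal_position_mb: float = 70.44
    cis_effect: float = 0.45
    noise_sd: float = 0.3
    planted_correlates: Sequence[tuple[str, float]] = ()
    planted_trait_correlations: Sequence[tuple[str, float]] = ()
    n_background_genes: int = 1000
    de_genes: Sequence[tuple[str, float]] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 10:
            raise ValueError("n_strains must be >= 10")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for gene, r in self.planted_correlates:
            if abs(r) > 1:
                raise ValueError(f"target correlation for {gene} outside [-1, 1]")
        for trait, r in self.planted_trait_correlations:
            if abs(r) > 1:
                raise ValueError(f"target correlation for {trait} outside [-1, 1]")


def _rng(seed: int, component: str) -> np.random.Generator:
    """Deterministic per-component stream derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(component.encode())])
    )


def _ri_recomb_fraction(d_mb: np.ndarray) -> np.ndarray:
    """RI-expanded recombination fraction between adjacent markers.

    Haldane on cM distance (1 cM/Mb), then the 4r/(1+6r) expansion for a
    panel fixed by repeated sibling mating.
    """
    d_morgan = np.asarray(d_mb, dtype=float) / 100.0
    r = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
    return 4.0 * r / (1.0 + 6.0 * r)


def simulate_ri_genotypes(config: SimulationConfig, n_strains: Optional[int] = None) -> StrainGenotypes:
    """Homozygous RI genotypes (0 = B allele, 1 = D allele) along the map."""
    n = config.n_strains if n_strains is None else n_strains
    if n < 2:
        raise ValueError("need at least 2 strains")
    rng = _rng(config.seed, "genotypes")
    gmap = config.genetic_map
    columns: dict[str, np.ndarray] = {}
    for chrom, grp in gmap.table.groupby("chromosome", sort=False):
        pos = grp["position_mb"].to_numpy(dtype=float)
        markers = grp["marker"].tolist()
        state = (rng.random(n) < 0.5).astype(np.int8)
        columns[markers[0]] = state.copy()
        frac = _ri_recomb_fraction(np.diff(pos))
        for j, marker in enumerate(markers[1:]):
            flip = rng.random(n) < frac[j]
            state = np.where(flip, 1 - state, state).astype(np.int8)
            columns[marker] = state.copy()
    alleles = pd.DataFrame(
        {m: columns[m] for m in gmap.markers},
        index=[f"RI{i + 1:03d}" for i in range(n)],
    )
    return StrainGenotypes(alleles=alleles, genetic_map=gmap)


def _planted_partner(x: np.ndarray, target_r: float, rng: np.random.Generator) -> np.ndarray:
    """Standardized partner with expected Pearson correlation target_r with x."""
    z = (x - x.mean()) / x.std(ddof=1)
    eps = rng.standard_normal(x.size)
    return target_r * z + np.sqrt(1.0 - target_r**2) * eps


def simulate_expression(
    genotypes: StrainGenotypes, config: SimulationConfig, tissue: str = "tissue"
) -> ExpressionMatrix:
    """One tissue's strains x genes matrix on a log2-like scale centered near 8.

    The focal gene is cis-regulated at the marker nearest its locus; planted
    correlates are constructed from the focal values to have the requested
    expected Pearson r; background genes are independent noise with
    per-gene means drawn around 8.
    """
    rng = _rng(config.seed, f"expression:{tissue}")
    gmap = genotypes.genetic_map
    cis_marker = gmap.nearest_marker(config.focal_chromosome, config.focal_position_mb)
    allele = genotypes.alleles[cis_marker].to_numpy(dtype=float)
    n = allele.size

    baseline = 8.0 - config.cis_effect / 2.0
    focal = baseline + config.cis_effect * allele + rng.normal(0.0, config.noise_sd, n)

    data = {config.focal_gene: focal}
    for gene, target_r in config.planted_correlates:
        if abs(target_r) > 1:
            raise ValueError(f"target correlation for {gene} outside [-1, 1]")
        data[gene] = 8.0 + config.noise_sd * _planted_partner(focal, target_r, rng)
    bg_means = rng.normal(8.0, 0.8, config.n_background_genes)
    bg = bg_means + rng.normal(0.0, config.noise_sd, (n, config.n_background_genes))
    for k in range(config.n_background_genes):
        data[f"Bg{k + 1:04d}"] = bg[:, k]

    values = pd.DataFrame(data, index=genotypes.strains)
    annotation = pd.DataFrame(
        {"chromosome": [config.focal_chromosome], "position_mb": [config.focal_position_mb]},
        index=[config.focal_gene],
    )
    return ExpressionMatrix(values=values, tissue=tissue, annotation=annotation)


def simulate_traits(
    focal_values: pd.Series,
    config: SimulationConfig,
    n_null_traits: int = 0,
    missing_rate: float = 0.0,
) -> TraitTable:
    """Traits with planted genetic correlations to the focal gene's expression.

    Each planted trait has expected Pearson r with `focal_values` equal to
    its target; `n_null_traits` additional independent traits have target 0.
    Values are scaled to arbitrary phenotype units (mean 50, SD 10).
    Optional missing-value masks emulate sparse strain coverage.
    """
    if len(focal_values) < 3:
        raise ValueError("need at least 3 strains to simulate traits")
    rng = _rng(config.seed, "traits")
    x = focal_values.to_numpy(dtype=float)
    data = {}
    for trait, target_r in config.planted_trait_correlations:
        if abs(target_r) > 1:
            raise ValueError(f"target correlation for {trait} outside [-1, 1]")
        data[trait] = 50.0 + 10.0 * _planted_partner(x, target_r, rng)
    for k in range(n_null_traits):
        data[f"null_trait_{k + 1}"] = 50.0 + 10.0 * rng.standard_normal(x.size)
    values = pd.DataFrame(data, index=focal_values.index)
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values = values.mask(mask)
    return TraitTable(values=values)


def simulate_ppi(
    genes: Sequence[str],
    focal: str,
    planted_primary: Sequence[str],
    planted_secondary: Sequence[str],
    n_background_edges: int = 30,
    seed: int = 0,
) -> nx.Graph:
    """Undirected PPI graph with a designated interaction neighborhood.

    The focal gene is adjacent to exactly `planted_primary`; each planted
    secondary attaches to at least one primary but never to the focal gene.
    Background edges are drawn only among nodes outside the focal gene and
    its primaries, so the radius-2 ego set equals the planted sets.
    """
    genes = list(genes)
    if focal not in genes:
        raise ValueError(f"focal gene {focal!r} not among supplied genes")
    primary = list(planted_primary)
    secondary = list(planted_secondary)
    if set(primary) & set(secondary):
        raise ValueError("planted primary and secondary sets must be disjoint")
    for g in primary + secondary:
        if g not in genes:
            raise ValueError(f"planted gene {g!r} not among supplied genes")
    rng = _rng(seed, "ppi")
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    graph.add_edges_from((focal, p) for p in primary)
    for s in secondary:
        graph.add_edge(s, primary[int(rng.integers(len(primary)))])
    # background edges avoid the focal gene and primaries to keep the
    # planted ego structure exact
    eligible = [g for g in genes if g != focal and g not in primary]
    if len(eligible) >= 2:
        for _ in range(n_background_edges):
            a, b = rng.choice(len(eligible), size=2, replace=False)
            graph.add_edge(eligible[a], eligible[b])
    graph.graph["focal"] = focal
    return graph


def simulate_case_control(
    genes: Sequence[str],
    de_genes: Sequence[tuple[str, float]],
    n_per_group: int = 8,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Two-group expression with planted mean shifts (in SD units) in cases."""
    if n_per_group < 3:
        raise ValueError("need at least 3 samples per group")
    genes = list(genes)
    shifts = dict(de_genes)
    unknown = set(shifts) - set(genes)
    if unknown:
        raise ValueError(f"shift specified for unknown genes: {sorted(unknown)}")
    rng = _rng(seed, "case_control")
    n = 2 * n_per_group
    values = 8.0 + rng.normal(0.0, noise_sd, (n, len(genes)))
    labels = ["case"] * n_per_group + ["control"] * n_per_group
    for j, g in enumerate(genes):
        if g in shifts:
            values[:n_per_group, j] += shifts[g] * noise_sd
    samples = [f"S{i + 1:02d}" for i in range(n)]
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=samples, columns=genes), tissue="case_control"
    )
    return expr, pd.Series(labels, index=samples, name="group")


@dataclass
class Cohort:
    """A complete synthetic study: every input the pipeline consumes."""

    config: SimulationConfig
    genotypes: StrainGenotypes
    expression: dict[str, ExpressionMatrix]
    traits: TraitTable
    ppi: nx.Graph
    autism_genes: set[str]
    case_control: list[tuple[ExpressionMatrix, pd.Series]]


def simulate_cohort(
    config: SimulationConfig,
    tissues: Sequence[str] = ("amygdala", "cerebellum", "hippocampus", "prefrontal_cortex"),
    planted_primary: Sequence[str] = (),
    planted_secondary: Sequence[str] = (),
    autism_genes: Sequence[str] = (),
    n_case_control_sets: int = 3,
    n_per_group: int = 8,
    tissue_strains: Optional[dict] = None,
) -> Cohort:
    """Assemble genotypes, per-tissue expression, traits, PPI and
    case/control sets into one reproducible cohort.

    ``tissue_strains`` maps a tissue to the subset of strain IDs measured
    in it, emulating unequal strain coverage across tissue datasets;
    tissues not listed keep the full panel.
    """
    genotypes = simulate_ri_genotypes(config)
    expression = {t: simulate_expression(genotypes, config, tissue=t) for t in tissues}
    if tissue_strains:
        for t, subset in tissue_strains.items():
            expr = expression[t]
            expression[t] = ExpressionMatrix(
                values=expr.values.loc[list(subset)],
                tissue=expr.tissue,
                annotation=expr.annotation,
            )
    focal_values = expression[tissues[0]].gene_values(config.focal_gene)
    traits = simulate_traits(focal_values, config)
    planted_genes = [g for g, _ in config.planted_correlates]
    graph_genes = [config.focal_gene] + planted_genes
    primary = list(planted_primary) if planted_primary else planted_genes[:2]
    graph = simulate_ppi(
        graph_genes, config.focal_gene, primary, list(planted_secondary), seed=config.seed
    )
    # chain the primaries so each has node degree > 1 inside the ego subgraph
    for a, b in zip(primary, primary[1:]):
        graph.add_edge(a, b)
    cc = [
        simulate_case_control(
            planted_genes or [config.focal_gene],
            config.de_genes,
            n_per_group=n_per_group,
            seed=config.seed + 1 + k,
        )
        for k in range(n_case_control_sets)
    ]
    return Cohort(
        config=config,
        genotypes=genotypes,
        expression=expression,
        traits=traits,
        ppi=graph,
        autism_genes=set(autism_genes),
        case_control=cc,
    )
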