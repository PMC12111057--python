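"""Tab-separated readers and writers for the pipeline's file formats.

All tables put strains (or samples) in rows with the ID in the first
column; the genetic map is (marker, chromosome, position_mb); PPI edge
lists are two-column TSV; gene lists are one symbol per line.
"""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .eqtl import AssociationScan
from .types import ExpressionMatrix, GeneticMap, StrainGenotypes, TraitTable

__all__ = [
    "read_expression",
    "write_expression",
    "read_genetic_map",
    "write_genetic_map",
    "read_genotypes",
    "write_genotypes",
    "read_traits",
    "write_traits",
    "read_gene_list",
    "write_gene_list",
    "read_groups",
    "write_groups",
    "write_scan",
    "write_interval_bed",
]


def _read_indexed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_expression(path, tissue: str = "", annotation_path=None) -> ExpressionMatrix:
    annotation = None
    if annotation_path is not None:
        annotation = pd.read_csv(annotation_path, sep="\t", index_col=0)
    return ExpressionMatrix(
        values=_read_indexed(path), tissue=tissue or Path(path).stem, annotation=annotation
    )


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="strain")


def read_genetic_map(path) -> GeneticMap:
    table = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return GeneticMap(table=table[["marker", "chromosome", "position_mb"]])


def write_genetic_map(gmap: GeneticMap, path) -> None:
    gmap.table.to_csv(path, sep="\t", index=False)


def read_genotypes(geno_path, map_path) -> StrainGenotypes:
    gmap = read_genetic_map(map_path)
    alleles = _read_indexed(geno_path)
    return StrainGenotypes(alleles=alleles[gmap.markers], genetic_map=gmap)


def write_genotypes(genotypes: StrainGenotypes, geno_path, map_path=None) -> None:
    genotypes.alleles.to_csv(geno_path, sep="\t", index_label="strain")
    if map_path is not None:
        write_genetic_map(genotypes.genetic_map, map_path)


def read_traits(path) -> TraitTable:
    return TraitTable(values=_read_indexed(path))


def write_traits(traits: TraitTable, path) -> None:
    traits.values.to_csv(path, sep="\t", index_label="strain")


def read_gene_list(path) -> list[str]:
    """Flat gene list, one symbol per line; blank lines and '#' comments skipped."""
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line.split("\t")[0])
    return genes


def write_gene_list(genes: Sequence[str], path) -> None:
    Path(path).write_text("\n".join(genes) + ("\n" if genes else ""))


def read_groups(path) -> pd.Series:
    """Two-column TSV sample -> group label ('case' / 'control')."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def write_groups(groups: pd.Series, path) -> None:
    groups.rename("group").to_csv(path, sep="\t", index_label="sample")


def write_scan(scan: AssociationScan, path) -> None:
    scan.records.to_csv(path, sep="\t", index=False)


def write_interval_bed(interval: tuple | None, path, name: str = "qtl") -> None:
    """Significant interval as BED (0-based, half-open), Mb converted to bp."""
    with open(path, "w") as fh:
        if interval is not None:
            chrom, lo, hi = interval
            start = int(round(lo * 1e6))
            end = max(int(round(hi * 1e6)), start + 1)
            fh.write(f"chr{chrom}\t{start}\t{end}\t{name}\n")
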