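"""Core in-memory containers shared across the pipeline.

All tabular containers are thin dataclass wrappers around pandas objects,
validated on construction.  Strains are row labels throughout; genes,
markers and traits are column labels.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker map: one row per marker with chromosome and Mb position.

    Positions must be strictly increasing within each chromosome.
    """

    table: pd.DataFrame  # columns: marker, chromosome, position_mb

    def __post_init__(self) -> None:
        required = {"marker", "chromosome", "position_mb"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"genetic map missing columns: {sorted(missing)}")
        if self.table.empty:
            raise ValidationError("genetic map has no markers")
        if self.table["marker"].duplicated().any():
            dups = self.table.loc[self.table["marker"].duplicated(), "marker"].tolist()
            raise ValidationError(f"duplicate marker IDs: {dups}")
        for chrom, grp in self.table.groupby("chromosome", sort=False):
            pos = grp["position_mb"].to_numpy(dtype=float)
            if not np.all(np.diff(pos) > 0):
                raise ValidationError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    @property
    def markers(self) -> list[str]:
        return self.table["marker"].tolist()

    @property
    def chromosomes(self) -> list:
        return self.table["chromosome"].drop_duplicates().tolist()

    def chromosome_of(self, marker: str):
        row = self.table.loc[self.table["marker"] == marker]
        if row.empty:
            raise KeyError(f"marker {marker!r} not on map")
        return row["chromosome"].iloc[0]

    def position_of(self, marker: str) -> float:
        row = self.table.loc[self.table["marker"] == marker]
        if row.empty:
            raise KeyError(f"marker {marker!r} not on map")
        return float(row["position_mb"].iloc[0])

    def nearest_marker(self, chromosome, position_mb: float) -> str:
        """Marker on `chromosome` closest to `position_mb`."""
        grp = self.table.loc[self.table["chromosome"] == chromosome]
        if grp.empty:
            raise KeyError(f"chromosome {chromosome!r} not on map")
        i = (grp["position_mb"] - position_mb).abs().idxmin()
        return grp.loc[i, "marker"]


@dataclass
class StrainGenotypes:
    """Biallelic homozygous genotypes for an RI panel: 0 = B allele, 1 = D allele."""

    alleles: pd.DataFrame  # strains x markers, values in {0, 1}
    genetic_map: GeneticMap

    def __post_init__(self) -> None:
        if self.alleles.index.duplicated().any():
            raise ValidationError("duplicate strain IDs in genotypes")
        vals = self.alleles.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValidationError("genotypes must be 0/1 (homozygous RI coding)")
        if list(self.alleles.columns) != self.genetic_map.markers:
            raise ValidationError("genotype columns must match the genetic map order")

    @property
    def strains(self) -> list[str]:
        return self.alleles.index.tolist()

    @property
    def n_strains(self) -> int:
        return self.alleles.shape[0]


@dataclass
class ExpressionMatrix:
    """Strains x genes log2-scale expression for one tissue.

    `annotation` maps gene symbol -> (chromosome, position_mb); it may cover
    only a subset of genes (background simulated genes need no locus).
    """

    values: pd.DataFrame  # strains x genes
    tissue: str = "tissue"
    annotation: Optional[pd.DataFrame] = None  # index gene; columns chromosome, position_mb

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate strain IDs in expression matrix")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate gene symbols in expression matrix")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.isfinite(arr[~np.isnan(arr)]).all():
            raise ValidationError("expression values must be finite where present")
        if self.annotation is not None and len(self.annotation):
            if (self.annotation["position_mb"] < 0).any():
                raise ValidationError("annotation positions must be >= 0")

    @property
    def strains(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def genes(self) -> list[str]:
        return self.values.columns.tolist()

    def gene_values(self, gene: str) -> pd.Series:
        if gene not in self.values.columns:
            raise KeyError(f"gene {gene!r} not in expression matrix")
        return self.values[gene]

    def locus_of(self, gene: str) -> tuple:
        if self.annotation is None or gene not in self.annotation.index:
            raise KeyError(f"gene {gene!r} has no annotated locus")
        row = self.annotation.loc[gene]
        return row["chromosome"], float(row["position_mb"])


@dataclass
class TraitTable:
    """Strains x named phenotypes; missing values (NaN) allowed."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate strain IDs in trait table")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate trait IDs in trait table")

    @property
    def strains(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def traits(self) -> list[str]:
        return self.values.columns.tolist()
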