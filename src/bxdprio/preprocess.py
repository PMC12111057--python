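"""Expression normalization and per-gene strain-variation summaries.

The 2Z + 8 transformation is the GeneNetwork display convention for
log2 microarray data: z-score each normalization unit, then rescale to
mean 8 and standard deviation 2 so all values are positive and
comparable across arrays.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ExpressionMatrix

__all__ = ["normalize_2z8", "transform_2z8", "strain_summary", "StrainSummary"]


def transform_2z8(values: np.ndarray) -> np.ndarray:
    """2Z + 8 on one unit: 2 * (x - mean) / sd + 8, sample SD (ddof=1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("normalization unit needs at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance normalization unit")
    return 2.0 * (x - x.mean()) / sd + 8.0


def normalize_2z8(matrix: ExpressionMatrix, per_gene: bool = False) -> ExpressionMatrix:
    """Rescale each normalization unit to mean 8, SD 2.

    The default unit is the strain (array) row, matching GeneNetwork
    practice; ``per_gene=True`` normalizes each gene column instead.
    Raises a ValueError naming the offending unit if any unit is constant.
    """
    df = matrix.values
    axis_labels = df.columns if per_gene else df.index
    arr = df.to_numpy(dtype=float)
    if per_gene:
        arr = arr.T
    if arr.shape[1] < 2:
        raise ValueError("each normalization unit needs at least 2 values")
    means = arr.mean(axis=1, keepdims=True)
    sds = arr.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sds.ravel() == 0)
    if flat.size:
        unit = "gene" if per_gene else "strain"
        names = [str(axis_labels[i]) for i in flat[:5]]
        raise ValueError(f"zero-variance {unit} unit(s): {names}")
    out = 2.0 * (arr - means) / sds + 8.0
    if per_gene:
        out = out.T
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=df.index, columns=df.columns),
        tissue=matrix.tissue,
        annotation=matrix.annotation,
    )


@dataclass(frozen=True)
class StrainSummary:
    """Per-gene variation across a strain panel on the log2 scale.

    fold_difference = 2 ** (max - min): the ratio between the highest- and
    lowest-expressing strains.
    """

    gene: str
    n_strains: int
    mean: float
    sd: float
    fold_difference: float


def strain_summary(values: pd.Series, gene: str = "", exclude: list | None = None) -> StrainSummary:
    """Mean, sample SD and fold difference of one gene's per-strain values.

    Missing values are dropped first; at least two finite values required.
    `exclude` drops named strains (e.g. parental strains and F1 hybrids,
    which are conventionally left out of RI-panel range summaries).
    """
    series = pd.Series(values)
    if exclude:
        series = series.drop(index=[s for s in exclude if s in series.index])
    x = series.dropna().to_numpy(dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 finite per-strain values")
    return StrainSummary(
        gene=gene or (values.name if values.name else ""),
        n_strains=int(x.size),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        fold_difference=float(2.0 ** (x.max() - x.min())),
    )
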