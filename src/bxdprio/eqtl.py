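"""Linear mixed-model association scans with kinship correction and LOCO.

For a phenotype y over n strains the model at each marker is

    y = mu + x beta + g + e,    g ~ N(0, sg^2 K),    e ~ N(0, se^2 I)

with K the centered marker-based relatedness matrix.  Under LOCO
(leave one chromosome out), K is rebuilt excluding the tested marker's
chromosome so the polygenic term is not contaminated by the proximal
signal.  The variance ratio lambda = sg^2 / se^2 is profiled out by
maximum likelihood with a single eigendecomposition of K per chromosome
(EMMA-style rotation): a coarse log-spaced grid over 1e-5..1e5 followed
by bounded local refinement.  beta = 0 is tested by a Wald F statistic
referred to F(1, n - 2), so with K = I the scan reduces exactly to the
single-marker ordinary least squares F-test.

Also provides peak/interval extraction, cis/trans classification and a
PheWAS-style phenome scan (one locus against many traits with
Benjamini-Hochberg q-values).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .enrich import bh_fdr
from .types import GeneticMap, StrainGenotypes, TraitTable

__all__ = [
    "KinshipMatrix",
    "AssociationScan",
    "EqtlCall",
    "PhenomeScanResult",
    "kinship_matrix",
    "lmm_scan",
    "qtl_interval",
    "classify_eqtl",
    "phenome_scan",
]

SUGGESTIVE_LOGP = 2.5
SIGNIFICANT_LOGP = 4.0

_LAMBDA_GRID = np.logspace(-5, 5, 100)


@dataclass
class KinshipMatrix:
    """Centered marker-based relatedness: K = (1/M) sum_m (x_m - xbar)(x_m - xbar)^T."""

    strains: list[str]
    K: np.ndarray
    excluded_chromosome: Optional[str] = None

    def __post_init__(self) -> None:
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")
        eigvals = np.linalg.eigvalsh(self.K)
        if eigvals.min() < -1e-8:
            raise ValueError("kinship matrix must be positive semi-definite")


def kinship_matrix(
    genotypes: StrainGenotypes, exclude_chromosome: Optional[str] = None
) -> KinshipMatrix:
    """Centered relatedness over all markers, optionally excluding one chromosome."""
    gmap = genotypes.genetic_map.table
    keep = gmap["marker"].tolist()
    if exclude_chromosome is not None:
        keep = gmap.loc[gmap["chromosome"] != exclude_chromosome, "marker"].tolist()
    if len(keep) < 2:
        raise ValueError("fewer than 2 markers remain after chromosome exclusion")
    X = genotypes.alleles[keep].to_numpy(dtype=float)
    Xc = X - X.mean(axis=0, keepdims=True)
    K = Xc @ Xc.T / Xc.shape[1]
    return KinshipMatrix(
        strains=genotypes.strains, K=K, excluded_chromosome=exclude_chromosome
    )


def _ml_neg_loglik(log_lambda: float, s: np.ndarray, Uty: np.ndarray, UtX: np.ndarray) -> float:
    lam = np.exp(log_lambda)
    d = lam * s + 1.0
    n = Uty.size
    XtDX = (UtX.T / d) @ UtX
    XtDy = (UtX.T / d) @ Uty
    beta = np.linalg.solve(XtDX, XtDy)
    resid = Uty - UtX @ beta
    rss = float(np.sum(resid**2 / d))
    sigma2 = rss / n
    return 0.5 * (n * np.log(2 * np.pi * sigma2) + float(np.sum(np.log(d))) + n)


def _fit_marker(s: np.ndarray, Uty: np.ndarray, UtX: np.ndarray) -> tuple[float, float, float]:
    """Profile lambda by ML; return (beta_marker, logp, lambda_hat).

    Wald F on the marker coefficient with n - p denominator df.
    """
    n = Uty.size
    grid = np.log(_LAMBDA_GRID)
    vals = [_ml_neg_loglik(g, s, Uty, UtX) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            _ml_neg_loglik, bounds=(lo, hi), args=(s, Uty, UtX), method="bounded"
        )
        log_lam = float(res.x) if res.fun <= vals[i] else grid[i]
    else:
        log_lam = grid[i]
    lam = np.exp(log_lam)
    d = lam * s + 1.0
    p = UtX.shape[1]
    XtDX = (UtX.T / d) @ UtX
    XtDy = (UtX.T / d) @ Uty
    XtDX_inv = np.linalg.inv(XtDX)
    beta = XtDX_inv @ XtDy
    resid = Uty - UtX @ beta
    rss = float(np.sum(resid**2 / d))
    sigma2 = rss / (n - p)
    var_beta = sigma2 * XtDX_inv[-1, -1]
    F = beta[-1] ** 2 / var_beta if var_beta > 0 else np.inf
    logp = -stats.f.logsf(F, 1, n - p) / np.log(10)
    return float(beta[-1]), float(logp), float(lam)


@dataclass
class AssociationScan:
    """Per-marker mixed-model association results for one phenotype."""

    records: pd.DataFrame  # marker, chromosome, position_mb, beta, logp
    suggestive_threshold: float = SUGGESTIVE_LOGP
    significant_threshold: float = SIGNIFICANT_LOGP

    @property
    def peak(self) -> pd.Series:
        return self.records.loc[self.records["logp"].idxmax()]


def _align(phenotype: pd.Series, genotypes: StrainGenotypes) -> tuple[np.ndarray, pd.DataFrame]:
    pheno = pd.Series(phenotype).dropna()
    common = [s for s in genotypes.strains if s in pheno.index]
    missing = [s for s in pheno.index if s not in genotypes.strains]
    if missing:
        raise ValueError(f"phenotyped strains without genotypes: {missing[:5]}")
    y = pheno.loc[common].to_numpy(dtype=float)
    return y, genotypes.alleles.loc[common]


def lmm_scan(
    phenotype: pd.Series,
    genotypes: StrainGenotypes,
    loco: bool = True,
    kinship: Optional[KinshipMatrix] = None,
) -> AssociationScan:
    """Genome scan of one phenotype against every marker.

    With ``loco=True`` the kinship excludes each tested marker's
    chromosome.  A pre-built ``kinship`` (e.g. the identity for an OLS
    cross-check) overrides LOCO.
    """
    y, alleles = _align(phenotype, genotypes)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 strains with phenotype and genotypes")
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant")
    gmap = genotypes.genetic_map.table
    sub = StrainGenotypes(alleles=alleles, genetic_map=genotypes.genetic_map)

    rows = []
    ones = np.ones(n)
    for chrom, grp in gmap.groupby("chromosome", sort=False):
        if kinship is not None:
            kin = kinship
        elif loco:
            kin = kinship_matrix(sub, exclude_chromosome=chrom)
        else:
            kin = kinship_matrix(sub)
        s, U = np.linalg.eigh(kin.K)
        s = np.clip(s, 0.0, None)
        Uty = U.T @ y
        Ut1 = U.T @ ones
        for _, mrow in grp.iterrows():
            x = alleles[mrow["marker"]].to_numpy(dtype=float)
            if np.ptp(x) == 0:  # monomorphic marker in this strain subset
                rows.append((mrow["marker"], chrom, mrow["position_mb"], 0.0, 0.0))
                continue
            UtX = np.column_stack([Ut1, U.T @ x])
            beta, logp, _ = _fit_marker(s, Uty, UtX)
            rows.append((mrow["marker"], chrom, mrow["position_mb"], beta, logp))
    records = pd.DataFrame(
        rows, columns=["marker", "chromosome", "position_mb", "beta", "logp"]
    )
    return AssociationScan(records=records)


def qtl_interval(
    scan: AssociationScan, threshold: float = SIGNIFICANT_LOGP
) -> Optional[tuple]:
    """Mb span of the contiguous above-threshold marker run around the peak.

    Returns (chromosome, start_mb, end_mb), or None when the peak itself
    is below threshold.  A single qualifying marker yields a zero-width
    interval.
    """
    if scan.records.empty:
        raise ValueError("empty scan")
    peak = scan.peak
    if peak["logp"] < threshold:
        return None
    chrom = peak["chromosome"]
    grp = scan.records.loc[scan.records["chromosome"] == chrom].reset_index(drop=True)
    i_peak = int(grp["logp"].idxmax())
    above = grp["logp"].to_numpy() >= threshold
    lo = i_peak
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = i_peak
    while hi < len(grp) - 1 and above[hi + 1]:
        hi += 1
    return (chrom, float(grp.loc[lo, "position_mb"]), float(grp.loc[hi, "position_mb"]))


@dataclass(frozen=True)
class EqtlCall:
    gene: str
    gene_chromosome: str
    gene_position_mb: float
    peak_marker: str
    peak_logp: float
    interval: Optional[tuple]
    classification: str  # cis | trans | none
    cis_window_mb: float


def classify_eqtl(
    scan: AssociationScan,
    gene: str,
    gene_locus: tuple,
    cis_window_mb: float = 10.0,
    threshold: float = SIGNIFICANT_LOGP,
) -> EqtlCall:
    """Call the scan cis, trans, or none for the gene at `gene_locus`.

    cis: the significant interval (or the peak, when the interval is a
    single marker) lies on the gene's chromosome within `cis_window_mb` of
    the gene position (distance 0 if the position falls inside the
    interval).  trans: significant elsewhere.  none: nothing significant.
    """
    chrom, pos = str(gene_locus[0]), float(gene_locus[1])
    interval = qtl_interval(scan, threshold=threshold)
    peak = scan.peak
    if interval is None:
        cls = "none"
    else:
        ichrom, lo, hi = str(interval[0]), interval[1], interval[2]
        if ichrom == chrom:
            dist = 0.0 if lo <= pos <= hi else min(abs(pos - lo), abs(pos - hi))
            cls = "cis" if dist <= cis_window_mb else "trans"
        else:
            cls = "trans"
    return EqtlCall(
        gene=gene,
        gene_chromosome=chrom,
        gene_position_mb=pos,
        peak_marker=str(peak["marker"]),
        peak_logp=float(peak["logp"]),
        interval=interval,
        classification=cls,
        cis_window_mb=cis_window_mb,
    )


@dataclass
class PhenomeScanResult:
    """One locus against many traits, with BH q-values across traits."""

    records: pd.DataFrame  # trait, n, beta, logp, p, q
    q_significant: float = 0.05
    q_stringent: float = 0.001

    @property
    def significant(self) -> list[str]:
        return self.records.loc[self.records["q"] < self.q_significant, "trait"].tolist()

    @property
    def stringent(self) -> list[str]:
        return self.records.loc[self.records["q"] < self.q_stringent, "trait"].tolist()


def phenome_scan(
    genotypes: StrainGenotypes,
    locus_marker: str,
    traits: TraitTable,
    min_strains: int = 10,
) -> PhenomeScanResult:
    """Mixed-model association of one marker with every usable trait.

    The kinship leaves out the locus marker's chromosome (LOCO); traits
    with fewer than `min_strains` complete strains are dropped.  q-values
    are Benjamini-Hochberg across the tested traits.
    """
    chrom = genotypes.genetic_map.chromosome_of(locus_marker)
    rows = []
    for trait in traits.traits:
        t = traits.values[trait].dropna()
        common = [s for s in genotypes.strains if s in t.index]
        if len(common) < min_strains:
            continue
        y = t.loc[common].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            continue
        sub = StrainGenotypes(
            alleles=genotypes.alleles.loc[common], genetic_map=genotypes.genetic_map
        )
        x = sub.alleles[locus_marker].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            continue
        kin = kinship_matrix(sub, exclude_chromosome=chrom)
        s, U = np.linalg.eigh(kin.K)
        s = np.clip(s, 0.0, None)
        UtX = np.column_stack([U.T @ np.ones(len(y)), U.T @ x])
        beta, logp, _ = _fit_marker(s, U.T @ y, UtX)
        rows.append((trait, len(y), beta, logp, 10.0 ** (-logp)))
    if not rows:
        raise ValueError("no usable traits for the phenome scan")
    records = pd.DataFrame(rows, columns=["trait", "n", "beta", "logp", "p"])
    records["q"] = bh_fdr(records["p"].tolist())
    return PhenomeScanResult(records=records)
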