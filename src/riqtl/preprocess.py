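"""Expression normalization and broad-sense heritability.

The normalization is the modified Z score used throughout GeneNetwork
BXD expression datasets: per array, take log2 of the summarized
intensities, standardize to a z-score, multiply by 2 and add 8.  Every
array then has mean 8 and sample variance 4 (standard deviation 2), and
a two-fold expression difference corresponds to roughly one unit.

Broad-sense heritability of a transcript across an RI panel is
estimated from variance components of the strain structure:

    h^2 = 0.5 VA / (0.5 VA + VE)

with VA the variance among strain means and VE the pooled within-strain
variance.  The factor 0.5 corrects for the doubled additive variance
among inbred strains relative to an outbred population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TREATMENTS",
    "ExpressionMatrix",
    "StrainMeans",
    "HeritabilityResult",
    "modified_z_transform",
    "strain_means",
    "broad_sense_heritability",
    "heritability_table",
]

logger = logging.getLogger(__name__)

TREATMENTS = frozenset({"saline", "ethanol", "none"})


@dataclass
class ExpressionMatrix:
    """Gene x sample expression with strain/treatment metadata.

    ``values``: genes x samples DataFrame on the post-transform scale.
    ``samples``: DataFrame indexed by sample_id with columns
    ``strain``, ``treatment`` (saline / ethanol / none), ``replicate``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("strain", "treatment", "replicate") if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample sheet lacks columns: {missing}")
        orphans = [s for s in self.values.columns if s not in self.samples.index]
        if orphans:
            raise ValueError(f"samples absent from sheet: {orphans}")
        bad = set(self.samples["treatment"]) - TREATMENTS
        if bad:
            raise ValueError(f"unknown treatment labels: {sorted(bad)}")
        if not np.all(np.isfinite(self.values.to_numpy(float))):
            raise ValueError("expression values must be finite")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        # keep sheet aligned to the matrix column order
        self.samples = self.samples.loc[self.values.columns]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def strains(self) -> list[str]:
        return list(pd.unique(self.samples["strain"]))

    def subset_treatment(self, treatment: str) -> "ExpressionMatrix":
        keep = self.samples.index[self.samples["treatment"] == treatment]
        return ExpressionMatrix(self.values[keep], self.samples.loc[keep])


@dataclass
class StrainMeans:
    """Gene x strain mean expression with per-strain sample counts."""

    values: pd.DataFrame  # genes x strains
    n_per_strain: pd.Series

    def __post_init__(self) -> None:
        if (self.n_per_strain < 1).any():
            raise ValueError("per-strain sample counts must be >= 1")
        if list(self.values.columns) != list(self.n_per_strain.index):
            raise ValueError("strain order mismatch between values and counts")


@dataclass
class HeritabilityResult:
    gene: str
    VA: float
    VE: float
    h2: float

    def __post_init__(self) -> None:
        if self.VA < 0 or self.VE < 0:
            raise ValueError("variance components must be non-negative")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")


def modified_z_transform(
    raw,
    already_log2: bool = False,
    scale: float = 2.0,
    offset: float = 8.0,
):
    """Per-array modified Z normalization: 2 z(log2 x) + 8.

    Accepts a genes x samples DataFrame (or an :class:`ExpressionMatrix`,
    whose values are transformed in a copy).  Each output column has
    mean ``offset`` and sample variance ``scale**2`` exactly.

    Raises
    ------
    ValueError
        If any intensity is non-positive (log2 undefined) or an array
        has zero variance (z-score undefined); the error names the
        offending column.
    """
    if isinstance(raw, ExpressionMatrix):
        return ExpressionMatrix(
            modified_z_transform(raw.values, already_log2, scale, offset),
            raw.samples.copy(),
        )
    values = pd.DataFrame(raw).astype(float)
    if not already_log2:
        if (values.to_numpy() <= 0).any():
            bad = values.columns[(values <= 0).any(axis=0)].tolist()
            raise ValueError(f"non-positive intensities in arrays: {bad}")
        values = np.log2(values)
    sd = values.std(axis=0, ddof=1)
    zero = sd.index[(sd == 0) | sd.isna()].tolist()
    if zero:
        raise ValueError(f"arrays with zero variance (constant column): {zero}")
    z = (values - values.mean(axis=0)) / sd
    return scale * z + offset


def strain_means(expr: ExpressionMatrix, treatment_filter: str | None = None) -> StrainMeans:
    """Average samples to one value per gene per strain.

    With ``treatment_filter`` set, only samples of that treatment group
    are averaged; strains left without samples are dropped with a
    warning.
    """
    sheet = expr.samples
    if treatment_filter is not None:
        if treatment_filter not in TREATMENTS:
            raise ValueError(f"unknown treatment: {treatment_filter!r}")
        keep = sheet.index[sheet["treatment"] == treatment_filter]
        dropped = sorted(set(sheet["strain"]) - set(sheet.loc[keep, "strain"]))
        if dropped:
            logger.warning("strains with no %s samples dropped: %s", treatment_filter, dropped)
        sheet = sheet.loc[keep]
    if len(sheet) == 0:
        raise ValueError("no samples retained")
    by_strain = expr.values[sheet.index].T.groupby(sheet["strain"], sort=False)
    means = by_strain.mean().T
    counts = sheet.groupby("strain", sort=False).size().loc[means.columns]
    return StrainMeans(values=means, n_per_strain=counts)


def _components(values_by_strain: list[np.ndarray]) -> tuple[float, float]:
    """(VA, VE): variance of strain means, pooled within-strain variance."""
    means = np.array([v.mean() for v in values_by_strain])
    VA = float(np.var(means, ddof=1))
    num = 0.0
    df = 0
    for v in values_by_strain:
        if len(v) >= 2:
            num += float(np.var(v, ddof=1)) * (len(v) - 1)
            df += len(v) - 1
    if df == 0:
        raise ValueError(
            "within-strain variance inestimable: every strain has a single sample"
        )
    return VA, num / df


def broad_sense_heritability(expr: ExpressionMatrix, gene: str) -> HeritabilityResult:
    """Broad-sense heritability h2 = 0.5 VA / (0.5 VA + VE) for one gene.

    VA is the sample variance of strain means; VE the within-strain
    sample variance pooled across strains weighted by degrees of
    freedom (single-replicate strains contribute nothing to VE).
    """
    if gene not in expr.values.index:
        raise KeyError(gene)
    row = expr.values.loc[gene]
    groups = [
        row[expr.samples.index[expr.samples["strain"] == s]].to_numpy(float)
        for s in expr.strains
    ]
    if len(groups) < 2:
        raise ValueError("heritability requires at least 2 strains")
    VA, VE = _components(groups)
    denom = 0.5 * VA + VE
    h2 = 0.0 if VA == 0 else (1.0 if denom == 0 else 0.5 * VA / denom)
    return HeritabilityResult(gene=gene, VA=VA, VE=VE, h2=min(max(h2, 0.0), 1.0))


def heritability_table(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene VA, VE, h2 table over all genes in the matrix."""
    rows = []
    for gene in expr.genes:
        res = broad_sense_heritability(expr, gene)
        rows.append({"gene": gene, "VA": res.VA, "VE": res.VE, "h2": res.h2})
    return pd.DataFrame(rows).set_index("gene")
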