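"""Synthetic BXD-like recombinant-inbred panel with planted ground truth.

Generates everything the downstream stages consume — marker maps, RI
genotypes, expression with a cis-regulated target gene, literature
similarity matrices, phenotypes, and qPCR Ct plates — so the whole
pipeline is exercisable and its parameter recovery testable without any
external dataset.

Genotypes are simulated as a two-state Markov chain along each
chromosome: the first marker's allele is Bernoulli(0.5) and the switch
probability across each marker gap is the RI-expanded recombination
fraction R = 4r/(1+6r) (sib mating), with r from the Haldane map
function.  Chromosomes are independent and lines are fully inbred (no
heterozygotes), mirroring how BXD strains segregate the parental B6 (B)
and D2 (D) alleles.

Expression for the target gene is

    baseline + cis_effect * genotype(cis_marker) + strain effect
             + treatment_effect * 1(ethanol) + residual noise,

with the strain-effect variance solved so that the broad-sense
heritability 0.5 VA / (0.5 VA + VE) of the strain structure equals the
requested ``true_h2``.  Module genes share a standardized latent copy
of the target's strain-level signal, giving pairwise strain-mean
correlation ~ rho with the target; background genes are independent
noise around the baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix
from .qtl import _switch_prob

__all__ = [
    "MarkerMap",
    "GenotypeMatrix",
    "PanelTruth",
    "LiteratureSimilarity",
    "simulate_marker_map",
    "simulate_ri_genotypes",
    "simulate_expression",
    "simulate_literature_similarity",
    "simulate_phenotypes",
    "simulate_qpcr",
]

logger = logging.getLogger(__name__)

BASELINE = 8.0  # post-normalization expression scale centre


@dataclass
class MarkerMap:
    """Chromosome-ordered marker positions.

    ``table`` is indexed by marker id with columns ``chromosome``,
    ``position_cM``, ``position_Mb``; within each chromosome both
    coordinates must be strictly increasing (and hence agree in order).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("marker ids must be unique")
        for chrom, sub in self.table.groupby("chromosome", sort=False):
            cm = sub["position_cM"].to_numpy(float)
            mb = sub["position_Mb"].to_numpy(float)
            if np.any(cm < 0) or np.any(mb < 0):
                raise ValueError(f"negative positions on chromosome {chrom}")
            if np.any(np.diff(cm) <= 0) or np.any(np.diff(mb) <= 0):
                raise ValueError(
                    f"marker positions must be strictly increasing on chromosome {chrom}"
                )

    @property
    def marker_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GenotypeMatrix:
    """Strain x marker biallelic calls: 0 = B allele, 1 = D allele, NaN = missing."""

    strains: list[str]
    markers: MarkerMap
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.calls.index) != list(self.strains):
            raise ValueError("calls index must equal the strain list")
        if list(self.calls.columns) != self.markers.marker_ids:
            raise ValueError("calls columns must equal the marker list")
        vals = self.calls.to_numpy(float)
        bad = ~(np.isnan(vals) | (vals == 0) | (vals == 1))
        if bad.any():
            raise ValueError("genotype calls must be 0, 1 or missing (RI lines are isogenic)")


@dataclass
class PanelTruth:
    """Planted ground truth of a simulated panel, for recovery tests."""

    target_gene: str
    cis_marker: str
    cis_effect: float
    true_h2: float
    treatment_effect: float
    module_genes: list[str] = field(default_factory=list)
    module_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_h2 <= 1.0:
            raise ValueError("true_h2 must lie in [0, 1]")
        if not -1.0 < self.module_rho < 1.0:
            raise ValueError("module_rho must lie in (-1, 1)")


@dataclass
class LiteratureSimilarity:
    """Symmetric gene x gene cosine-similarity matrix in [0, 1], diagonal 1."""

    genes: list[str]
    matrix: pd.DataFrame

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy(float)
        if list(self.matrix.index) != self.genes or list(self.matrix.columns) != self.genes:
            raise ValueError("matrix must be indexed by the gene list on both axes")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("similarity diagonal must be exactly 1")
        if m.min() < 0 or m.max() > 1:
            raise ValueError("similarity values must lie in [0, 1]")

    def value(self, a: str, b: str) -> float:
        return float(self.matrix.loc[a, b])


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

def simulate_marker_map(
    n_chromosomes: int,
    markers_per_chromosome: int,
    chrom_length_cM: float = 80.0,
    mb_per_cM: float = 2.0,
    seed: int = 0,
    spacing: str = "even",
) -> MarkerMap:
    """Marker map with even or uniformly random spacing per chromosome.

    ``mb_per_cM`` converts genetic to physical coordinates (the mouse
    genome averages roughly 2 Mb per cM).
    """
    if n_chromosomes < 1 or markers_per_chromosome < 1:
        raise ValueError("counts must be positive")
    if chrom_length_cM <= 0 or mb_per_cM <= 0:
        raise ValueError("lengths must be positive")
    if spacing not in {"even", "random"}:
        raise ValueError(f"unknown spacing: {spacing!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(1, n_chromosomes + 1):
        m = markers_per_chromosome
        if spacing == "even":
            cm = np.linspace(0.0, chrom_length_cM, m) if m > 1 else np.array([0.0])
        else:
            cm = np.sort(rng.uniform(0.0, chrom_length_cM, size=m))
            while m > 1 and np.any(np.diff(cm) <= 1e-9):
                cm = np.sort(rng.uniform(0.0, chrom_length_cM, size=m))
        for i, pos in enumerate(cm, start=1):
            rows.append(
                {
                    "marker_id": f"m{c}_{i}",
                    "chromosome": str(c),
                    "position_cM": float(pos),
                    "position_Mb": float(pos * mb_per_cM),
                }
            )
    return MarkerMap(pd.DataFrame(rows).set_index("marker_id"))


def simulate_ri_genotypes(
    marker_map: MarkerMap,
    n_strains: int,
    seed: int = 0,
    mating: str = "sib",
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """RI genotypes as independent per-chromosome Markov chains.

    First marker of each chromosome is Bernoulli(0.5); adjacent markers
    switch allele with the RI-expanded recombination fraction of their
    cM gap.
    """
    if n_strains < 2:
        raise ValueError("need at least 2 strains")
    rng = np.random.default_rng(seed)
    strains = [f"BXD{i:03d}" for i in range(1, n_strains + 1)]
    cols: dict[str, np.ndarray] = {}
    for chrom, sub in marker_map.table.groupby("chromosome", sort=False):
        cm = sub["position_cM"].to_numpy(float)
        g = np.empty((n_strains, len(cm)), dtype=float)
        g[:, 0] = rng.random(n_strains) < 0.5
        for j in range(1, len(cm)):
            R = _switch_prob(cm[j] - cm[j - 1], mating)
            switch = rng.random(n_strains) < R
            g[:, j] = np.where(switch, 1.0 - g[:, j - 1], g[:, j - 1])
        for j, mid in enumerate(sub.index):
            cols[mid] = g[:, j]
    calls = pd.DataFrame(cols, index=strains)[marker_map.marker_ids]
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls = calls.mask(mask)
    return GenotypeMatrix(strains=strains, markers=marker_map, calls=calls)


def _strain_effect_sd(truth: PanelTruth, cis_var: float, residual_var: float) -> float:
    """Strain-effect s.d. solving 0.5 VA / (0.5 VA + VE) = true_h2.

    VA is the among-strain variance (cis + strain effect) and VE the
    residual (within-strain) variance; the cis contribution is fixed by
    the genotypes, so the strain effect absorbs the remainder.
    """
    if truth.true_h2 >= 1.0:
        raise ValueError("true_h2 = 1 requires zero residual noise; use true_h2 < 1")
    target_VA = 2.0 * residual_var * truth.true_h2 / (1.0 - truth.true_h2)
    var = target_VA - cis_var
    if var < 0:
        logger.warning(
            "cis effect alone exceeds the strain variance implied by true_h2=%.3f; "
            "strain effect clamped to 0",
            truth.true_h2,
        )
        var = 0.0
    return float(np.sqrt(var))


def simulate_expression(
    genotypes: GenotypeMatrix,
    truth: PanelTruth,
    n_replicates_per_strain_per_group: int = 1,
    n_background_genes: int = 100,
    residual_sd: float = 0.25,
    groups: tuple[str, ...] = ("saline", "ethanol"),
    baseline: float = BASELINE,
    scale: str = "normalized",
) -> tuple[ExpressionMatrix, PanelTruth]:
    """Sample-level expression for target, module and background genes.

    ``groups=("none",)`` emulates an untreated mapping panel.  With
    ``scale="raw"`` values are emitted as ``2**x`` so the modified-Z
    transform can be exercised on raw-scale intensities.
    """
    if n_replicates_per_strain_per_group < 1:
        raise ValueError("replicate count must be >= 1")
    if truth.cis_marker not in genotypes.markers.marker_ids:
        raise ValueError(f"cis marker {truth.cis_marker!r} not in the map")
    if scale not in {"normalized", "raw"}:
        raise ValueError(f"unknown scale: {scale!r}")
    rng = np.random.default_rng(truth.seed)
    strains = genotypes.strains
    S = len(strains)
    g = genotypes.calls[truth.cis_marker].to_numpy(float)
    if np.isnan(g).any():
        raise ValueError("cis marker must be fully genotyped for simulation")
    cis_var = truth.cis_effect**2 * float(np.var(g, ddof=1))
    strain_sd = _strain_effect_sd(truth, cis_var, residual_sd**2)
    u = rng.normal(0.0, strain_sd, size=S) if strain_sd > 0 else np.zeros(S)
    target_signal = truth.cis_effect * g + u  # strain-level, shared across groups
    total_strain_var = cis_var + strain_sd**2

    # standardized latent copy of the target's strain signal for module genes
    centred = target_signal - target_signal.mean()
    norm = centred.std(ddof=1)
    latent = centred / norm if norm > 0 else np.zeros(S)
    rho = truth.module_rho
    mod_sd = np.sqrt(total_strain_var) if total_strain_var > 0 else 1.0
    module_signals = {}
    for mg in truth.module_genes:
        eta = rng.normal(0.0, 1.0, size=S)
        eta = (eta - eta.mean()) / eta.std(ddof=1)
        module_signals[mg] = mod_sd * (rho * latent + np.sqrt(1.0 - rho**2) * eta)

    background = [f"bg{i:04d}" for i in range(1, n_background_genes + 1)]
    genes = [truth.target_gene] + list(truth.module_genes) + background

    sample_rows = []
    data: dict[str, np.ndarray] = {}
    for group in groups:
        for rep in range(1, n_replicates_per_strain_per_group + 1):
            for si, strain in enumerate(strains):
                sid = f"{strain}_{group}_{rep}"
                treat = truth.treatment_effect if group == "ethanol" else 0.0
                col = np.empty(len(genes))
                col[0] = baseline + target_signal[si] + treat
                for k, mg in enumerate(truth.module_genes, start=1):
                    col[k] = baseline + module_signals[mg][si]
                col[1 + len(truth.module_genes):] = baseline
                col += rng.normal(0.0, residual_sd, size=len(genes))
                data[sid] = col
                sample_rows.append(
                    {"sample_id": sid, "strain": strain, "treatment": group, "replicate": rep}
                )
    values = pd.DataFrame(data, index=genes)
    if scale == "raw":
        values = 2.0**values
    sheet = pd.DataFrame(sample_rows).set_index("sample_id")
    return ExpressionMatrix(values=values, samples=sheet), truth


def simulate_literature_similarity(
    genes: list[str],
    module_blocks: list[set[str] | list[str]],
    within_block_cosine: float = 0.9,
    background_cosine: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> LiteratureSimilarity:
    """Block-structured cosine-similarity matrix.

    Pairs within a block centre on ``within_block_cosine``, all other
    pairs on ``background_cosine``; optional symmetric Gaussian noise is
    added and values clipped to [0, 1], with the diagonal pinned at 1.
    """
    if not 0.0 <= within_block_cosine <= 1.0 or not 0.0 <= background_cosine <= 1.0:
        raise ValueError("cosines must lie in [0, 1]")
    blocks = [set(b) for b in module_blocks]
    for b in blocks:
        if not b.issubset(genes):
            raise ValueError("block members must come from the gene list")
    for i, a in enumerate(blocks):
        for b in blocks[i + 1:]:
            if a & b:
                raise ValueError(f"blocks overlap: {sorted(a & b)}")
    rng = np.random.default_rng(seed)
    n = len(genes)
    idx = {g: i for i, g in enumerate(genes)}
    m = np.full((n, n), background_cosine, dtype=float)
    for b in blocks:
        ii = [idx[g] for g in b]
        m[np.ix_(ii, ii)] = within_block_cosine
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=(n, n))
        m = m + (noise + noise.T) / 2.0
    m = np.clip(m, 0.0, 1.0)
    np.fill_diagonal(m, 1.0)
    frame = pd.DataFrame(m, index=genes, columns=genes)
    return LiteratureSimilarity(genes=list(genes), matrix=frame)


def simulate_phenotypes(
    target_strain_means: pd.Series,
    n_correlated: int = 3,
    n_null: int = 5,
    correlation: float = 0.7,
    seed: int = 0,
) -> pd.DataFrame:
    """Phenotype x strain table with some phenotypes tracking the target.

    Correlated phenotypes are noisy linear transforms of the target's
    strain means; null phenotypes are independent noise.
    """
    rng = np.random.default_rng(seed)
    t = target_strain_means.to_numpy(float)
    tz = (t - t.mean()) / t.std(ddof=1)
    rows = {}
    for i in range(1, n_correlated + 1):
        eps = rng.normal(0.0, 1.0, size=len(t))
        rows[f"pheno_corr_{i}"] = correlation * tz + np.sqrt(1 - correlation**2) * eps
    for i in range(1, n_null + 1):
        rows[f"pheno_null_{i}"] = rng.normal(0.0, 1.0, size=len(t))
    return pd.DataFrame(rows, index=target_strain_means.index).T


def simulate_qpcr(
    truth: PanelTruth,
    n_strains: int = 10,
    fold_change: float = 0.6,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    reference_gene: str = "Actb",
    base_ct_target: float = 25.0,
    base_ct_reference: float = 20.0,
) -> pd.DataFrame:
    """Triplicate qPCR Ct plate for the target and a reference gene.

    The ethanol-group target Ct is shifted by ``-log2(fold_change)``
    relative to the reference gene, so the ddCt pipeline should recover
    ``fold_change`` as the relative expression.  Per-strain and
    per-(strain, group) Ct offsets shared by both genes emulate input
    and plate variation, which ddCt must cancel.
    """
    if fold_change <= 0:
        raise ValueError("fold change must be positive")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    strains = [f"BXD{i:03d}" for i in range(1, n_strains + 1)]
    shift = -np.log2(fold_change)
    rows = []
    for strain in strains:
        strain_off = rng.normal(0.0, 0.5)
        for group in ("saline", "ethanol"):
            plate_off = rng.normal(0.0, 0.3)
            for gene, base in (
                (truth.target_gene, base_ct_target),
                (reference_gene, base_ct_reference),
            ):
                mu = base + strain_off + plate_off
                if gene == truth.target_gene and group == "ethanol":
                    mu += shift
                cts = mu + rng.normal(0.0, ct_noise_sd, size=n_replicates)
                row = {"strain": strain, "group": group, "gene": gene}
                row.update({f"ct{i+1}": float(c) for i, c in enumerate(cts)})
                rows.append(row)
    return pd.DataFrame(rows)
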