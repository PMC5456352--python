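"""eQTL interval mapping on recombinant-inbred (RI) strain panels.

Implements regression-based (Haley–Knott-style) simple and composite
interval mapping of strain-level phenotypes on biallelic RI genotypes,
permutation-derived genome-wide significance thresholds, and cis/trans
classification of the peak locus.

The linkage statistic is the likelihood ratio statistic

    LRS = n * ln(RSS0 / RSS1)

where ``RSS0`` is the residual sum of squares of the null model
(intercept plus any cofactor markers) and ``RSS1`` that of the model
augmented with the expected genotype at the tested locus.  LOD scores
are ``LRS / (2 ln 10)``.

Genetic distances are converted to single-meiosis recombination
fractions with the Haldane map function (no interference) and expanded
to RI-panel recombination fractions with ``R = 4r/(1+6r)`` for
sib-mated lines (``2r/(1+2r)`` for selfing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, types only
    from .panel import GenotypeMatrix, MarkerMap

__all__ = [
    "LRS_CAP",
    "LOD_SCALE",
    "QTLScan",
    "PermutationThresholds",
    "CisTransCall",
    "haldane_recombination",
    "ri_expand",
    "pseudomarker_probabilities",
    "interval_map",
    "permutation_thresholds",
    "classify_cis_trans",
]

#: Default ceiling for the LRS when the full model fits perfectly
#: (RSS1 underflows); 460 corresponds to roughly LOD 100.
LRS_CAP = 460.0

#: LOD = LRS / LOD_SCALE
LOD_SCALE = 2.0 * math.log(10.0)

MIN_INFORMATIVE_STRAINS = 8


# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------

def haldane_recombination(d: float | np.ndarray) -> float | np.ndarray:
    """Haldane map function: cM distance -> recombination fraction.

    r = (1 - exp(-2 d / 100)) / 2, assuming no crossover interference.

    Parameters
    ----------
    d : float or array
        Genetic distance in centimorgans, >= 0.
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("genetic distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d_arr / 100.0))
    return float(r) if np.isscalar(d) or d_arr.ndim == 0 else r


def ri_expand(r: float | np.ndarray, mating: str = "sib") -> float | np.ndarray:
    """Map expansion for RI lines: single-meiosis r -> observed RI fraction R.

    Sib-mated lines (e.g. BXD): R = 4r / (1 + 6r).
    Selfed lines: R = 2r / (1 + 2r).
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any((r_arr < 0) | (r_arr > 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    if mating == "sib":
        R = 4.0 * r_arr / (1.0 + 6.0 * r_arr)
    elif mating == "self":
        R = 2.0 * r_arr / (1.0 + 2.0 * r_arr)
    else:
        raise ValueError(f"unknown mating system: {mating!r}")
    return float(R) if np.isscalar(r) or r_arr.ndim == 0 else R


def _switch_prob(d_cM: float | np.ndarray, mating: str = "sib"):
    """Probability that adjacent RI genotypes differ across a cM gap."""
    return ri_expand(haldane_recombination(d_cM), mating=mating)


def pseudomarker_probabilities(
    left_genotype: float | None,
    right_genotype: float | None,
    d_left: float,
    d_right: float,
    mating: str = "sib",
) -> float:
    """P(D allele) at an interior locus given flanking RI genotypes.

    Conditions on the two-step Markov chain along the chromosome whose
    per-interval switch probabilities are the RI-expanded recombination
    fractions: with flanks L and R,

        P(D | L, R) = P(L -> D) P(D -> R) / P(L -> R via the chain).

    A missing flank (None or NaN) drops out and the other flank alone is
    conditioned on; with both flanks missing the prior 0.5 is returned.
    """
    if d_left < 0 or d_right < 0:
        raise ValueError("flanking distances must be non-negative")
    left_missing = left_genotype is None or (
        isinstance(left_genotype, float) and math.isnan(left_genotype)
    )
    right_missing = right_genotype is None or (
        isinstance(right_genotype, float) and math.isnan(right_genotype)
    )
    if left_missing and right_missing:
        return 0.5
    r1 = _switch_prob(d_left, mating)
    r2 = _switch_prob(d_right, mating)
    if right_missing:
        return 1.0 - r1 if left_genotype == 1 else r1
    if left_missing:
        return 1.0 - r2 if right_genotype == 1 else r2
    # numerator: pass through D
    p_l_to_d = 1.0 - r1 if left_genotype == 1 else r1
    p_d_to_r = 1.0 - r2 if right_genotype == 1 else r2
    num = p_l_to_d * p_d_to_r
    # denominator: both intermediate states
    p_l_to_b = r1 if left_genotype == 1 else 1.0 - r1
    p_b_to_r = r2 if right_genotype == 1 else 1.0 - r2
    denom = num + p_l_to_b * p_b_to_r
    return num / denom


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class QTLScan:
    """Genome-scan profile of the likelihood ratio statistic for one trait."""

    gene: str
    loci: pd.DataFrame  # columns: chromosome, position_cM, position_Mb, is_pseudomarker
    lrs: np.ndarray
    cofactors: tuple[str, ...] = ()
    n_strains: int = 0

    def __post_init__(self) -> None:
        self.lrs = np.asarray(self.lrs, dtype=float)
        if len(self.lrs) != len(self.loci):
            raise ValueError("lrs length must match loci table")
        if not np.all(np.isfinite(self.lrs)) or np.any(self.lrs < 0):
            raise ValueError("LRS values must be finite and non-negative")

    @property
    def lod(self) -> np.ndarray:
        return self.lrs / LOD_SCALE

    @property
    def peak_index(self) -> int:
        # ties break toward the smallest genomic coordinate (first in map order)
        return int(np.argmax(self.lrs))

    @property
    def peak(self) -> pd.Series:
        row = self.loci.iloc[self.peak_index].copy()
        row["lrs"] = self.lrs[self.peak_index]
        row["lod"] = row["lrs"] / LOD_SCALE
        return row

    def to_frame(self) -> pd.DataFrame:
        out = self.loci.copy()
        out["lrs"] = self.lrs
        out["lod"] = self.lod
        return out


@dataclass
class PermutationThresholds:
    """Genome-wide LRS thresholds from a permutation null distribution.

    ``significant_lrs`` is the empirical 95th percentile of per-scan
    maximum LRS values under permutation (genome-wide p = 0.05);
    ``suggestive_lrs`` is the 37th percentile, the value exceeded by 63%
    of null scans (the once-per-genome-scan convention).
    """

    n_perm: int
    max_lrs_null: np.ndarray
    seed: int | None = None
    significant_quantile: float = 0.95
    suggestive_quantile: float = 0.37

    def __post_init__(self) -> None:
        self.max_lrs_null = np.asarray(self.max_lrs_null, dtype=float)
        if self.n_perm != len(self.max_lrs_null):
            raise ValueError("n_perm must match the null sample size")

    @property
    def significant_lrs(self) -> float:
        return float(np.quantile(self.max_lrs_null, self.significant_quantile))

    @property
    def suggestive_lrs(self) -> float:
        return float(np.quantile(self.max_lrs_null, self.suggestive_quantile))


@dataclass
class CisTransCall:
    """Classification of a scan peak relative to the gene's own location."""

    gene: str
    gene_chromosome: str
    gene_position_Mb: float
    peak: pd.Series
    window_Mb: float
    call: str  # "cis" | "trans" | "none"

    def __post_init__(self) -> None:
        if self.call not in {"cis", "trans", "none"}:
            raise ValueError(f"invalid call: {self.call!r}")


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _marker_table(markers) -> pd.DataFrame:
    table = markers.table if hasattr(markers, "table") else markers
    required = {"chromosome", "position_cM", "position_Mb"}
    if not required.issubset(table.columns):
        raise ValueError(f"marker table must have columns {sorted(required)}")
    return table


def _genotype_calls(genotypes) -> pd.DataFrame:
    return genotypes.calls if hasattr(genotypes, "calls") else genotypes


def build_locus_grid(markers, step_cM: float = 1.0) -> pd.DataFrame:
    """Marker + pseudomarker positions, ordered along the genome.

    Pseudomarkers are placed every ``step_cM`` between the first and last
    marker of each chromosome; Mb positions of pseudomarkers are
    interpolated linearly in cM between flanking markers.
    """
    if step_cM <= 0:
        raise ValueError("step_cM must be positive")
    table = _marker_table(markers)
    rows = []
    for chrom in table["chromosome"].unique():
        sub = table[table["chromosome"] == chrom].sort_values("position_cM")
        cm = sub["position_cM"].to_numpy(float)
        mb = sub["position_Mb"].to_numpy(float)
        grid = np.arange(cm[0], cm[-1], step_cM)
        positions = np.union1d(grid, cm)
        marker_pos = {c: mid for c, mid in zip(cm, sub.index)}
        for pos in positions:
            is_marker = pos in marker_pos
            rows.append(
                {
                    "locus": marker_pos[pos] if is_marker else f"c{chrom}_{pos:.3f}",
                    "chromosome": chrom,
                    "position_cM": float(pos),
                    "position_Mb": float(np.interp(pos, cm, mb)),
                    "is_pseudomarker": not is_marker,
                }
            )
    grid_df = pd.DataFrame(rows).set_index("locus")
    return grid_df


def expected_genotypes(
    genotypes,
    markers,
    step_cM: float = 1.0,
    mating: str = "sib",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expected D-allele dosage at every marker and pseudomarker.

    Returns ``(grid, X)`` where ``grid`` is the locus table from
    :func:`build_locus_grid` and ``X`` is a strains x loci matrix of
    conditional D-allele probabilities.  Observed genotypes pass through
    unchanged; pseudomarkers and missing calls are imputed from the
    nearest non-missing flanking markers on the same chromosome.
    """
    table = _marker_table(markers)
    calls = _genotype_calls(genotypes)
    grid = build_locus_grid(table, step_cM)
    strains = calls.index
    X = np.empty((len(strains), len(grid)), dtype=float)

    for chrom in table["chromosome"].unique():
        sub = table[table["chromosome"] == chrom].sort_values("position_cM")
        marker_ids = list(sub.index)
        cm = sub["position_cM"].to_numpy(float)
        G = calls[marker_ids].to_numpy(float)  # strains x markers, NaN = missing
        sel = grid["chromosome"] == chrom
        grid_cm = grid.loc[sel, "position_cM"].to_numpy(float)
        cols = np.flatnonzero(sel.to_numpy())
        if not np.isnan(G).any():
            # fully observed chromosome: condition on the adjacent flanking
            # markers, vectorized over strains
            for pos, col in zip(grid_cm, cols):
                j = int(np.searchsorted(cm, pos))
                if j < cm.size and cm[j] == pos:
                    X[:, col] = G[:, j]
                    continue
                left, right = G[:, j - 1], G[:, j]
                r1 = _switch_prob(pos - cm[j - 1], mating)
                r2 = _switch_prob(cm[j] - pos, mating)
                p_l_to_d = np.where(left == 1, 1.0 - r1, r1)
                p_d_to_r = np.where(right == 1, 1.0 - r2, r2)
                p_l_to_b = np.where(left == 1, r1, 1.0 - r1)
                p_b_to_r = np.where(right == 1, r2, 1.0 - r2)
                num = p_l_to_d * p_d_to_r
                X[:, col] = num / (num + p_l_to_b * p_b_to_r)
            continue
        for si in range(len(strains)):
            observed = np.flatnonzero(~np.isnan(G[si]))
            obs_cm = cm[observed]
            obs_g = G[si, observed]
            for pos, col in zip(grid_cm, cols):
                if observed.size == 0:
                    X[si, col] = 0.5
                    continue
                j = np.searchsorted(obs_cm, pos)
                exact = j < obs_cm.size and obs_cm[j] == pos
                if exact:
                    X[si, col] = obs_g[j]
                    continue
                left = obs_g[j - 1] if j > 0 else None
                d_left = pos - obs_cm[j - 1] if j > 0 else 0.0
                right = obs_g[j] if j < obs_cm.size else None
                d_right = obs_cm[j] - pos if j < obs_cm.size else 0.0
                X[si, col] = pseudomarker_probabilities(
                    left, right, d_left, d_right, mating=mating
                )
    return grid, pd.DataFrame(X, index=strains, columns=grid.index)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _align(phenotype, calls: pd.DataFrame) -> pd.Series:
    y = pd.Series(phenotype, dtype=float) if not isinstance(phenotype, pd.Series) else phenotype.astype(float)
    y = y.dropna()
    shared = [s for s in calls.index if s in y.index]
    return y.loc[shared]


def _residualize(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of the columns of M after OLS projection on Z."""
    beta, *_ = np.linalg.lstsq(Z, M, rcond=None)
    return M - Z @ beta


def _lrs_profile(
    yres: np.ndarray, Xres: np.ndarray, n: int, cap: float
) -> np.ndarray:
    """Vectorized per-locus LRS given null-model residuals (Frisch–Waugh)."""
    rss0 = float(yres @ yres)
    if rss0 <= 1e-300:
        return np.zeros(Xres.shape[1])
    sxx = np.einsum("ij,ij->j", Xres, Xres)
    sxy = yres @ Xres
    with np.errstate(divide="ignore", invalid="ignore"):
        reduction = np.where(sxx > 1e-12 * n, sxy**2 / sxx, 0.0)
    rss1 = np.maximum(rss0 - reduction, 0.0)
    rss1[rss1 < rss0 * 1e-12] = 0.0  # numerically perfect fit
    floor = rss0 * math.exp(-cap / n)
    lrs = n * np.log(rss0 / np.maximum(rss1, floor))
    return np.minimum(lrs, cap)


def interval_map(
    phenotype,
    genotypes,
    markers=None,
    step_cM: float = 1.0,
    cofactors: Sequence[str] = (),
    lrs_cap: float = LRS_CAP,
    mating: str = "sib",
    gene: str = "trait",
) -> QTLScan:
    """Simple or composite interval mapping of a strain phenotype.

    Parameters
    ----------
    phenotype : mapping or Series
        Strain-indexed trait values (strain means); missing values are
        dropped listwise.
    genotypes : GenotypeMatrix or DataFrame
        Strain x marker calls in {0 (B), 1 (D), NaN}.
    markers : MarkerMap or DataFrame, optional
        Marker positions; taken from ``genotypes.markers`` when omitted.
    cofactors : sequence of marker ids
        Markers whose expected genotypes are held in both null and full
        models (composite interval mapping).
    """
    if markers is None:
        markers = getattr(genotypes, "markers", None)
        if markers is None:
            raise ValueError("markers must be supplied when genotypes carry no map")
    calls = _genotype_calls(genotypes)
    table = _marker_table(markers)
    y = _align(phenotype, calls)
    if len(y) < MIN_INFORMATIVE_STRAINS:
        raise ValueError(
            f"need at least {MIN_INFORMATIVE_STRAINS} strains with phenotype and "
            f"genotype, got {len(y)}"
        )
    for cof in cofactors:
        if cof not in table.index:
            raise ValueError(f"cofactor {cof!r} not in the marker map")

    grid, X = expected_genotypes(calls.loc[y.index], table, step_cM, mating)
    Xm = X.to_numpy(float)
    n = len(y)
    Z = np.ones((n, 1))
    if cofactors:
        Z = np.column_stack([Z] + [X[c].to_numpy(float) for c in cofactors])
    yres = _residualize(y.to_numpy(float)[:, None], Z)[:, 0]
    Xres = _residualize(Xm, Z)
    lrs = _lrs_profile(yres, Xres, n, lrs_cap)
    return QTLScan(
        gene=gene, loci=grid, lrs=lrs, cofactors=tuple(cofactors), n_strains=n
    )


def permutation_thresholds(
    phenotype,
    genotypes,
    markers=None,
    n_perm: int = 2000,
    step_cM: float = 1.0,
    seed: int | None = None,
    lrs_cap: float = LRS_CAP,
    mating: str = "sib",
) -> PermutationThresholds:
    """Genome-wide LRS thresholds by permuting strain labels of the phenotype.

    The phenotype values are shuffled across strains while genotypes stay
    fixed; a full genome scan is run per permutation and the per-scan
    maximum LRS retained.  Significant = 95th percentile of the null
    maxima; suggestive = 37th percentile (exceeded by 63% of null scans).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if markers is None:
        markers = getattr(genotypes, "markers", None)
        if markers is None:
            raise ValueError("markers must be supplied when genotypes carry no map")
    calls = _genotype_calls(genotypes)
    table = _marker_table(markers)
    y = _align(phenotype, calls)
    if len(y) < MIN_INFORMATIVE_STRAINS:
        raise ValueError("too few informative strains for permutation thresholds")

    _, X = expected_genotypes(calls.loc[y.index], table, step_cM, mating)
    Xm = X.to_numpy(float)
    n = len(y)
    rng = np.random.default_rng(seed)
    yv = y.to_numpy(float)
    # permuted phenotype matrix, one column per permutation
    perms = np.stack([rng.permutation(yv) for _ in range(n_perm)], axis=1)
    maxima = max_lrs_null(perms, Xm, lrs_cap)
    return PermutationThresholds(n_perm=n_perm, max_lrs_null=maxima, seed=seed)


def max_lrs_null(Y: np.ndarray, X: np.ndarray, cap: float = LRS_CAP) -> np.ndarray:
    """Per-column maximum LRS of many phenotypes on one expected-genotype matrix.

    ``Y`` is strains x phenotypes, ``X`` strains x loci.  Used both for
    permutation thresholds and for batched null-calibration scans; the
    regression includes an intercept only.
    """
    n = X.shape[0]
    Yc = Y - Y.mean(axis=0, keepdims=True)
    Xc = X - X.mean(axis=0, keepdims=True)
    rss0 = np.einsum("ij,ij->j", Yc, Yc)  # per phenotype
    sxx = np.einsum("ij,ij->j", Xc, Xc)  # per locus
    informative = sxx > 1e-12 * n
    sxy = Xc.T @ Yc  # loci x phenotypes
    with np.errstate(divide="ignore", invalid="ignore"):
        reduction = np.where(informative[:, None], sxy**2 / sxx[:, None], 0.0)
    rss1 = np.maximum(rss0[None, :] - reduction, 0.0)
    rss1 = np.where(rss1 < rss0[None, :] * 1e-12, 0.0, rss1)
    ok = rss0 > 1e-300
    floor = rss0 * math.exp(-cap / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        lrs = n * np.log(rss0[None, :] / np.maximum(rss1, floor[None, :]))
    lrs = np.where(ok[None, :], np.minimum(lrs, cap), 0.0)
    return lrs.max(axis=0)


def classify_cis_trans(
    scan: QTLScan,
    thresholds: PermutationThresholds,
    gene_chromosome: str,
    gene_position_Mb: float,
    window_Mb: float = 10.0,
) -> CisTransCall:
    """Call the scan peak cis, trans, or none.

    cis: peak LRS reaches the genome-wide significant threshold, sits on
    the gene's own chromosome, and lies within ``window_Mb`` of the gene.
    trans: significant elsewhere.  none: no significant peak.
    """
    known = set(scan.loci["chromosome"].astype(str))
    if str(gene_chromosome) not in known:
        raise ValueError(f"unknown chromosome label: {gene_chromosome!r}")
    peak = scan.peak
    if peak["lrs"] < thresholds.significant_lrs:
        call = "none"
    elif (
        str(peak["chromosome"]) == str(gene_chromosome)
        and abs(float(peak["position_Mb"]) - gene_position_Mb) <= window_Mb
    ):
        call = "cis"
    else:
        call = "trans"
    return CisTransCall(
        gene=scan.gene,
        gene_chromosome=str(gene_chromosome),
        gene_position_Mb=float(gene_position_Mb),
        peak=peak,
        window_Mb=float(window_Mb),
        call=call,
    )
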