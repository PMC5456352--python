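"""Calibration and parameter-recovery studies on synthetic panels.

These are the package's own validation experiments: type-I-error
calibration of the permutation-derived genome-wide threshold, detection
power for a planted cis-eQTL, and recovery of planted broad-sense
heritability.  They run entirely on the synthetic panel generator and
are reused by the test suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import panel, preprocess, qtl

__all__ = [
    "null_scan_calibration",
    "cis_detection_power",
    "heritability_recovery",
]


@dataclass
class CalibrationResult:
    """Fraction of null genome scans exceeding their own permutation threshold."""

    n_scans: int
    n_exceeding: int
    thresholds: np.ndarray
    max_lrs: np.ndarray

    @property
    def type_i_error(self) -> float:
        return self.n_exceeding / self.n_scans


def null_scan_calibration(
    n_scans: int = 200,
    n_perm: int = 1000,
    n_strains: int = 30,
    n_chromosomes: int = 20,
    markers_per_chromosome: int = 10,
    chrom_length_cM: float = 80.0,
    step_cM: float = 1.0,
    seed: int = 0,
) -> CalibrationResult:
    """Empirical genome-wide type-I error of the significant threshold.

    One RI panel is simulated; ``n_scans`` independent phenotypes with
    no genetic effect are each interval-mapped, a permutation threshold
    (95th percentile of null scan maxima, ``n_perm`` permutations)
    computed per phenotype, and the fraction of scans whose own maximum
    LRS exceeds their own threshold recorded.  Calibration means this
    fraction is close to 0.05.
    """
    rng = np.random.default_rng(seed)
    marker_map = panel.simulate_marker_map(
        n_chromosomes, markers_per_chromosome, chrom_length_cM, seed=seed
    )
    genotypes = panel.simulate_ri_genotypes(marker_map, n_strains, seed=seed + 1)
    _, X = qtl.expected_genotypes(genotypes.calls, marker_map.table, step_cM)
    Xm = X.to_numpy(float)
    n = n_strains
    thresholds = np.empty(n_scans)
    observed = np.empty(n_scans)
    for i in range(n_scans):
        y = rng.normal(size=n)
        observed[i] = qtl.max_lrs_null(y[:, None], Xm)[0]
        perms = np.stack([rng.permutation(y) for _ in range(n_perm)], axis=1)
        thresholds[i] = np.quantile(qtl.max_lrs_null(perms, Xm), 0.95)
    exceed = int(np.sum(observed > thresholds))
    return CalibrationResult(
        n_scans=n_scans, n_exceeding=exceed, thresholds=thresholds, max_lrs=observed
    )


def cis_detection_power(
    n_sims: int = 100,
    n_strains: int = 60,
    cis_effect: float = 1.0,
    residual_sd: float = 0.5,
    n_perm: int = 1000,
    n_chromosomes: int = 20,
    markers_per_chromosome: int = 10,
    chrom_length_cM: float = 80.0,
    step_cM: float = 1.0,
    window_Mb: float = 10.0,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Fraction of simulations in which a planted cis-eQTL is called cis.

    Per simulation: fresh genotypes, a strain-mean phenotype
    ``cis_effect * genotype + N(0, residual_sd)`` at a mid-genome
    marker, a full scan with its permutation threshold, and the
    cis/trans call at the true gene location.  Success requires a cis
    call with the peak within ``window_Mb`` of the planted marker.
    """
    rng = np.random.default_rng(seed)
    marker_map = panel.simulate_marker_map(
        n_chromosomes, markers_per_chromosome, chrom_length_cM, seed=seed
    )
    chrom = str(max(1, n_chromosomes // 2))
    chrom_markers = marker_map.table[marker_map.table["chromosome"] == chrom]
    cis_marker = chrom_markers.index[len(chrom_markers) // 2]
    true_mb = float(marker_map.table.loc[cis_marker, "position_Mb"])
    rows = []
    for i in range(n_sims):
        genotypes = panel.simulate_ri_genotypes(
            marker_map, n_strains, seed=int(rng.integers(2**31))
        )
        grid, X = qtl.expected_genotypes(genotypes.calls, marker_map.table, step_cM)
        Xm = X.to_numpy(float)
        g = genotypes.calls[cis_marker].to_numpy(float)
        y = cis_effect * g + rng.normal(0.0, residual_sd, size=n_strains)
        yc = y - y.mean()
        Xc = Xm - Xm.mean(axis=0, keepdims=True)
        lrs = qtl._lrs_profile(yc, Xc, n_strains, qtl.LRS_CAP)
        scan = qtl.QTLScan(gene="target", loci=grid, lrs=lrs, n_strains=n_strains)
        perms = np.stack([rng.permutation(y) for _ in range(n_perm)], axis=1)
        thresholds = qtl.PermutationThresholds(
            n_perm=n_perm, max_lrs_null=qtl.max_lrs_null(perms, Xm)
        )
        call = qtl.classify_cis_trans(scan, thresholds, chrom, true_mb, window_Mb)
        peak = scan.peak
        rows.append(
            {
                "call": call.call,
                "peak_chromosome": str(peak["chromosome"]),
                "peak_Mb": float(peak["position_Mb"]),
                "peak_lrs": float(peak["lrs"]),
                "significant_lrs": thresholds.significant_lrs,
                "hit": call.call == "cis"
                and abs(float(peak["position_Mb"]) - true_mb) <= window_Mb,
            }
        )
    results = pd.DataFrame(rows)
    return float(results["hit"].mean()), results


def heritability_recovery(
    true_h2: float,
    n_strains: int = 60,
    n_replicates: int = 4,
    n_reps: int = 100,
    residual_sd: float = 0.25,
    seed: int = 0,
) -> float:
    """Mean estimated h2 over repeated panels with planted heritability.

    Uses an untreated panel (no cis effect; the strain effect carries
    all the genetic variance) with ``n_replicates`` samples per strain.
    """
    rng = np.random.default_rng(seed)
    marker_map = panel.simulate_marker_map(1, 2, 50.0, seed=seed)
    genotypes = panel.simulate_ri_genotypes(marker_map, n_strains, seed=seed + 1)
    estimates = np.empty(n_reps)
    for i in range(n_reps):
        truth = panel.PanelTruth(
            target_gene="target",
            cis_marker=marker_map.marker_ids[0],
            cis_effect=0.0,
            true_h2=true_h2,
            treatment_effect=0.0,
            seed=int(rng.integers(2**31)),
        )
        expr, _ = panel.simulate_expression(
            genotypes,
            truth,
            n_replicates_per_strain_per_group=n_replicates,
            n_background_genes=0,
            residual_sd=residual_sd,
            groups=("none",),
        )
        estimates[i] = preprocess.broad_sense_heritability(expr, "target").h2
    return float(estimates.mean())
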