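# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic panel does and does not emulate, and the
numerical choices that matter at the edges.

## Normalization

The modified-Z score operates per array (per sample column): take log2 of
the summarized intensities, standardize with the sample (n−1) standard
deviation, multiply by 2 and add 8. The n−1 convention is what makes the
post-conditions exact — every output column has mean 8 and sample variance
4 to machine precision — and the z-score is computed across all genes on
one array, not across arrays for one gene. On an array whose log2 values
happen to have sample sd exactly 2, a raw two-fold difference maps to
exactly one output unit; on real arrays the sd is only near 2, which is why
"two-fold ≈ one unit" is an approximation. Non-positive intensities and
constant arrays are rejected with the offending column named; upstream
array summarization (RMA, rank-invariant) is out of scope and the package
consumes already-summarized matrices.

## Heritability

Broad-sense heritability is estimated from the strain structure as
h² = 0.5·V_A / (0.5·V_A + V_E), where V_A is the sample variance of strain
means and V_E the within-strain variance pooled across strains with
degrees-of-freedom weights (single-replicate strains contribute nothing to
V_E; if every strain is single-replicate, estimation fails loudly rather
than silently returning h² = 1). The 0.5 factor accounts for the doubling
of additive variance among fully inbred lines. Note V_A as estimated
contains a sampling term V_E/n̄ from averaging finitely many replicates;
with the default recovery conditions (60 strains × 4 replicates, residual
sd 0.25) this biases ĥ² upward by well under 0.1, which is why the
recovery study checks a ±0.1 band rather than unbiasedness.

## Genotype simulation and map functions

RI genotypes are simulated as a two-state Markov chain along each
chromosome: Bernoulli(0.5) at the first marker, then a switch across each
gap with probability R = 4r/(1+6r) (sib-mated map expansion; 2r/(1+2r)
available for selfed lines), where r comes from the Haldane map function
r = (1−e^(−2d/100))/2 — no crossover interference. This is the standard
RI approximation, not a pedigree simulation of actual breeding
generations: it reproduces marginal allele frequencies of 0.5, the
expanded adjacent-marker recombination fractions, and independence across
chromosomes, but not identity-by-descent block-length distributions beyond
the Markov approximation, residual heterozygosity, or segregation
distortion seen in real panels.

## Interval mapping

Mapping is regression-based (Haley–Knott style) on expected genotypes
rather than an EM mixture likelihood: at each marker and at pseudomarkers
every 1 cM (default), the strain-mean phenotype is regressed on the
conditional probability of the D allele, and LRS = n·ln(RSS₀/RSS₁). This
choice makes the statistic exactly checkable against an ordinary
least-squares oracle and matches the convention of RI-panel mappers; for
fully informative markers it coincides with marker regression. The
conditional probability at an interior point is the exact two-step Markov
conditioning P(L→D)·P(D→R) / [P(L→D)·P(D→R) + P(L→B)·P(B→R)] with
RI-expanded per-interval switch probabilities — the same chain the
simulator uses — and degrades gracefully with missing flanks (one flank:
single-transition probability; both missing: 0.5).

Numerical choices: LRS is capped at 460 (≈ LOD 100) with RSS₁ treated as
zero below a 1e−12 relative floor, so a numerically perfect fit reports
the cap instead of an arbitrary large number; loci whose residualized
genotype column is (near-)collinear with the null design report LRS 0; a
constant phenotype reports an all-zero profile; peak ties break toward the
smallest genomic coordinate. Composite interval mapping adds cofactor
marker columns to both null and full models (Frisch–Waugh
residualization), and permutations shuffle only the phenotype's strain
labels, leaving genotypes and cofactors attached to each other.

Thresholds: significant = empirical 95th percentile of per-scan maximum
LRS over permutations (genome-wide p = 0.05); suggestive = 37th percentile
(the value exceeded by 63% of null scans, the once-per-scan convention).
Published threshold pairs for real BXD datasets are dataset-specific and
are not reproduction targets; what is checked instead is calibration — the
fraction of null scans whose maximum exceeds their own threshold sits at
0.05 ± 0.02 over 200 scans — and power, a planted 1.0-unit cis effect with
residual sd 0.5 on 60 strains being called cis with the peak within 10 Mb
in ≥ 95% of runs. The cis window defaults to ±10 Mb as an operational
reading of "within or near the gene"; it is configurable.

## Differential expression and qPCR

The strain × treatment analysis is the additive two-way ANOVA with one
observation per cell (the strain-by-group mean when replicate-level data
are supplied), so the error stratum is the strain × treatment interaction
with (S−1)(T−1) degrees of freedom. A "const" row (N·ȳ² on 1 df) is
reported for fidelity to classical print-outs but excluded from the total.
If MS_error is exactly zero (a saturated additive fit), effect F ratios
are reported as infinite with p = 0 rather than dividing by zero.
`anova_from_components` rebuilds MS/F/p from printed SS and df columns, so
published tables can be checked without raw data.

ΔΔCt: triplicate Ct values are averaged per strain/group/gene, ΔCt =
Ct_target − Ct_reference, ΔΔCt = ΔCt_treated − ΔCt_calibrator, relative
expression = 2^(−ΔΔCt), summarized as the mean over strains. Because the
reference gene absorbs any per-plate additive shift, the result is exactly
invariant to adding a constant to all Ct values of one strain/group — a
property the simulator deliberately stresses with per-strain and per-plate
offsets. The group test is a one-way ANOVA on per-strain ΔCt values (the
variance-stabilized scale), not on the exponentiated ratios. No
amplification-efficiency (Pfaffl) correction is applied.

## Correlation cascade

Correlations are computed on strain means (the RI-panel convention).
Stages apply in the fixed order floor → genetic → partial → literature
with strict inequalities: mean expression > 7.0, genetic p < 0.05, partial
p < 0.05, literature cosine > 0.3. No multiple-testing correction is
applied at the genetic stage — the workflow filters at nominal p, and the
audit trail records survivors per stage so the attrition is visible.
Partial correlation residualizes target and candidate on (intercept +
control genotype) and takes Pearson on the residuals, with p from the t
transform on n−3 df; it agrees with the closed-form identity
r_xy·z = (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)) to 1e−12. The control
variable is the genotype at the target's peak significant marker (its own
eQTL); the floor is interpreted as the mean across strains, configurable.
Phenotype correlation is Spearman with average-rank ties and a two-sided
t-approximation p (exact rank-permutation enumeration available for
n ≤ 8).

## Enrichment and cohesion

Over-representation uses the upper hypergeometric tail P(X ≥ k) only — the
workflow asks about over-, not under-representation — with the universe
defaulting to the annotation's own gene set and BH step-up adjustment
across categories (flag at adjusted p < 0.05). BH adjusted values
dominate the raw p-values and are monotone along the sorted order; they
are not a fixed point of re-adjustment, which is why no idempotence is
claimed.

The cohesion network connects genes with literature cosine strictly above
0.6. The "literature p-value" is this package's interpretation of a
gene-set cohesion test that is underspecified in the tools it emulates: a
2×2 table of above- vs at-or-below-threshold pairs in the set against a
background gene set (default: all similarity-matrix genes outside the
set), tested with one-sided Fisher's exact for enrichment of
above-threshold pairs. An analytic background was preferred over a single
random draw because it makes the statistic deterministic and exchangeable
under gene relabeling. Degenerate tables (a zero margin, e.g. every pair
everywhere above threshold) are an error rather than a silent p = 1.

## Synthetic panel: what it emulates and what it does not

The expression generator plants, on the modified-Z scale (baseline 8): a
target gene with a cis effect at a chosen marker, a per-strain random
effect whose variance is solved from 0.5·V_A/(0.5·V_A+V_E) = h²_true given
the residual variance (if the cis effect alone already exceeds the implied
strain variance, the strain effect clamps to zero with a warning — the
requested h² is then unattainably low), an additive ethanol shift, module
genes sharing a standardized latent copy of the target's strain signal
(latent correlation ρ; the observed strain-mean correlation is attenuated
by replicate noise), and independent background genes. Defaults — 1
replicate per strain per group (so a two-group, 26-strain design yields 52
observations), residual sd 0.25, cis effect 1.0 with planted h² 0.75
(chosen so the cis variance of 0.25 leaves a positive non-genetic strain
variance of 0.125, without which genotype control would correctly erase
the module) — are fixed study conditions, not tuning knobs. The generator
does not emulate probe-level intensity distributions, batch or sex
effects, heavy-tailed expression noise, or correlated background
structure, so passing recovery tests demonstrate correctness of the
estimators under the stated model, not robustness to everything real
arrays do.

The literature-similarity generator produces block-structured cosine
matrices (within-block vs background levels, symmetric Gaussian noise,
clipped to [0,1], unit diagonal); it stands in for a latent-semantic-
indexing model built from a text corpus, which is out of scope, and its
file format is the square TSV the readers consume.

## Problem sizes

The validation studies run at: 200 null scans × 1000 permutations on a
30-strain, 20-chromosome × 10-marker panel (threshold calibration); 100
simulations × 1000 permutations at 60 strains (cis power); 100 panels of
60 strains × 4 replicates per planted h² (heritability recovery); a
60-strain panel with a 10-gene ρ = 0.9 module over 200 background genes
(cascade recovery). These sizes give Monte-Carlo standard errors
comfortably inside the stated tolerance bands while keeping a full run in
the low tens of seconds.

## Known limitations

No X-chromosome special-casing, no epistasis or multiple-QTL model
selection, no interference-aware map functions, no amplification-
efficiency correction, no fuzzy strain-name matching. Published values
that depend on the real arrays and literature model (dataset LRS and
threshold values, the h² of the motivating transcript, genome-wide
correlate counts) are treated as qualitative surfaces — the package
reproduces the procedures and their calibration, not those numbers.
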