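"""Candidate-gene correlation cascade and phenotype correlation.

The cascade filters transcripts for a target gene in four ordered
stages, each a strict threshold:

1. expression floor — mean expression across strains > 7.0 (on the
   modified-Z scale, where the population centre is 8);
2. genetic correlation — Pearson r of strain means with the target,
   two-sided p < 0.05;
3. partial correlation — Pearson r after removing the linear effect of
   the genotype at the target's own eQTL, p < 0.05; this eliminates
   candidates whose correlation is purely genotype-driven;
4. literature correlation — cosine similarity with the target in a
   literature model, r > 0.3.

Strain-level phenotype correlation uses Spearman's rank correlation
with average ranks for ties and a two-sided t-approximation p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .panel import LiteratureSimilarity
from .preprocess import StrainMeans

__all__ = [
    "CorrelationRecord",
    "genetic_correlation",
    "partial_correlation",
    "add_partial_correlation",
    "literature_filter",
    "cascade_filter",
    "correlation_cascade",
    "phenotype_correlation",
]

logger = logging.getLogger(__name__)

EXPRESSION_FLOOR = 7.0
LITERATURE_THRESHOLD = 0.3
ALPHA = 0.05
MIN_SHARED_STRAINS = 4


@dataclass
class CorrelationRecord:
    """Per-candidate correlation evidence across the cascade stages."""

    gene: str
    r_genetic: float
    p_genetic: float
    mean_expression: float
    n: int
    r_partial: float = float("nan")
    p_partial: float = float("nan")
    r_literature: float = float("nan")


def _pearson_p(r: float, n: int, df: int | None = None) -> float:
    """Two-sided p for Pearson r via the t transform with given df."""
    df = n - 2 if df is None else df
    if df <= 0 or abs(r) >= 1.0:
        return 0.0 if abs(r) >= 1.0 and df > 0 else float("nan")
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


def _as_means_frame(candidates) -> pd.DataFrame:
    return candidates.values if isinstance(candidates, StrainMeans) else pd.DataFrame(candidates)


def genetic_correlation(target: pd.Series, candidates) -> pd.DataFrame:
    """Pearson correlation of every candidate's strain means with the target.

    Uses the pairwise strain intersection per candidate; candidates
    sharing fewer than 4 strains with the target are flagged
    not-evaluable (NaN r/p).  Returns a records DataFrame indexed by
    gene with columns r_genetic, p_genetic, mean_expression, n.
    """
    target = pd.Series(target, dtype=float).dropna()
    frame = _as_means_frame(candidates)
    rows = []
    for gene, row in frame.iterrows():
        vals = row.dropna().astype(float)
        shared = target.index.intersection(vals.index)
        rec = {
            "gene": gene,
            "mean_expression": float(vals.mean()) if len(vals) else float("nan"),
            "n": len(shared),
        }
        if len(shared) < MIN_SHARED_STRAINS:
            rec.update(r_genetic=float("nan"), p_genetic=float("nan"))
        else:
            x = target.loc[shared].to_numpy()
            y = vals.loc[shared].to_numpy()
            if x.std() == 0 or y.std() == 0:
                rec.update(r_genetic=float("nan"), p_genetic=float("nan"))
            else:
                r = float(np.corrcoef(x, y)[0, 1])
                rec.update(r_genetic=r, p_genetic=_pearson_p(r, len(shared)))
        rows.append(rec)
    return pd.DataFrame(rows).set_index("gene")


def partial_correlation(target, candidate, control) -> tuple[float, float]:
    """Pearson correlation of target and candidate given a control variable.

    Both variables are residualized on (intercept + control) by OLS and
    the Pearson correlation of the residuals taken; the p-value uses a
    t transform with n - 3 degrees of freedom (one df spent on the
    control).  Equivalent to the closed-form identity
    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2)).
    """
    x = np.asarray(target, dtype=float)
    y = np.asarray(candidate, dtype=float)
    z = np.asarray(control, dtype=float)
    if not (len(x) == len(y) == len(z)):
        raise ValueError("target, candidate and control must share the same strains")
    if np.std(z) == 0:
        raise ValueError("control variable is constant: nothing to control for")
    Z = np.column_stack([np.ones_like(z), z])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        return float("nan"), float("nan")
    r = float((rx @ ry) / denom)
    r = max(-1.0, min(1.0, r))
    return r, _pearson_p(r, len(x), df=len(x) - 3)


def add_partial_correlation(
    records: pd.DataFrame,
    target: pd.Series,
    candidates,
    control: pd.Series,
) -> pd.DataFrame:
    """Fill r_partial / p_partial for every record, controlling for ``control``.

    ``control`` is typically the genotype at the target's peak
    significant eQTL marker.
    """
    frame = _as_means_frame(candidates)
    target = pd.Series(target, dtype=float)
    control = pd.Series(control, dtype=float)
    out = records.copy()
    out["r_partial"] = np.nan
    out["p_partial"] = np.nan
    for gene in out.index:
        if gene not in frame.index:
            continue
        vals = frame.loc[gene].dropna().astype(float)
        shared = target.dropna().index.intersection(vals.index).intersection(
            control.dropna().index
        )
        if len(shared) < MIN_SHARED_STRAINS:
            continue
        r, p = partial_correlation(
            target.loc[shared], vals.loc[shared], control.loc[shared]
        )
        out.loc[gene, ["r_partial", "p_partial"]] = [r, p]
    return out


def literature_filter(
    records: pd.DataFrame,
    similarity: LiteratureSimilarity,
    target: str,
    threshold: float = LITERATURE_THRESHOLD,
) -> pd.DataFrame:
    """Attach literature cosine with the target and the stage pass flag.

    Pass requires a strict ``r > threshold``; genes absent from the
    similarity matrix fail with a logged reason.
    """
    if target not in similarity.genes:
        raise ValueError(f"target {target!r} absent from the similarity matrix")
    out = records.copy()
    known = set(similarity.genes)
    r_lit = []
    for gene in out.index:
        if gene in known:
            r_lit.append(similarity.value(target, gene))
        else:
            r_lit.append(float("nan"))
    out["r_literature"] = r_lit
    absent = out.index[out["r_literature"].isna()].tolist()
    if absent:
        logger.info("genes absent from the literature model fail the stage: %s", absent)
    out["pass_literature"] = out["r_literature"] > threshold
    return out


def cascade_filter(
    records: pd.DataFrame,
    expression_floor: float = EXPRESSION_FLOOR,
    alpha_genetic: float = ALPHA,
    alpha_partial: float = ALPHA,
    literature_threshold: float = LITERATURE_THRESHOLD,
) -> tuple[list[str], dict[str, int], pd.DataFrame]:
    """Conjunction of the four stages, with a stage-by-stage audit trail.

    Stages apply in order floor -> genetic -> partial -> literature; the
    audit dict records the survivor count after each stage (hence
    monotonically non-increasing).  Returns (passing gene list, audit,
    annotated records).
    """
    out = records.copy()
    out["pass_floor"] = out["mean_expression"] > expression_floor
    out["pass_genetic"] = out["p_genetic"] < alpha_genetic
    out["pass_partial"] = out["p_partial"] < alpha_partial
    if "r_literature" in out.columns:
        out["pass_literature"] = out["r_literature"] > literature_threshold
    elif "pass_literature" not in out.columns:
        raise ValueError("records lack the literature stage; run literature_filter first")
    audit = {"input": len(out)}
    surviving = out
    for stage in ("floor", "genetic", "partial", "literature"):
        surviving = surviving[surviving[f"pass_{stage}"].fillna(False)]
        audit[stage] = len(surviving)
    out["pass_overall"] = (
        out["pass_floor"]
        & out["pass_genetic"].fillna(False)
        & out["pass_partial"].fillna(False)
        & out["pass_literature"].fillna(False)
    )
    return list(surviving.index), audit, out


def correlation_cascade(
    target_gene: str,
    means: StrainMeans,
    control_genotype: pd.Series,
    similarity: LiteratureSimilarity,
    expression_floor: float = EXPRESSION_FLOOR,
    alpha_genetic: float = ALPHA,
    alpha_partial: float = ALPHA,
    literature_threshold: float = LITERATURE_THRESHOLD,
) -> tuple[list[str], dict[str, int], pd.DataFrame]:
    """Run the full cascade for one target against all other genes."""
    if target_gene not in means.values.index:
        raise KeyError(target_gene)
    target = means.values.loc[target_gene]
    candidates = means.values.drop(index=target_gene)
    records = genetic_correlation(target, candidates)
    records = add_partial_correlation(records, target, candidates, control_genotype)
    records = literature_filter(records, similarity, target_gene, literature_threshold)
    return cascade_filter(
        records, expression_floor, alpha_genetic, alpha_partial, literature_threshold
    )


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Exact two-sided permutation p for Spearman rho (small n only)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    observed = abs(rho)
    count = 0
    total = 0
    for perm in permutations(ry):
        r = np.corrcoef(rx, perm)[0, 1]
        if abs(r) >= observed - 1e-12:
            count += 1
        total += 1
    return count / total


def phenotype_correlation(
    target: pd.Series,
    phenotypes: pd.DataFrame,
    alpha: float = ALPHA,
    method: str = "t",
) -> pd.DataFrame:
    """Spearman correlation of strain phenotypes with the target's strain means.

    ``phenotypes`` is phenotype x strain.  Each phenotype is evaluated
    on its strain intersection with the target (average-rank ties);
    phenotypes sharing fewer than 4 strains are skipped with a log
    entry.  ``method="exact"`` enumerates rank permutations for n <= 8;
    otherwise the two-sided t approximation with n - 2 df is used.
    """
    target = pd.Series(target, dtype=float).dropna()
    rows = []
    for pheno, row in phenotypes.iterrows():
        vals = row.dropna().astype(float)
        shared = target.index.intersection(vals.index)
        if len(shared) < MIN_SHARED_STRAINS:
            logger.info("phenotype %s skipped: only %d shared strains", pheno, len(shared))
            continue
        x = target.loc[shared].to_numpy()
        y = vals.loc[shared].to_numpy()
        rho, p = stats.spearmanr(x, y)
        rho = float(rho)
        if method == "exact" and len(shared) <= 8:
            p = _spearman_exact_p(x, y, rho)
        rows.append(
            {
                "phenotype": pheno,
                "n": len(shared),
                "spearman_rho": rho,
                "p": float(p),
                "significant": float(p) < alpha,
            }
        )
    return pd.DataFrame(rows).set_index("phenotype") if rows else pd.DataFrame(
        columns=["n", "spearman_rho", "p", "significant"]
    )
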