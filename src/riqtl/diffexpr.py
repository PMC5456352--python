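"""Strain x treatment differential expression and qPCR quantification.

The microarray analysis is an additive two-way ANOVA with strain and
treatment as crossed factors and one observation per cell (the
strain-by-group mean), so the error term is the strain x treatment
interaction:

    SS_treatment = S * sum_t (ybar_t - ybar)^2     df = T - 1
    SS_strain    = T * sum_s (ybar_s - ybar)^2     df = S - 1
    SS_error     = SS_total - SS_treatment - SS_strain
    F            = MS_effect / MS_error

A "const" row (N * ybar^2 on 1 df) is reported for fidelity to the
classical ANOVA print-out but excluded from SS_total.

qPCR relative expression uses the ddCt method against a reference gene
(beta-actin in the original assay): per strain and group, triplicate Ct
values are averaged, dCt = Ct_target - Ct_reference, ddCt =
dCt_treated - dCt_calibrator, and relative expression = 2^(-ddCt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ExpressionMatrix

__all__ = [
    "AnovaTable",
    "QpcrResult",
    "two_way_anova",
    "anova_from_components",
    "strain_treatment_cells",
    "ddct_relative_expression",
]


@dataclass
class AnovaTable:
    """Five-row additive ANOVA table (const, treatment, strain, error, total)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        expected = ["const", "treatment", "strain", "error", "total"]
        if list(self.table.index) != expected:
            raise ValueError(f"rows must be {expected}")

    def __getitem__(self, source: str) -> pd.Series:
        return self.table.loc[source]

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


@dataclass
class QpcrResult:
    """Per-strain ddCt quantification and its group comparison."""

    gene: str
    reference_gene: str
    per_strain: pd.DataFrame  # dct_<calibrator>, dct_<treated>, ddct, relative_expression
    relative_expression: float  # mean over strains
    f_statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if (self.per_strain["relative_expression"] <= 0).any():
            raise ValueError("relative expression must be positive")


def strain_treatment_cells(
    expr: ExpressionMatrix,
    gene: str,
    treatments: tuple[str, str] = ("saline", "ethanol"),
) -> pd.DataFrame:
    """Strain x treatment cell means for one gene from replicate-level data."""
    if gene not in expr.values.index:
        raise KeyError(gene)
    row = expr.values.loc[gene]
    sheet = expr.samples
    cells = (
        pd.DataFrame({"value": row, "strain": sheet["strain"], "treatment": sheet["treatment"]})
        .groupby(["strain", "treatment"], sort=False)["value"]
        .mean()
        .unstack("treatment")
    )
    missing = [t for t in treatments if t not in cells.columns]
    if missing:
        raise ValueError(f"no samples for treatment level(s): {missing}")
    return cells[list(treatments)]


def two_way_anova(cell_values: pd.DataFrame) -> AnovaTable:
    """Additive strain x treatment ANOVA, one observation per cell.

    ``cell_values``: strains as rows, exactly two treatment columns, no
    empty cells.  Returns the five-row table with SS, df, MS, F and p
    (F rows for treatment and strain only).
    """
    cells = pd.DataFrame(cell_values).astype(float)
    if cells.shape[1] != 2:
        raise ValueError("exactly 2 treatment levels are required")
    if cells.shape[0] < 2:
        raise ValueError("at least 2 strains are required")
    if cells.isna().any().any():
        empties = [
            (s, t) for s in cells.index for t in cells.columns if pd.isna(cells.loc[s, t])
        ]
        raise ValueError(f"empty cells: {empties}")
    S, T = cells.shape
    N = S * T
    y = cells.to_numpy()
    grand = y.mean()
    ss_treat = S * float(((y.mean(axis=0) - grand) ** 2).sum())
    ss_strain = T * float(((y.mean(axis=1) - grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_error = ss_total - ss_treat - ss_strain
    ss = {
        "const": N * grand**2,
        "treatment": ss_treat,
        "strain": ss_strain,
        "error": ss_error,
        "total": ss_total,
    }
    df = {
        "const": 1,
        "treatment": T - 1,
        "strain": S - 1,
        "error": (S - 1) * (T - 1),
        "total": N - 1,
    }
    return anova_from_components(ss, df)


def anova_from_components(ss: dict[str, float], df: dict[str, int]) -> AnovaTable:
    """Assemble MS, F and p from sums of squares and degrees of freedom.

    Also usable to reconstitute a published ANOVA table from its printed
    SS/df columns.  ``ss``/``df`` need keys treatment, strain, error;
    const and total are filled in when absent (total = treatment +
    strain + error, excluding const).
    """
    ss = dict(ss)
    df = dict(df)
    for key in ("treatment", "strain", "error"):
        if key not in ss or key not in df:
            raise ValueError(f"missing component: {key}")
    ss.setdefault("total", ss["treatment"] + ss["strain"] + ss["error"])
    df.setdefault("total", df["treatment"] + df["strain"] + df["error"])
    ss.setdefault("const", np.nan)
    df.setdefault("const", 1)
    ms_error = ss["error"] / df["error"]
    rows = []
    for source in ("const", "treatment", "strain", "error", "total"):
        entry = {"source": source, "df": df[source], "SS": ss[source]}
        if source != "total":
            entry["MS"] = ss[source] / df[source]
        else:
            entry["MS"] = np.nan
        if source in ("treatment", "strain") or (
            source == "const" and np.isfinite(ss["const"])
        ):
            if ms_error > 0:
                entry["F"] = entry["MS"] / ms_error
                entry["p"] = float(stats.f.sf(entry["F"], df[source], df["error"]))
            else:  # saturated additive fit: any effect is infinitely sharp
                entry["F"] = np.inf if entry["MS"] > 0 else np.nan
                entry["p"] = 0.0 if entry["MS"] > 0 else np.nan
        else:
            entry["F"] = np.nan
            entry["p"] = np.nan
        rows.append(entry)
    return AnovaTable(pd.DataFrame(rows).set_index("source"))


def _mean_ct(ct_table: pd.DataFrame, gene: str, group: str) -> pd.Series:
    sub = ct_table[(ct_table["gene"] == gene) & (ct_table["group"] == group)]
    ct_cols = [c for c in sub.columns if c.startswith("ct")]
    if sub.empty or not ct_cols:
        raise ValueError(f"no Ct values for gene {gene!r} in group {group!r}")
    vals = sub.set_index("strain")[ct_cols]
    if (vals.to_numpy() < 0).any():
        raise ValueError(f"negative Ct values for gene {gene!r}")
    return vals.mean(axis=1)


def ddct_relative_expression(
    ct_table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator_group: str = "saline",
    treatment_group: str = "ethanol",
) -> QpcrResult:
    """ddCt relative quantification normalized to a reference gene.

    ``ct_table`` is tidy with columns strain, group, gene and replicate
    Ct columns ct1..ctN.  Replicates are averaged per strain/group/gene
    before differencing.  The group comparison (F, p) is a one-way ANOVA
    on per-strain dCt values between the two groups — the
    variance-stabilized scale, rather than the exponentiated ratios.
    """
    genes = set(ct_table["gene"])
    if reference_gene not in genes:
        raise ValueError(f"reference gene {reference_gene!r} absent from the Ct table")
    if target_gene not in genes:
        raise ValueError(f"target gene {target_gene!r} absent from the Ct table")
    dct = {}
    for group in (calibrator_group, treatment_group):
        t = _mean_ct(ct_table, target_gene, group)
        r = _mean_ct(ct_table, reference_gene, group)
        shared = t.index.intersection(r.index)
        dct[group] = (t.loc[shared] - r.loc[shared]).rename(f"dct_{group}")
    strains = dct[calibrator_group].index.intersection(dct[treatment_group].index)
    if len(strains) == 0:
        raise ValueError("no strain measured in both groups")
    per = pd.concat([dct[calibrator_group].loc[strains], dct[treatment_group].loc[strains]], axis=1)
    per["ddct"] = per[f"dct_{treatment_group}"] - per[f"dct_{calibrator_group}"]
    per["relative_expression"] = 2.0 ** (-per["ddct"])
    if len(strains) >= 2:
        f, p = stats.f_oneway(
            dct[calibrator_group].loc[strains], dct[treatment_group].loc[strains]
        )
        f, p = float(f), float(p)
    else:
        f, p = float("nan"), float("nan")
    return QpcrResult(
        gene=target_gene,
        reference_gene=reference_gene,
        per_strain=per,
        relative_expression=float(per["relative_expression"].mean()),
        f_statistic=f,
        p_value=p,
    )
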