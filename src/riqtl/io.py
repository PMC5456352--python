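"""Readers and writers for the pipeline's on-disk formats.

Genotypes use a GeneNetwork-like ``.geno`` dialect: ``@key: value``
header lines, then one tab-separated header row (Chr, Locus, cM, Mb,
one column per strain) and one row per marker with allele codes B
(C57BL/6J allele), D (DBA/2J allele), U (unknown); H (heterozygous,
which a finished RI line should not carry) is read as missing with a
logged count.

Expression travels as a genes x samples TSV plus a sample-sheet TSV
(sample_id, strain, treatment, replicate).  Literature similarity is a
square TSV, phenotypes a phenotype x strain TSV, qPCR plates a tidy
strain/group/gene/ct1..ctN TSV, and panel truth a plain key=value file.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import GenotypeMatrix, LiteratureSimilarity, MarkerMap, PanelTruth
from .preprocess import ExpressionMatrix

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_expression",
    "write_expression",
    "read_similarity",
    "write_similarity",
    "read_phenotypes",
    "write_phenotypes",
    "read_ct_table",
    "write_ct_table",
    "read_truth",
    "write_truth",
    "read_snp_table",
    "load_cd14_snps",
]

logger = logging.getLogger(__name__)

_ALLELE_CODES = {"B": 0.0, "D": 1.0, "U": np.nan, "H": np.nan}
_GENO_COLUMNS = ["Chr", "Locus", "cM", "Mb"]


def read_genotypes(path) -> GenotypeMatrix:
    """Parse a GeneNetwork-like .geno file into genotypes plus marker map.

    Markers are sorted by cM within each chromosome on read, with a
    warning if the file was out of order.
    """
    path = Path(path)
    header: list[str] | None = None
    metadata: dict[str, str] = {}
    marker_rows = []
    call_rows = []
    h_count = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if line.startswith("@"):
                key, _, value = line[1:].partition(":")
                metadata[key.strip()] = value.strip()
                continue
            parts = line.split("\t")
            if header is None:
                if parts[: len(_GENO_COLUMNS)] != _GENO_COLUMNS:
                    raise ValueError(
                        f"{path}:{line_no}: header must start with {_GENO_COLUMNS}"
                    )
                header = parts
                continue
            chrom, locus, cm, mb = parts[:4]
            codes = parts[4:]
            calls = []
            for strain, code in zip(header[4:], codes):
                code = code.strip()
                if code not in _ALLELE_CODES:
                    raise ValueError(
                        f"{path}:{line_no}: unknown allele code {code!r} for strain {strain}"
                    )
                if code == "H":
                    h_count += 1
                calls.append(_ALLELE_CODES[code])
            marker_rows.append(
                {
                    "marker_id": locus,
                    "chromosome": chrom,
                    "position_cM": float(cm),
                    "position_Mb": float(mb),
                }
            )
            call_rows.append(calls)
    if header is None or not marker_rows:
        raise ValueError(f"{path}: no genotype rows found")
    if h_count:
        logger.warning("%d heterozygous (H) calls read as missing", h_count)
    markers = pd.DataFrame(marker_rows).set_index("marker_id")
    if markers.index.duplicated().any():
        dups = markers.index[markers.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate marker ids: {dups}")
    strains = header[4:]
    calls = pd.DataFrame(
        np.asarray(call_rows, dtype=float).T, index=strains, columns=markers.index
    )
    # enforce per-chromosome cM order, preserving chromosome appearance order
    chrom_rank = {c: i for i, c in enumerate(pd.unique(markers["chromosome"]))}
    ordered = markers.sort_values(
        ["chromosome", "position_cM"],
        key=lambda col: col.map(chrom_rank) if col.name == "chromosome" else col,
        kind="stable",
    )
    if list(ordered.index) != list(markers.index):
        logger.warning("%s: markers reordered by cM within chromosomes", path)
        markers = ordered
    calls = calls[markers.index]
    calls.columns = pd.Index(list(markers.index))
    return GenotypeMatrix(strains=strains, markers=MarkerMap(markers), calls=calls)


def write_genotypes(genotypes: GenotypeMatrix, path, metadata: dict | None = None) -> None:
    """Write the .geno dialect (B/D/U codes)."""
    meta = {"type": "riset", "mat": "B", "pat": "D", "het": "H", "unk": "U"}
    meta.update(metadata or {})
    table = genotypes.markers.table
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"@{key}: {value}\n")
        fh.write("\t".join(_GENO_COLUMNS + list(genotypes.strains)) + "\n")
        for marker_id, row in table.iterrows():
            codes = []
            for strain in genotypes.strains:
                call = genotypes.calls.loc[strain, marker_id]
                codes.append("U" if pd.isna(call) else ("D" if call == 1 else "B"))
            fh.write(
                "\t".join(
                    [
                        str(row["chromosome"]),
                        str(marker_id),
                        f"{row['position_cM']:g}",
                        f"{row['position_Mb']:g}",
                    ]
                    + codes
                )
                + "\n"
            )


def read_expression(matrix_path, sample_sheet_path) -> ExpressionMatrix:
    """Read a genes x samples TSV and its sample sheet.

    Every matrix column must appear in the sheet and vice versa;
    mismatches are enumerated in the error.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    sheet = pd.read_csv(sample_sheet_path, sep="\t", index_col=0)
    orphan_cols = [c for c in values.columns if c not in sheet.index]
    orphan_sheet = [s for s in sheet.index if s not in values.columns]
    if orphan_cols or orphan_sheet:
        raise ValueError(
            f"sample mismatch between matrix and sheet: matrix-only={orphan_cols}, "
            f"sheet-only={orphan_sheet}"
        )
    if values.index.duplicated().any():
        dups = values.index[values.index.duplicated()].tolist()
        raise ValueError(f"duplicate gene ids: {dups}")
    values.index.name = None
    return ExpressionMatrix(values=values, samples=sheet.loc[values.columns])


def write_expression(expr: ExpressionMatrix, matrix_path, sample_sheet_path) -> None:
    expr.values.to_csv(matrix_path, sep="\t", index_label="gene")
    expr.samples.to_csv(sample_sheet_path, sep="\t", index_label="sample_id")


def read_similarity(path) -> LiteratureSimilarity:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.columns = [str(c) for c in frame.columns]
    frame.index = [str(i) for i in frame.index]
    return LiteratureSimilarity(genes=list(frame.index), matrix=frame)


def write_similarity(similarity: LiteratureSimilarity, path) -> None:
    similarity.matrix.to_csv(path, sep="\t", index_label="gene")


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype x strain TSV."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, sep="\t", index_label="phenotype")


def read_ct_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"strain", "group", "gene"}
    if not required.issubset(table.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)} plus ct1..ctN")
    if not any(c.startswith("ct") for c in table.columns):
        raise ValueError("Ct table has no replicate columns (ct1..ctN)")
    return table


def write_ct_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_truth(truth: PanelTruth, path) -> None:
    """Plain key=value record of the planted ground truth."""
    with open(path, "w") as fh:
        fh.write(f"target_gene={truth.target_gene}\n")
        fh.write(f"cis_marker={truth.cis_marker}\n")
        fh.write(f"cis_effect={truth.cis_effect!r}\n")
        fh.write(f"true_h2={truth.true_h2!r}\n")
        fh.write(f"treatment_effect={truth.treatment_effect!r}\n")
        fh.write(f"module_genes={','.join(truth.module_genes)}\n")
        fh.write(f"module_rho={truth.module_rho!r}\n")
        fh.write(f"seed={truth.seed}\n")


def read_truth(path) -> PanelTruth:
    fields: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            fields[key] = value
    return PanelTruth(
        target_gene=fields["target_gene"],
        cis_marker=fields["cis_marker"],
        cis_effect=float(fields["cis_effect"]),
        true_h2=float(fields["true_h2"]),
        treatment_effect=float(fields["treatment_effect"]),
        module_genes=[g for g in fields.get("module_genes", "").split(",") if g],
        module_rho=float(fields.get("module_rho", 0.0)),
        seed=int(fields.get("seed", 0)),
    )


def read_snp_table(path) -> pd.DataFrame:
    """Parse a printed SNP annotation table (variants between B6 and D2).

    Expected tab-separated columns: snp_id, chromosome, position_Mb,
    alleles, gene, exon, function, b6_allele, d2_allele.  ``function``
    distinguishes synonymous from nonsynonymous coding variants.
    """
    table = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = {"snp_id", "chromosome", "position_Mb", "function"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"SNP table lacks columns: {sorted(missing)}")
    return table.set_index("snp_id")


def load_cd14_snps() -> pd.DataFrame:
    """The published Cd14 coding SNPs between the B6 and D2 parental strains."""
    with resources.as_file(resources.files("riqtl.data") / "cd14_snps.tsv") as p:
        return read_snp_table(p)
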