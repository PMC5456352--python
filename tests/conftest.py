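import numpy as np
import pandas as pd
import pytest

from riqtl import (
    ExpressionMatrix,
    PanelTruth,
    simulate_expression,
    simulate_literature_similarity,
    simulate_marker_map,
    simulate_ri_genotypes,
)


def make_expression(strain_samples: dict[str, list[float]], gene: str = "g1",
                    treatment: str = "none") -> ExpressionMatrix:
    """One-gene ExpressionMatrix from {strain: [replicate values]}."""
    data = {}
    rows = []
    for strain, values in strain_samples.items():
        for rep, v in enumerate(values, start=1):
            sid = f"{strain}_{rep}"
            data[sid] = [float(v)]
            rows.append({"sample_id": sid, "strain": strain,
                         "treatment": treatment, "replicate": rep})
    return ExpressionMatrix(
        values=pd.DataFrame(data, index=[gene]),
        samples=pd.DataFrame(rows).set_index("sample_id"),
    )


@pytest.fixture(scope="session")
def small_panel():
    """30-strain, 5-chromosome panel with a planted cis target."""
    marker_map = simulate_marker_map(5, 9, 80.0, 2.0, seed=11)
    genotypes = simulate_ri_genotypes(marker_map, 30, seed=12)
    chrom3 = marker_map.table[marker_map.table["chromosome"] == "3"]
    truth = PanelTruth(
        target_gene="target",
        cis_marker=chrom3.index[4],
        cis_effect=1.0,
        true_h2=0.75,
        treatment_effect=-0.25,
        seed=13,
    )
    expr, truth = simulate_expression(
        genotypes, truth, n_replicates_per_strain_per_group=1,
        n_background_genes=20, residual_sd=0.25,
    )
    return marker_map, genotypes, truth, expr


@pytest.fixture(scope="session")
def planted_module_panel():
    """60-strain panel with a 10-gene co-expression module (rho = 0.9),
    200 background genes, and a matching literature-similarity block."""
    marker_map = simulate_marker_map(5, 9, 80.0, 2.0, seed=21)
    genotypes = simulate_ri_genotypes(marker_map, 60, seed=22)
    chrom3 = marker_map.table[marker_map.table["chromosome"] == "3"]
    module = [f"mod{i:02d}" for i in range(1, 11)]
    truth = PanelTruth(
        target_gene="target",
        cis_marker=chrom3.index[4],
        cis_effect=0.5,
        true_h2=0.6,
        treatment_effect=0.0,
        module_genes=module,
        module_rho=0.9,
        seed=23,
    )
    expr, truth = simulate_expression(
        genotypes, truth, n_replicates_per_strain_per_group=2,
        n_background_genes=200, residual_sd=0.25, groups=("none",),
    )
    similarity = simulate_literature_similarity(
        expr.genes, [["target", *module]],
        within_block_cosine=0.9, background_cosine=0.1, noise_sd=0.05, seed=24,
    )
    return marker_map, genotypes, truth, expr, similarity
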