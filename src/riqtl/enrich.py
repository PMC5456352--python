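"""Gene-set over-representation and literature-cohesion networks.

Over-representation uses the upper hypergeometric tail: with a universe
of N genes of which K belong to a category, and a query of n genes of
which k hit the category, raw_p = P(X >= k) for X ~
Hypergeometric(N, K, n).  Raw p-values are adjusted across categories
with the Benjamini–Hochberg step-up procedure; adjusted p < 0.05 flags
a category as significantly over-represented.

The cohesion network connects genes whose literature cosine similarity
strictly exceeds a threshold (0.6 by default).  Functional cohesion of
a gene set is tested with a one-sided Fisher's exact test on the 2x2
table of above-/below-threshold pairs in the set versus a background
gene set; the resulting probability is the "literature p-value" of the
network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .panel import LiteratureSimilarity

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "CohesionNetwork",
    "read_gmt",
    "write_gmt",
    "hypergeometric_enrichment",
    "bh_adjust",
    "fisher_exact_2x2",
    "build_cohesion_network",
    "cohesion_fisher_p",
]

logger = logging.getLogger(__name__)

COSINE_THRESHOLD = 0.6


@dataclass
class GeneSetCollection:
    """Named gene sets with an annotation universe."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = frozenset().union(*self.sets.values()) if self.sets else frozenset()
        for name, members in self.sets.items():
            if not members <= self.universe:
                raise ValueError(f"set {name!r} has members outside the universe")


@dataclass
class EnrichmentResult:
    category: str
    k: int
    K: int
    n: int
    N: int
    raw_p: float
    adj_p: float = float("nan")

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n):
            raise ValueError("overlap cannot exceed category or query size")


@dataclass
class CohesionNetwork:
    """Thresholded literature-similarity graph with a cohesion p-value."""

    graph: nx.Graph
    threshold: float
    literature_p: float = float("nan")
    background_pairs: tuple[int, int] = (0, 0)  # (above, at-or-below)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(a, b, d["cosine"]) for a, b, d in self.graph.edges(data=True)]

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["gene_a", "gene_b", "cosine"])


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name <tab> description <tab> member genes...)."""
    sets: dict[str, frozenset[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: GMT line needs name, description, members")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{line_no}: duplicate set name {name!r}")
            sets[name] = frozenset(g for g in parts[2:] if g)
            desc[name] = parts[1]
    return GeneSetCollection(sets=sets, descriptions=desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, original order preserved.

    adj_i = min_{j >= i} p_(j) * m / j over the ascending order, capped
    at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def hypergeometric_enrichment(
    query,
    collection: GeneSetCollection,
    background=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation over all categories.

    Query genes outside the universe are logged and dropped.  Results
    come back sorted by adjusted p with a ``significant`` flag at
    ``adj_p < alpha``.
    """
    universe = frozenset(background) if background is not None else collection.universe
    if not universe:
        raise ValueError("empty annotation universe")
    query_set = set(query)
    outside = sorted(query_set - universe)
    if outside:
        logger.info("query genes outside the universe dropped: %s", outside)
        query_set -= set(outside)
    if not query_set:
        raise ValueError("query is empty after restricting to the universe")
    N = len(universe)
    n = len(query_set)
    rows = []
    for name, members in collection.sets.items():
        members = members & universe
        K = len(members)
        if K == 0:
            continue
        k = len(query_set & members)
        raw_p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"category": name, "k": k, "K": K, "n": n, "N": N, "raw_p": raw_p})
    result = pd.DataFrame(rows).set_index("category")
    result["adj_p"] = bh_adjust(result["raw_p"].to_numpy())
    result["significant"] = result["adj_p"] < alpha
    return result.sort_values(["adj_p", "raw_p"])


def fisher_exact_2x2(table) -> tuple[float, float, float]:
    """Fisher's exact test on a 2x2 table.

    Returns (odds_ratio, one-sided p for enrichment of the [0,0] cell,
    two-sided p by summing tables at most as probable as observed).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer) and np.any(t != np.floor(t)):
        raise ValueError("counts must be non-negative integers")
    t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("degenerate table: a margin is zero")
    odds, p_two = stats.fisher_exact(t, alternative="two-sided")
    _, p_one = stats.fisher_exact(t, alternative="greater")
    return float(odds), float(p_one), float(p_two)


def build_cohesion_network(
    genes,
    similarity: LiteratureSimilarity,
    threshold: float = COSINE_THRESHOLD,
) -> CohesionNetwork:
    """Graph on ``genes`` with an edge for every pair of cosine > threshold.

    Isolated genes stay in the node set.
    """
    genes = list(genes)
    unknown = sorted(set(genes) - set(similarity.genes))
    if unknown:
        raise ValueError(f"genes absent from the similarity matrix: {unknown}")
    g = nx.Graph()
    g.add_nodes_from(genes)
    for a, b in combinations(genes, 2):
        cos = similarity.value(a, b)
        if cos > threshold:
            g.add_edge(a, b, cosine=cos)
    return CohesionNetwork(graph=g, threshold=threshold)


def _pair_counts(genes, similarity: LiteratureSimilarity, threshold: float) -> tuple[int, int]:
    above = below = 0
    for a, b in combinations(genes, 2):
        if similarity.value(a, b) > threshold:
            above += 1
        else:
            below += 1
    return above, below


def cohesion_fisher_p(
    network: CohesionNetwork,
    similarity: LiteratureSimilarity,
    background_genes=None,
) -> float:
    """One-sided Fisher's exact cohesion p-value of the network's gene set.

    The 2x2 table compares above-/at-or-below-threshold pair counts in
    the set against a background gene set (all similarity-matrix genes
    not in the set, by default).  Small p means the set is more
    literature-cohesive than background, the "literature p-value" of
    the network.  The value is stored on the network and returned.
    """
    set_genes = network.nodes
    if background_genes is None:
        background_genes = [g for g in similarity.genes if g not in set(set_genes)]
    background_genes = list(background_genes)
    if len(set_genes) < 2 or len(background_genes) < 2:
        raise ValueError("both the set and the background need at least 2 genes")
    set_above, set_below = _pair_counts(set_genes, similarity, network.threshold)
    bg_above, bg_below = _pair_counts(background_genes, similarity, network.threshold)
    table = np.array([[set_above, set_below], [bg_above, bg_below]])
    if table.sum(axis=1).min() == 0:
        raise ValueError("degenerate cohesion table: a gene set yields zero pairs")
    _, p_one, _ = fisher_exact_2x2(table)
    network.literature_p = p_one
    network.background_pairs = (bg_above, bg_below)
    return p_one
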