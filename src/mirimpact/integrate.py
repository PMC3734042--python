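"""Cross-referencing miRNA targets with differentially expressed genes.

The integration step asks which differentially expressed genes are plausibly
under miRNA control: a gene qualifies when it is DE *and* is a predicted
target (union over the prediction sources) of at least one DE miRNA.  The
integrated table can then be annotated with immune-ontology membership,
ranked into top-increased/top-decreased tables, tested for functional-module
over-representation (hypergeometric), and rendered as a bipartite
miRNA-gene graph whose node colors encode the direction of expression
change.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .io import GeneSetCollection, TargetMap

__all__ = [
    "ModuleEnrichmentResult",
    "cross_reference",
    "classify_immune",
    "top_tables",
    "module_enrichment",
    "build_graph",
    "write_integrated_table",
    "write_graph",
]


@dataclass(frozen=True)
class ModuleEnrichmentResult:
    term_id: str
    term_name: str
    overlap: int  # x: query genes in the module
    set_size: int  # K: module genes in the universe
    query_size: int  # n
    universe_size: int  # N
    p_hypergeometric: float
    enriched: bool


def cross_reference(
    de_genes: Iterable[str],
    de_mirnas: Iterable[str],
    maps: Sequence[TargetMap],
    gene_annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Integrated gene table: DE genes targeted by >=1 DE miRNA.

    Target sets are unioned over all prediction maps, so a miRNA covered by
    only one source still contributes.  Returns a DataFrame indexed by
    gene_id with a ``regulating_mirnas`` column of frozensets plus
    ``fold_change``/``q_value`` copied from ``gene_annotations`` (a DE table
    indexed by feature) when provided.  The operation is idempotent and
    independent of the order of the map list.
    """
    de_genes = set(de_genes)
    de_mirnas = set(de_mirnas)
    if not de_genes or not de_mirnas:
        raise InputError("DE gene and DE miRNA sets must be non-empty")
    regulating: dict[str, set[str]] = {}
    for mirna in sorted(de_mirnas):
        targets: set[str] = set()
        for tmap in maps:
            targets |= set(tmap.sets.get(mirna, frozenset()))
        for gene in targets & de_genes:
            regulating.setdefault(gene, set()).add(mirna)
    genes = sorted(regulating)
    table = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    table["regulating_mirnas"] = [frozenset(regulating[g]) for g in genes]
    table["fold_change"] = np.nan
    table["q_value"] = np.nan
    if gene_annotations is not None:
        common = table.index.intersection(gene_annotations.index)
        for col in ("fold_change", "q_value"):
            if col in gene_annotations.columns:
                table.loc[common, col] = gene_annotations.loc[common, col]
    table["is_immune"] = False
    return table


def classify_immune(table: pd.DataFrame, immune_terms: GeneSetCollection) -> pd.DataFrame:
    """Flag integrated genes belonging to any immune-ontology term."""
    if not immune_terms.sets:
        raise InputError("immune annotation is empty")
    immune_genes = immune_terms.union()
    out = table.copy()
    out["is_immune"] = [g in immune_genes for g in out.index]
    return out


def top_tables(table: pd.DataFrame, n: int = 25) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top ``n`` increased (fold change > 1) and decreased (< 1) genes.

    Genes at fold change exactly 1 appear in neither list.  Ties break by
    q-value then gene ID, so the ranking is fully deterministic.
    """
    t = table.reset_index().rename(columns={table.index.name or "index": "gene_id"})
    up = t[t["fold_change"] > 1].sort_values(
        ["fold_change", "q_value", "gene_id"], ascending=[False, True, True]
    )
    down = t[t["fold_change"] < 1].sort_values(
        ["fold_change", "q_value", "gene_id"], ascending=[True, True, True]
    )
    return up.head(n).set_index("gene_id"), down.head(n).set_index("gene_id")


def module_enrichment(
    query: Iterable[str],
    modules: GeneSetCollection,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> list[ModuleEnrichmentResult]:
    """Hypergeometric over-representation of the query in each module.

    p = P(X >= x) for X ~ Hypergeometric(N, K, n) with N the universe size,
    K the module size within the universe, n the query size, and x the
    observed overlap.  Modules with no gene in the universe are skipped.
    """
    universe = set(universe)
    query = set(query)
    if not query.issubset(universe):
        raise InputError("query must be a subset of the universe")
    n = len(query)
    N = len(universe)
    out: list[ModuleEnrichmentResult] = []
    for term_id, (term_name, members) in modules.sets.items():
        members_u = members & universe
        K = len(members_u)
        if K == 0:
            continue
        x = len(members_u & query)
        p = float(np.clip(stats.hypergeom.sf(x - 1, N, K, n), np.finfo(float).tiny, 1.0))
        out.append(
            ModuleEnrichmentResult(term_id, term_name, x, K, n, N, p, enriched=p < alpha)
        )
    return out


def _direction(fold_change: float) -> str:
    return "increased" if fold_change > 1 else "decreased"


def build_graph(
    table: pd.DataFrame,
    mirna_de: pd.DataFrame,
    gene_de: pd.DataFrame | None = None,
    immune_only: bool = False,
) -> nx.Graph:
    """Bipartite miRNA-gene graph of the integrated regulatory relations.

    Square/circle rendering is presentational; here nodes carry ``kind``
    ('mirna'/'gene') and ``direction`` ('increased'/'decreased', by fold
    change vs 1) attributes.  Only miRNAs with at least one edge appear.
    """
    if immune_only and "is_immune" in table.columns:
        table = table[table["is_immune"]]
    g = nx.Graph()
    for gene, row in table.iterrows():
        fc = row["fold_change"]
        if gene_de is not None and gene in gene_de.index:
            fc = gene_de.loc[gene, "fold_change"]
        g.add_node(gene, kind="gene", direction=_direction(float(fc)), bipartite=1)
        for mirna in sorted(row["regulating_mirnas"]):
            if mirna not in g:
                m_fc = float(mirna_de.loc[mirna, "fold_change"]) if mirna in mirna_de.index else 1.0
                g.add_node(mirna, kind="mirna", direction=_direction(m_fc), bipartite=0)
            g.add_edge(mirna, gene)
    return g


def write_integrated_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out["regulating_mirnas"] = [";".join(sorted(s)) for s in out["regulating_mirnas"]]
    out.to_csv(path, sep="\t", index_label="gene_id")


def write_graph(g: nx.Graph, edges_path: str | Path, nodes_path: str | Path) -> None:
    """Edge-list TSV plus a node-attribute TSV (GraphML-compatible keys)."""
    with open(edges_path, "w") as fh:
        fh.write("mirna_id\tgene_id\n")
        for u, v in sorted(g.edges()):
            mirna, gene = (u, v) if g.nodes[u]["kind"] == "mirna" else (v, u)
            fh.write(f"{mirna}\t{gene}\n")
    with open(nodes_path, "w") as fh:
        fh.write("node\tkind\tdirection\n")
        for node in sorted(g.nodes()):
            attrs = g.nodes[node]
            fh.write(f"{node}\t{attrs['kind']}\t{attrs['direction']}\n")
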