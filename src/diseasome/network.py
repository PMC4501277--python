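"""Bipartite and tripartite network construction and projection.

The disease-gene map defines a bipartite network (disease codes vs gene
symbols); joining it with gene-pathway memberships yields the tripartite
code-gene-pathway network.  Projecting either onto diseases links two
codes whenever they share at least one element (gene or pathway), the
shared set becoming the edge weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence, Union

import networkx as nx
import pandas as pd

from .errors import ContractViolationError
from .model import (
    DiseaseGeneAssociation,
    DiseasePair,
    ElementProfile,
    GenePathwayAssociation,
    GeneSymbol,
    IcdCode,
    TripartiteTriple,
)


@dataclass(frozen=True)
class BipartiteNetwork:
    """The disease-gene bipartite network (codes on one side, genes on the other)."""

    disease_nodes: frozenset[IcdCode]
    gene_nodes: frozenset[GeneSymbol]
    edges: frozenset[DiseaseGeneAssociation]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for code in sorted(self.disease_nodes):
            g.add_node(str(code), node_type="disease", bipartite=0)
        for gene in sorted(self.gene_nodes):
            g.add_node(str(gene), node_type="gene", bipartite=1)
        for code, gene in sorted(self.edges):
            g.add_edge(str(code), str(gene))
        return g


def build_bipartite(assocs: Sequence[DiseaseGeneAssociation]) -> BipartiteNetwork:
    """Build the bipartite network; node sets are the distinct edge endpoints."""
    edges = frozenset(assocs)
    return BipartiteNetwork(
        disease_nodes=frozenset(e.code for e in edges),
        gene_nodes=frozenset(e.gene for e in edges),
        edges=edges,
    )


def disease_profiles(net: BipartiteNetwork) -> list[ElementProfile]:
    """One gene-mode profile per disease node (its adjacent gene set)."""
    by_code: dict[IcdCode, set] = {}
    for code, gene in net.edges:
        by_code.setdefault(code, set()).add(gene)
    return [
        ElementProfile(entity=code, elements=frozenset(genes), mode="gene")
        for code, genes in sorted(by_code.items())
    ]


def build_tripartite(
    dg: Sequence[DiseaseGeneAssociation],
    gp: Sequence[GenePathwayAssociation],
) -> list[TripartiteTriple]:
    """Join the two edge sets on genes: {(c,g,p) : (c,g) in dg and (g,p) in gp}.

    Genes lacking either side contribute nothing; in particular genes with
    pathway memberships but no phenotype-causing mutation never enter the
    tripartite network.
    """
    paths_by_gene: dict[GeneSymbol, list] = {}
    for gene, pathway in set(gp):
        paths_by_gene.setdefault(gene, []).append(pathway)
    triples = [
        TripartiteTriple(code, gene, pathway)
        for code, gene in set(dg)
        for pathway in paths_by_gene.get(gene, ())
    ]
    return sorted(triples)


def disease_pathway_profiles(triples: Sequence[TripartiteTriple]) -> list[ElementProfile]:
    """One pathway-mode profile per code: the union of pathways over its triples."""
    by_code: dict[IcdCode, set] = {}
    for code, _gene, pathway in triples:
        by_code.setdefault(code, set()).add(pathway)
    return [
        ElementProfile(entity=code, elements=frozenset(paths), mode="pathway")
        for code, paths in sorted(by_code.items())
    ]


def project_disease_pairs(profiles: Sequence[ElementProfile]) -> list[DiseasePair]:
    """All unordered disease pairs with a non-empty element intersection.

    Uses an inverted element->diseases index so that sparse overlap scales
    with the number of co-memberships, not with all C(n,2) pairs.
    """
    modes = {p.mode for p in profiles}
    if len(modes) > 1:
        raise ContractViolationError(f"mixed profile modes {sorted(modes)}")
    mode = modes.pop() if modes else "gene"
    entities = [p.entity for p in profiles]
    if len(set(entities)) != len(entities):
        raise ContractViolationError("duplicate entities among profiles")

    diseases_by_element: dict[object, list] = {}
    for prof in profiles:
        for el in prof.elements:
            diseases_by_element.setdefault(el, []).append(prof.entity)

    shared: dict[tuple, set] = {}
    for el, codes in diseases_by_element.items():
        for x, y in combinations(sorted(codes), 2):
            shared.setdefault((x, y), set()).add(el)

    return [
        DiseasePair(x=x, y=y, shared=frozenset(els), mode=mode)
        for (x, y), els in sorted(shared.items())
    ]


def export_network(
    net: Union[BipartiteNetwork, Sequence[DiseasePair]],
    path: Union[str, Path],
    format: str = "edge_list_tsv",
) -> None:
    """Write a network as a TSV edge list or GraphML.

    Bipartite edge lists carry a ``node_types`` column ("disease|gene");
    projections carry a ``weight`` column equal to the shared-element
    count.  Output is UTF-8, LF line endings, deterministically sorted.
    """
    if format not in ("edge_list_tsv", "graphml"):
        raise ValueError(f"unknown export format {format!r}")
    path = Path(path)
    if isinstance(net, BipartiteNetwork):
        if format == "edge_list_tsv":
            rows = sorted((str(c), str(g)) for c, g in net.edges)
            df = pd.DataFrame(rows, columns=["source", "target"])
            df["node_types"] = "disease|gene"
            df.to_csv(path, sep="\t", index=False, lineterminator="\n")
        else:
            nx.write_graphml(net.to_networkx(), path)
    else:
        pairs = list(net)
        if format == "edge_list_tsv":
            rows = sorted((str(p.x), str(p.y), len(p.shared)) for p in pairs)
            df = pd.DataFrame(rows, columns=["source", "target", "weight"])
            df.to_csv(path, sep="\t", index=False, lineterminator="\n")
        else:
            g = nx.Graph()
            nodes = sorted({str(p.x) for p in pairs} | {str(p.y) for p in pairs})
            for n in nodes:
                g.add_node(n, node_type="disease")
            for p in sorted(pairs, key=lambda p: (p.x, p.y)):
                g.add_edge(str(p.x), str(p.y), weight=len(p.shared))
            nx.write_graphml(g, path)
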