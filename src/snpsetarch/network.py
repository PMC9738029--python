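"""Genotypic network: retained SNP sets linked by shared SNPs.

Edges carry the hypergeometric upper-tail p of the shared-SNP count
(universe = pooled panel size) and are thresholded by Bonferroni over all
unordered pairs; edge weight is the SNP-Jaccard coefficient.  Connected
components partition the nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import pandas as pd

from .architecture import hypergeom_overlap, jaccard
from .nsnmf import SNPSet

logger = logging.getLogger(__name__)


@dataclass
class GenotypicNetwork:
    graph: nx.Graph = field(repr=False)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, dict]]:
        return [(a, b, dict(d)) for a, b, d in self.graph.edges(data=True)]

    @property
    def components(self) -> list[frozenset[str]]:
        comps = [frozenset(c) for c in nx.connected_components(self.graph)]
        return sorted(comps, key=lambda c: sorted(c)[0])

    def component_of(self) -> dict[str, int]:
        return {node: idx for idx, comp in enumerate(self.components)
                for node in comp}


def build_genotypic_network(sets: list[SNPSet], panel_size: int,
                            alpha: float = 0.05) -> GenotypicNetwork:
    """Pairwise shared-SNP hypergeometric tests over the retained sets."""
    if not sets:
        raise ValueError("need at least one retained set")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate set labels")
    g = nx.Graph()
    for s in sets:
        g.add_node(s.label, n_snps=len(s.snp_ids),
                   n_subjects=len(s.subject_ids))
    pairs = list(combinations(sets, 2))
    thresh = alpha / len(pairs) if pairs else alpha
    for a, b in pairs:
        shared, p = hypergeom_overlap(a.snp_ids, b.snp_ids, panel_size)
        if shared > 0 and p < thresh:
            g.add_edge(a.label, b.label, shared_snps=shared,
                       p=p, jaccard=jaccard(a.snp_ids, b.snp_ids),
                       shared_snp_ids=",".join(
                           sorted(set(a.snp_ids) & set(b.snp_ids))))
    net = GenotypicNetwork(g)
    logger.info("network: %d nodes, %d edges, %d components",
                g.number_of_nodes(), g.number_of_edges(),
                len(net.components))
    return net


def export_graph(net: GenotypicNetwork, path, format: str = "graphml") -> None:
    """Write the network as GraphML or an edge-list TSV.

    Both carry nodes, edges, weights and component ids and round-trip
    losslessly through the matching reader.
    """
    comp = net.component_of()
    g = net.graph.copy()
    nx.set_node_attributes(g, comp, "component")
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "edge_tsv":
        rows = [{
            "set_a": a, "set_b": b, "shared_snps": d["shared_snps"],
            "p": repr(d["p"]), "jaccard": repr(d["jaccard"]),
            "component": comp[a], "shared_snp_ids": d["shared_snp_ids"],
        } for a, b, d in g.edges(data=True)]
        edge_df = pd.DataFrame(rows, columns=["set_a", "set_b", "shared_snps",
                                              "p", "jaccard", "component",
                                              "shared_snp_ids"])
        node_df = pd.DataFrame([{
            "node": n, "n_snps": d["n_snps"], "n_subjects": d["n_subjects"],
            "component": comp[n],
        } for n, d in g.nodes(data=True)])
        with open(path, "w") as fh:
            fh.write("#nodes\n")
            node_df.to_csv(fh, sep="\t", index=False)
            fh.write("#edges\n")
            edge_df.to_csv(fh, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format {format!r}")


def read_graph(path, format: str = "graphml") -> GenotypicNetwork:
    if format == "graphml":
        g = nx.read_graphml(path)
        return GenotypicNetwork(nx.Graph(g))
    if format == "edge_tsv":
        with open(path) as fh:
            text = fh.read()
        node_part = text.split("#nodes\n")[1].split("#edges\n")[0]
        edge_part = text.split("#edges\n")[1]
        from io import StringIO
        nodes = pd.read_csv(StringIO(node_part), sep="\t")
        g = nx.Graph()
        for r in nodes.itertuples():
            g.add_node(r.node, n_snps=int(r.n_snps),
                       n_subjects=int(r.n_subjects))
        if edge_part.strip():
            edges = pd.read_csv(StringIO(edge_part), sep="\t")
            for r in edges.itertuples():
                g.add_edge(r.set_a, r.set_b, shared_snps=int(r.shared_snps),
                           p=float(r.p), jaccard=float(r.jaccard),
                           shared_snp_ids=str(r.shared_snp_ids))
        return GenotypicNetwork(g)
    raise ValueError(f"unknown import format {format!r}")
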