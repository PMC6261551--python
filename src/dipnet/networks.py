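"""Interaction-network maps induced from filtered gene lists.

A map is the subgraph of a scored protein-interaction edge list induced by a
gene list; genes with no retained interaction remain as singleton nodes.
lincRNA associations are overlaid as typed links to in-map targets and never
contribute to protein connectivity.  Comparing the map induced by an
unconstrained gene list with the map induced by a thresholded subset shows
how constraints dissolve connectivity: edge/node retention fractions,
component and singleton deltas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

OVERLAY_KIND = "overlay"


@dataclass
class NetworkMap:
    graph: nx.Graph
    label: str = "unconstrained"
    ncrna_overlays: list[tuple[str, str]] = field(default_factory=list)

    @property
    def gene_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True)
                if d.get("kind", "gene") == "gene"}

    def interaction_edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted((a, b))) for a, b, d in self.graph.edges(data=True)
                if d.get("kind", "interaction") != OVERLAY_KIND}


@dataclass(frozen=True)
class ConnectivitySummary:
    n_nodes: int
    n_edges: int
    n_components: int
    n_singletons: int
    degree_histogram: dict[int, int]
    largest_component: int

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["degree_histogram"] = {str(k): v for k, v in self.degree_histogram.items()}
        return d


def validate_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Reject self-loops and duplicate unordered pairs, naming the row."""
    for col in ("node_a", "node_b"):
        if col not in edges.columns:
            raise ValueError(f"edge table missing column {col!r}")
    seen: dict[tuple[str, str], int] = {}
    for i, (a, b) in enumerate(zip(edges["node_a"], edges["node_b"])):
        if a == b:
            raise ValueError(f"self-loop ({a},{b}) at edge row {i + 1}")
        key = tuple(sorted((str(a), str(b))))
        if key in seen:
            raise ValueError(
                f"duplicate pair {key} at edge row {i + 1} "
                f"(first seen at row {seen[key] + 1})")
        seen[key] = i
    return edges


def induce_map(gene_list, edges: pd.DataFrame, min_score: float = 0.0,
               label: str = "unconstrained") -> NetworkMap:
    """Subgraph on ``gene_list``: all listed genes as nodes (singletons kept),
    edges with both endpoints in the list and score >= min_score."""
    validate_edges(edges)
    genes = set(gene_list)
    g = nx.Graph()
    g.add_nodes_from(sorted(genes), kind="gene")
    score = edges["score"] if "score" in edges.columns else pd.Series(
        [1.0] * len(edges))
    for a, b, s in zip(edges["node_a"], edges["node_b"], score):
        if a in genes and b in genes and float(s) >= min_score:
            g.add_edge(a, b, score=float(s), kind="interaction")
    return NetworkMap(graph=g, label=label)


def overlay_ncrna(net_map: NetworkMap, target_assignments: pd.DataFrame,
                  window_mb: int = 1) -> NetworkMap:
    """Attach ncRNA nodes to their window-qualified targets present in the map.

    ``target_assignments`` is the target-assignment table (ncrna_id,
    target_gene_id, window_mb, ...).  ncRNAs whose targets are all absent
    from the map are not added; overlay links are typed and excluded from
    protein connectivity.
    """
    g = net_map.graph
    genes = net_map.gene_nodes
    rows = target_assignments.loc[target_assignments["window_mb"] == window_mb]
    overlays = list(net_map.ncrna_overlays)
    for nc, tg in zip(rows["ncrna_id"], rows["target_gene_id"]):
        if tg in genes:
            if nc not in g:
                g.add_node(nc, kind="ncrna")
            g.add_edge(nc, tg, kind=OVERLAY_KIND)
            overlays.append((nc, tg))
    return NetworkMap(graph=g, label=net_map.label, ncrna_overlays=overlays)


def summarize(net_map: NetworkMap) -> ConnectivitySummary:
    """Connectivity accounting over gene nodes and interaction edges only."""
    sub = nx.Graph()
    sub.add_nodes_from(net_map.gene_nodes)
    sub.add_edges_from(net_map.interaction_edges())
    comps = list(nx.connected_components(sub)) if sub.number_of_nodes() else []
    degrees = [d for _, d in sub.degree()]
    hist: dict[int, int] = {}
    for d in degrees:
        hist[d] = hist.get(d, 0) + 1
    return ConnectivitySummary(
        n_nodes=sub.number_of_nodes(),
        n_edges=sub.number_of_edges(),
        n_components=len(comps),
        n_singletons=sum(1 for c in comps if len(c) == 1),
        degree_histogram=dict(sorted(hist.items())),
        largest_component=max((len(c) for c in comps), default=0),
    )


def compare_maps(unconstrained: NetworkMap, constrained: NetworkMap) -> dict:
    """Retention report for a thresholded map against its parent map.

    Requires constrained nodes/edges to be subsets of the unconstrained ones
    (a filter must only remove).
    """
    un_nodes, con_nodes = unconstrained.gene_nodes, constrained.gene_nodes
    if not con_nodes <= un_nodes:
        raise ValueError("constrained map contains genes absent from the "
                         f"unconstrained map: {sorted(con_nodes - un_nodes)[:5]}")
    un_edges, con_edges = unconstrained.interaction_edges(), constrained.interaction_edges()
    if not con_edges <= un_edges:
        raise ValueError("constrained map contains edges absent from the "
                         "unconstrained map")
    s_un, s_con = summarize(unconstrained), summarize(constrained)
    return {
        "node_retention": len(con_nodes) / len(un_nodes) if un_nodes else 1.0,
        "edge_retention": len(con_edges) / len(un_edges) if un_edges else 1.0,
        "singleton_delta": s_con.n_singletons - s_un.n_singletons,
        "component_delta": s_con.n_components - s_un.n_components,
        "summary_unconstrained": s_un.to_dict(),
        "summary_constrained": s_con.to_dict(),
    }
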