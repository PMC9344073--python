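"""Topological characterization of a regulatory network.

Degree statistics, clustering coefficients (on the underlying
undirected simple graph), hub calling over the TF out-degree
distribution, and co-regulation modules from common-neighbor
similarity: two regulators are similar when their regulons overlap
(Jaccard of out-neighborhoods), two targets when their regulator sets
overlap (in-neighborhoods).  Modules are the connected components of
the thresholded similarity graph (single linkage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np

from grntransfer.annotation_io import GRN
from grntransfer.errors import UnknownGeneError, UsageError


@dataclass
class TopologyReport:
    """Per-node metrics plus hub and module calls for one GRN."""

    organism: str
    in_degree: dict[str, int]
    out_degree: dict[str, int]
    total_degree: dict[str, int]
    clustering: dict[str, float]
    hubs: set[str]
    modules: list[set[str]] = field(default_factory=list)
    singletons: set[str] = field(default_factory=set)


def degree_stats(grn: GRN) -> dict[str, tuple[int, int, int]]:
    """Per-node (in, out, total) degree; a self-loop counts once in each."""
    g = grn.to_networkx()
    return {
        n: (g.in_degree(n), g.out_degree(n), g.in_degree(n) + g.out_degree(n))
        for n in g.nodes
    }


def clustering_coefficient(grn: GRN, node: str) -> float:
    """Clustering on the underlying undirected simple graph.

    2 * triangles(node) / (k * (k - 1)); 0 for degree < 2.
    """
    g = grn.to_networkx()
    if node not in g:
        raise UnknownGeneError(f"{node!r} not in network")
    und = nx.Graph(g)
    und.remove_edges_from(nx.selfloop_edges(und))
    return nx.clustering(und, node)


def find_hubs(
    grn: GRN, method: str = "top_fraction", param: float = 0.05
) -> set[str]:
    """Call hub TFs from the out-degree distribution.

    ``top_fraction``: the TFs in the top ``param`` fraction by
    out-degree, ties at the cutoff included (at least one hub).
    ``degree_threshold``: TFs with out-degree >= mean + param * sd
    over all TFs.
    """
    tfs = sorted(grn.tfs)
    if not tfs:
        raise UsageError("network has no TFs")
    g = grn.to_networkx()
    out = {tf: g.out_degree(tf) for tf in tfs}
    if method == "top_fraction":
        if not 0 < param <= 1:
            raise UsageError("top_fraction param must be in (0, 1]")
        ranked = sorted(tfs, key=lambda t: (-out[t], t))
        k = max(1, int(np.ceil(param * len(tfs))))
        cutoff = out[ranked[k - 1]]
        return {tf for tf in tfs if out[tf] >= cutoff}
    if method == "degree_threshold":
        if param < 0:
            raise UsageError("degree_threshold param must be >= 0")
        degs = np.array([out[tf] for tf in tfs], dtype=float)
        threshold = degs.mean() + param * degs.std()
        return {tf for tf in tfs if out[tf] >= threshold}
    raise UsageError(f"unknown hub method {method!r}")


def coregulation_similarity(
    grn: GRN, g1: str, g2: str, mode: str = "count", neighborhood: str = "out"
) -> float:
    """Common-neighbor similarity between two genes.

    ``neighborhood="out"`` compares regulons (for regulator pairs),
    ``"in"`` compares regulator sets (for target pairs).  ``count``
    returns |N(g1) ∩ N(g2)|; ``jaccard`` divides by the union size
    (0 when the union is empty).
    """
    g = grn.to_networkx()
    for gene in (g1, g2):
        if gene not in g:
            raise UnknownGeneError(f"{gene!r} not in network")
    if neighborhood == "out":
        n1, n2 = set(g.successors(g1)), set(g.successors(g2))
    elif neighborhood == "in":
        n1, n2 = set(g.predecessors(g1)), set(g.predecessors(g2))
    else:
        raise UsageError(f"unknown neighborhood {neighborhood!r}")
    inter = len(n1 & n2)
    if mode == "count":
        return float(inter)
    if mode == "jaccard":
        union = len(n1 | n2)
        return inter / union if union else 0.0
    raise UsageError(f"unknown similarity mode {mode!r}")


def find_modules(
    grn: GRN,
    similarity_threshold: float = 0.5,
    neighborhood: str = "out",
) -> tuple[list[set[str]], set[str]]:
    """Partition regulators into co-regulation modules.

    Builds the regulator-pair graph with an edge wherever the Jaccard
    regulon similarity reaches ``similarity_threshold`` and returns
    its connected components of size >= 2 (sorted largest first) plus
    the singleton regulators.
    """
    if not 0 <= similarity_threshold <= 1:
        raise UsageError("similarity_threshold must be in [0, 1]")
    tfs = sorted(grn.tfs)
    if not tfs:
        raise UsageError("network has no TFs")
    sim = nx.Graph()
    sim.add_nodes_from(tfs)
    for i, t1 in enumerate(tfs):
        for t2 in tfs[i + 1 :]:
            s = coregulation_similarity(grn, t1, t2, "jaccard", neighborhood)
            if s >= similarity_threshold and s > 0:
                sim.add_edge(t1, t2)
    components = [set(c) for c in nx.connected_components(sim)]
    modules = sorted(
        (c for c in components if len(c) >= 2), key=lambda c: (-len(c), sorted(c))
    )
    singletons = set().union(*(c for c in components if len(c) == 1)) if any(
        len(c) == 1 for c in components
    ) else set()
    return modules, singletons


def topology_report(
    grn: GRN,
    hub_method: str = "top_fraction",
    hub_param: float = 0.05,
    similarity_threshold: float = 0.5,
) -> TopologyReport:
    """Full per-node topology report for one network."""
    g = grn.to_networkx()
    und = nx.Graph(g)
    und.remove_edges_from(nx.selfloop_edges(und))
    clustering = nx.clustering(und)
    modules, singletons = find_modules(grn, similarity_threshold)
    return TopologyReport(
        organism=grn.organism,
        in_degree={n: g.in_degree(n) for n in g.nodes},
        out_degree={n: g.out_degree(n) for n in g.nodes},
        total_degree={n: g.in_degree(n) + g.out_degree(n) for n in g.nodes},
        clustering=dict(clustering),
        hubs=find_hubs(grn, hub_method, hub_param),
        modules=modules,
        singletons=singletons,
    )


def write_topology_report(report: TopologyReport, path: str | Path) -> None:
    """Per-node metric table: degrees, clustering, hub flag, module label."""
    module_of: dict[str, str] = {}
    for i, module in enumerate(report.modules, start=1):
        for tf in module:
            module_of[tf] = f"M{i}"
    with open(path, "w") as fh:
        fh.write("gene\tin_degree\tout_degree\ttotal_degree\t"
                 "clustering\tis_hub\tmodule\n")
        for gene in sorted(report.total_degree):
            fh.write(
                "\t".join(
                    [
                        gene,
                        str(report.in_degree[gene]),
                        str(report.out_degree[gene]),
                        str(report.total_degree[gene]),
                        f"{report.clustering.get(gene, 0.0):.4f}",
                        "yes" if gene in report.hubs else "no",
                        module_of.get(gene, "-"),
                    ]
                )
                + "\n"
            )
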