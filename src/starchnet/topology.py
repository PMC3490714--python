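"""Topology of the inferred regulatory network.

Builds an undirected, role-annotated graph from the selected edges and
provides the summaries used to interpret it: the degree distribution and
hub gene, the first-neighbor subnetwork around the starch (target) genes,
edge-type counts by the roles of the endpoints, and edge overlap between
two networks (the robustness comparison against an expanded gene set).

Clock genes are pooled with transcription factors as "regulators" for
edge typing, so the three edge types are regulator-regulator,
regulator-target, and target-target.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

from .datamodel import canonical_edge

logger = logging.getLogger(__name__)

EDGE_TYPES = ("regulator-regulator", "regulator-target", "target-target")


def build_graph(network, annotation: pd.DataFrame | None = None) -> nx.Graph:
    """Undirected signed graph from a PartialCorrelationNetwork.

    Nodes carry ``role``/``family`` attributes from the annotation table;
    edges carry pcor, q and sign.  Only genes incident to a selected edge
    (plus any annotated isolated genes already in the network node set)
    appear with their attributes; the graph is simple by construction.
    """
    roles = {}
    families = {}
    if annotation is not None:
        roles = dict(zip(annotation["gene_id"], annotation["role"]))
        families = dict(zip(annotation["gene_id"], annotation.get("family", "")))
    g = nx.Graph()
    edge_table = network.edge_table()
    nodes = sorted(set(edge_table["gene_a"]) | set(edge_table["gene_b"]))
    for gene in nodes:
        g.add_node(gene, role=roles.get(gene, ""), family=families.get(gene, ""))
    for _, row in edge_table.iterrows():
        a, b = canonical_edge(row["gene_a"], row["gene_b"])
        if a == b:
            continue
        g.add_edge(a, b, pcor=float(row["pcor"]), q=float(row["q_value"]), sign=row["sign"])
    return g


def degree_table(g: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Per-node degrees, the degree histogram, and the hub gene(s).

    The hub is the maximum-degree node; ties are broken lexicographically
    for the canonical hub but all tied nodes are returned.
    """
    if g.number_of_nodes() == 0:
        empty = pd.DataFrame(columns=["gene_id", "degree"])
        hist = pd.DataFrame(columns=["degree", "n_nodes"])
        return empty, hist, []
    rows = sorted(g.degree(), key=lambda t: t[0])
    table = pd.DataFrame(rows, columns=["gene_id", "degree"])
    hist = (
        table.groupby("degree").size().reset_index(name="n_nodes").sort_values("degree")
    ).reset_index(drop=True)
    max_deg = table["degree"].max()
    hubs = sorted(table.loc[table["degree"] == max_deg, "gene_id"])
    return table, hist, hubs


def first_neighbor_subnetwork(g: nx.Graph, seed_nodes) -> nx.Graph:
    """Induced subgraph on the seeds plus their direct neighbors.

    Missing seeds are warned about and skipped; seeds with no edges are
    retained as isolated nodes.  Idempotent when re-applied with the same
    seeds on its own output restricted to the same seed set's closure.
    """
    seeds = set(seed_nodes)
    missing = seeds - set(g.nodes)
    if missing:
        logger.warning("seed nodes not in graph, skipped: %s", ", ".join(sorted(missing)))
    seeds &= set(g.nodes)
    keep = set(seeds)
    for s in seeds:
        keep.update(g.neighbors(s))
    return g.subgraph(keep).copy()


def classify_edges(g: nx.Graph, annotation: pd.DataFrame | None = None) -> dict[str, int]:
    """Count edges by endpoint roles: the three-way regulatory typology.

    Clock genes count as regulators.  Every edge lands in exactly one
    type, so the counts sum to the edge count.  Raises if an endpoint has
    no role annotation.
    """
    roles = {}
    if annotation is not None:
        roles = dict(zip(annotation["gene_id"], annotation["role"]))
    counts = {t: 0 for t in EDGE_TYPES}
    for a, b in g.edges():
        ra = roles.get(a) or g.nodes[a].get("role") or None
        rb = roles.get(b) or g.nodes[b].get("role") or None
        if ra is None or rb is None:
            missing = a if ra is None else b
            raise ValueError(f"unannotated endpoint: {missing}")
        reg_a = ra in ("regulator", "clock")
        reg_b = rb in ("regulator", "clock")
        if reg_a and reg_b:
            counts["regulator-regulator"] += 1
        elif reg_a or reg_b:
            counts["regulator-target"] += 1
        else:
            counts["target-target"] += 1
    return counts


def _typed_edge_sets(g: nx.Graph) -> dict[str, set]:
    roles = {n: g.nodes[n].get("role", "") for n in g.nodes}
    sets: dict[str, set] = {t: set() for t in EDGE_TYPES}
    for a, b in g.edges():
        e = canonical_edge(a, b)
        reg_a = roles[a] in ("regulator", "clock")
        reg_b = roles[b] in ("regulator", "clock")
        if reg_a and reg_b:
            sets["regulator-regulator"].add(e)
        elif reg_a or reg_b:
            sets["regulator-target"].add(e)
        else:
            sets["target-target"].add(e)
    return sets


def edge_overlap(g1: nx.Graph, g2: nx.Graph) -> pd.DataFrame:
    """Shared edge fraction of g1 (the reference) found in g2, per type.

    Returns a row per edge type plus an ``overall`` row with the shared
    count, reference count, and fraction (NaN when the reference has no
    edges of that type).
    """
    s1 = _typed_edge_sets(g1)
    e2 = {canonical_edge(a, b) for a, b in g2.edges()}
    rows = []
    total_shared = 0
    total_ref = 0
    for t in EDGE_TYPES:
        shared = len(s1[t] & e2)
        ref = len(s1[t])
        total_shared += shared
        total_ref += ref
        rows.append(
            {
                "edge_type": t,
                "shared": shared,
                "reference_total": ref,
                "fraction": shared / ref if ref else float("nan"),
            }
        )
    rows.append(
        {
            "edge_type": "overall",
            "shared": total_shared,
            "reference_total": total_ref,
            "fraction": total_shared / total_ref if total_ref else float("nan"),
        }
    )
    return pd.DataFrame(rows)
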