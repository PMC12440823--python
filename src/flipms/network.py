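"""Network-level identification of changing protein complexes.

Proteins with interface-marker hits seed a personalized PageRank (random
walk with restart, damping 0.9) on an undirected, unweighted co-membership
network built from curated complex definitions.  The top-scoring 40% of the
network is kept, clustered with the walktrap algorithm (4-step random
walks, cut at maximal modularity), and clusters with at least four subunits
are named after the complex contributing the most changing-marker proteins.
Two conditions can then be compared cluster by cluster through their
changing-marker sets.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd


def read_complex_table(path) -> pd.DataFrame:
    """TSV with columns complex_id, complex_name, members (';'-separated)."""
    return pd.read_csv(path, sep="\t", dtype=str)


def build_network(
    complexes: pd.DataFrame,
) -> tuple[nx.Graph, dict[str, tuple[str, frozenset]]]:
    """Co-membership network: a clique per complex, deduplicated, undirected,
    unweighted, self-loop free.

    ``complexes`` follows :func:`read_complex_table`; returns the graph and
    {complex_id: (name, member set)}.
    """
    graph = nx.Graph()
    cmap: dict[str, tuple[str, frozenset]] = {}
    for row in complexes.itertuples(index=False):
        members = sorted({m for m in str(row.members).split(";") if m})
        cmap[row.complex_id] = (row.complex_name, frozenset(members))
        graph.add_nodes_from(members)
        graph.add_edges_from(
            (members[i], members[j])
            for i in range(len(members))
            for j in range(i + 1, len(members))
        )
    graph.remove_edges_from(nx.selfloop_edges(graph))
    return graph, cmap


def personalized_pagerank(
    graph: nx.Graph,
    seed_proteins: Iterable[str],
    damping: float = 0.9,
    tol: float = 1e-12,
    max_iter: int = 1000,
) -> dict[str, float]:
    """Random walk with restart to a uniform distribution over the seed
    proteins present in the network; scores sum to 1.

    ``damping`` is the probability of following an edge rather than
    restarting.  Dangling mass is redistributed to the restart vector.
    """
    seeds = sorted(set(seed_proteins) & set(graph.nodes))
    if not seeds:
        raise ValueError("no seed protein is present in the network")
    personalization = {s: 1.0 / len(seeds) for s in seeds}
    return nx.pagerank(
        graph,
        alpha=damping,
        personalization=personalization,
        dangling=personalization,
        tol=tol,
        max_iter=max_iter,
    )


def top_quantile_subnetwork(
    graph: nx.Graph, scores: Mapping[str, float], keep_fraction: float = 0.40
) -> nx.Graph:
    """Induced subgraph of nodes scoring at or above the (1 - keep_fraction)
    quantile; ties at the threshold are retained."""
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    values = np.array([scores[n] for n in graph.nodes])
    threshold = np.quantile(values, 1.0 - keep_fraction)
    keep = [n for n in graph.nodes if scores[n] >= threshold]
    return graph.subgraph(keep).copy()


def walktrap_clusters(graph: nx.Graph, steps: int = 4) -> list[set[str]]:
    """Pons-Latapy walktrap communities at the maximal-modularity cut.

    Isolated nodes become singleton communities.
    """
    import igraph as ig

    if graph.number_of_nodes() == 0:
        return []
    isolated = [n for n in graph.nodes if graph.degree(n) == 0]
    core = graph.subgraph(n for n in graph.nodes if graph.degree(n) > 0)
    communities: list[set[str]] = [{n} for n in isolated]
    if core.number_of_nodes():
        nodes = list(core.nodes)
        index = {n: i for i, n in enumerate(nodes)}
        g = ig.Graph(
            n=len(nodes), edges=[(index[u], index[v]) for u, v in core.edges()]
        )
        clustering = g.community_walktrap(steps=steps).as_clustering()
        communities += [
            {nodes[i] for i in community} for community in clustering
        ]
    return communities


def filter_and_name(
    partition: Sequence[set[str]],
    complexes: Mapping[str, tuple[str, frozenset]],
    changing_proteins: Iterable[str],
    min_size: int = 4,
) -> pd.DataFrame:
    """Keep clusters with at least ``min_size`` subunits and name them.

    Each kept cluster is named after the overlapping complex holding the most
    changing-marker proteins; co-equal complexes yield a joined name
    ('A/B'), which also covers the case where all changing markers are shared
    between complexes.  Clusters whose changing markers overlap no complex
    fall back to the complex with the largest member overlap, or
    'unassigned'.
    """
    changing = set(changing_proteins)
    rows = []
    for k, cluster in enumerate(partition):
        if len(cluster) < min_size:
            continue
        marker_counts: dict[str, int] = {}
        overlap_counts: dict[str, int] = {}
        for cid, (name, members) in complexes.items():
            inter = cluster & members
            if inter:
                overlap_counts[cid] = len(inter)
                n_changing = len(inter & changing)
                if n_changing:
                    marker_counts[cid] = n_changing
        if marker_counts:
            best = max(marker_counts.values())
            named = sorted(cid for cid, n in marker_counts.items() if n == best)
        elif overlap_counts:
            best = max(overlap_counts.values())
            named = sorted(cid for cid, n in overlap_counts.items() if n == best)
        else:
            named = []
        name = (
            "/".join(complexes[cid][0] for cid in named) if named else "unassigned"
        )
        rows.append(
            {
                "cluster_id": k,
                "name": name,
                "named_complexes": named,
                "size": len(cluster),
                "members": sorted(cluster),
                "changing_proteins": sorted(cluster & changing),
                "n_changing": len(cluster & changing),
            }
        )
    columns = [
        "cluster_id", "name", "named_complexes", "size", "members",
        "changing_proteins", "n_changing",
    ]
    return pd.DataFrame(rows, columns=columns)


def propagate_and_cluster(
    graph: nx.Graph,
    seed_proteins: Iterable[str],
    complexes: Mapping[str, tuple[str, frozenset]],
    damping: float = 0.9,
    keep_fraction: float = 0.40,
    steps: int = 4,
    min_size: int = 4,
) -> pd.DataFrame:
    """The full network stage: propagate, cut, cluster, filter, name."""
    scores = personalized_pagerank(graph, seed_proteins, damping=damping)
    sub = top_quantile_subnetwork(graph, scores, keep_fraction)
    partition = walktrap_clusters(sub, steps=steps)
    return filter_and_name(partition, complexes, seed_proteins, min_size=min_size)


def compare_conditions(
    clusters: pd.DataFrame,
    markers_condition1: Iterable[tuple],
    markers_condition2: Iterable[tuple],
    protein_of=lambda marker: marker[0],
) -> pd.DataFrame:
    """Per-cluster comparison of changing-marker sets between two conditions.

    Both marker collections must already be restricted to regions detected
    in both datasets.  Markers are any hashables whose protein is given by
    ``protein_of`` (default: first tuple element).  Classes: ``shared``
    (equal nonempty sets), ``gain_c1``/``gain_c2`` (strict superset in one
    condition), ``divergent`` (both nonempty, non-nested), ``none``.
    """
    m1 = {m for m in markers_condition1}
    m2 = {m for m in markers_condition2}
    rows = []
    for row in clusters.itertuples(index=False):
        members = set(row.members)
        s1 = {m for m in m1 if protein_of(m) in members}
        s2 = {m for m in m2 if protein_of(m) in members}
        if not s1 and not s2:
            delta = "none"
        elif s1 == s2:
            delta = "shared"
        elif s1 > s2:
            delta = "gain_c1"
        elif s2 > s1:
            delta = "gain_c2"
        else:
            delta = "divergent"
        rows.append(
            {
                "cluster_id": row.cluster_id,
                "name": row.name,
                "delta": delta,
                "n_markers_c1": len(s1),
                "n_markers_c2": len(s2),
            }
        )
    return pd.DataFrame(
        rows, columns=["cluster_id", "name", "delta", "n_markers_c1", "n_markers_c2"]
    )
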