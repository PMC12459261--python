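"""Co-expression networks, node metrics, consensus edges, communities.

Networks are undirected and unweighted (rho is kept as an edge attribute
but does not weight metrics).  Betweenness is Brandes shortest-path
betweenness, unnormalised, with each unordered (s,t) pair counted once;
node degree is normalised by n-1.  The consensus network keeps an edge iff
it is significant (p < alpha) in strictly more than ``min_support`` cell
types.  Communities come from Clauset-Newman-Moore greedy modularity
maximisation.
"""

from __future__ import annotations

import dataclasses
import warnings

import networkx as nx
import pandas as pd

from .data_model import ValidationError

__all__ = [
    "CommunityPartition",
    "build_network",
    "node_metrics",
    "consensus_network",
    "greedy_modularity",
    "modularity",
]


def build_network(pairs: pd.DataFrame, alpha: float = 0.01) -> nx.Graph:
    """Graph of significantly correlated pairs (raw p < alpha) from one
    cell type.  Nodes are genes with at least one retained edge."""
    net = nx.Graph()
    sig = pairs[pairs["p_value"] < alpha]
    for row in sig.itertuples(index=False):
        net.add_edge(row.gene_a, row.gene_b, rho=float(row.rho))
    if net.number_of_edges() == 0:
        warnings.warn("no edges pass the significance threshold; empty network")
    return net


def node_metrics(net: nx.Graph) -> pd.DataFrame:
    """Per-node degree, normalised degree (degree/(n-1)) and unnormalised
    Brandes betweenness."""
    n = net.number_of_nodes()
    if n < 2:
        raise ValidationError("node metrics undefined for networks with <2 nodes")
    betw = nx.betweenness_centrality(net, normalized=False)
    rows = [
        {
            "gene": node,
            "degree": net.degree(node),
            "normalized_degree": net.degree(node) / (n - 1),
            "betweenness": betw[node],
        }
        for node in sorted(net.nodes)
    ]
    return pd.DataFrame(rows).set_index("gene")


def consensus_network(per_celltype_pairs: list[pd.DataFrame],
                      min_support: int | None = None,
                      alpha: float = 0.01) -> nx.Graph:
    """Edges significant in more than ``min_support`` cell types.

    ``min_support`` defaults to floor(total/2) ("more than half"); the
    comparison is strict (support == min_support is dropped).  Edge
    attributes: ``support`` and mean rho over supporting cell types.
    """
    if not per_celltype_pairs:
        raise ValidationError("need at least one cell type's pairs")
    total = len(per_celltype_pairs)
    if min_support is None:
        min_support = total // 2
    support: dict[tuple[str, str], list[float]] = {}
    for pairs in per_celltype_pairs:
        sig = pairs[pairs["p_value"] < alpha]
        for row in sig.itertuples(index=False):
            key = (row.gene_a, row.gene_b)
            support.setdefault(key, []).append(float(row.rho))
    net = nx.Graph()
    for (a, b), rhos in sorted(support.items()):
        if len(rhos) > min_support:
            net.add_edge(a, b, support=len(rhos), rho=sum(rhos) / len(rhos))
    return net


def modularity(net: nx.Graph, communities: list[set]) -> float:
    """Newman modularity Q = sum_c (e_c/m - (d_c/2m)^2)."""
    m = net.number_of_edges()
    if m == 0:
        raise ValidationError("modularity undefined for an edgeless network")
    return nx.community.modularity(net, communities)


@dataclasses.dataclass
class CommunityPartition:
    """node -> community index plus the partition's modularity Q."""

    membership: dict[str, int]
    q: float

    def communities(self) -> list[set]:
        out: dict[int, set] = {}
        for node, c in self.membership.items():
            out.setdefault(c, set()).add(node)
        return [out[c] for c in sorted(out)]


def greedy_modularity(net: nx.Graph) -> CommunityPartition:
    """Clauset-Newman-Moore agglomerative modularity maximisation."""
    if net.number_of_edges() == 0:
        raise ValidationError("community detection needs at least one edge")
    comms = nx.community.greedy_modularity_communities(net)
    comms = [set(c) for c in comms]
    # deterministic labelling: communities ordered by their smallest member
    comms.sort(key=lambda c: sorted(c)[0])
    membership = {node: i for i, c in enumerate(comms) for node in sorted(c)}
    return CommunityPartition(membership=membership, q=modularity(net, comms))
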