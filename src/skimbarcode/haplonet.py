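"""Haplotype collapsing and median-joining networks.

Samples collapse to a haplotype when their sequences are identical at every
column where both are unambiguous (missing-tolerant matching: N and gaps are
compatible with any base).  Compatibility is closed transitively with a
union-find, so a partially ambiguous sequence can bridge two otherwise
distinct sequences into one haplotype; the first member's sequence is the
representative.

The network is built Bandelt-style:

1. pairwise Hamming distances over mutually unambiguous columns;
2. the minimum-spanning network (MSN): the union of all minimum spanning
   trees, i.e. every edge whose weight is within ``epsilon`` of the minimax
   path weight between its endpoints;
3. iterative addition of median vectors: for connected triplets of the
   current network (three nodes sharing at least two edges), the
   per-site-majority consensus (sites where all three states differ
   contribute no median) is added when it is novel and strictly reduces the
   cost of connecting the triplet;
4. median vectors of degree <= 2 are pruned (they add no reticulation).

With epsilon = 0 and unique shortest connections the result is exactly the
minimum spanning tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .alphabet import decode, encode_matrix
from .errors import SkimBarcodeError
from .seqio import ConcatenatedDataSet, RegionAlignment


@dataclass
class HaplotypeSet:
    """Observed haplotypes: id -> representative sequence and members."""

    sequences: dict[str, str]  # haplotype id -> representative sequence
    members: dict[str, list[str]]  # haplotype id -> sample ids
    sample_to_haplotype: dict[str, str]

    @property
    def n_haplotypes(self) -> int:
        return len(self.sequences)

    def multiplicity(self, haplotype_id: str) -> int:
        return len(self.members[haplotype_id])


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph  # node attrs: sequence, is_median, samples; edge attr: weight
    epsilon: float

    @property
    def median_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["is_median"]]

    def total_weight(self) -> float:
        return sum(w for _, _, w in self.graph.edges(data="weight"))


def collapse_haplotypes(
    alignment: ConcatenatedDataSet | RegionAlignment,
    sample_subset: list[str] | None = None,
) -> HaplotypeSet:
    """Collapse samples into haplotypes under missing-tolerant matching."""
    aln = alignment.alignment if isinstance(alignment, ConcatenatedDataSet) else alignment
    if sample_subset is not None:
        aln = aln.subset(sample_subset)
    if aln.n_samples < 1:
        raise ValueError("need at least one sample")
    enc = aln.encoded()
    n = aln.n_samples
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            both = (enc[i] < 4) & (enc[j] < 4)
            if not np.any(enc[i][both] != enc[j][both]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    members: dict[int, list[int]] = {}
    for i in range(n):
        members.setdefault(find(i), []).append(i)
    sequences: dict[str, str] = {}
    member_ids: dict[str, list[str]] = {}
    sample_to_hap: dict[str, str] = {}
    for k, root in enumerate(sorted(members, key=lambda r: members[r][0]), start=1):
        hid = f"H{k}"
        idx = members[root]
        sequences[hid] = aln.sequences[idx[0]]
        member_ids[hid] = [aln.samples[i] for i in idx]
        for i in idx:
            sample_to_hap[aln.samples[i]] = hid
    return HaplotypeSet(sequences=sequences, members=member_ids, sample_to_haplotype=sample_to_hap)


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    both = (a < 4) & (b < 4)
    return int(np.sum(a[both] != b[both]))


def _minimax_weights(nodes: list[str], dist: dict) -> dict[tuple[str, str], float]:
    """Minimax path weight between all node pairs, from one MST.

    The minimax (bottleneck) value is MST-independent, so any single MST
    suffices; an edge belongs to some MST iff its weight equals the minimax
    weight between its endpoints.
    """
    complete = nx.Graph()
    complete.add_nodes_from(nodes)
    for u, v in combinations(nodes, 2):
        complete.add_edge(u, v, weight=dist[(u, v)])
    mst = nx.minimum_spanning_tree(complete)
    out: dict[tuple[str, str], float] = {}
    for src in nodes:
        # DFS over the MST tracking the largest edge weight on the path
        stack = [(src, None, 0.0)]
        while stack:
            node, prev, running_max = stack.pop()
            if node != src:
                key = (min(src, node), max(src, node))
                out[key] = running_max
            for nbr in mst[node]:
                if nbr != prev:
                    stack.append((nbr, node, max(running_max, mst[node][nbr]["weight"])))
    return out


def _spanning_network(nodes: list[str], dist: dict, epsilon: float) -> nx.Graph:
    minimax = _minimax_weights(nodes, dist)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v in combinations(nodes, 2):
        key = (min(u, v), max(u, v))
        if dist[(u, v)] <= minimax[key] + epsilon:
            g.add_edge(u, v, weight=dist[(u, v)])
    return g


def median_joining_network(
    haplotypes: HaplotypeSet, epsilon: float = 0.0, max_rounds: int = 100
) -> HaplotypeNetwork:
    """Median-joining network over observed haplotypes; see module docstring."""
    if haplotypes.n_haplotypes < 2:
        raise ValueError("need >= 2 haplotypes for a network")
    ids = list(haplotypes.sequences)
    enc = {h: row for h, row in zip(ids, encode_matrix([haplotypes.sequences[h] for h in ids]))}

    def all_dist(nodes: list[str]) -> dict:
        d = {}
        for u, v in combinations(nodes, 2):
            d[(u, v)] = d[(v, u)] = _hamming(enc[u], enc[v])
        return d

    nodes = list(ids)
    median_count = 0
    for _round in range(max_rounds):
        dist = all_dist(nodes)
        net = _spanning_network(nodes, dist, epsilon)
        existing = {enc[x].tobytes() for x in nodes}
        best_gain, best_seq = 0, None
        # Connected triplets: a center node plus two of its neighbours.
        seen_triples: set[tuple] = set()
        for center in nodes:
            for u, v in combinations(sorted(net[center]), 2):
                triple = tuple(sorted((center, u, v)))
                if triple in seen_triples:
                    continue
                seen_triples.add(triple)
                a, b, c = triple
                tri = np.vstack([enc[a], enc[b], enc[c]])
                unamb = tri < 4
                counts = np.stack([((tri == s) & unamb).sum(axis=0) for s in range(4)])
                top = counts.max(axis=0)
                if np.any((unamb.sum(axis=0) >= 2) & (top < 2)):
                    continue  # some site lacks a majority state: no median here
                median = np.where(top >= 2, counts.argmax(axis=0), enc[a]).astype(np.uint8)
                if median.tobytes() in existing:
                    continue
                connect_now = sum(sorted([dist[(a, b)], dist[(a, c)], dist[(b, c)]])[:2])
                connect_med = (
                    _hamming(median, enc[a]) + _hamming(median, enc[b]) + _hamming(median, enc[c])
                )
                gain = connect_now - connect_med
                if gain > best_gain:
                    best_gain, best_seq = gain, median
        if best_seq is None:
            break
        median_count += 1
        mid = f"MV{median_count}"
        enc[mid] = best_seq
        nodes.append(mid)

    # Prune uninformative median vectors, rebuilding the network each time.
    while True:
        dist = all_dist(nodes)
        g = _spanning_network(nodes, dist, epsilon)
        removable = [n for n in nodes if n.startswith("MV") and g.degree(n) <= 2]
        if not removable:
            break
        nodes = [n for n in nodes if n not in removable]

    if not nx.is_connected(g):
        raise SkimBarcodeError("internal error: haplotype network is disconnected")
    for node in g.nodes:
        is_median = node.startswith("MV")
        g.nodes[node]["sequence"] = decode(enc[node])
        g.nodes[node]["is_median"] = is_median
        g.nodes[node]["samples"] = [] if is_median else list(haplotypes.members[node])
        g.nodes[node]["multiplicity"] = 0 if is_median else haplotypes.multiplicity(node)
    return HaplotypeNetwork(graph=g, epsilon=epsilon)


def network_tables(
    network: HaplotypeNetwork, metadata: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(node table, edge list) for export and downstream colouring."""
    taxon_of = {} if metadata is None else dict(zip(metadata["sample_id"], metadata["taxon"]))
    pop_of = {} if metadata is None else dict(zip(metadata["sample_id"], metadata["population"]))
    node_rows = []
    for node, data in network.graph.nodes(data=True):
        samples = data["samples"]
        node_rows.append(
            {
                "node": node,
                "is_median": data["is_median"],
                "multiplicity": data["multiplicity"],
                "samples": ";".join(samples),
                "taxa": ";".join(sorted({taxon_of[s] for s in samples if s in taxon_of})),
                "populations": ";".join(sorted({pop_of[s] for s in samples if s in pop_of})),
            }
        )
    edge_rows = [
        {"from": u, "to": v, "mutations": w}
        for u, v, w in sorted(network.graph.edges(data="weight"))
    ]
    return pd.DataFrame(node_rows), pd.DataFrame(edge_rows)


def write_network(network: HaplotypeNetwork, gml_path: str | Path) -> None:
    g = network.graph.copy()
    for node in g.nodes:
        g.nodes[node]["samples"] = ";".join(g.nodes[node]["samples"])
        g.nodes[node]["is_median"] = int(g.nodes[node]["is_median"])
    nx.write_gml(g, str(gml_path))
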