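from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from skimbarcode.haplonet import (
    HaplotypeSet,
    _spanning_network,
    collapse_haplotypes,
    median_joining_network,
    network_tables,
)
from skimbarcode.seqio import build_datasets
from skimbarcode.simulate import (
    HybridSpec,
    RegionSpec,
    SimulationConfig,
    simulate_dataset,
)
from .conftest import make_alignment


def hapset(seqs):
    return HaplotypeSet(
        sequences={f"H{i+1}": s for i, s in enumerate(seqs)},
        members={f"H{i+1}": [f"s{i+1}"] for i in range(len(seqs))},
        sample_to_haplotype={f"s{i+1}": f"H{i+1}" for i in range(len(seqs))},
    )


def test_collapse_identical_sequences():
    hs = collapse_haplotypes(make_alignment(["ACGT"] * 4))
    assert hs.n_haplotypes == 1
    assert hs.multiplicity("H1") == 4


def test_collapse_distinct_sequences():
    hs = collapse_haplotypes(make_alignment(["AAA", "AAT"]))
    assert hs.n_haplotypes == 2


def test_collapse_missing_tolerant_matching():
    hs = collapse_haplotypes(make_alignment(["AAA", "AAN"]))
    assert hs.n_haplotypes == 1
    # the ambiguous sequence can bridge two distinct ones (transitive closure)
    hs2 = collapse_haplotypes(make_alignment(["AAA", "AAN", "AAT"]))
    assert hs2.n_haplotypes == 1


def test_chain_topology():
    net = median_joining_network(hapset(["AAA", "AAT", "ATT"]))
    g = net.graph
    assert net.median_nodes == []
    assert sorted(d for _, d in g.degree()) == [1, 1, 2]
    assert g.has_edge("H1", "H2") and g.has_edge("H2", "H3")
    assert g["H1"]["H2"]["weight"] == 1 and g["H2"]["H3"]["weight"] == 1


def test_four_cycle_retained():
    net = median_joining_network(hapset(["AA", "AT", "TA", "TT"]))
    g = net.graph
    assert net.median_nodes == []  # candidate medians coincide with observed nodes
    assert g.number_of_edges() == 4
    assert all(w == 1 for _, _, w in g.edges(data="weight"))
    assert all(d == 2 for _, d in g.degree())  # a 4-cycle


def test_star_topology():
    center = "AAAA"
    satellites = ["TAAA", "ACAA", "AAGA", "AAAC"]
    net = median_joining_network(hapset([center] + satellites))
    g = net.graph
    assert g.degree("H1") == 4
    assert g.number_of_edges() == 4
    assert net.median_nodes == []


def test_median_vector_added_for_steiner_triple():
    # three haplotypes pairwise 2 apart whose majority consensus is unobserved
    net = median_joining_network(hapset(["TCA", "ACC", "TAC"]))
    # consensus of (TCA, ACC, TAC) is TCC: connecting via it costs 3 < 4
    assert len(net.median_nodes) == 1
    mv = net.median_nodes[0]
    assert net.graph.nodes[mv]["sequence"] == "TCC"
    assert net.graph.degree(mv) == 3
    assert net.total_weight() == 3


def msn_oracle(seqs):
    """Brute-force minimum spanning network: edge (u,v) is kept iff no path
    connects u,v using only edges strictly shorter than d(u,v)."""
    n = len(seqs)
    d = {}
    for i, j in combinations(range(n), 2):
        d[(i, j)] = sum(a != b for a, b in zip(seqs[i], seqs[j]))
    edges = set()
    for (i, j), w in d.items():
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for (a, b), wv in d.items():
            if wv < w:
                g.add_edge(a, b)
        if not nx.has_path(g, i, j):
            edges.add((i, j))
    return edges, d


def test_spanning_network_matches_bruteforce_oracle():
    rng = np.random.default_rng(17)
    for _ in range(60):
        n = int(rng.integers(4, 9))
        seqs = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(n)]
        if len(set(seqs)) != n:
            continue
        want, d = msn_oracle(seqs)
        ids = [f"H{i+1}" for i in range(n)]
        dist = {}
        for i, j in combinations(range(n), 2):
            dist[(ids[i], ids[j])] = dist[(ids[j], ids[i])] = d[(i, j)]
        g = _spanning_network(ids, dist, epsilon=0.0)
        got = {(int(u[1:]) - 1, int(v[1:]) - 1) for u, v in g.edges}
        got = {(min(p), max(p)) for p in got}
        assert got == want
        # the MSN never loses to a single MST on total connectivity weight
        mst_weight = sum(
            w for _, _, w in nx.minimum_spanning_tree(
                nx.Graph([(u, v, {"weight": w}) for (u, v), w in dist.items()])
            ).edges(data="weight")
        )
        assert sum(w for _, _, w in g.edges(data="weight")) >= mst_weight


def test_unique_weights_epsilon_zero_equals_mst():
    rng = np.random.default_rng(23)
    for _ in range(30):
        n = int(rng.integers(4, 9))
        ids = [f"H{i+1}" for i in range(n)]
        weights = rng.permutation(len(ids) * (len(ids) - 1) // 2) + 1.0  # unique
        dist = {}
        for k, (u, v) in enumerate(combinations(ids, 2)):
            dist[(u, v)] = dist[(v, u)] = float(weights[k])
        g = _spanning_network(ids, dist, epsilon=0.0)
        mst = nx.minimum_spanning_tree(
            nx.Graph([(u, v, {"weight": w}) for (u, v), w in dist.items() if u < v])
        )
        assert set(map(frozenset, g.edges)) == set(map(frozenset, mst.edges))
        assert nx.is_tree(g)


def test_network_connected_and_all_haplotypes_present(default_datasets):
    hs = collapse_haplotypes(default_datasets["A"])
    net = median_joining_network(hs)
    assert nx.is_connected(net.graph)
    for h in hs.sequences:
        assert h in net.graph
    for mv in net.median_nodes:
        assert net.graph.degree(mv) >= 3


def test_population_private_organellar_haplotypes():
    """With within-population diversity off and population founder mutations
    on, every mitochondrial haplotype is private to one population."""
    config = SimulationConfig(
        species_tree="((x:0.002,y:0.002):0.002,z:0.004);",
        samples_per_population=3,
        populations_per_taxon={"x": 2, "y": 2, "z": 2},
        region_plan=[RegionSpec("mt1", "mito_gene", 3000, 1.0)],
        within_population_theta=0.0,
        between_population_divergence=0.01,
        seed=8,
    )
    ds = simulate_dataset(config)
    hs = collapse_haplotypes(ds.regions[0])
    pop_of = ds.truth["population_of"]
    for members in hs.members.values():
        assert len({pop_of[s] for s in members}) == 1


def test_network_tables_composition(default_datasets, default_dataset):
    hs = collapse_haplotypes(default_datasets["B"])
    net = median_joining_network(hs)
    nodes, edges = network_tables(net, default_dataset.metadata)
    assert nodes["multiplicity"].sum() == len(default_dataset.metadata)
    assert (edges["mutations"] >= 1).all()
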