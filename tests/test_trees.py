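import numpy as np
import pandas as pd
import pytest

from skimbarcode.distances import DistanceMatrix
from skimbarcode.seqio import concatenate_regions
from skimbarcode.simulate import RegionSpec, SimulationConfig, simulate_dataset
from skimbarcode.trees import (
    FAILURE,
    NOT_ASSESSABLE,
    SUCCESS,
    bipartition_supports,
    bipartitions,
    bootstrap_supports,
    neighbor_joining,
    read_tree,
    taxon_monophyly,
    write_tree,
)


def dm(labels, values):
    values = np.asarray(values, dtype=float)
    return DistanceMatrix(labels=list(labels), values=values, mask=np.zeros_like(values, dtype=bool))


def tip_tip(tree):
    d = tree.tip_tip_distances()
    return {frozenset(p): d[p[0], p[1]] for p in [(a, b) for a in d.ids for b in d.ids if a < b]}


def test_three_taxon_closed_form():
    m = dm("abc", [[0, 3, 4], [3, 0, 5], [4, 5, 0]])
    tree = neighbor_joining(m)
    d = tip_tip(tree)
    assert d[frozenset("ab")] == pytest.approx(3)
    assert d[frozenset("ac")] == pytest.approx(4)
    assert d[frozenset("bc")] == pytest.approx(5)


def test_nj_recovers_additive_four_taxon_tree():
    # tree ((a:1,b:2):1,(c:3,d:4)): pairwise path lengths below
    m = dm("abcd", [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]])
    tree = neighbor_joining(m)
    splits = {frozenset(s) for s in bipartitions(tree)}
    assert splits == {frozenset("cd")} or splits == {frozenset("ab")}
    d = tip_tip(tree)
    for pair, want in [("ab", 3), ("ac", 5), ("ad", 6), ("bc", 6), ("bd", 7), ("cd", 7)]:
        assert d[frozenset(pair)] == pytest.approx(want)


def random_additive_matrix(rng, n_leaves):
    """Random binary tree with positive lengths -> its additive distance matrix."""
    import io
    from skbio import TreeNode

    labels = [f"t{i}" for i in range(n_leaves)]
    nodes = list(labels)
    parts = {l: l for l in labels}
    while len(nodes) > 2:
        a, b = rng.choice(len(nodes), size=2, replace=False)
        a, b = sorted((a, b))
        la, lb = nodes[b], nodes[a]
        merged = f"({parts[la]}:{rng.uniform(0.1, 1):.4f},{parts[lb]}:{rng.uniform(0.1, 1):.4f})"
        nodes = [x for x in nodes if x not in (la, lb)] + [merged]
        parts[merged] = merged
    newick = f"({nodes[0]}:{rng.uniform(0.1, 1):.4f},{nodes[1]}:{rng.uniform(0.1, 1):.4f});"
    tree = TreeNode.read(io.StringIO(newick))
    d = tree.tip_tip_distances()
    order = sorted(d.ids)
    values = np.array([[0 if x == y else d[x, y] for y in order] for x in order])
    return dm(order, values), tree


def test_nj_exact_on_random_additive_matrices():
    rng = np.random.default_rng(2024)
    for _ in range(60):
        n = int(rng.integers(8, 13))
        matrix, true_tree = random_additive_matrix(rng, n)
        est = neighbor_joining(matrix)
        assert {frozenset(s) for s in bipartitions(est)} == {
            frozenset(s) for s in bipartitions(true_tree)
        }
        d = tip_tip(est)
        dt = tip_tip(true_tree)
        for pair in d:
            assert d[pair] == pytest.approx(dt[pair], abs=1e-9)


def test_nj_degenerate_equal_distances_has_zero_internal_edge():
    m = dm("abcd", (np.ones((4, 4)) - np.eye(4)))
    tree = neighbor_joining(m)
    internal = [n for n in tree.non_tips() if n.length is not None]
    assert any(n.length == pytest.approx(0, abs=1e-12) for n in internal)


def _two_clade_dataset(seed=0):
    config = SimulationConfig(
        species_tree="(x:0.05,y:0.05);",
        samples_per_population=4,
        populations_per_taxon={"x": 1, "y": 1},
        region_plan=[RegionSpec("locus", "plastid_gene", 2000, 1.0)],
        within_population_theta=0.002,
        between_population_divergence=0.0,
        seed=seed,
    )
    return simulate_dataset(config)


def test_bootstrap_high_support_for_separated_clades():
    ds = _two_clade_dataset(seed=3)
    aln = concatenate_regions(ds.regions, "X")
    tree = bootstrap_supports(aln, B=200, seed=9)
    supports = bipartition_supports(tree)
    x_samples = frozenset(s for s, t in ds.truth["taxon_partition"].items() if t == "x")
    leaves = frozenset(t.name for t in tree.tips())
    target = x_samples if min(leaves) not in x_samples else leaves - x_samples
    assert target in supports
    assert supports[target] >= 95


def test_bootstrap_b1_supports_are_zero_or_hundred():
    ds = _two_clade_dataset(seed=4)
    tree = bootstrap_supports(ds.regions[0], B=1, seed=1)
    vals = [v for v in bipartition_supports(tree).values() if v is not None]
    assert vals and all(v in (0.0, 100.0) for v in vals)


def test_bootstrap_deterministic_under_seed():
    ds = _two_clade_dataset(seed=5)
    t1 = bootstrap_supports(ds.regions[0], B=30, seed=7)
    t2 = bootstrap_supports(ds.regions[0], B=30, seed=7)
    assert bipartition_supports(t1) == bipartition_supports(t2)


META = pd.DataFrame(
    {
        "sample_id": ["a1", "a2", "b1", "b2"],
        "taxon": ["A", "A", "B", "B"],
        "population": ["p"] * 4,
    }
)


def test_monophyly_success_failure_and_threshold():
    good = read_tree("((a1:1,a2:1)90:1,(b1:1,b2:1)90:1);")
    assert taxon_monophyly(good, META, "A").status == SUCCESS
    tangled = read_tree("((a1:1,b1:1):1,(a2:1,b2:1):1);")
    res = taxon_monophyly(tangled, META, "A")
    assert res.status == FAILURE
    assert res.smallest_clade_size == 4  # only the whole tree contains both a's
    weak = read_tree("((a1:1,a2:1)34:1,(b1:1,b2:1)34:1);")
    res = taxon_monophyly(weak, META, "A")
    assert res.status == FAILURE and res.support == 34  # strict > 50 rule
    border = read_tree("((a1:1,a2:1)50:1,(b1:1,b2:1)50:1);")
    assert taxon_monophyly(border, META, "A").status == FAILURE


def test_monophyly_singleton_not_assessable():
    meta = pd.DataFrame(
        {
            "sample_id": ["a1", "b1", "b2", "c1"],
            "taxon": ["A", "B", "B", "C"],
            "population": ["p"] * 4,
        }
    )
    tree = read_tree("((a1:1,c1:1)80:1,(b1:1,b2:1)80:1);")
    assert taxon_monophyly(tree, meta, "A").status == NOT_ASSESSABLE


def test_newick_roundtrip_preserves_supports_and_verdicts(tmp_path):
    tree = read_tree("((a1:1,a2:1)90:1,(b1:1,b2:1)75:2);")
    path = tmp_path / "t.nwk"
    write_tree(tree, path)
    back = read_tree(path)
    assert bipartition_supports(back) == bipartition_supports(tree)
    assert taxon_monophyly(back, META, "A").status == SUCCESS


def test_comment_dialect_supports():
    # 5 leaves -> three distinct informative bipartitions
    t1 = read_tree(
        "((a1:1,a2:1):1[90],((b1:1,b2:1):1[75],c1:1):1[60],c2:1);", dialect="comment"
    )
    t2 = read_tree(
        "((a1:1,a2:1)[90]:1,((b1:1,b2:1)[75]:1,c1:1)[60]:1,c2:1);", dialect="comment"
    )
    for t in (t1, t2):
        assert set(bipartition_supports(t).values()) == {90.0, 75.0, 60.0}
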