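"""Distance trees, bootstrap supports, and the tree-based delimitation test.

Trees are scikit-bio ``TreeNode`` objects; bootstrap supports are stored as
internal node names (the newick dialect used by most tree viewers and by
ML programs' consensus output), as percentages in [0, 100].

The tree criterion is evaluated on *unrooted bipartitions*: a taxon is
successfully delimited when removing some internal edge splits the leaves
into (exactly the taxon's samples | everything else) and that edge's
support strictly exceeds the threshold (default 50).  Working with
bipartitions avoids any dependence on where the tree happens to be rooted.

The tree builder here is neighbor joining over K2P distances.  Externally
computed trees (e.g. maximum likelihood with bootstrap) are accepted via
``read_tree`` and feed the same criterion.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import skbio
from skbio import TreeNode
from skbio.tree import nj

from .distances import DistanceMatrix, pairwise_matrix
from .errors import FormatError, SaturationError
from .seqio import ConcatenatedDataSet, RegionAlignment

logger = logging.getLogger(__name__)

SUCCESS = "success"
FAILURE = "failure"
NOT_ASSESSABLE = "not_assessable"


@dataclass
class MonophylyResult:
    taxon: str
    status: str
    support: float | None  # support of the exact taxon edge, when one exists
    smallest_clade_size: int | None  # diagnostics when no exact edge exists


def neighbor_joining(matrix: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining (scikit-bio), with negative branch
    lengths clamped to zero and the excess moved to the sibling branch so
    path lengths through the parent are preserved."""
    if matrix.n < 3:
        raise ValueError("neighbor joining needs >= 3 labels")
    if matrix.n_masked_pairs:
        raise SaturationError("distance matrix has masked pairs")
    if matrix.n == 3:
        # Closed form: the unique unrooted 3-taxon star.
        (a, b, c), d = matrix.labels, matrix.values
        x = max(0.0, (d[0, 1] + d[0, 2] - d[1, 2]) / 2)
        y = max(0.0, (d[0, 1] + d[1, 2] - d[0, 2]) / 2)
        z = max(0.0, (d[0, 2] + d[1, 2] - d[0, 1]) / 2)
        return TreeNode.read(io.StringIO(f"({a}:{x},{b}:{y},{c}:{z});"), convert_underscores=False)
    tree = nj(matrix.to_skbio(), neg_as_zero=False)
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            excess = -node.length
            node.length = 0.0
            siblings = [s for s in node.parent.children if s is not node]
            if siblings and siblings[0].length is not None:
                siblings[0].length += excess
            elif node.parent.length is not None:
                node.parent.length += excess
    return tree


def _canonical(side: frozenset, all_leaves: frozenset) -> frozenset:
    ref = min(all_leaves)
    return frozenset(side) if ref not in side else all_leaves - side


def bipartitions(tree: TreeNode) -> dict[frozenset, TreeNode]:
    """Informative bipartitions of an unrooted tree.

    Maps the canonical leaf set (the side not containing the smallest leaf
    label) of every internal edge to the child node defining it; both sides
    of an informative edge have >= 2 leaves.
    """
    all_leaves = frozenset(t.name for t in tree.tips())
    n = len(all_leaves)
    out: dict[frozenset, TreeNode] = {}
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= n - 2:
            out[_canonical(side, all_leaves)] = node
    return out


def _parse_support(name) -> float | None:
    if name is None:
        return None
    try:
        return float(name)
    except (TypeError, ValueError):
        return None


def bipartition_supports(tree: TreeNode) -> dict[frozenset, float | None]:
    return {split: _parse_support(node.name) for split, node in bipartitions(tree).items()}


def bootstrap_supports(
    alignment: ConcatenatedDataSet | RegionAlignment,
    B: int = 1000,
    seed: int | None = None,
    tree_builder=None,
    max_drop_fraction: float = 0.1,
) -> TreeNode:
    """Column bootstrap: resample alignment columns with replacement, rebuild
    the tree per replicate, and support each internal edge of the full-data
    tree by the percentage of replicates containing its bipartition.

    Replicates producing a saturated (undefined-K2P) pair are dropped and
    logged; more than ``max_drop_fraction`` dropped replicates is an error.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    tree_builder = tree_builder or neighbor_joining
    aln = alignment.alignment if isinstance(alignment, ConcatenatedDataSet) else alignment
    matrix = pairwise_matrix(aln)
    tree = tree_builder(matrix)
    target_splits = bipartitions(tree)
    counts = {split: 0 for split in target_splits}

    enc = aln.encoded()
    n, L = enc.shape
    ii, jj = np.triu_indices(n, k=1)
    a, b = enc[ii], enc[jj]
    valid = ((a < 4) & (b < 4)).astype(np.float32)
    ts = (valid.astype(bool) & (a != b) & ((a ^ 2) == b)).astype(np.float32)
    tv = (valid.astype(bool) & (a != b) & ((a ^ 2) != b)).astype(np.float32)

    rng = np.random.default_rng(seed)
    weights = rng.multinomial(L, np.full(L, 1.0 / L), size=B).astype(np.float32).T
    n_sites = valid @ weights  # (n_pairs, B)
    n_ts = ts @ weights
    n_tv = tv @ weights

    dropped = 0
    used = 0
    for rep in range(B):
        s, t, v = n_ts[:, rep], n_tv[:, rep], n_sites[:, rep]
        with np.errstate(divide="ignore", invalid="ignore"):
            P, Q = s / v, t / v
            w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
        if np.any((v == 0) | (w1 <= 0) | (w2 <= 0)):
            dropped += 1
            logger.warning("bootstrap replicate %d dropped (saturated pair)", rep)
            continue
        d = -0.5 * np.log(w1 * np.sqrt(w2))
        values = np.zeros((n, n))
        values[ii, jj] = d
        values[jj, ii] = d
        rep_matrix = DistanceMatrix(
            labels=list(aln.samples), values=values, mask=np.zeros((n, n), dtype=bool)
        )
        rep_tree = tree_builder(rep_matrix)
        rep_splits = set(bipartitions(rep_tree))
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
        used += 1
    if dropped > max_drop_fraction * B:
        raise SaturationError(
            f"{dropped}/{B} bootstrap replicates dropped due to saturation"
        )
    for split, node in target_splits.items():
        node.name = f"{100.0 * counts[split] / used:g}" if used else "0"
    tree.bootstrap_replicates_used = used
    return tree


def taxon_monophyly(
    tree: TreeNode,
    metadata: pd.DataFrame,
    taxon: str,
    support_threshold: float = 50.0,
) -> MonophylyResult:
    """Tree-based delimitation verdict for one taxon.

    Success iff an internal edge induces a bipartition with one side exactly
    the taxon's samples AND support strictly above the threshold.  A taxon
    with a single sample is not assessable (monophyly undefined).
    """
    taxon_samples = frozenset(
        metadata.loc[metadata["taxon"] == taxon, "sample_id"]
    )
    if not taxon_samples:
        raise ValueError(f"taxon {taxon!r} absent from metadata")
    leaves = frozenset(t.name for t in tree.tips())
    missing = taxon_samples - leaves
    if missing:
        raise ValueError(f"taxon {taxon!r}: samples not in tree: {sorted(missing)}")
    if len(taxon_samples) == 1:
        return MonophylyResult(taxon, NOT_ASSESSABLE, None, None)
    target = _canonical(taxon_samples, leaves)
    supports = bipartition_supports(tree)
    if target in supports:
        support = supports[target]
        ok = support is not None and support > support_threshold
        return MonophylyResult(taxon, SUCCESS if ok else FAILURE, support, len(taxon_samples))
    # No exact edge: report the smallest clade containing the taxon.
    best = len(leaves)
    for node in tree.traverse(include_self=True):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if taxon_samples <= side and len(side) < best:
            best = len(side)
        complement = leaves - side
        if taxon_samples <= complement and len(complement) < best:
            best = len(complement)
    return MonophylyResult(taxon, FAILURE, None, best)


_COMMENT_AFTER_LENGTH = re.compile(r"\)(:[0-9.eE+\-]+)\[([0-9.]+)\]")
_COMMENT_BEFORE_LENGTH = re.compile(r"\)\[([0-9.]+)\]")


def read_tree(source: str | Path, dialect: str = "node-label") -> TreeNode:
    """Read a newick tree with supports.

    ``dialect='node-label'`` (default): supports are internal node labels,
    e.g. ``(a,b)95:0.1``.  ``dialect='comment'``: supports are bracketed
    comments on internal edges, e.g. ``(a,b):0.1[95]`` or ``(a,b)[95]:0.1``;
    they are rewritten to node labels before parsing.
    """
    path = Path(source)
    text = path.read_text() if path.exists() else str(source)
    if dialect == "comment":
        text = _COMMENT_AFTER_LENGTH.sub(r")\2\1", text)
        text = _COMMENT_BEFORE_LENGTH.sub(r")\1", text)
    elif dialect != "node-label":
        raise FormatError(f"unknown newick support dialect {dialect!r}")
    try:
        return TreeNode.read(io.StringIO(text), convert_underscores=False)
    except Exception as exc:
        raise FormatError(f"unreadable newick: {exc}") from exc


def write_tree(tree: TreeNode, path: str | Path) -> None:
    with open(path, "w") as fh:
        tree.write(fh)


def monophyly_table(results: list[MonophylyResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon": r.taxon,
                "status": r.status,
                "support": r.support,
                "smallest_clade_size": r.smallest_clade_size,
            }
            for r in results
        ]
    )
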