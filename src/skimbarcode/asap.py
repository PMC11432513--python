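"""ASAP-style automatic species partitioning on a distance matrix.

This is a self-contained surrogate for the published ASAP web service, built
on the same skeleton: single-linkage hierarchical clustering yields a nested
ladder of candidate partitions (one per distinct merge threshold, from
all-singletons to one group), and every non-trivial candidate is scored by
two ranked components whose average is the "asap score" (lower = better):

* gap width  w = min between-group distance - max within-group distance,
  ranked descending (wide barcode gaps are good);
* a panmixia probability, here a seeded permutation test: the probability
  that a random relabelling of the samples (group sizes preserved) achieves
  a gap width strictly wider than the observed one, ranked ascending.
  (Strict comparison matters: with few groups a random relabelling
  occasionally recreates the candidate itself, and counting those equal-gap
  events would penalize exactly the well-separated partitions the score is
  meant to find.)

The original program's coalescent-derived panmixia probability is replaced
by this permutation test; interfaces and interpretation (candidate
partitions, two ranked components, averaged-rank score) are preserved, but
exact reproduction of the web server's partitions or scores is a non-goal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import rankdata

from .distances import DistanceMatrix
from .errors import SaturationError
from .trees import FAILURE, SUCCESS
from .delimit import DelimitationResult, TaxonVerdict

logger = logging.getLogger(__name__)


@dataclass
class PartitionCandidate:
    threshold: float
    grouping: dict[str, int]  # sample -> group id (1-based, arbitrary)
    n_groups: int
    gap_width: float | None = None
    panmixia_p: float | None = None
    rank_w: float | None = None
    rank_p: float | None = None
    asap_score: float | None = None

    def groups(self) -> dict[int, frozenset]:
        out: dict[int, set] = {}
        for sample, gid in self.grouping.items():
            out.setdefault(gid, set()).add(sample)
        return {gid: frozenset(members) for gid, members in out.items()}


def _canonical_labels(labels: np.ndarray) -> tuple:
    """Group labels renumbered by first appearance, for deduplication."""
    mapping: dict[int, int] = {}
    out = []
    for l in labels:
        mapping.setdefault(int(l), len(mapping) + 1)
        out.append(mapping[int(l)])
    return tuple(out)


def build_partition_ladder(matrix: DistanceMatrix) -> list[PartitionCandidate]:
    """Nested partitions from single-linkage clustering at every midpoint
    between consecutive distinct pairwise distances (plus both trivial ends).

    Duplicate groupings are removed; the result runs from all-singletons to
    one all-inclusive group and each partition refines the next coarser one.
    """
    if matrix.n < 3:
        raise ValueError("partition ladder needs >= 3 samples")
    if matrix.n_masked_pairs:
        raise SaturationError("distance matrix has masked pairs")
    condensed = matrix.condensed()
    Z = linkage(condensed, method="single")
    distinct = np.unique(condensed)
    thresholds = [-1.0]  # strictly below every distance: all singletons
    thresholds += [
        (lo + hi) / 2.0 for lo, hi in zip(distinct[:-1], distinct[1:])
    ]
    thresholds.append(float(distinct[-1]) + 1.0)  # everything in one group

    ladder: list[PartitionCandidate] = []
    seen: set[tuple] = set()
    for t in thresholds:
        if t < 0:
            labels = np.arange(1, matrix.n + 1)
        else:
            labels = fcluster(Z, t=t, criterion="distance")
        key = _canonical_labels(labels)
        if key in seen:
            continue
        seen.add(key)
        ladder.append(
            PartitionCandidate(
                threshold=float(t),
                grouping=dict(zip(matrix.labels, (int(l) for l in labels))),
                n_groups=int(len(set(labels))),
            )
        )
    return ladder


def _gap_width(condensed: np.ndarray, within: np.ndarray) -> float:
    return float(condensed[~within].min() - condensed[within].max())


def score_partitions(
    ladder: list[PartitionCandidate],
    matrix: DistanceMatrix,
    n_permutations: int = 999,
    seed: int | None = None,
) -> list[PartitionCandidate]:
    """Score all non-trivial candidates (2 <= groups <= n-1), lowest first.

    Ties in either component share the mean rank.  With no non-trivial
    candidate (e.g. all distances equal) an empty list is returned with a
    logged notice.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if n_permutations < 99:
        logger.warning(
            "n_permutations=%d is low; panmixia probabilities will be coarse",
            n_permutations,
        )
    n = matrix.n
    condensed = matrix.condensed()
    ii, jj = np.triu_indices(n, k=1)
    candidates = [c for c in ladder if 2 <= c.n_groups <= n - 1]
    if not candidates:
        logger.info("no non-trivial partition candidates to score")
        return []
    rng = np.random.default_rng(seed)
    for cand in candidates:
        labels = np.array([cand.grouping[s] for s in matrix.labels])
        within = labels[ii] == labels[jj]
        w_obs = _gap_width(condensed, within)
        cand.gap_width = w_obs
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(labels)
            w_perm = _gap_width(condensed, perm[ii] == perm[jj])
            if w_perm > w_obs:
                hits += 1
        cand.panmixia_p = (1.0 + hits) / (n_permutations + 1.0)
    rank_w = rankdata([-c.gap_width for c in candidates], method="average")
    rank_p = rankdata([c.panmixia_p for c in candidates], method="average")
    for cand, rw, rp in zip(candidates, rank_w, rank_p):
        cand.rank_w = float(rw)
        cand.rank_p = float(rp)
        cand.asap_score = (float(rw) + float(rp)) / 2.0
    return sorted(candidates, key=lambda c: (c.asap_score, c.n_groups))


def asap_taxon_verdicts(
    best: PartitionCandidate, metadata: pd.DataFrame, code: str = ""
) -> DelimitationResult:
    """A taxon succeeds iff some group equals exactly its sample set
    (all individuals of the taxon in one OTU, and nothing else in it)."""
    groups = set(best.groups().values())
    verdicts = []
    for taxon in sorted(metadata["taxon"].unique()):
        members = frozenset(metadata.loc[metadata["taxon"] == taxon, "sample_id"])
        ok = members in groups
        verdicts.append(
            TaxonVerdict(taxon, SUCCESS if ok else FAILURE, matching_group=ok)
        )
    return DelimitationResult(code=code, method="asap", verdicts=verdicts)


def candidate_table(candidates: list[PartitionCandidate], top: int = 10) -> pd.DataFrame:
    """Ranked-candidate table (one row per candidate, best first)."""
    rows = []
    for rank, c in enumerate(candidates[:top], start=1):
        sizes = sorted((len(g) for g in c.groups().values()), reverse=True)
        rows.append(
            {
                "rank": rank,
                "n_groups": c.n_groups,
                "asap_score": c.asap_score,
                "gap_width": c.gap_width,
                "panmixia_p": c.panmixia_p,
                "threshold": c.threshold,
                "group_sizes": ",".join(map(str, sizes)),
            }
        )
    return pd.DataFrame(rows)


def partition_table(candidates: list[PartitionCandidate], top: int = 10) -> pd.DataFrame:
    """Partition-overview table: columns = top candidates, cells = group sizes."""
    data = {}
    for rank, c in enumerate(candidates[:top], start=1):
        sizes = sorted((len(g) for g in c.groups().values()), reverse=True)
        data[f"candidate_{rank} (score={c.asap_score:.2f})"] = pd.Series(sizes)
    return pd.DataFrame(data)
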