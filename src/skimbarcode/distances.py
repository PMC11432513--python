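"""Kimura 2-parameter distances: pairwise, matrix, and population level.

The K2P distance between two aligned sequences is

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

with P and Q the proportions of transition- and transversion-differing
sites among pairwise-complete sites (both bases unambiguous).  Missing data
are handled by pairwise deletion by default; complete deletion is available
by flag.  Pairs where the logarithm's argument is non-positive are
*saturated*: they are masked in matrices (and downstream criteria that need
them must fail loudly) rather than clamped.

Population-level divergence is the average K2P distance over all
cross-population sequence pairs, with a column bootstrap for its standard
error (distances are functions of alignment columns, so resampling columns
is the matching resampling scheme).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio

from .alphabet import encode
from .errors import SaturationError
from .seqio import ConcatenatedDataSet, RegionAlignment

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with an unavailability mask.

    ``mask[i, j]`` is True when the pair's distance is undefined
    (saturation); the diagonal is zero and never masked.
    """

    labels: list[str]
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        assert self.values.shape == (n, n) and self.mask.shape == (n, n)

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_masked_pairs(self) -> int:
        iu = np.triu_indices(self.n, k=1)
        return int(self.mask[iu].sum())

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(
            labels=list(labels),
            values=self.values[np.ix_(idx, idx)].copy(),
            mask=self.mask[np.ix_(idx, idx)].copy(),
        )

    def condensed(self) -> np.ndarray:
        if self.n_masked_pairs:
            raise SaturationError("matrix has masked (saturated) pairs")
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_skbio(self) -> skbio.DistanceMatrix:
        if self.n_masked_pairs:
            raise SaturationError("matrix has masked (saturated) pairs")
        return skbio.DistanceMatrix(self.values, ids=self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        return df.mask(pd.DataFrame(self.mask, index=self.labels, columns=self.labels))


@dataclass
class PopulationDivergence:
    population_a: str
    population_b: str
    mean: float
    se: float
    n_pairs: int


def _k2p_from_counts(n_ts: float, n_tv: float, n_sites: float):
    """K2P distance from site counts; returns (d, saturated_flag)."""
    P = n_ts / n_sites
    Q = n_tv / n_sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return np.nan, True
    return float(-0.5 * np.log(w1 * np.sqrt(w2))), False


def pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(transitions, transversions, comparable sites) between encoded seqs."""
    valid = (a < 4) & (b < 4)
    diff = valid & (a != b)
    ts = diff & ((a ^ 2) == b)  # A<->G / C<->T under the 0..3 encoding
    n_ts = int(ts.sum())
    n_diff = int(diff.sum())
    return n_ts, n_diff - n_ts, int(valid.sum())


def k2p_distance(seq_a: str | np.ndarray, seq_b: str | np.ndarray) -> float:
    """K2P distance between two equal-length sequences (pairwise deletion)."""
    a = encode(seq_a) if isinstance(seq_a, str) else seq_a
    b = encode(seq_b) if isinstance(seq_b, str) else seq_b
    if a.size != b.size:
        raise ValueError("sequences must have equal aligned length")
    n_ts, n_tv, n_sites = pair_counts(a, b)
    if n_sites == 0:
        raise SaturationError("no pairwise-complete sites")
    d, saturated = _k2p_from_counts(n_ts, n_tv, n_sites)
    if saturated:
        raise SaturationError(
            f"saturated pair: P={n_ts / n_sites:.3f}, Q={n_tv / n_sites:.3f}"
        )
    return d


def _encoded(alignment, sample_subset):
    aln = alignment.alignment if isinstance(alignment, ConcatenatedDataSet) else alignment
    if sample_subset is not None:
        aln = aln.subset(sample_subset)
    return aln, aln.encoded()


def pairwise_matrix(
    alignment: ConcatenatedDataSet | RegionAlignment,
    sample_subset: list[str] | None = None,
    deletion: str = "pairwise",
) -> DistanceMatrix:
    """K2P distance matrix over all samples of an alignment.

    Saturated pairs are masked with a logged warning.  A sample with zero
    comparable sites against every other sample is an error (it would mask a
    whole row).  ``deletion='complete'`` first drops every column containing
    any missing/ambiguous character.
    """
    aln, enc = _encoded(alignment, sample_subset)
    if aln.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if deletion == "complete":
        enc = enc[:, (enc < 4).all(axis=0)]
    elif deletion != "pairwise":
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    n = aln.n_samples
    values = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    comparable = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            n_ts, n_tv, n_sites = pair_counts(enc[i], enc[j])
            comparable[i] += n_sites
            comparable[j] += n_sites
            if n_sites == 0:
                mask[i, j] = mask[j, i] = True
                continue
            d, saturated = _k2p_from_counts(n_ts, n_tv, n_sites)
            if saturated:
                logger.warning(
                    "saturated pair masked: %s vs %s", aln.samples[i], aln.samples[j]
                )
                mask[i, j] = mask[j, i] = True
            else:
                values[i, j] = values[j, i] = d
    dead = [aln.samples[i] for i in range(n) if comparable[i] == 0]
    if dead:
        raise SaturationError(f"samples with zero comparable sites: {dead}")
    return DistanceMatrix(labels=list(aln.samples), values=values, mask=mask)


def _population_pairs(samples: list[str], metadata: pd.DataFrame):
    pop_of = dict(zip(metadata["sample_id"], metadata["population"]))
    pops = sorted({pop_of[s] for s in samples})
    idx_of_pop = {p: [i for i, s in enumerate(samples) if pop_of[s] == p] for p in pops}
    return pops, idx_of_pop


def population_divergence(
    alignment: ConcatenatedDataSet | RegionAlignment,
    metadata: pd.DataFrame,
    B: int = 1000,
    seed: int | None = None,
    include_within: bool = True,
) -> list[PopulationDivergence]:
    """Mean K2P divergence between (and within) populations with bootstrap SE.

    The bootstrap resamples alignment columns with replacement ``B`` times
    (implemented as multinomial column weights, which is equivalent and
    vectorizes).  Within-population entries average the population's internal
    pairs; populations with a single sample report NaN within-distance.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    aln, enc = _encoded(alignment, None)
    rng = np.random.default_rng(seed)
    pops, idx_of_pop = _population_pairs(aln.samples, metadata)
    L = enc.shape[1]

    # Per-pair per-column indicators; weighted sums give bootstrap counts.
    pair_list: list[tuple[int, int]] = []
    for i in range(len(aln.samples)):
        for j in range(i + 1, len(aln.samples)):
            pair_list.append((i, j))
    ii = np.array([p[0] for p in pair_list])
    jj = np.array([p[1] for p in pair_list])
    a, b = enc[ii], enc[jj]
    valid = (a < 4) & (b < 4)
    diff = valid & (a != b)
    ts = diff & ((a ^ 2) == b)
    tv = diff & ~ts

    def pair_k2p(weights: np.ndarray) -> np.ndarray:
        n_sites = valid @ weights
        n_ts = ts @ weights
        n_tv = tv @ weights
        with np.errstate(divide="ignore", invalid="ignore"):
            P = n_ts / n_sites
            Q = n_tv / n_sites
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            d = -0.5 * np.log(w1 * np.sqrt(w2))
        d[(n_sites == 0) | (w1 <= 0) | (w2 <= 0)] = np.nan
        return d

    d_obs = pair_k2p(np.ones(L))
    boot = np.empty((B, len(pair_list)))
    for rep in range(B):
        weights = rng.multinomial(L, np.full(L, 1.0 / L)).astype(float)
        boot[rep] = pair_k2p(weights)

    pair_index = {(i, j): k for k, (i, j) in enumerate(pair_list)}

    def collect(idx_a, idx_b, same: bool):
        ks = []
        for x in idx_a:
            for y in idx_b:
                if same and y <= x:
                    continue
                ks.append(pair_index[(min(x, y), max(x, y))])
        return ks

    out: list[PopulationDivergence] = []
    for pi, pa in enumerate(pops):
        for pb in pops[pi + (0 if include_within else 1):]:
            same = pa == pb
            ks = collect(idx_of_pop[pa], idx_of_pop[pb], same)
            if not ks:
                out.append(PopulationDivergence(pa, pb, float("nan"), float("nan"), 0))
                continue
            mean = float(np.nanmean(d_obs[ks]))
            boot_means = np.nanmean(boot[:, ks], axis=1)
            se = float(np.nanstd(boot_means, ddof=1)) if B > 1 else 0.0
            out.append(PopulationDivergence(pa, pb, mean, se, len(ks)))
    return out


def population_matrix(divergences: list[PopulationDivergence]) -> pd.DataFrame:
    """Square population-by-population table of mean K2P distances."""
    pops = sorted({d.population_a for d in divergences} | {d.population_b for d in divergences})
    df = pd.DataFrame(np.nan, index=pops, columns=pops)
    for d in divergences:
        df.loc[d.population_a, d.population_b] = d.mean
        df.loc[d.population_b, d.population_a] = d.mean
    return df


def combined_population_table(
    lower: list[PopulationDivergence], upper: list[PopulationDivergence]
) -> pd.DataFrame:
    """Heat-map style table: lower triangle from one data set, upper from another.

    Mirrors the common presentation where two marker systems share one
    population-by-population table; the diagonal carries the lower set's
    within-population means.
    """
    ml, mu = population_matrix(lower), population_matrix(upper)
    pops = list(ml.index)
    combined = ml.copy()
    for i, pa in enumerate(pops):
        for j, pb in enumerate(pops):
            if j > i:
                combined.loc[pa, pb] = mu.loc[pa, pb] if pb in mu.columns and pa in mu.index else np.nan
    return combined
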