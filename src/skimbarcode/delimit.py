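"""Distance-based barcoding-gap test and discrimination-rate aggregation.

A taxon passes the distance criterion when its minimum interspecific K2P
distance (over all pairs of one member and one non-member) strictly exceeds
its maximum intraspecific distance (over all member pairs).  Verdicts from
the tree, distance and partitioning methods aggregate into a per-data-set
discrimination table; taxa that are not assessable (singletons) count as
failures so every cell shares the same denominator (the taxon count).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .errors import DelimitationError
from .trees import FAILURE, NOT_ASSESSABLE, SUCCESS
from .variability import percentage

METHODS = ("tree", "distance", "asap")


@dataclass
class TaxonVerdict:
    taxon: str
    status: str  # success | failure | not_assessable
    max_intra: float | None = None
    min_inter: float | None = None
    support: float | None = None
    matching_group: bool | None = None


@dataclass
class DelimitationResult:
    code: str
    method: str
    verdicts: list[TaxonVerdict]

    @property
    def n_success(self) -> int:
        return sum(v.status == SUCCESS for v in self.verdicts)

    @property
    def n_taxa(self) -> int:
        return len(self.verdicts)


def barcoding_gap_test(
    matrix: DistanceMatrix, metadata: pd.DataFrame, taxon: str
) -> TaxonVerdict:
    """Distance-based verdict for one taxon (pairwise extremes, strict >)."""
    pop = dict(zip(metadata["sample_id"], metadata["taxon"]))
    members = [i for i, s in enumerate(matrix.labels) if pop.get(s) == taxon]
    others = [i for i, s in enumerate(matrix.labels) if pop.get(s) != taxon]
    if not members:
        raise ValueError(f"taxon {taxon!r} has no samples in the matrix")
    if not others:
        raise ValueError(f"taxon {taxon!r} covers the whole matrix")
    if len(members) < 2:
        return TaxonVerdict(taxon, NOT_ASSESSABLE)
    intra_idx = np.ix_(members, members)
    inter_idx = np.ix_(members, others)
    if matrix.mask[intra_idx].any() or matrix.mask[inter_idx].any():
        raise DelimitationError(
            f"taxon {taxon!r}: required distance pairs are masked (saturation)"
        )
    intra = matrix.values[intra_idx]
    max_intra = float(intra[np.triu_indices(len(members), k=1)].max())
    min_inter = float(matrix.values[inter_idx].min())
    status = SUCCESS if min_inter > max_intra else FAILURE
    return TaxonVerdict(taxon, status, max_intra=max_intra, min_inter=min_inter)


def distance_delimitation(
    matrix: DistanceMatrix, metadata: pd.DataFrame, code: str
) -> DelimitationResult:
    taxa = sorted(metadata["taxon"].unique())
    return DelimitationResult(
        code=code,
        method="distance",
        verdicts=[barcoding_gap_test(matrix, metadata, t) for t in taxa],
    )


def summarize_discrimination(results: list[DelimitationResult]) -> pd.DataFrame:
    """Discrimination-rate table: rows = data sets, columns = methods.

    Cells hold ``k/n (xx.xx%)`` where n is the full taxon count; verdict
    lists must all cover the same taxon set.
    """
    if not results:
        raise ValueError("no delimitation results to summarize")
    taxon_sets = {frozenset(v.taxon for v in r.verdicts) for r in results}
    if len(taxon_sets) != 1:
        raise ValueError("delimitation results reference different taxon sets")
    codes = sorted({r.code for r in results})
    methods = [m for m in METHODS if any(r.method == m for r in results)]
    table = pd.DataFrame(index=codes, columns=methods, dtype=object)
    table.index.name = "data_set"
    for r in results:
        rate = percentage(r.n_success, r.n_taxa, decimals=2)
        table.loc[r.code, r.method] = f"{r.n_success}/{r.n_taxa} ({rate:.2f}%)"
    return table


def discrimination_rate(n_success: int, n_taxa: int) -> float:
    """Success rate in percent, 2 decimals, half-up (3/6 -> 50.00)."""
    return percentage(n_success, n_taxa, decimals=2)


def verdict_table(results: list[DelimitationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for v in r.verdicts:
            rows.append(
                {
                    "data_set": r.code,
                    "method": r.method,
                    "taxon": v.taxon,
                    "status": v.status,
                    "max_intra": v.max_intra,
                    "min_inter": v.min_inter,
                    "support": v.support,
                    "matching_group": v.matching_group,
                }
            )
    return pd.DataFrame(rows)
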