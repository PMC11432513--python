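"""Principal coordinate analysis (classical MDS) of a distance matrix.

Standard Gower double-centering: B = -1/2 * J * D^2 * J with J the centering
operator; coordinates are eigenvectors scaled by the square root of their
(positive) eigenvalues.  Negative eigenvalues - evidence that the distances
are not perfectly Euclidean - are reported and their axes dropped, with no
Lingoes/Cailliez correction applied.  The sign of each axis is fixed by
making its largest-magnitude loading positive, so output is reproducible
across platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .errors import SaturationError

logger = logging.getLogger(__name__)

_EIG_TOL = 1e-10  # relative threshold separating "positive" from numerical zero


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x axes ("PCo1", ...)
    eigenvalues: np.ndarray  # all eigenvalues, sorted descending
    pct_explained: np.ndarray  # per retained axis, % of positive eigenvalue sum
    negative_eigenvalues: np.ndarray  # the negative tail, for distortion checks

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]


def pcoa(matrix: DistanceMatrix, k: int = 2) -> PCoAResult:
    """Embed a distance matrix into k principal coordinate axes.

    If fewer than k positive eigenvalues exist, k is truncated with a
    warning.  Coordinates are centered (column means zero) by construction.
    """
    if matrix.n < 3:
        raise ValueError("PCoA needs >= 3 samples")
    if matrix.n_masked_pairs:
        raise SaturationError("distance matrix has masked pairs")
    n = matrix.n
    D2 = matrix.values.astype(float) ** 2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    scale = max(abs(eigval[0]), 1.0)
    positive = eigval > _EIG_TOL * scale
    n_pos = int(positive.sum())
    if k > n_pos:
        logger.warning("only %d positive eigenvalues; truncating k from %d", n_pos, k)
        k = n_pos
    coords = eigvec[:, :k] * np.sqrt(eigval[:k]) if k else np.zeros((n, 0))
    for axis in range(k):
        col = coords[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    pos_sum = eigval[positive].sum()
    pct = 100.0 * eigval[:k] / pos_sum if k else np.array([])
    negatives = eigval[eigval < -_EIG_TOL * scale]
    if negatives.size:
        logger.info(
            "PCoA: %d negative eigenvalues (largest magnitude %.3g); "
            "distances are not perfectly Euclidean",
            negatives.size,
            float(-negatives.min()),
        )
    return PCoAResult(
        coordinates=pd.DataFrame(
            coords, index=matrix.labels, columns=[f"PCo{i+1}" for i in range(k)]
        ),
        eigenvalues=eigval,
        pct_explained=np.asarray(pct),
        negative_eigenvalues=negatives,
    )


def coordinates_table(result: PCoAResult, metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Coordinates joined with sample metadata, ready for plotting."""
    df = result.coordinates.copy()
    df.index.name = "sample_id"
    df = df.reset_index()
    if metadata is not None:
        df = df.merge(metadata, on="sample_id", how="left")
    return df
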