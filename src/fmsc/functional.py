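"""Functional connectivity networks, sparsification, and node graph metrics.

The functional connectivity network (FCN) correlates parcel-averaged
resting-state time series between all region pairs.  Thresholding the FCN at
an edge-strength cutoff yields a binary adjacency whose node degrees (ND)
summarize hub structure; node strength (NS) sums the signed edge weights of
the unthresholded FCN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fmsc.core import Connectome, FmscError, ParcelTimeSeries

#: Edge-strength cutoffs applied to the FCN before computing node degree.
DEFAULT_THRESHOLDS: tuple[float, ...] = (0.4, 0.5, 0.6, 0.7, 0.8)


@dataclass
class SparsifiedAdjacency:
    """Binary undirected adjacency from thresholding an FCN."""

    matrix: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise FmscError("adjacency must be square")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise FmscError("adjacency must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise FmscError("adjacency diagonal must be 0")
        if not np.all(np.isin(self.matrix, (0, 1))):
            raise FmscError("adjacency entries must be binary")
        if not (0.0 < self.threshold < 1.0):
            raise FmscError(f"threshold must lie in (0, 1), got {self.threshold}")

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]


def build_fcn(
    ts: ParcelTimeSeries, region_ids: tuple[str, ...] | None = None
) -> Connectome:
    """Pearson-correlation FCN from a regions x timepoints matrix."""
    values = ts.values
    if region_ids is None:
        region_ids = tuple(f"region_{i:02d}" for i in range(ts.n_regions))
    sd = values.std(axis=1)
    # relative guard: a numerically constant row (sd at rounding level of its
    # mean) leaves the correlation undefined just as an exactly constant one
    flat = np.flatnonzero(sd <= 1e-12 * (np.abs(values.mean(axis=1)) + 1.0))
    if flat.size:
        raise FmscError(
            f"region {region_ids[flat[0]]!r} has zero-variance time series for "
            f"subject {ts.subject_id}: correlation undefined"
        )
    r = np.corrcoef(values)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return Connectome(r, region_ids, "FCN")


def sparsify(
    fcn: Connectome, threshold: float, use_abs: bool = False
) -> SparsifiedAdjacency:
    """Binarize an FCN: edge present iff its correlation passes ``threshold``.

    By default the signed correlation is compared (r >= threshold), which
    drops both weak and negative edges; ``use_abs=True`` compares |r| instead.
    """
    if fcn.kind != "FCN":
        raise FmscError(f"sparsify expects an FCN, got kind {fcn.kind!r}")
    if not (0.0 < threshold < 1.0):
        raise FmscError(f"threshold must lie in (0, 1), got {threshold}")
    r = np.abs(fcn.matrix) if use_abs else fcn.matrix
    a = (r >= threshold).astype(int)
    np.fill_diagonal(a, 0)
    return SparsifiedAdjacency(a, threshold)


def node_degree(a: SparsifiedAdjacency) -> np.ndarray:
    """Edges incident on each node of a binarized network."""
    return a.matrix.sum(axis=1)


def node_strength(fcn: Connectome, positive_only: bool = False) -> np.ndarray:
    """Sum of signed edge weights incident on each node of the weighted FCN.

    The unit self-correlation on the diagonal is excluded.  With
    ``positive_only=True`` negative correlations are ignored rather than
    subtracted.
    """
    if fcn.kind != "FCN":
        raise FmscError(f"node_strength expects an FCN, got kind {fcn.kind!r}")
    w = fcn.matrix.copy()
    np.fill_diagonal(w, 0.0)
    if positive_only:
        w = np.clip(w, 0.0, None)
    return w.sum(axis=1)
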