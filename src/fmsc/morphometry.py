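"""Curvature-derived anatomical indices and morphometric similarity networks.

A morphometric similarity network (MSN) correlates the anatomical profiles of
pairs of cortical regions: each region carries a vector of measures (surface
area, gray-matter volume, thickness statistics, curvature indices, ...), each
measure is z-scored across regions to remove scale differences between
measures, and the Pearson correlation between two regions' z-scored profiles
becomes the network edge weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from fmsc.core import Connectome, FmscError, MorphometryTable


@dataclass
class CurvatureField:
    """Principal-curvature samples over a surface patch.

    ``kappa1`` is the maximum and ``kappa2`` the minimum principal curvature
    (both in 1/mm), so ``kappa1 >= kappa2`` element-wise.
    """

    kappa1: np.ndarray
    kappa2: np.ndarray

    def __post_init__(self) -> None:
        self.kappa1 = np.atleast_1d(np.asarray(self.kappa1, dtype=float))
        self.kappa2 = np.atleast_1d(np.asarray(self.kappa2, dtype=float))
        if self.kappa1.shape != self.kappa2.shape:
            raise FmscError(
                f"curvature length mismatch: {self.kappa1.shape} vs {self.kappa2.shape}"
            )
        if self.kappa1.size < 1:
            raise FmscError("curvature field must be non-empty")
        if np.any(self.kappa1 < self.kappa2):
            raise FmscError("kappa1 (maximum curvature) must be >= kappa2 element-wise")


def mean_curvature(f: CurvatureField, rectify: bool = False) -> np.ndarray:
    """Mean curvature (kappa1 + kappa2) / 2.

    ``rectify=True`` returns the absolute value, for pipelines whose upstream
    surface extraction reports rectified curvature.
    """
    mc = (f.kappa1 + f.kappa2) / 2.0
    return np.abs(mc) if rectify else mc


def gaussian_curvature(f: CurvatureField, rectify: bool = False) -> np.ndarray:
    """Gaussian curvature kappa1 * kappa2, an intrinsic surface curvature."""
    gc = f.kappa1 * f.kappa2
    return np.abs(gc) if rectify else gc


def folding_index(f: CurvatureField) -> np.ndarray:
    """Folding index |kappa1| * (|kappa1| - |kappa2|), a gyrification measure."""
    a1, a2 = np.abs(f.kappa1), np.abs(f.kappa2)
    return a1 * (a1 - a2)


def region_reduce(values: np.ndarray) -> float:
    """Aggregate vertex-wise values to one region value (arithmetic mean)."""
    return float(np.mean(values))


def zscore_across_regions(
    values: Sequence[float], ddof: int = 1, name: str = "feature"
) -> np.ndarray:
    """Z-score one measure across regions: (A_i - mean) / sd.

    The standard deviation uses the sample (n-1) convention by default;
    pass ``ddof=0`` for the population convention.  A constant measure cannot
    be normalized and raises an error naming it.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise FmscError("zscore_across_regions expects a 1-D per-region vector")
    if v.size < 2:
        raise FmscError("need at least 2 regions to z-score")
    sd = v.std(ddof=ddof)
    if sd <= 1e-12 * (abs(v.mean()) + 1.0) or not np.isfinite(sd):
        raise FmscError(f"cannot z-score {name!r}: zero variance across regions")
    return (v - v.mean()) / sd


def _zscore_columns(values: np.ndarray, names: Sequence[str], ddof: int = 1) -> np.ndarray:
    cols = [zscore_across_regions(values[:, k], ddof=ddof, name=names[k]) for k in range(values.shape[1])]
    return np.column_stack(cols)


def similarity_from_node_features(
    features: np.ndarray,
    region_ids: tuple[str, ...],
    channel_names: Sequence[str],
    kind: str,
    ddof: int = 1,
) -> Connectome:
    """Pearson-correlation similarity network from a regions x channels grid.

    Each channel is z-scored across regions first; the (i, j) entry is then
    the Pearson correlation between region i's and region j's channel
    profiles.  Shared by MSN and FMSC construction so that the FMSC restricted
    to anatomical channels reduces exactly to the MSN.
    """
    if features.shape[1] < 2:
        raise FmscError("need at least 2 channels to correlate region profiles")
    z = _zscore_columns(features, list(channel_names), ddof=ddof)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(z)
    if not np.all(np.isfinite(r)):
        flat = np.argwhere(~np.isfinite(r))
        i = int(flat[0][0])
        raise FmscError(
            f"correlation undefined: region {region_ids[i]!r} has a constant "
            "profile across the selected channels"
        )
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return Connectome(r, tuple(region_ids), kind)


def build_msn(
    t: MorphometryTable,
    metrics: Sequence[str] | None = None,
    region_ids: tuple[str, ...] | None = None,
    ddof: int = 1,
) -> Connectome:
    """Build a morphometric similarity network from one subject's table.

    Parameters
    ----------
    t
        Per-subject regions x metrics table.
    metrics
        Subset of metric names to use (default: all columns of ``t``).  At
        least two are required; with exactly two every off-diagonal entry is
        forced to +/-1, so a warning is emitted.
    region_ids
        Region labels for the resulting connectome; defaults to generic
        positional labels when not given.
    """
    if metrics is None:
        metrics = t.metric_names
    metrics = tuple(metrics)
    if len(metrics) < 2:
        raise FmscError("build_msn needs at least 2 metrics")
    if len(metrics) == 2:
        warnings.warn(
            "MSN from exactly 2 metrics: every correlation is forced to +/-1",
            stacklevel=2,
        )
    missing = [m for m in metrics if m not in t.metric_names]
    if missing:
        raise FmscError(f"metric(s) {missing} not present in table for {t.subject_id}")
    cols = [t.metric_names.index(m) for m in metrics]
    features = t.values[:, cols]
    if region_ids is None:
        region_ids = tuple(f"region_{i:02d}" for i in range(t.n_regions))
    return similarity_from_node_features(features, region_ids, metrics, "MSN", ddof=ddof)
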