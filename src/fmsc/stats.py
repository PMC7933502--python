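"""Group statistics: two-sample t-tests, Holm-Sidak FWE correction,
region-by-metric screening, and fold-internal univariate feature selection.

Two distinct uses of the t-test coexist here and must not be conflated: the
anatomical screen tests every (region, metric) cell and controls the
family-wise error rate with the Holm-Sidak step-down procedure, while the
per-fold feature selection inside cross-validation keeps every edge feature
with raw p < alpha, uncorrected, by design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from fmsc.core import FmscError, MorphometryTable


def two_sample_t(
    x: Sequence[float], y: Sequence[float], variant: str = "pooled"
) -> tuple[float, float]:
    """Two-sided two-sample t-test; t > 0 when mean(x) > mean(y).

    ``variant='pooled'`` is the classic equal-variance Student test;
    ``'welch'`` drops the equal-variance assumption.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise FmscError("two_sample_t needs at least 2 observations per group")
    if variant not in ("pooled", "welch"):
        raise FmscError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        raise FmscError("degenerate samples: zero variance in both groups")
    res = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    t, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(t):
        raise FmscError("t-statistic undefined for the given samples")
    return t, max(p, np.finfo(float).tiny)


def holm_sidak_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values, in the input order.

    Sort the m raw p-values ascending; the i-th smallest (1-based) is
    adjusted to 1 - (1 - p_(i))^(m - i + 1); a running maximum then enforces
    monotonicity of the step-down sequence.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise FmscError("holm_sidak_adjust expects a non-empty 1-D vector")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise FmscError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    exponents = m - np.arange(m)
    adjusted_sorted = 1.0 - (1.0 - sorted_p) ** exponents
    adjusted_sorted = np.maximum.accumulate(adjusted_sorted)
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted


@dataclass
class ScreenResult:
    """Per-(region, metric) screening table with FWE-adjusted p-values."""

    table: pd.DataFrame  # columns: region_id, metric, t, raw_p, adjusted_p, significant
    alpha: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]].reset_index(drop=True)

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def any_significant(self) -> bool:
        return self.n_significant > 0


def _stack_cohort(cohort: Sequence[MorphometryTable]) -> np.ndarray:
    first = cohort[0]
    for t in cohort[1:]:
        if t.metric_names != first.metric_names or t.n_regions != first.n_regions:
            raise FmscError(
                f"subject {t.subject_id} has different regions/metrics from "
                f"{first.subject_id}"
            )
    return np.stack([t.values for t in cohort])


def region_metric_screen(
    cohort: Sequence[MorphometryTable],
    labels: Sequence[int],
    alpha: float = 0.05,
    variant: str = "pooled",
    region_ids: Sequence[str] | None = None,
) -> ScreenResult:
    """Screen every (region, metric) cell for a group difference.

    One two-sample t-test per cell; the Holm-Sidak correction is applied over
    the full family of regions x metrics tests jointly, and a cell is flagged
    significant when its adjusted p falls below ``alpha``.
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(cohort):
        raise FmscError("labels length does not match cohort size")
    values = _stack_cohort(cohort)  # subjects x regions x metrics
    g1 = values[labels == 1]
    g0 = values[labels == 0]
    if g0.shape[0] < 2 or g1.shape[0] < 2:
        raise FmscError("each group needs at least 2 subjects to test")
    res = sps.ttest_ind(g1, g0, axis=0, equal_var=(variant == "pooled"))
    t = np.asarray(res.statistic)
    p = np.asarray(res.pvalue)
    if np.any(~np.isfinite(t)):
        r, m = np.argwhere(~np.isfinite(t))[0]
        raise FmscError(
            f"t-test degenerate for region index {int(r)}, metric "
            f"{cohort[0].metric_names[int(m)]!r}"
        )
    adjusted = holm_sidak_adjust(p.ravel()).reshape(p.shape)
    metric_names = cohort[0].metric_names
    if region_ids is None:
        region_ids = [f"region_{i:02d}" for i in range(values.shape[1])]
    rows = []
    for r in range(values.shape[1]):
        for m, metric in enumerate(metric_names):
            rows.append(
                {
                    "region_id": region_ids[r],
                    "metric": metric,
                    "t": t[r, m],
                    "raw_p": p[r, m],
                    "adjusted_p": adjusted[r, m],
                    "significant": bool(adjusted[r, m] < alpha),
                }
            )
    return ScreenResult(pd.DataFrame(rows), alpha)


def feature_t_scores(
    X: np.ndarray, labels: Sequence[int], variant: str = "pooled"
) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise two-sample t and p over a subjects x features matrix.

    Degenerate columns (zero variance in both groups) yield t = 0, p = 1 so
    that selection simply skips them.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    res = sps.ttest_ind(X[labels == 1], X[labels == 0], axis=0, equal_var=(variant == "pooled"))
    t = np.nan_to_num(np.asarray(res.statistic, dtype=float), nan=0.0)
    p = np.asarray(res.pvalue, dtype=float)
    p[~np.isfinite(p)] = 1.0
    return t, p


def select_features_by_t(
    X: np.ndarray, labels: Sequence[int], alpha: float = 0.05
) -> np.ndarray:
    """Indices of features whose raw two-sided p < alpha (uncorrected).

    Intended for TRAINING folds only; the cross-validation driver guarantees
    the test fold never enters this computation.  May be empty.
    """
    _, p = feature_t_scores(X, labels)
    return np.flatnonzero(p < alpha)
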