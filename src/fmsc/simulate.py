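"""Synthetic two-group cohorts with known ground truth.

Generates per-subject morphometry tables and parcel time series whose
statistical structure mimics a two-group resting-state study: 34 regions
(17 networks x 2 hemispheres), ~200 usable volumes per scan, anatomical
measures at realistic scales with Gaussian subject noise, and
covariance-structured time series drawn from group-specific correlation
matrices.  Group effects are injected explicitly — per-(region, metric) mean
shifts in units of the subject noise SD, and per-edge correlation deltas —
and recorded as ground truth so that every downstream stage (screening,
network construction, classification, consensus reporting) can be validated
against what was actually planted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from fmsc.core import (
    CohortManifest,
    FmscError,
    METRIC_NAMES,
    MorphometryTable,
    Parcellation,
    ParcelTimeSeries,
)

# Per-metric (population mean, between-region spread, within-group subject
# noise SD).  Scales follow typical cortical-surface statistics: surface area
# in hundreds of mm^2 per parcel, gray-matter volume in thousands of mm^3,
# mean thickness near 2.5 mm, curvatures of order 0.1/mm.
METRIC_SCALES: dict[str, tuple[float, float, float]] = {
    "SA": (600.0, 150.0, 40.0),
    "GMV": (1800.0, 400.0, 120.0),
    "CT_avg": (2.5, 0.25, 0.12),
    "CT_sd": (0.5, 0.08, 0.05),
    "MC": (0.13, 0.02, 0.012),
    "GC": (0.025, 0.008, 0.004),
    "CI": (3.0, 0.8, 0.35),
    "FI": (2.0, 0.6, 0.25),
}


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults emulate a 23-vs-24 subject study over 34 functional parcels
    with 200 usable volumes per scan.  ``morph_effects`` lists
    (region index, metric, shift in subject-SD units) applied to group 1;
    ``fc_effects`` lists ((i, j), correlation delta) applied to group 1's
    target correlation matrix before positive-definite repair.
    """

    n_group0: int = 23
    n_group1: int = 24
    n_regions: int = 34
    n_timepoints: int = 200
    morph_effects: tuple[tuple[int, str, float], ...] = ()
    fc_effects: tuple[tuple[tuple[int, int], float], ...] = ()
    base_homotopic_r: float = 0.6
    base_block_r: float = 0.45
    base_background_r: float = 0.1
    ar1_phi: float = 0.0  # temporal autocorrelation; 0 = white
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group0 < 2 or self.n_group1 < 2:
            raise FmscError("each group needs at least 2 subjects")
        for region, metric, shift in self.morph_effects:
            if metric not in METRIC_NAMES:
                raise FmscError(f"morph effect names unknown metric {metric!r}")
            if not (0 <= region < self.n_regions):
                raise FmscError(f"morph effect region {region} out of range")
            if not np.isfinite(shift):
                raise FmscError("morph effect shift must be finite")
        for (i, j), delta in self.fc_effects:
            if not (0 <= i < j < self.n_regions):
                raise FmscError(f"fc effect edge ({i}, {j}) invalid (need 0 <= i < j < n)")
            if not np.isfinite(delta):
                raise FmscError("fc effect delta must be finite")
        if not (-1.0 < self.ar1_phi < 1.0):
            raise FmscError("ar1_phi must lie in (-1, 1)")

    @property
    def n_subjects(self) -> int:
        return self.n_group0 + self.n_group1

    @property
    def labels(self) -> np.ndarray:
        return np.asarray([0] * self.n_group0 + [1] * self.n_group1, dtype=int)

    @property
    def parcellation(self) -> Parcellation:
        if self.n_regions == 34:
            return Parcellation.yeo17_two_hemisphere()
        return Parcellation.generic(self.n_regions)


@dataclass
class GroundTruth:
    """The exact effects injected into a simulated cohort."""

    morph_effects: tuple[tuple[int, str, float], ...]
    fc_effects: tuple[tuple[tuple[int, int], float], ...]
    target_corr_group0: np.ndarray | None
    target_corr_group1: np.ndarray | None
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "morph_effects": [
                {"region": int(r), "metric": m, "shift_sd": float(s)}
                for r, m, s in self.morph_effects
            ],
            "fc_effects": [
                {"edge": [int(i), int(j)], "delta": float(d)}
                for (i, j), d in self.fc_effects
            ],
            "target_corr_group0": None
            if self.target_corr_group0 is None
            else self.target_corr_group0.tolist(),
            "target_corr_group1": None
            if self.target_corr_group1 is None
            else self.target_corr_group1.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _region_baselines(cfg: SimConfig) -> np.ndarray:
    """Region x metric baseline means: a fixed population template.

    Drawn from a dedicated fixed generator so that the template depends only
    on the parcellation size, not on the cohort seed — the seed varies the
    subjects, not the population they are drawn from.
    """
    rng = np.random.default_rng(1711)
    base = np.empty((cfg.n_regions, len(METRIC_NAMES)))
    for k, metric in enumerate(METRIC_NAMES):
        mean, spread, _ = METRIC_SCALES[metric]
        base[:, k] = mean + spread * rng.standard_normal(cfg.n_regions)
    return base


def simulate_morphometry(cfg: SimConfig) -> tuple[list[MorphometryTable], GroundTruth]:
    """Simulate per-subject morphometry tables for both groups.

    Values are region-specific baselines plus Gaussian subject noise; group-1
    subjects are additionally shifted by each configured effect, expressed in
    units of that metric's subject noise SD.
    """
    rng = np.random.default_rng([cfg.seed % (2**31), 23])
    baselines = _region_baselines(cfg)
    noise_sd = np.asarray([METRIC_SCALES[m][2] for m in METRIC_NAMES])
    shift = np.zeros_like(baselines)
    for region, metric, s in cfg.morph_effects:
        k = METRIC_NAMES.index(metric)
        shift[region, k] += s * noise_sd[k]
    tables = []
    for s_idx, label in enumerate(cfg.labels):
        values = baselines + noise_sd * rng.standard_normal(baselines.shape)
        if label == 1:
            values = values + shift
        tables.append(
            MorphometryTable(
                subject_id=f"sub-{s_idx:03d}",
                values=values,
                metric_names=METRIC_NAMES,
            )
        )
    truth = GroundTruth(cfg.morph_effects, cfg.fc_effects, None, None, cfg.seed)
    return tables, truth


def base_correlation_matrix(cfg: SimConfig) -> np.ndarray:
    """Block-structured target correlation shared by both groups.

    Homotopic pairs (same network, opposite hemisphere: indices 2i, 2i+1)
    correlate at ``base_homotopic_r``; blocks of four consecutive regions
    (two neighboring networks) at ``base_block_r``; everything else at the
    background level.
    """
    n = cfg.n_regions
    c = np.full((n, n), cfg.base_background_r)
    for start in range(0, n - (n % 4), 4):
        c[start : start + 4, start : start + 4] = cfg.base_block_r
    for i in range(0, n - 1, 2):
        c[i, i + 1] = c[i + 1, i] = cfg.base_homotopic_r
    np.fill_diagonal(c, 1.0)
    return c


def repair_positive_definite(
    c: np.ndarray, floor: float = 1e-6, max_iter: int = 100
) -> np.ndarray:
    """Nearest-ish correlation matrix: clip eigenvalues, renormalize diagonal.

    Iterates eigenvalue clipping (floor 1e-6) and unit-diagonal rescaling
    until the matrix is positive definite; raises if it fails to converge.
    """
    a = (c + c.T) / 2.0
    for _ in range(max_iter):
        w, v = np.linalg.eigh(a)
        if w.min() >= floor / 2:
            return a
        w = np.clip(w, floor, None)
        a = (v * w) @ v.T
        d = np.sqrt(np.diag(a))
        a = a / np.outer(d, d)
        a = (a + a.T) / 2.0
        np.fill_diagonal(a, 1.0)
    raise FmscError(
        "positive-definite repair did not converge; the configured fc_effects "
        "may be jointly infeasible"
    )


def group_target_correlations(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Positive-definite target correlation matrices for groups 0 and 1."""
    base = base_correlation_matrix(cfg)
    delta = np.zeros_like(base)
    for (i, j), d in cfg.fc_effects:
        delta[i, j] += d
        delta[j, i] += d
    perturbed = base + delta
    off = ~np.eye(len(base), dtype=bool)
    perturbed[off] = np.clip(perturbed[off], -0.99, 0.99)
    c0 = repair_positive_definite(base)
    c1 = repair_positive_definite(perturbed)
    return c0, c1


def simulate_timeseries(cfg: SimConfig) -> tuple[list[ParcelTimeSeries], GroundTruth]:
    """Simulate per-subject parcel time series for both groups.

    Each subject's series is drawn from a zero-mean multivariate normal with
    the group's target correlation matrix; samples are temporally white by
    default, or AR(1) with coefficient ``ar1_phi`` (which preserves the
    spatial correlation structure).
    """
    rng = np.random.default_rng([cfg.seed % (2**31), 37])
    c0, c1 = group_target_correlations(cfg)
    chol = {0: np.linalg.cholesky(c0), 1: np.linalg.cholesky(c1)}
    series = []
    for s_idx, label in enumerate(cfg.labels):
        innov = rng.standard_normal((cfg.n_regions, cfg.n_timepoints))
        if cfg.ar1_phi != 0.0:
            phi = cfg.ar1_phi
            out = np.empty_like(innov)
            out[:, 0] = innov[:, 0]
            scale = np.sqrt(1.0 - phi**2)
            for t in range(1, cfg.n_timepoints):
                out[:, t] = phi * out[:, t - 1] + scale * innov[:, t]
            innov = out
        values = chol[int(label)] @ innov
        series.append(ParcelTimeSeries(subject_id=f"sub-{s_idx:03d}", values=values))
    truth = GroundTruth(cfg.morph_effects, cfg.fc_effects, c0, c1, cfg.seed)
    return series, truth


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[list[MorphometryTable], list[ParcelTimeSeries], np.ndarray, GroundTruth]:
    """Full cohort: morphometry tables, time series, labels, ground truth."""
    tables, _ = simulate_morphometry(cfg)
    series, truth_ts = simulate_timeseries(cfg)
    truth = GroundTruth(
        cfg.morph_effects,
        cfg.fc_effects,
        truth_ts.target_corr_group0,
        truth_ts.target_corr_group1,
        cfg.seed,
    )
    return tables, series, cfg.labels, truth


def write_cohort(
    tables: Sequence[MorphometryTable],
    series: Sequence[ParcelTimeSeries],
    labels: Sequence[int],
    out_dir: str | Path,
    parcellation: Parcellation,
    truth: GroundTruth | None = None,
) -> CohortManifest:
    """Write a cohort to disk in the package's CSV formats plus a manifest."""
    import pandas as pd

    out = Path(out_dir)
    (out / "morphometry").mkdir(parents=True, exist_ok=True)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    if len(tables) != len(series) or len(tables) != len(labels):
        raise FmscError("tables, series and labels must align one-to-one")
    subject_ids, morph_paths, ts_paths = [], [], []
    for table, ts in zip(tables, series):
        if table.subject_id != ts.subject_id:
            raise FmscError(
                f"subject order mismatch: {table.subject_id} vs {ts.subject_id}"
            )
        m_path = out / "morphometry" / f"{table.subject_id}.csv"
        df = pd.DataFrame(table.values, columns=list(table.metric_names))
        df.insert(0, "region_id", list(parcellation.region_ids))
        df.to_csv(m_path, index=False, float_format="%.17g")
        t_path = out / "timeseries" / f"{ts.subject_id}.csv"
        ts_df = pd.DataFrame(
            ts.values, columns=[f"t{t}" for t in range(ts.n_timepoints)]
        )
        ts_df.insert(0, "region_id", list(parcellation.region_ids))
        ts_df.to_csv(t_path, index=False, float_format="%.17g")
        subject_ids.append(table.subject_id)
        # manifest paths are relative to out_dir so the cohort is relocatable
        # and regeneration is byte-identical regardless of where it lands
        morph_paths.append(str(m_path.relative_to(out)))
        ts_paths.append(str(t_path.relative_to(out)))
    manifest = CohortManifest(
        tuple(subject_ids), tuple(int(g) for g in labels), tuple(morph_paths), tuple(ts_paths)
    )
    manifest.write(out / "manifest.csv")
    if truth is not None:
        truth.to_json(out / "ground_truth.json")
    return manifest
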