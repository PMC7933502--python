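"""Domain types, tabular I/O, and symmetric-matrix <-> feature-vector plumbing.

Every network in this package is a square symmetric region-by-region matrix
(:class:`Connectome`).  Classification consumes the strict upper triangle of
such matrices as a flat feature vector; the bijection between flat indices and
region pairs lives here so that edge features keep a stable identity across
subjects and folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Canonical ordering of the eight anatomical measures per region:
#: surface area, gray-matter volume, mean and standard deviation of cortical
#: thickness, mean curvature, Gaussian curvature, curvature index, folding
#: index.
METRIC_NAMES: tuple[str, ...] = (
    "SA",
    "GMV",
    "CT_avg",
    "CT_sd",
    "MC",
    "GC",
    "CI",
    "FI",
)

#: The 17 canonical resting-state networks of the Yeo parcellation; with one
#: parcel per hemisphere this yields the default 34-region parcellation.
YEO17_NETWORKS: tuple[str, ...] = (
    "Central visual",
    "Peripheral visual",
    "Somatomotor A",
    "Somatomotor B",
    "Dorsal attention A",
    "Dorsal attention B",
    "Saliency and ventral attention A",
    "Saliency and ventral attention B",
    "Limbic A",
    "Limbic B",
    "Control A",
    "Control B",
    "Control C",
    "Default mode A",
    "Default mode B",
    "Default mode C",
    "Tempoparietal",
)

CONNECTOME_KINDS = ("MSN", "FCN", "FMSC", "adjacency")

_SYMMETRY_TOL = 1e-10


class FmscError(ValueError):
    """Base class for domain validation errors."""


def _check_finite(values: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(np.asarray(values, dtype=float)))
        loc = ", ".join(str(tuple(int(x) for x in b)) for b in bad[:5])
        raise FmscError(f"{what} contains non-finite values at {loc}")


@dataclass(frozen=True)
class Parcellation:
    """An ordered set of cortical regions.

    The region order is canonical for a study: every morphometry table, time
    series, and connectome is aligned to it, so edge (i, j) means the same
    pair of regions for every subject.
    """

    region_ids: tuple[str, ...]
    hemisphere: tuple[str, ...]
    network_name: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.region_ids)
        if n < 2:
            raise FmscError("parcellation needs at least 2 regions")
        if len(set(self.region_ids)) != n:
            raise FmscError("region_ids must be unique")
        if len(self.hemisphere) != n or len(self.network_name) != n:
            raise FmscError("hemisphere/network_name length mismatch")
        bad = set(self.hemisphere) - {"L", "R"}
        if bad:
            raise FmscError(f"hemisphere tags must be L or R, got {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.region_ids)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def index_of(self, region_id: str) -> int:
        try:
            return self.region_ids.index(region_id)
        except ValueError:
            raise FmscError(f"unknown region {region_id!r}") from None

    @classmethod
    def yeo17_two_hemisphere(cls) -> "Parcellation":
        """The default 34-region parcellation: 17 networks x {L, R}."""
        ids, hemi, net = [], [], []
        for name in YEO17_NETWORKS:
            for h in ("L", "R"):
                ids.append(f"{name} ({h})")
                hemi.append(h)
                net.append(name)
        return cls(tuple(ids), tuple(hemi), tuple(net))

    @classmethod
    def generic(cls, n_regions: int) -> "Parcellation":
        """An unnamed parcellation for simulations at arbitrary size."""
        ids = tuple(f"region_{i:02d} ({'L' if i % 2 == 0 else 'R'})" for i in range(n_regions))
        hemi = tuple("L" if i % 2 == 0 else "R" for i in range(n_regions))
        net = tuple(f"region_{i:02d}" for i in range(n_regions))
        return cls(ids, hemi, net)


@dataclass
class MorphometryTable:
    """Per-subject regions x metrics grid of anatomical measures."""

    subject_id: str
    values: np.ndarray
    metric_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FmscError("morphometry values must be 2-D (regions x metrics)")
        if self.values.shape[0] < 2:
            raise FmscError("morphometry table needs at least 2 regions")
        if self.values.shape[1] != len(self.metric_names):
            raise FmscError("metric_names length does not match value columns")
        unknown = [m for m in self.metric_names if m not in METRIC_NAMES]
        if unknown:
            raise FmscError(f"unknown metric name(s): {unknown}")
        _check_finite(self.values, f"morphometry for subject {self.subject_id}")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def metric_column(self, metric: str) -> np.ndarray:
        if metric not in self.metric_names:
            raise FmscError(
                f"metric {metric!r} not present for subject {self.subject_id}"
            )
        return self.values[:, self.metric_names.index(metric)]


@dataclass
class ParcelTimeSeries:
    """Per-subject regions x timepoints matrix of parcel-averaged signal."""

    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FmscError("time series must be 2-D (regions x timepoints)")
        if self.values.shape[1] < 3:
            raise FmscError("time series needs at least 3 timepoints")
        _check_finite(self.values, f"time series for subject {self.subject_id}")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class Connectome:
    """A square symmetric similarity/connectivity matrix with region labels.

    Correlation kinds (MSN, FCN, FMSC) have unit diagonal and off-diagonal
    entries in [-1, 1]; the ``adjacency`` kind is binary with zero diagonal.
    """

    matrix: np.ndarray
    region_ids: tuple[str, ...]
    kind: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.region_ids)
        if self.matrix.shape != (n, n):
            raise FmscError(
                f"matrix shape {self.matrix.shape} does not match {n} regions"
            )
        if self.kind not in CONNECTOME_KINDS:
            raise FmscError(f"kind must be one of {CONNECTOME_KINDS}")
        _check_finite(self.matrix, f"{self.kind} matrix")
        asym = np.max(np.abs(self.matrix - self.matrix.T)) if n else 0.0
        if asym > _SYMMETRY_TOL:
            raise FmscError(f"matrix asymmetric beyond tolerance (max |A-A'| = {asym:g})")
        diag = np.diag(self.matrix)
        off = self.matrix[~np.eye(n, dtype=bool)]
        if self.kind == "adjacency":
            if not np.allclose(diag, 0.0):
                raise FmscError("adjacency diagonal must be 0")
            if not np.all(np.isin(off, (0.0, 1.0))):
                raise FmscError("adjacency entries must be binary")
        else:
            if not np.allclose(diag, 1.0, atol=_SYMMETRY_TOL):
                raise FmscError(f"{self.kind} diagonal must be 1")
            if off.size and (off.min() < -1 - _SYMMETRY_TOL or off.max() > 1 + _SYMMETRY_TOL):
                raise FmscError(f"{self.kind} off-diagonal entries must lie in [-1, 1]")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)


@dataclass
class CohortManifest:
    """Cohort roster: subject ids, binary group labels, and data file paths."""

    subject_ids: tuple[str, ...]
    groups: tuple[int, ...]
    morphometry_paths: tuple[str, ...]
    timeseries_paths: tuple[str, ...]
    positive_label: int = 1

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        if len(set(self.subject_ids)) != n:
            raise FmscError("subject ids must be unique")
        if not (len(self.groups) == len(self.morphometry_paths) == len(self.timeseries_paths) == n):
            raise FmscError("manifest column lengths differ")
        if set(self.groups) != {0, 1}:
            raise FmscError("both groups (0 and 1) must be non-empty")

    def __len__(self) -> int:
        return len(self.subject_ids)

    @property
    def labels(self) -> np.ndarray:
        return np.asarray(self.groups, dtype=int)

    @classmethod
    def read(cls, path: str | Path) -> "CohortManifest":
        df = pd.read_csv(path)
        required = ["subject_id", "group", "morphometry_path", "timeseries_path"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FmscError(f"manifest {path} missing column(s) {missing}")
        base = Path(path).parent

        def resolve(p: str) -> str:
            q = Path(p)
            return str(q if q.is_absolute() else base / q)

        return cls(
            tuple(df["subject_id"].astype(str)),
            tuple(int(g) for g in df["group"]),
            tuple(resolve(p) for p in df["morphometry_path"].astype(str)),
            tuple(resolve(p) for p in df["timeseries_path"].astype(str)),
        )

    def write(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "group": self.groups,
                "morphometry_path": self.morphometry_paths,
                "timeseries_path": self.timeseries_paths,
            }
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Upper-triangle vectorization
# ---------------------------------------------------------------------------

def n_edge_features(m: int) -> int:
    """Feature-vector length m(m-1)/2 for an m x m symmetric matrix."""
    return m * (m - 1) // 2


def vectorize_upper_triangle(c: Connectome | np.ndarray) -> np.ndarray:
    """Extract the strict upper triangle in row-major (i, j), i < j order.

    For a 34 x 34 connectome this yields the 561-dimensional edge feature
    vector used for classification.
    """
    a = c.matrix if isinstance(c, Connectome) else np.asarray(c, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise FmscError("vectorize_upper_triangle requires a square matrix")
    if a.shape[0] and np.max(np.abs(a - a.T)) > _SYMMETRY_TOL:
        raise FmscError("matrix is not symmetric")
    iu, ju = np.triu_indices(a.shape[0], k=1)
    return a[iu, ju].copy()


def devectorize_upper_triangle(v: Sequence[float], m: int, diagonal: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize_upper_triangle` (symmetric fill)."""
    v = np.asarray(v, dtype=float)
    if v.shape != (n_edge_features(m),):
        raise FmscError(f"expected {n_edge_features(m)} values for m={m}, got {v.shape}")
    a = np.full((m, m), diagonal, dtype=float)
    iu, ju = np.triu_indices(m, k=1)
    a[iu, ju] = v
    a[ju, iu] = v
    return a


def pair_to_flat_index(i: int, j: int, m: int) -> int:
    """Row-major flat index of the strict upper-triangle pair (i, j), i < j."""
    if not (0 <= i < j < m):
        raise FmscError(f"need 0 <= i < j < m, got i={i}, j={j}, m={m}")
    # offset of row i = sum over rows r < i of (m - 1 - r)
    return i * (2 * m - i - 1) // 2 + (j - i - 1)


def flat_index_to_pair(k: int, m: int) -> tuple[int, int]:
    """Region pair (i, j), i < j for flat index ``k`` (row-major order)."""
    total = n_edge_features(m)
    if not (0 <= k < total):
        raise FmscError(f"flat index {k} out of range [0, {total}) for m={m}")
    # closed form: smallest i with cumulative row length > k
    i = int(m - 2 - math.floor((math.sqrt(8 * (total - k - 1) + 1) - 1) / 2))
    row_offset = i * (2 * m - i - 1) // 2
    j = k - row_offset + i + 1
    return i, j


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_morphometry(path: str | Path, parcellation: Parcellation) -> MorphometryTable:
    """Read a morphometry CSV (``region_id`` column + metric columns).

    Rows are reordered to the parcellation's canonical region order; metric
    columns keep their file order but must be drawn from the known metric set.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if "region_id" not in df.columns:
        raise FmscError(f"{path}: first column must be 'region_id'")
    metric_cols = [c for c in df.columns if c != "region_id"]
    unknown = [c for c in metric_cols if c not in METRIC_NAMES]
    if unknown:
        raise FmscError(f"{path}: unknown metric column(s) {unknown}")
    df = df.set_index("region_id")
    missing = [r for r in parcellation.region_ids if r not in df.index]
    if missing:
        raise FmscError(f"{path}: missing region(s) {missing}")
    extra = [r for r in df.index if r not in parcellation.region_ids]
    if extra:
        raise FmscError(f"{path}: unexpected region(s) {extra}")
    df = df.loc[list(parcellation.region_ids)]
    for col in metric_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna()]
        if len(bad):
            raise FmscError(
                f"{path}: non-numeric or missing value in column {col!r}, row {bad[0]!r}"
            )
        df[col] = numeric
    return MorphometryTable(
        subject_id=Path(path).stem,
        values=df[metric_cols].to_numpy(dtype=float),
        metric_names=tuple(metric_cols),
    )


def read_timeseries(path: str | Path, parcellation: Parcellation | None = None) -> ParcelTimeSeries:
    """Read a parcel time-series CSV (``region_id`` column + t0..t{T-1})."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "region_id" not in df.columns:
        raise FmscError(f"{path}: first column must be 'region_id'")
    df = df.set_index("region_id")
    if parcellation is not None:
        missing = [r for r in parcellation.region_ids if r not in df.index]
        if missing:
            raise FmscError(f"{path}: missing region(s) {missing}")
        df = df.loc[list(parcellation.region_ids)]
    values = df.to_numpy(dtype=float)
    return ParcelTimeSeries(subject_id=Path(path).stem, values=values)


def write_connectome(path: str | Path, c: Connectome) -> None:
    """Write a connectome as labeled TSV at full double precision."""
    df = pd.DataFrame(c.matrix, index=list(c.region_ids), columns=list(c.region_ids))
    df.index.name = f"#kind={c.kind}"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_connectome(
    path: str | Path,
    kind: str | None = None,
    parcellation: Parcellation | None = None,
) -> Connectome:
    """Read a labeled connectome TSV written by :func:`write_connectome`."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    file_kind = None
    if df.index.name and df.index.name.startswith("#kind="):
        file_kind = df.index.name.split("=", 1)[1]
    resolved = kind or file_kind
    if resolved is None:
        raise FmscError(f"{path}: connectome kind not recorded and not supplied")
    if list(df.index) != list(df.columns):
        raise FmscError(f"{path}: row and column labels differ")
    if parcellation is not None and list(df.index) != list(parcellation.region_ids):
        raise FmscError(f"{path}: region labels do not match the expected parcellation")
    return Connectome(df.to_numpy(dtype=float), tuple(df.index), resolved)
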