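"""The functional morphometric similarity connectome (FMSC).

Each region's node feature vector concatenates its anatomical measures with
graph metrics of the functional connectivity network: node strength (NS) from
the weighted FCN and node degree (ND@t) from the FCN binarized at each
edge-strength threshold t.  With the eight anatomical measures and the five
default thresholds this gives 14 channels per region.  Channels are z-scored
across regions and region pairs are correlated, exactly as for the MSN — so
an FMSC restricted to anatomical channels equals the corresponding MSN.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np

from fmsc.core import Connectome, FmscError, METRIC_NAMES, MorphometryTable
from fmsc.functional import DEFAULT_THRESHOLDS, node_degree, node_strength, sparsify
from fmsc.morphometry import similarity_from_node_features


def nd_channel_name(threshold: float) -> str:
    return f"ND@{threshold:g}"


#: The full default channel pool: 8 anatomical + NS + 5 node-degree channels.
FULL_CHANNELS: tuple[str, ...] = METRIC_NAMES + ("NS",) + tuple(
    nd_channel_name(t) for t in DEFAULT_THRESHOLDS
)


@dataclass
class NodeFeatureMatrix:
    """Per-subject regions x channels grid of combined node features."""

    subject_id: str
    values: np.ndarray
    channel_names: tuple[str, ...]
    region_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.region_ids), len(self.channel_names)):
            raise FmscError("node feature shape does not match labels")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise FmscError("duplicate channel names")

    def select(self, channels: Sequence[str]) -> np.ndarray:
        missing = [c for c in channels if c not in self.channel_names]
        if missing:
            raise FmscError(f"channel(s) {missing} not present")
        cols = [self.channel_names.index(c) for c in channels]
        return self.values[:, cols]


@dataclass(frozen=True)
class ModelSpec:
    """A named candidate model: one subset of node-feature channels."""

    name: str
    channels: tuple[str, ...]
    family: str = "FMSC"

    def __post_init__(self) -> None:
        if self.family not in ("MSN", "FMSC"):
            raise FmscError("family must be MSN or FMSC")
        if self.family == "MSN":
            bad = [c for c in self.channels if c not in METRIC_NAMES]
            if bad:
                raise FmscError(f"MSN family admits anatomical channels only, got {bad}")


def assemble_node_features(
    m: MorphometryTable,
    fcn: Connectome,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    region_ids: tuple[str, ...] | None = None,
) -> NodeFeatureMatrix:
    """Concatenate anatomical measures with NS and per-threshold ND channels.

    With the 8 anatomical metrics and the default thresholds {0.4..0.8} the
    result has 14 channels per region.
    """
    if m.n_regions != fcn.n_regions:
        raise FmscError(
            f"parcellation mismatch: morphometry has {m.n_regions} regions, "
            f"FCN has {fcn.n_regions}"
        )
    if region_ids is None:
        region_ids = fcn.region_ids
    cols = [m.values]
    names = list(m.metric_names)
    cols.append(node_strength(fcn)[:, None])
    names.append("NS")
    for t in thresholds:
        cols.append(node_degree(sparsify(fcn, t)).astype(float)[:, None])
        names.append(nd_channel_name(t))
    return NodeFeatureMatrix(
        subject_id=m.subject_id,
        values=np.hstack(cols),
        channel_names=tuple(names),
        region_ids=tuple(region_ids),
    )


def build_fmsc(nf: NodeFeatureMatrix, channels: Sequence[str] | None = None) -> Connectome:
    """Correlate z-scored node feature vectors between regions.

    A channel that is constant across regions (e.g. ND at a high threshold
    when no edge survives) cannot be z-scored; the error names it so the
    caller can drop that channel.
    """
    if channels is None:
        channels = nf.channel_names
    channels = tuple(channels)
    if len(channels) < 2:
        raise FmscError("build_fmsc needs at least 2 channels")
    features = nf.select(channels)
    return similarity_from_node_features(features, nf.region_ids, channels, "FMSC")


def enumerate_model_specs(
    pool: Sequence[str], kmin: int, kmax: int, family: str = "FMSC"
) -> list[ModelSpec]:
    """All channel subsets of sizes kmin..kmax, in deterministic order.

    Subsets are emitted by increasing size, lexicographically in pool order
    within each size; the count is sum_{k=kmin}^{kmax} C(|pool|, k).  The two
    model searches of interest are the 219 anatomical models (8 metrics,
    k = 3..8) and the 364 combined models (14 channels, k = 3).
    """
    pool = tuple(pool)
    if len(set(pool)) != len(pool):
        raise FmscError("channel pool contains duplicates")
    if not (2 <= kmin <= kmax <= len(pool)):
        raise FmscError(
            f"need 2 <= kmin <= kmax <= |pool|, got kmin={kmin}, kmax={kmax}, |pool|={len(pool)}"
        )
    specs = []
    for k in range(kmin, kmax + 1):
        for subset in combinations(pool, k):
            specs.append(ModelSpec(name="+".join(subset), channels=subset, family=family))
    assert len(specs) == sum(comb(len(pool), k) for k in range(kmin, kmax + 1))
    return specs


def preset_model_specs(preset: str) -> list[ModelSpec]:
    """Named enumeration presets.

    ``anatomical-219``: the 8 anatomical metrics, subsets of size 3..8.
    ``combined-364``: the full 14-channel pool, subsets of size 3.
    """
    if preset in ("anatomical-219", "paper-msn"):
        return enumerate_model_specs(METRIC_NAMES, 3, 8, family="MSN")
    if preset in ("combined-364", "paper-fmsc-364"):
        return enumerate_model_specs(FULL_CHANNELS, 3, 3, family="FMSC")
    raise FmscError(f"unknown preset {preset!r}")
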