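"""Per-electrode graph metrics and Table-style feature assembly.

Each connectivity matrix is read as an undirected weighted graph on the
19 electrodes (edge iff weight > 0). Three node metrics are computed:

* ``d_v`` — weighted degree, the sum of incident edge weights;
* ``E_v`` — total weight of edges among the neighbors of v;
* ``C_v`` — clustering coefficient, 2 E_v / (k_v (k_v - 1)) where k_v is
  the *binary* neighbor count (0 when k_v < 2).

The binary count in the denominator keeps C_v in [0, 1] for weighted
graphs (each of the k_v(k_v-1)/2 possible neighbor edges has weight at
most 1); on binary graphs it reduces to the classical clustering
coefficient. A fully binary mode is available for sensitivity analysis.

A feature table holds one metric for one band: one row per subject,
19 electrode columns, and a class column (HA/AA/LA).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .montage import CHANNELS, N_CHANNELS

METRICS = ("dv", "Ev", "Cv")
CLASS_COLUMN = "class"
CLASS_LABELS = ("HA", "AA", "LA")


@dataclass
class NodeMetrics:
    """Per-electrode metrics for one graph."""

    d_v: np.ndarray   # weighted degree
    k_v: np.ndarray   # binary neighbor count
    E_v: np.ndarray   # weight among neighbors
    C_v: np.ndarray   # clustering coefficient

    def by_name(self, metric: str) -> np.ndarray:
        try:
            return {"dv": self.d_v, "Ev": self.E_v, "Cv": self.C_v}[metric]
        except KeyError:
            raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def _validate_weights(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("weight matrix must be symmetric")
    if W.min() < 0 or W.max() > 1:
        raise ValueError("weights must lie in [0, 1]")
    if np.any(np.diag(W) != 0):
        raise ValueError("diagonal (self-loops) must be zero")
    return W


def node_metrics(W: np.ndarray, binary: bool = False) -> NodeMetrics:
    """Compute d_v, k_v, E_v, C_v for every vertex of a weighted graph."""
    W = _validate_weights(W)
    if binary:
        W = (W > 0).astype(float)
    n = W.shape[0]
    adj = W > 0
    d_v = W.sum(axis=1)
    k_v = adj.sum(axis=1).astype(int)
    E_v = np.empty(n)
    for v in range(n):
        nb = np.flatnonzero(adj[v])
        E_v[v] = W[np.ix_(nb, nb)].sum() / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        C_v = np.where(k_v >= 2, 2.0 * E_v / (k_v * (k_v - 1.0)), 0.0)
    return NodeMetrics(d_v=d_v, k_v=k_v, E_v=E_v, C_v=C_v)


@dataclass
class FeatureTable:
    """Subjects x electrodes table of one graph metric for one band."""

    data: pd.DataFrame
    band: str
    metric: str

    def __post_init__(self) -> None:
        expected = list(CHANNELS) + [CLASS_COLUMN]
        if list(self.data.columns) != expected:
            raise ValueError(
                f"feature table must have columns {expected}"
            )
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric tag {self.metric!r}")

    @property
    def tag(self) -> str:
        """The B_i G_j variant tag, e.g. ``Balpha_GCv``."""
        return f"B{self.band}_G{self.metric}"

    @property
    def features(self) -> pd.DataFrame:
        return self.data[list(CHANNELS)]

    @property
    def classes(self) -> pd.Series:
        return self.data[CLASS_COLUMN]


def build_feature_table(
    matrices: Iterable[ConnectivityMatrix],
    metric: str,
    labels: Mapping[str, str],
    binary: bool = False,
) -> FeatureTable:
    """Assemble one (band, metric) feature table from per-subject graphs.

    Subject rows are ordered lexically by subject id. Every subject in
    ``labels`` must have exactly one matrix, all for the same band.
    """
    mats = {m.subject_id: m for m in matrices}
    bands = {m.band.name for m in mats.values()}
    if len(bands) != 1:
        raise ValueError(f"matrices mix bands: {sorted(bands)}")
    band = bands.pop()
    missing = sorted(set(labels) - set(mats))
    if missing:
        raise ValueError(f"missing connectivity matrix for subject(s): {missing}")

    rows = []
    subjects = sorted(labels)
    for sid in subjects:
        vals = node_metrics(mats[sid].W, binary=binary).by_name(metric)
        rows.append(list(vals) + [labels[sid]])
    data = pd.DataFrame(rows, index=pd.Index(subjects, name="Participant"),
                        columns=list(CHANNELS) + [CLASS_COLUMN])
    return FeatureTable(data=data, band=band, metric=metric)


def all_feature_tables(
    matrices_by_band: Mapping[str, Iterable[ConnectivityMatrix]],
    labels: Mapping[str, str],
    binary: bool = False,
) -> dict[str, FeatureTable]:
    """All (band, metric) table variants — 15 for the five canonical bands."""
    tables: dict[str, FeatureTable] = {}
    for band, mats in matrices_by_band.items():
        mats = list(mats)
        for metric in METRICS:
            t = build_feature_table(mats, metric, labels, binary=binary)
            tables[t.tag] = t
    return tables
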