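"""Connectome construction and regional homogeneity.

A connectome is the node-by-node matrix of Fisher r-to-z transformed Pearson
correlations between regional mean time series (zero diagonal, symmetric).
Global strength summarizes one connectome as the mean of its strictly positive
edges. Regional homogeneity (ReHo) quantifies local synchrony of a node as
Kendall's coefficient of concordance W across the node's 27 voxel time series
(center voxel plus its 26 neighbors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import mat_to_vec

__all__ = [
    "TimeSeriesMatrix",
    "VoxelBlock",
    "R_CLAMP",
    "compute_connectome",
    "global_strength",
    "kendalls_w",
    "node_reho_table",
    "ConnectomeTransformer",
]

#: correlations are clamped to +/- this value before atanh so z stays finite
R_CLAMP = 1.0 - 1e-7


@dataclass
class TimeSeriesMatrix:
    """One subject's node x time signal array with identifying labels."""

    subject_id: str
    data: np.ndarray  # (n_nodes, n_samples)
    group: str | None = None
    time_point: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be 2-D (nodes x samples)")
        if self.data.shape[1] < 3:
            raise ValueError("need at least 3 time samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time-series data contains non-finite values")


@dataclass
class VoxelBlock:
    """3x3x3 voxel neighborhood of one node: 27 aligned time series."""

    node_id: int
    series: np.ndarray  # (27, n_samples)

    def __post_init__(self):
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2 or self.series.shape[0] != 27:
            raise ValueError("a voxel block holds exactly 27 series")
        if not np.all(np.isfinite(self.series)):
            raise ValueError("voxel series contain non-finite values")


def compute_connectome(ts, clamp: float = R_CLAMP) -> np.ndarray:
    """Pearson-correlate all node pairs and Fisher-transform to z.

    Parameters
    ----------
    ts : TimeSeriesMatrix or ndarray of shape (n_nodes, n_samples)
    clamp : float
        |r| is clamped to this value before atanh; keeps degenerate
        (perfectly correlated) edges finite.

    Returns
    -------
    ndarray of shape (n_nodes, n_nodes)
        Symmetric Fisher-z matrix with zero diagonal.
    """
    data = ts.data if isinstance(ts, TimeSeriesMatrix) else np.asarray(ts, dtype=float)
    if data.ndim != 2 or data.shape[1] < 3:
        raise ValueError("expected a (nodes x samples) array with >= 3 samples")
    sd = data.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance node series: {dead.tolist()}")
    r = np.corrcoef(data)
    r = np.clip(r, -clamp, clamp)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(z, 0.0)
    return z


def global_strength(connectome: np.ndarray) -> float:
    """Mean of the strictly positive upper-triangle entries.

    Negative connections and the diagonal are excluded. Returns 0.0 (with a
    warning) for a connectome with no positive edge.
    """
    vec = mat_to_vec(np.asarray(connectome, dtype=float))
    pos = vec[vec > 0]
    if pos.size == 0:
        warnings.warn("connectome has no positive connections; global strength set to 0")
        return 0.0
    return float(pos.mean())


def kendalls_w(series: np.ndarray) -> float:
    """Kendall's coefficient of concordance across m aligned series.

    Each series ranks the T time points (mid-ranks for ties); W is
    ``12 S / (m^2 (T^3 - T) - m C)`` with S the sum of squared deviations of
    the rank sums and C the standard tie correction.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("expected a 2-D array (m series x T samples)")
    m, t = series.shape
    if t < 3:
        raise ValueError("need at least 3 time samples")
    ranks = sps.rankdata(series, axis=1)
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    correction = 0.0
    for row in series:
        _, counts = np.unique(row, return_counts=True)
        correction += float((counts**3 - counts).sum())
    denom = m**2 * (t**3 - t) - m * correction
    if denom <= 0:  # every series entirely tied
        return 1.0 if s == 0 else 0.0
    return float(np.clip(12.0 * s / denom, 0.0, 1.0))


def node_reho_table(blocks, n_nodes: int | None = None) -> pd.DataFrame:
    """Per-node ReHo: Kendall's W of each node's 27-voxel block.

    If ``n_nodes`` is given, missing node ids raise with the full list.
    """
    rows = [(int(b.node_id), kendalls_w(b.series)) for b in blocks]
    table = pd.DataFrame(rows, columns=["node_id", "W"]).sort_values("node_id")
    table = table.reset_index(drop=True)
    if n_nodes is not None:
        missing = sorted(set(range(n_nodes)) - set(table["node_id"]))
        if missing:
            raise ValueError(f"missing voxel blocks for nodes: {missing}")
    return table


class ConnectomeTransformer(TransformerMixin, BaseEstimator):
    """Transform stacked node time series into Fisher-z connectomes.

    Stateless sklearn transformer: ``transform`` maps an array of shape
    (n_subjects, n_nodes, n_samples) — or a list of TimeSeriesMatrix — to
    (n_subjects, n_nodes, n_nodes).

    Parameters
    ----------
    clamp : float, default 1 - 1e-7
        Correlation clamp applied before the Fisher transform.
    """

    def __init__(self, clamp: float = R_CLAMP):
        self.clamp = clamp

    def fit(self, X, y=None):
        self.n_features_in_ = len(X)
        return self

    def transform(self, X) -> np.ndarray:
        return np.stack([compute_connectome(ts, clamp=self.clamp) for ts in X])
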