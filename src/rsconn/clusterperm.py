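"""Cluster-based permutation inference over density-threshold curves.

Group differences in a topology metric are tested at every proportional
density with a two-tailed Welch t-test; contiguous runs of significant
thresholds form clusters whose size k (number of thresholds) is compared with
the permutation null distribution of the maximal cluster size. Crucially, the
group labels are shuffled ONCE per permutation and applied across the whole
grid, preserving the dependency of a subject's curve across thresholds; the
family-wise error is controlled within each topological measure.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from ._utils import max_run_length

__all__ = [
    "ClusterResult",
    "pointwise_tests",
    "find_clusters",
    "ClusterPermutation",
    "cluster_fwe_test",
    "change_curves",
]


@dataclass
class ClusterResult:
    """One contiguous run of significant thresholds with its FWE p-value."""

    metric: str
    start_index: int
    end_index: int  # inclusive
    k: int
    p_fwe: float
    start_density: float | None = None
    end_density: float | None = None

    def __post_init__(self):
        if self.k != self.end_index - self.start_index + 1:
            raise ValueError("k must equal the run length")


def _welch_rows(x: np.ndarray, in_a: np.ndarray):
    """Two-tailed Welch t and p per column, for one or many boolean label rows."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean(axis=0)  # centering: exact zeros for identical groups
    in_a = np.atleast_2d(np.asarray(in_a, dtype=bool))
    s = x.shape[0]
    na = in_a.sum(axis=1).astype(float)
    nb = s - na
    p = in_a.astype(float)
    sum_a, sq_a = p @ x, p @ (x**2)
    sum_all, sq_all = x.sum(axis=0), (x**2).sum(axis=0)
    mean_a = sum_a / na[:, None]
    mean_b = (sum_all - sum_a) / nb[:, None]
    var_a = np.maximum((sq_a - na[:, None] * mean_a**2) / (na - 1)[:, None], 0.0)
    var_b = np.maximum((sq_all - sq_a - nb[:, None] * mean_b**2) / (nb - 1)[:, None], 0.0)
    va, vb = var_a / na[:, None], var_b / nb[:, None]
    se2 = va + vb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se2 > 0, (mean_a - mean_b) / np.sqrt(se2), 0.0)
        df = np.where(
            se2 > 0,
            se2**2 / (va**2 / (na - 1)[:, None] + vb**2 / (nb - 1)[:, None]),
            (na + nb - 2)[:, None],
        )
    pval = np.where(se2 > 0, 2.0 * sps.t.sf(np.abs(t), df), 1.0)
    return t, df, pval


def pointwise_tests(curves: np.ndarray, labels, groups=None):
    """Two-tailed Welch t-test at every grid point.

    Parameters
    ----------
    curves : (n_subjects, n_grid) array of per-subject metric curves.
    labels : group label per subject.
    groups : optional pair fixing which label is "group A" (first minus second).

    Returns
    -------
    (t, df, p) arrays of length n_grid.
    """
    labels = np.asarray(labels)
    if groups is None:
        groups = tuple(sorted(np.unique(labels)))
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    in_a = labels == groups[0]
    if in_a.sum() < 2 or (labels == groups[1]).sum() < 2:
        raise ValueError("need >= 2 subjects per group")
    t, df, p = _welch_rows(np.asarray(curves, dtype=float), in_a)
    return t[0], df[0], p[0]


def find_clusters(p_vector: np.ndarray, alpha: float = 0.05):
    """Maximal runs of contiguous grid points with p < alpha.

    Returns a list of (start_index, end_index, k) in grid order.
    """
    sig = np.asarray(p_vector, dtype=float) < alpha
    out = []
    start = None
    for i, s in enumerate(sig):
        if s and start is None:
            start = i
        elif not s and start is not None:
            out.append((start, i - 1, i - start))
            start = None
    if start is not None:
        out.append((start, len(sig) - 1, len(sig) - start))
    return out


class ClusterPermutation(BaseEstimator):
    """Permutation FWE test on cluster sizes over the threshold grid.

    Parameters
    ----------
    alpha : float, default 0.05
        Cluster-forming pointwise significance level.
    n_perm : int, default 10000
    statistic : {"size", "mass"}, default "size"
        Cluster statistic: run length k, or summed |t| over the run.
    plus_one : bool, default True
        p = (1 + exceedances) / (1 + n_perm); with False, p = exceedances / n_perm.
    random_state : int or None

    Attributes
    ----------
    pointwise_t_, pointwise_p_ : observed per-grid-point Welch statistics.
    clusters_ : list of (start, end, k, p_fwe) tuples in grid order.
    null_max_stat_ : (n_perm,) maximal cluster statistic per permutation.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        n_perm: int = 10000,
        statistic: str = "size",
        plus_one: bool = True,
        random_state: int | None = None,
    ):
        self.alpha = alpha
        self.n_perm = n_perm
        self.statistic = statistic
        self.plus_one = plus_one
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        groups = tuple(sorted(np.unique(y)))
        if len(groups) != 2:
            raise ValueError("exactly two groups required")
        n1 = int((y == groups[0]).sum())
        from math import comb

        if comb(len(y), n1) < 10:
            warnings.warn("fewer than 10 distinct relabelings; permutation p-values are coarse")
        t, _, p = pointwise_tests(X, y, groups)
        self.pointwise_t_, self.pointwise_p_ = t, p
        observed = find_clusters(p, self.alpha)

        rng = np.random.default_rng(self.random_state)
        in_a = y == groups[0]
        perm = np.stack([rng.permutation(in_a) for _ in range(self.n_perm)])
        null_t, _, null_p = _welch_rows(X, perm)
        sig = null_p < self.alpha
        if self.statistic == "size":
            self.null_max_stat_ = max_run_length(sig).astype(float)
            obs_stats = [float(k) for (_, _, k) in observed]
        else:
            self.null_max_stat_ = _max_cluster_mass(sig, np.abs(null_t))
            obs_stats = [float(np.abs(t[s : e + 1]).sum()) for (s, e, _) in observed]

        add = 1 if self.plus_one else 0
        clusters = []
        for (s, e, k), stat in zip(observed, obs_stats):
            exceed = int((self.null_max_stat_ >= stat).sum())
            clusters.append((s, e, k, (exceed + add) / (self.n_perm + add)))
        self.clusters_ = clusters
        return self


def _max_cluster_mass(sig: np.ndarray, abs_t: np.ndarray) -> np.ndarray:
    out = np.zeros(sig.shape[0])
    for r in range(sig.shape[0]):
        best = 0.0
        for s, e, _ in find_clusters(np.where(sig[r], 0.0, 1.0), 0.5):
            best = max(best, float(abs_t[r, s : e + 1].sum()))
        out[r] = best
    return out


def change_curves(curves: pd.DataFrame, t1: str, t2: str) -> pd.DataFrame:
    """Per-subject change curves (t2 minus t1) in long format, complete cases only."""
    a = curves[curves["time_point"] == t1]
    b = curves[curves["time_point"] == t2]
    key = ["subject_id", "group", "metric", "density"]
    merged = a.merge(b, on=key, suffixes=("_1", "_2"))
    merged["value"] = merged["value_2"] - merged["value_1"]
    merged["time_point"] = f"{t2}-{t1}"
    return merged[key[:2] + ["time_point"] + key[2:] + ["value"]]


def cluster_fwe_test(
    curves: pd.DataFrame,
    time_point: str,
    groups=("AN", "HC"),
    metrics=None,
    alpha: float = 0.05,
    n_perm: int = 10000,
    statistic: str = "size",
    plus_one: bool = True,
    seed: int | None = None,
) -> list[ClusterResult]:
    """Run the cluster permutation test per metric on a long curve table.

    ``curves`` is the output of :func:`rsconn.topology.metric_curves` (or
    :func:`change_curves` for the longitudinal contrast, with ``time_point``
    set to its composite label). Each metric is tested separately against its
    own permutation null.
    """
    sel = curves[curves["time_point"] == time_point]
    if sel.empty:
        raise ValueError(f"no curves at time point {time_point!r}")
    metrics = sorted(sel["metric"].unique()) if metrics is None else list(metrics)
    results: list[ClusterResult] = []
    for m in metrics:
        sub = sel[sel["metric"] == m]
        wide = sub.pivot_table(index=["subject_id", "group"], columns="density", values="value", sort=True)
        densities = np.asarray(wide.columns, dtype=float)
        y = np.array([g for (_, g) in wide.index])
        keep = np.isin(y, groups)
        est = ClusterPermutation(
            alpha=alpha, n_perm=n_perm, statistic=statistic, plus_one=plus_one, random_state=seed
        )
        est.fit(wide.to_numpy()[keep], y[keep])
        for s, e, k, p in est.clusters_:
            results.append(
                ClusterResult(
                    metric=m,
                    start_index=int(s),
                    end_index=int(e),
                    k=int(k),
                    p_fwe=float(p),
                    start_density=float(densities[s]),
                    end_density=float(densities[e]),
                )
            )
    return results
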