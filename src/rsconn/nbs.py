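"""Network-based statistic (NBS).

Mass-univariate edge statistics over the connectome, thresholding at a primary
component-forming statistic value, extraction of suprathreshold connected
components, and permutation inference on the maximal component extent (edge
count) to control the family-wise error across all edges.

Supported designs
-----------------
two_sample
    Edge-wise two-sample t between two groups at one time point. Pooled
    variance by default (the classical NBS edge statistic); Welch optional.
paired
    Within-group comparison of two time points: one-sample t on per-subject
    edge differences, permutation by random sign flips.
interaction
    2x2 group-by-time interaction: F = squared pooled t on per-subject change
    scores, permutation of group labels with each subject's time points kept
    together (subjects are the exchangeable units).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._utils import component_labels_from_edges, mat_to_vec, max_component_extent, vec_to_mat

__all__ = [
    "SubnetworkResult",
    "NetworkBasedStatistic",
    "edge_stats",
    "extract_components",
    "nbs_test",
    "cohens_d_equivalent",
    "subnetwork_mean_connectivity",
]


@dataclass
class SubnetworkResult:
    """One suprathreshold connected component with its permutation FWE p."""

    component_id: int
    nodes: tuple
    edges: tuple  # ((i, j), ...) with i < j
    extent: int
    p_fwe: float
    contrast: str = ""

    def __post_init__(self):
        if self.extent != len(self.edges):
            raise ValueError("extent must equal the number of edges")


# ---------------------------------------------------------------------------
# vectorized edge statistics; X is (n_subjects, n_edges)
# ---------------------------------------------------------------------------

def _two_sample_t(x: np.ndarray, in_a: np.ndarray, pooled: bool = True) -> np.ndarray:
    """Edge-wise two-sample t (group A minus group B) for one or many label rows.

    ``in_a`` is a boolean array (n_subjects,) or (n_perm, n_subjects); returns
    t of matching leading shape by the group-sum trick.
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean(axis=0)  # centering: exact zeros for identical groups
    in_a = np.atleast_2d(np.asarray(in_a, dtype=bool))
    s = x.shape[0]
    na = in_a.sum(axis=1).astype(float)
    nb = s - na
    p = in_a.astype(float)
    sum_a = p @ x
    sq_a = p @ (x**2)
    sum_all = x.sum(axis=0)
    sq_all = (x**2).sum(axis=0)
    sum_b = sum_all - sum_a
    sq_b = sq_all - sq_a
    mean_a = sum_a / na[:, None]
    mean_b = sum_b / nb[:, None]
    var_a = (sq_a - na[:, None] * mean_a**2) / (na - 1)[:, None]
    var_b = (sq_b - nb[:, None] * mean_b**2) / (nb - 1)[:, None]
    var_a = np.maximum(var_a, 0.0)
    var_b = np.maximum(var_b, 0.0)
    if pooled:
        sp2 = ((na - 1)[:, None] * var_a + (nb - 1)[:, None] * var_b) / (na + nb - 2)[:, None]
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb)[:, None])
    else:
        se = np.sqrt(var_a / na[:, None] + var_b / nb[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (mean_a - mean_b) / se, 0.0)
    return t[0] if t.shape[0] == 1 and np.ndim(in_a) == 2 and in_a.shape[0] == 1 else t


def _paired_t(d: np.ndarray, signs: np.ndarray | None = None) -> np.ndarray:
    """One-sample t on difference vectors, optionally under sign-flip rows."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    sq = (d**2).sum(axis=0)  # invariant under sign flips
    if signs is None:
        total = d.sum(axis=0)[None, :]
    else:
        total = np.atleast_2d(signs.astype(float)) @ d
    mean = total / n
    var = np.maximum((sq[None, :] - n * mean**2) / (n - 1), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, mean / np.sqrt(var / n), 0.0)
    return t[0] if signs is None else t


class NetworkBasedStatistic(BaseEstimator):
    """Suprathreshold-component permutation test on connectome edges.

    Parameters
    ----------
    design : {"two_sample", "paired", "interaction"}
    threshold : float, default 3.0
        Primary component-forming statistic value (t for the t designs, F for
        the interaction design).
    contrast : {"greater", "less"}, default "greater"
        Direction for the t designs: "greater" tests first group (or second
        time point) above the other; ignored for the interaction F.
    n_perm : int, default 5000
    edge_stat : {"pooled", "welch"}, default "pooled"
    plus_one : bool, default True
        Use (1 + exceedances) / (1 + n_perm) for p so p is never zero.
    random_state : int or None

    Attributes
    ----------
    stat_ : ndarray (n_edges,)
        Observed edge statistics (signed per the contrast).
    edge_stats_ : ndarray (n_nodes, n_nodes)
        The same statistics mirrored into a symmetric matrix.
    components_ : list of SubnetworkResult, sorted by extent descending.
    null_max_extent_ : ndarray (n_perm,)
        Maximal component extent of each permutation.
    """

    def __init__(
        self,
        design: str = "two_sample",
        threshold: float = 3.0,
        contrast: str = "greater",
        n_perm: int = 5000,
        edge_stat: str = "pooled",
        plus_one: bool = True,
        random_state: int | None = None,
    ):
        self.design = design
        self.threshold = threshold
        self.contrast = contrast
        self.n_perm = n_perm
        self.edge_stat = edge_stat
        self.plus_one = plus_one
        self.random_state = random_state

    # -- helpers -------------------------------------------------------------
    def _edge_vectors(self, X):
        X = np.asarray(X, dtype=float)
        if self.design == "two_sample":
            if X.ndim != 3:
                raise ValueError("two_sample design expects X of shape (S, n, n)")
            self._n_nodes = X.shape[-1]
            return mat_to_vec(X)
        if X.ndim != 4 or X.shape[1] != 2:
            raise ValueError(f"{self.design} design expects X of shape (S, 2, n, n)")
        self._n_nodes = X.shape[-1]
        return mat_to_vec(X[:, 1] - X[:, 0])

    def _observed_stat(self, vec, y):
        sign = -1.0 if self.contrast == "less" else 1.0
        pooled = self.edge_stat == "pooled"
        if self.design == "paired":
            return sign * _paired_t(vec)
        if y is None:
            raise ValueError(f"{self.design} design requires group labels y")
        y = np.asarray(y)
        labels = np.unique(y)
        if labels.size != 2:
            raise ValueError(f"need exactly 2 groups, got {labels.tolist()}")
        self._in_a = y == labels[0]
        if self._in_a.sum() < 2 or (~self._in_a).sum() < 2:
            raise ValueError("need >= 2 subjects per group")
        t = _two_sample_t(vec, self._in_a, pooled=pooled)
        if self.design == "interaction":
            return np.atleast_2d(t)[0] ** 2
        return sign * np.atleast_2d(t)[0]

    def _null_stats(self, vec, rng):
        pooled = self.edge_stat == "pooled"
        s = vec.shape[0]
        if self.design == "paired":
            signs = rng.integers(0, 2, size=(self.n_perm, s)) * 2 - 1
            t = _paired_t(vec, signs=signs)
            return -t if self.contrast == "less" else t
        perm = np.stack([rng.permutation(self._in_a) for _ in range(self.n_perm)])
        t = _two_sample_t(vec, perm, pooled=pooled)
        if self.design == "interaction":
            return t**2
        return -t if self.contrast == "less" else t

    # -- sklearn API ----------------------------------------------------------
    def fit(self, X, y=None):
        """Run the permutation test; X stacks connectomes, y holds group labels."""
        if self.design not in ("two_sample", "paired", "interaction"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        vec = self._edge_vectors(X)
        stat = self._observed_stat(vec, y)
        self.stat_ = stat
        self.edge_stats_ = vec_to_mat(stat, self._n_nodes)

        iu, ju = np.triu_indices(self._n_nodes, k=1)
        sup = stat > self.threshold
        observed = _components(iu[sup], ju[sup])

        rng = np.random.default_rng(self.random_state)
        null_stat = self._null_stats(vec, rng)
        null_max = np.empty(self.n_perm, dtype=int)
        for p in range(self.n_perm):
            hit = null_stat[p] > self.threshold
            null_max[p] = max_component_extent(iu[hit], ju[hit])
        self.null_max_extent_ = null_max

        add = 1 if self.plus_one else 0
        results = []
        for cid, (nodes, edges) in enumerate(observed):
            extent = len(edges)
            exceed = int((null_max >= extent).sum())
            p_fwe = (exceed + add) / (self.n_perm + add)
            results.append(
                SubnetworkResult(
                    component_id=cid,
                    nodes=tuple(nodes),
                    edges=tuple(edges),
                    extent=extent,
                    p_fwe=float(p_fwe),
                    contrast=self.contrast if self.design != "interaction" else "interaction",
                )
            )
        self.components_ = results
        return self


def _components(i_idx, j_idx):
    """Connected components of an edge list, sorted (extent desc, min node asc)."""
    roots = component_labels_from_edges(i_idx, j_idx)
    groups: dict[int, list] = {}
    for a, b in zip(i_idx, j_idx):
        r = roots[int(a)]
        groups.setdefault(r, []).append((int(a), int(b)))
    comps = []
    for edges in groups.values():
        nodes = sorted({n for e in edges for n in e})
        comps.append((nodes, sorted(edges)))
    comps.sort(key=lambda c: (-len(c[1]), c[0][0]))
    return comps


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def edge_stats(panel, design="two_sample", groups=("AN", "HC"), time_point="TP1", times=None, contrast="greater", edge_stat="pooled"):
    """Edge-statistic matrix for a panel without running permutations."""
    est = NetworkBasedStatistic(design=design, contrast=contrast, edge_stat=edge_stat, n_perm=100, threshold=1.0)
    X, y = _panel_design(panel, design, groups, time_point, times)
    vec = est._edge_vectors(X)
    stat = est._observed_stat(vec, y)
    return vec_to_mat(stat, est._n_nodes)


def extract_components(stats: np.ndarray, primary_threshold: float):
    """Suprathreshold connected components of a symmetric statistic matrix.

    Returns a list of (nodes, edges) sorted by extent descending; empty list
    if no edge survives.
    """
    if primary_threshold <= 0:
        raise ValueError("threshold must be positive")
    stats = np.asarray(stats, dtype=float)
    n = stats.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    sup = stats[iu, ju] > primary_threshold
    return _components(iu[sup], ju[sup])


def _panel_design(panel, design, groups, time_point, times):
    if design == "two_sample":
        xa, ida = panel.stack(group=groups[0], time_point=time_point)
        xb, _ = panel.stack(group=groups[1], time_point=time_point)
        y = np.array([groups[0]] * xa.shape[0] + [groups[1]] * xb.shape[0])
        return np.concatenate([xa, xb]), y
    if times is None or len(times) != 2:
        raise ValueError(f"{design} design requires times=(t1, t2)")
    if design == "paired":
        X, _ = panel.paired_stack(groups if isinstance(groups, str) else groups[0], *times)
        return X, None
    X, y, _ = panel.longitudinal_stack(groups, *times)
    return X, y


def nbs_test(
    panel,
    design: str = "two_sample",
    groups=("AN", "HC"),
    time_point: str = "TP1",
    times=None,
    contrast: str = "greater",
    threshold: float = 3.0,
    n_perm: int = 5000,
    edge_stat: str = "pooled",
    seed: int | None = None,
) -> list[SubnetworkResult]:
    """Run the NBS on a cohort panel; see :class:`NetworkBasedStatistic`.

    For the two_sample design, ``contrast="greater"`` tests groups[0] > groups[1]
    edge-wise (so "less" tests the underconnectivity contrast AN < HC when
    groups=("AN", "HC")).
    """
    X, y = _panel_design(panel, design, groups, time_point, times)
    est = NetworkBasedStatistic(
        design=design,
        threshold=threshold,
        contrast=contrast,
        n_perm=n_perm,
        edge_stat=edge_stat,
        random_state=seed,
    )
    est.fit(X, y)
    return est.components_


def cohens_d_equivalent(t_value: float, n1: int, n2: int) -> float:
    """Cohen's d implied by a two-sample t: d = t * sqrt(1/n1 + 1/n2)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    return float(t_value * np.sqrt(1.0 / n1 + 1.0 / n2))


def subnetwork_mean_connectivity(panel, edge_set) -> pd.DataFrame:
    """Per subject-timepoint mean Fisher-z over a fixed edge set.

    Negative edges are included: this is the raw mean over the identified
    subnetwork, used to track its recovery over time.
    """
    edges = [(int(i), int(j)) for i, j in edge_set]
    if not edges:
        raise ValueError("edge set is empty")
    n = panel.n_nodes
    for i, j in edges:
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"edge ({i}, {j}) out of range for {n} nodes")
    ii = np.array([e[0] for e in edges])
    jj = np.array([e[1] for e in edges])
    rows = []
    for r in panel.manifest.itertuples():
        mat = panel.get(r.subject_id, r.time_point)
        rows.append((r.subject_id, r.group, r.time_point, float(mat[ii, jj].mean())))
    return pd.DataFrame(rows, columns=["subject_id", "group", "time_point", "mean_connectivity"])
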