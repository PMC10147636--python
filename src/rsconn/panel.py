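"""CohortPanel: manifest-indexed collection of connectomes.

The panel is the unit passed to every statistical stage: it couples a cohort
manifest (subject id, group, time point, optional covariates) with one
symmetric Fisher-z connectome per subject-timepoint.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._utils import mat_to_vec
from .connectome import global_strength

__all__ = ["CohortPanel"]


class CohortPanel:
    """Container of connectomes keyed by (subject_id, time_point).

    Parameters
    ----------
    manifest : DataFrame with columns subject_id, group, time_point
        plus optional covariate columns (BMI, EDE-Q, ...).
    connectomes : mapping (subject_id, time_point) -> (n, n) ndarray
    """

    def __init__(self, manifest: pd.DataFrame, connectomes: dict, node_table: pd.DataFrame | None = None):
        required = {"subject_id", "group", "time_point"}
        if not required.issubset(manifest.columns):
            raise ValueError(f"manifest must have columns {sorted(required)}")
        dup = manifest.duplicated(["subject_id", "time_point"])
        if dup.any():
            raise ValueError("manifest has duplicate (subject_id, time_point) rows")
        self.manifest = manifest.reset_index(drop=True)
        self.connectomes = dict(connectomes)
        self.node_table = node_table
        missing = [
            (r.subject_id, r.time_point)
            for r in self.manifest.itertuples()
            if (r.subject_id, r.time_point) not in self.connectomes
        ]
        if missing:
            raise ValueError(f"manifest rows without connectome: {missing[:5]}")
        first = next(iter(self.connectomes.values()))
        self.n_nodes = int(first.shape[0])

    # -- basic introspection -------------------------------------------------
    @property
    def groups(self) -> list[str]:
        return sorted(self.manifest["group"].unique())

    @property
    def time_points(self) -> list[str]:
        return sorted(self.manifest["time_point"].unique())

    def subjects(self, group: str | None = None, time_point: str | None = None) -> list[str]:
        df = self.manifest
        if group is not None:
            df = df[df["group"] == group]
        if time_point is not None:
            df = df[df["time_point"] == time_point]
        return sorted(df["subject_id"].unique())

    def get(self, subject_id: str, time_point: str) -> np.ndarray:
        return self.connectomes[(subject_id, time_point)]

    def validate(self, atol: float = 1e-8) -> None:
        """Assert symmetry, zero diagonal and finiteness of every connectome."""
        for key, mat in self.connectomes.items():
            if mat.shape != (self.n_nodes, self.n_nodes):
                raise ValueError(f"{key}: wrong shape {mat.shape}")
            if not np.all(np.isfinite(mat)):
                raise ValueError(f"{key}: non-finite entries")
            if np.abs(mat - mat.T).max() > atol:
                raise ValueError(f"{key}: asymmetric connectome")
            if np.abs(np.diag(mat)).max() > atol:
                raise ValueError(f"{key}: nonzero diagonal")

    # -- array extraction for the estimators ---------------------------------
    def stack(self, group: str | None = None, time_point: str | None = None):
        """Stacked connectomes (S, n, n) plus the matching subject ids."""
        ids = self.subjects(group=group, time_point=time_point)
        if time_point is None:
            raise ValueError("stack() requires a time_point")
        mats = np.stack([self.get(s, time_point) for s in ids])
        return mats, ids

    def edge_data(self, groups: tuple[str, str], time_point: str):
        """Edge-vector design matrix X (S, n_edges) and group labels y."""
        xs, ys = [], []
        for g in groups:
            mats, ids = self.stack(group=g, time_point=time_point)
            xs.append(mat_to_vec(mats))
            ys.extend([g] * len(ids))
        return np.vstack(xs), np.array(ys)

    def paired_stack(self, group: str, t1: str, t2: str):
        """(S, 2, n, n) array over subjects observed at both time points."""
        ids = sorted(set(self.subjects(group=group, time_point=t1)) & set(self.subjects(group=group, time_point=t2)))
        if not ids:
            raise ValueError(f"no subjects of group {group} at both {t1} and {t2}")
        mats = np.stack([[self.get(s, t1), self.get(s, t2)] for s in ids])
        return mats, ids

    def longitudinal_stack(self, groups: tuple[str, str], t1: str, t2: str):
        """(S, 2, n, n) across both groups (complete cases) plus labels."""
        mats, labels, ids = [], [], []
        for g in groups:
            m, i = self.paired_stack(g, t1, t2)
            mats.append(m)
            labels.extend([g] * len(i))
            ids.extend(i)
        return np.concatenate(mats), np.array(labels), ids

    # -- summaries ------------------------------------------------------------
    def global_strengths(self) -> pd.DataFrame:
        """Per subject-timepoint mean positive Fisher-z (global strength)."""
        rows = [
            (r.subject_id, r.group, r.time_point, global_strength(self.get(r.subject_id, r.time_point)))
            for r in self.manifest.itertuples()
        ]
        return pd.DataFrame(rows, columns=["subject_id", "group", "time_point", "global_strength"])

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"CohortPanel(n_nodes={self.n_nodes}, groups={self.groups}, "
            f"time_points={self.time_points}, n_rows={len(self.manifest)})"
        )
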