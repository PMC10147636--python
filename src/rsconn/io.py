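"""Plain-text formats: square matrices, node tables, manifests, configs.

Everything is TSV with a single header line; matrices carry their node ids as
both header and index so round trips are exact to the printed precision
(17 significant digits, i.e. bit-exact for doubles).
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .panel import CohortPanel
from .simulate import CommunityStructure, SimulationConfig

__all__ = [
    "write_matrix",
    "read_matrix",
    "validate_connectome",
    "default_node_table",
    "read_node_table",
    "write_node_table",
    "read_manifest",
    "write_manifest",
    "load_panel",
    "write_panel",
    "read_config",
    "write_config",
]

_LOBE_BLOCKS = (("C", 8), ("F", 24), ("I", 6), ("L", 12), ("O", 12), ("P", 10), ("S", 10), ("T", 12))


def write_matrix(path, mat: np.ndarray, node_ids=None) -> None:
    """Write a square matrix as TSV with node-id header and index."""
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"matrix must be square, got shape {mat.shape}")
    ids = [str(i) for i in (node_ids if node_ids is not None else range(mat.shape[0]))]
    df = pd.DataFrame(mat, index=ids, columns=ids)
    df.to_csv(path, sep="\t", float_format="%.17g", index_label="node")


def read_matrix(path, expected_nodes: int | None = None) -> np.ndarray:
    """Read a square TSV matrix; raises on ragged, non-numeric or wrong size."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"{path}: cannot parse matrix TSV ({exc})") from exc
    if df.isna().any().any():
        raise ValueError(f"{path}: ragged rows or missing cells")
    try:
        mat = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cells") from exc
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{path}: matrix is {mat.shape[0]}x{mat.shape[1]}, expected square")
    if expected_nodes is not None and mat.shape[0] != expected_nodes:
        raise ValueError(f"{path}: expected {expected_nodes} nodes, found {mat.shape[0]}")
    return mat


def validate_connectome(mat: np.ndarray, atol: float = 1e-8, name: str = "connectome") -> np.ndarray:
    """Check symmetry, zero diagonal and finiteness; report the worst cell."""
    mat = np.asarray(mat, dtype=float)
    if not np.all(np.isfinite(mat)):
        i, j = np.argwhere(~np.isfinite(mat))[0]
        raise ValueError(f"{name}: non-finite entry at ({i}, {j})")
    asym = np.abs(mat - mat.T)
    if asym.max() > atol:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValueError(
            f"{name}: asymmetric at ({i}, {j}): {mat[i, j]!r} vs {mat[j, i]!r} (|diff| = {asym[i, j]:.3g})"
        )
    d = np.abs(np.diag(mat))
    if d.max() > atol:
        i = int(np.argmax(d))
        raise ValueError(f"{name}: nonzero diagonal at node {i}: {mat[i, i]!r}")
    return mat


def default_node_table(n_nodes: int = 94) -> pd.DataFrame:
    """Synthetic node table: contiguous ids, region labels, hemisphere, lobe code.

    At 94 nodes the lobe block sizes mirror an anatomical parcellation
    (central, frontal, insula, limbic, occipital, parietal, subcortical,
    temporal); other sizes spread nodes evenly over the eight codes.
    """
    if n_nodes == 94:
        lobes = [code for code, size in _LOBE_BLOCKS for _ in range(size)]
    else:
        codes = [c for c, _ in _LOBE_BLOCKS]
        base, extra = divmod(n_nodes, len(codes))
        lobes = [codes[i] for i in range(len(codes)) for _ in range(base + (1 if i < extra else 0))]
    rows = []
    for i, lobe in enumerate(lobes):
        hemi = "L" if i % 2 == 0 else "R"
        rows.append((i, f"{lobe}{i // 2 + 1:02d}{hemi}", hemi, lobe))
    return pd.DataFrame(rows, columns=["node_id", "label", "hemisphere", "lobe"])


def write_node_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_node_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"node_id", "label", "hemisphere", "lobe"}
    if not required.issubset(table.columns):
        raise ValueError(f"node table must have columns {sorted(required)}")
    ids = table["node_id"].to_numpy()
    if not np.array_equal(ids, np.arange(len(ids))):
        raise ValueError("node ids must be 0-based and contiguous")
    if table["label"].duplicated().any():
        raise ValueError("node labels must be unique")
    return table


def write_manifest(path, manifest: pd.DataFrame) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest(path, check_files: bool = True) -> pd.DataFrame:
    manifest = pd.read_csv(path, sep="\t")
    required = {"subject_id", "group", "time_point"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    if manifest.duplicated(["subject_id", "time_point"]).any():
        raise ValueError("manifest has duplicate (subject_id, time_point) rows")
    if check_files and "file" in manifest.columns:
        root = Path(path).parent
        missing = [f for f in manifest["file"] if not (root / f).exists() and not Path(f).exists()]
        if missing:
            raise ValueError(f"manifest references missing files: {missing[:5]}")
    return manifest


def load_panel(manifest_path, validate: bool = True) -> CohortPanel:
    """Load a cohort of connectome TSVs referenced by a manifest."""
    manifest = read_manifest(manifest_path)
    if "file" not in manifest.columns:
        raise ValueError("manifest needs a 'file' column to load connectomes")
    root = Path(manifest_path).parent
    mats = {}
    for r in manifest.itertuples():
        p = Path(r.file) if Path(r.file).exists() else root / r.file
        mat = read_matrix(p)
        if validate:
            validate_connectome(mat, name=str(p))
        mats[(r.subject_id, r.time_point)] = mat
    return CohortPanel(manifest.drop(columns=["file"]), mats)


def write_panel(panel: CohortPanel, outdir) -> Path:
    """Write one matrix TSV per subject-timepoint plus the manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for r in panel.manifest.itertuples():
        fname = f"{r.subject_id}_{r.time_point}.tsv"
        write_matrix(outdir / fname, panel.get(r.subject_id, r.time_point))
        files.append(fname)
    manifest = panel.manifest.copy()
    manifest["file"] = files
    mpath = outdir / "manifest.tsv"
    write_manifest(mpath, manifest)
    return mpath


# ---------------------------------------------------------------------------
# simulation config files
# ---------------------------------------------------------------------------

def write_config(path, config: SimulationConfig) -> None:
    payload = asdict(config)
    payload["communities"] = {g: {"within_r": c.within_r, "between_r": c.between_r} for g, c in config.communities.items()}
    payload["time_points"] = {g: list(t) for g, t in config.time_points.items()}
    payload["planted_subnetwork"] = list(config.planted_subnetwork)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_config(path) -> SimulationConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    if "communities" in payload:
        payload["communities"] = {g: CommunityStructure(**c) for g, c in payload["communities"].items()}
    if "time_points" in payload:
        payload["time_points"] = {g: tuple(t) for g, t in payload["time_points"].items()}
    if "planted_subnetwork" in payload:
        payload["planted_subnetwork"] = tuple(payload["planted_subnetwork"])
    if "community_sizes" in payload and payload["community_sizes"] is not None:
        payload["community_sizes"] = tuple(payload["community_sizes"])
    cfg = SimulationConfig(**payload)
    cfg.validate()
    return cfg
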