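"""Synthetic two-group, multi-time-point resting-state cohorts.

The generator works in Fisher-z space. Each group (patients "AN", controls
"HC") has a block-structured target correlation matrix: nodes fall into
communities (by default mirroring the lobe groups of the 94-node table) with a
within-community and a between-community correlation level. The overall scale
is calibrated so that the expected per-subject global strength (mean positive
Fisher-z) matches the configured group mean (defaults 0.29 for patients,
0.33 for controls). An optional planted subnetwork attenuates the patient
group's edges within a node set by a configurable Fisher-z shift per time
point, emulating focal underconnectivity that partially recovers.

Subject-level heterogeneity has three seeded components, all in z-space:
a scalar strength offset (shifts all edges of a subject), edge-level
perturbations, and measurement noise from the finite time series itself. The
first two are split into a latent part shared across a subject's time points
and an occasion-specific part, mixed by ``longitudinal_rho`` so that rho is
the across-time correlation of a subject's edge perturbations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy import stats as sps
import pandas as pd

from ._utils import mat_to_vec, rng_for, vec_to_mat
from .connectome import TimeSeriesMatrix, VoxelBlock, compute_connectome
from .panel import CohortPanel

__all__ = [
    "CommunityStructure",
    "SimulationConfig",
    "study_config",
    "community_labels",
    "build_target_covariance",
    "simulate_subject_timeseries",
    "simulate_cohort",
    "null_cohort",
    "simulate_voxel_blocks",
]

#: node counts per lobe code for the default 94-node table
LOBE_SIZES_94 = (("C", 8), ("F", 24), ("I", 6), ("L", 12), ("O", 12), ("P", 10), ("S", 10), ("T", 12))


@dataclass(frozen=True)
class CommunityStructure:
    """Within/between-community correlation levels of one group."""

    within_r: float
    between_r: float


def _default_communities():
    # Patients: disproportionately weakened between-community coupling ->
    # higher modularity and path length, lower clustering after proportional
    # thresholding; controls keep stronger long-range integration.
    return {
        "AN": CommunityStructure(within_r=0.50, between_r=0.14),
        "HC": CommunityStructure(within_r=0.55, between_r=0.24),
    }


def _default_base_connectivity():
    return {"AN": {"TP1": 0.29, "TP2": 0.31, "TP3": 0.29}, "HC": 0.33}


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator (see module docstring).

    Defaults emulate the study conditions: 94 nodes, groups of 27 patients
    (three time points) and 40 controls (two time points), group global
    strengths 0.29/0.31/0.29 vs 0.33.
    """

    n_nodes: int = 94
    n_timepoints_signal: int = 200
    group_sizes: dict = field(default_factory=lambda: {"AN": 27, "HC": 40})
    time_points: dict = field(default_factory=lambda: {"AN": ("TP1", "TP2", "TP3"), "HC": ("TP1", "TP3")})
    base_connectivity: dict | None = field(default_factory=_default_base_connectivity)
    communities: dict = field(default_factory=_default_communities)
    n_communities: int = 7
    community_sizes: tuple | None = None
    planted_subnetwork: tuple = ()
    planted_effect: float | dict = 0.0  # Fisher-z shift (negative = underconnectivity)
    planted_group: str = "AN"
    longitudinal_rho: float = 0.5
    noise_sd: float = 0.02
    subject_strength_sd: float = 0.08
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs >= 2 subjects (got {n})")
            if g not in self.time_points:
                raise ValueError(f"no time points configured for group {g!r}")
            if g not in self.communities:
                raise ValueError(f"no community structure configured for group {g!r}")
        if not 0.0 <= self.longitudinal_rho < 1.0:
            raise ValueError("longitudinal_rho must lie in [0, 1)")
        if self.n_timepoints_signal < 10:
            raise ValueError("n_timepoints_signal must be >= 10")
        bad = [i for i in self.planted_subnetwork if not 0 <= int(i) < self.n_nodes]
        if bad:
            raise ValueError(f"planted_subnetwork indices out of range: {bad}")
        for g, cs in self.communities.items():
            if not (-1 < cs.between_r < 1 and -1 < cs.within_r < 1):
                raise ValueError(f"correlations of group {g!r} must lie in (-1, 1)")


def study_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Config emulating the full study design, including the planted patient subnetwork.

    The planted effect (Fisher-z attenuation on a 10-node set) is strongest
    in the underweight phase (TP1) and partially recovers afterwards.
    """
    cfg = SimulationConfig(
        planted_subnetwork=tuple(range(10)),
        planted_effect={"TP1": -0.15, "TP2": -0.10, "TP3": -0.10},
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def community_labels(config: SimulationConfig) -> np.ndarray:
    """Community index per node: lobe-group sizes at 94 nodes, else even split."""
    if config.community_sizes is not None:
        sizes = list(config.community_sizes)
    elif config.n_nodes == 94 and config.n_communities == 7:
        # merge the two smallest lobe groups pairwise into 7 blocks
        lobes = [s for _, s in LOBE_SIZES_94]  # 8 lobes
        lobes[0] += lobes[2]  # central + insula
        del lobes[2]
        sizes = lobes
    else:
        k = config.n_communities
        base, extra = divmod(config.n_nodes, k)
        sizes = [base + (1 if i < extra else 0) for i in range(k)]
    if sum(sizes) != config.n_nodes:
        raise ValueError(f"community sizes {sizes} do not sum to n_nodes={config.n_nodes}")
    return np.repeat(np.arange(len(sizes)), sizes)


def _edge_sigma(config: SimulationConfig) -> float:
    """Total sd of a realized Fisher-z edge around its target value."""
    sampling_var = 1.0 / (config.n_timepoints_signal - 3)
    return float(np.sqrt(config.noise_sd**2 + config.subject_strength_sd**2 + sampling_var))


def _expected_mean_positive(z: np.ndarray, sigma: float) -> float:
    """E[mean of positive realized edges] for targets z with Gaussian spread sigma."""
    lam = z / sigma
    num = (z * sps.norm.cdf(lam) + sigma * sps.norm.pdf(lam)).sum()
    den = sps.norm.cdf(lam).sum()
    return float(num / den)


def _base_value(config: SimulationConfig, group: str, time: str) -> float | None:
    if config.base_connectivity is None:
        return None
    val = config.base_connectivity.get(group)
    if val is None:
        return None
    if isinstance(val, dict):
        if time not in val:
            raise ValueError(f"no base_connectivity for group {group!r} at {time!r}")
        return float(val[time])
    return float(val)


def _planted_delta(config: SimulationConfig, time: str) -> float:
    eff = config.planted_effect
    if isinstance(eff, dict):
        return float(eff.get(time, 0.0))
    return float(eff)


def build_target_covariance(config: SimulationConfig, group: str, time: str) -> np.ndarray:
    """Target correlation matrix of one (group, time) cell.

    Symmetric positive definite; when ``base_connectivity`` is set, the matrix
    is rescaled in z-space so the expected realized global strength (including
    noise and positive-part truncation) equals the configured group mean.
    Raises with the offending parameters if the result is not positive
    definite or the calibration target is unreachable.
    """
    config.validate()
    cs: CommunityStructure = config.communities[group]
    labels = community_labels(config)
    same = labels[:, None] == labels[None, :]
    r0 = np.where(same, cs.within_r, cs.between_r).astype(float)
    np.fill_diagonal(r0, 1.0)
    z0 = np.arctanh(mat_to_vec(r0))

    target = _base_value(config, group, time)
    if target is not None and np.any(z0 != 0):
        sigma = _edge_sigma(config)
        zmax = np.abs(z0).max()
        c_hi = np.arctanh(0.99) / zmax

        def gap(c):
            return _expected_mean_positive(c * z0, sigma) - target

        if gap(c_hi) < 0:
            raise ValueError(
                f"base_connectivity {target} unreachable for group {group!r} "
                f"(within_r={cs.within_r}, between_r={cs.between_r}): max attainable "
                f"{_expected_mean_positive(c_hi * z0, sigma):.3f}"
            )
        if gap(1e-9) > 0:
            raise ValueError(
                f"base_connectivity {target} below the noise floor "
                f"{_expected_mean_positive(0 * z0, sigma):.3f} for group {group!r}"
            )
        c = optimize.brentq(gap, 1e-9, c_hi, xtol=1e-12)
        z = c * z0
    elif target is not None and not np.any(z0 != 0):
        raise ValueError(f"cannot calibrate base_connectivity {target} with zero off-diagonal correlation")
    else:
        z = z0

    delta = _planted_delta(config, time)
    if config.planted_subnetwork and group == config.planted_group and delta != 0.0:
        nodes = np.asarray(config.planted_subnetwork, dtype=int)
        iu, ju = np.triu_indices(config.n_nodes, k=1)
        in_set = np.isin(iu, nodes) & np.isin(ju, nodes)
        z = z.copy()
        z[in_set] += delta

    r = vec_to_mat(np.tanh(z), config.n_nodes, diag=1.0)
    w = np.linalg.eigvalsh(r)
    if w.min() <= 1e-10:
        raise ValueError(
            f"target covariance not positive definite for group {group!r} at {time!r} "
            f"(within_r={cs.within_r}, between_r={cs.between_r}, planted delta={delta}); "
            f"min eigenvalue {w.min():.3e}"
        )
    return r


def _nearest_pd_correlation(r: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues and renormalize the diagonal to 1 (deterministic)."""
    w, v = np.linalg.eigh(r)
    if w.min() > floor:
        return r
    w = np.clip(w, floor, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    return (fixed + fixed.T) / 2.0


def _subject_target_z(config: SimulationConfig, group: str, time: str, subject: str, base_z: np.ndarray) -> np.ndarray:
    """Per subject-timepoint target z vector: base + latent/occasion perturbations."""
    rho = config.longitudinal_rho
    latent = rng_for(config.seed, "latent", subject)
    occ = rng_for(config.seed, "occasion", subject, time)
    n_edges = base_z.shape[0]
    a = latent.standard_normal(n_edges)
    s_lat = latent.standard_normal()
    b = occ.standard_normal(n_edges)
    s_occ = occ.standard_normal()
    edge_pert = config.noise_sd * (np.sqrt(rho) * a + np.sqrt(1.0 - rho) * b)
    offset = config.subject_strength_sd * (np.sqrt(rho) * s_lat + np.sqrt(1.0 - rho) * s_occ)
    return base_z + edge_pert + offset


def simulate_subject_timeseries(
    config: SimulationConfig,
    group: str,
    time: str,
    subject: str,
    covariance: np.ndarray | None = None,
) -> TimeSeriesMatrix:
    """Multivariate-normal node time series for one subject-timepoint.

    Bit-identical on repeated calls with the same config: the draw streams are
    keyed by (config.seed, subject, time), so subject order does not matter.
    """
    if covariance is None:
        covariance = build_target_covariance(config, group, time)
    base_z = np.arctanh(np.clip(mat_to_vec(covariance), -1 + 1e-12, 1 - 1e-12))
    z = _subject_target_z(config, group, time, subject, base_z)
    r = vec_to_mat(np.tanh(z), config.n_nodes, diag=1.0)
    r = _nearest_pd_correlation(r)
    chol = np.linalg.cholesky(r)
    draw = rng_for(config.seed, "signal", subject, time)
    x = chol @ draw.standard_normal((config.n_nodes, config.n_timepoints_signal))
    return TimeSeriesMatrix(subject_id=subject, data=x, group=group, time_point=time)


def simulate_subject_connectome(
    config: SimulationConfig,
    group: str,
    time: str,
    subject: str,
    covariance: np.ndarray | None = None,
) -> np.ndarray:
    """Draw a subject connectome directly in Fisher-z space (no signal sampling).

    The edge values are the subject's target z plus the seeded latent/occasion
    perturbations; ``noise_sd`` is then the entire independent edge spread.
    Unlike :func:`simulate_subject_timeseries`, edges are independent across
    the connectome, which makes planted per-edge effect sizes exact — the
    mode used by the recovery benchmarks.
    """
    if covariance is None:
        covariance = build_target_covariance(config, group, time)
    base_z = np.arctanh(np.clip(mat_to_vec(covariance), -1 + 1e-12, 1 - 1e-12))
    z = _subject_target_z(config, group, time, subject, base_z)
    return vec_to_mat(z, config.n_nodes, diag=0.0)


def subject_ids(config: SimulationConfig) -> dict[str, list[str]]:
    return {g: [f"{g}{i + 1:03d}" for i in range(n)] for g, n in sorted(config.group_sizes.items())}


def simulate_cohort(config: SimulationConfig, return_timeseries: bool = False, mode: str = "timeseries"):
    """Generate the full cohort.

    ``mode="timeseries"`` (default) draws node signals and correlates them —
    the realistic route, in which sample correlations share node signals and
    are therefore dependent across edges. ``mode="direct"`` draws Fisher-z
    connectomes with independent edge noise (see
    :func:`simulate_subject_connectome`).

    Returns a :class:`CohortPanel` of connectomes, or (panel, {key: TimeSeriesMatrix})
    when ``return_timeseries`` is true.
    """
    if mode not in ("timeseries", "direct"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "direct" and return_timeseries:
        raise ValueError("direct mode draws no time series")
    config.validate()
    rows, mats, series = [], {}, {}
    for group, ids in subject_ids(config).items():
        for time in config.time_points[group]:
            cov = build_target_covariance(config, group, time)
            for sid in ids:
                if mode == "direct":
                    mats[(sid, time)] = simulate_subject_connectome(config, group, time, sid, covariance=cov)
                else:
                    ts = simulate_subject_timeseries(config, group, time, sid, covariance=cov)
                    if return_timeseries:
                        series[(sid, time)] = ts
                    mats[(sid, time)] = compute_connectome(ts)
                rows.append((sid, group, time))
    manifest = pd.DataFrame(rows, columns=["subject_id", "group", "time_point"])
    panel = CohortPanel(manifest, mats)
    return (panel, series) if return_timeseries else panel


def null_cohort(config: SimulationConfig, seed: int) -> CohortPanel:
    """Cohort in which both groups share one generative process (type-I harness).

    Group labels keep their sizes and time points, but community structure,
    calibration target and planted effects are identical across groups (taken
    from the control group when present).
    """
    ref_group = "HC" if "HC" in config.communities else sorted(config.communities)[0]
    cs = config.communities[ref_group]
    base = None
    if config.base_connectivity is not None:
        ref = config.base_connectivity.get(ref_group)
        if isinstance(ref, dict):
            ref = float(np.mean(list(ref.values())))
        base = {g: ref for g in config.group_sizes} if ref is not None else None
    cfg = replace(
        config,
        seed=seed,
        planted_subnetwork=(),
        planted_effect=0.0,
        communities={g: cs for g in config.group_sizes},
        base_connectivity=base,
    )
    return simulate_cohort(cfg)


def simulate_voxel_blocks(config: SimulationConfig, subject: str, reho_w_target: float, seed: int) -> list[VoxelBlock]:
    """One 27-voxel block per node whose concordance grows with the mixing weight.

    ``reho_w_target`` in [0, 1] is the shared-signal mixing weight: 1 makes the
    27 voxel series identical (W = 1); 0 makes them independent (E[W] ~ 1/27).
    """
    if not 0.0 <= reho_w_target <= 1.0:
        raise ValueError("reho_w_target must lie in [0, 1]")
    t = config.n_timepoints_signal
    blocks = []
    for node in range(config.n_nodes):
        rng = rng_for(seed, "voxel", subject, node)
        shared = rng.standard_normal(t)
        noise = rng.standard_normal((27, t))
        series = reho_w_target * shared[None, :] + (1.0 - reho_w_target) * noise
        blocks.append(VoxelBlock(node_id=node, series=series))
    return blocks
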