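"""End-to-end pipeline driver.

Runs the full analysis in study order — connectomes, global strength
statistics, network-based statistic, topology curves, cluster-based
permutation — writing one deterministic directory of TSV results. Every stage
logs its parameters and seed; a failing stage halts only its dependents.
"""

from __future__ import annotations

import hashlib
import json
import traceback
from pathlib import Path

import pandas as pd
import yaml

from . import io as rio
from .clusterperm import cluster_fwe_test
from .nbs import nbs_test, subnetwork_mean_connectivity
from .panel import CohortPanel
from .simulate import SimulationConfig, simulate_cohort
from .stats import mixed_anova, paired_t, welch_t
from .topology import default_density_grid, metric_curves

__all__ = ["run_pipeline"]


def _config_hash(config) -> str:
    if isinstance(config, SimulationConfig):
        payload = yaml.safe_dump(
            {k: str(v) for k, v in vars(config).items()}, sort_keys=True
        )
    else:
        payload = str(config)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(
    config,
    outdir,
    *,
    groups=("AN", "HC"),
    nbs_threshold: float = 3.0,
    n_perm_nbs: int = 5000,
    n_perm_cluster: int = 10000,
    densities=None,
    n_restarts: int = 20,
    seed: int | None = None,
    write_connectomes: bool = True,
) -> dict:
    """Run every analysis stage on a simulated or loaded cohort.

    Parameters
    ----------
    config : SimulationConfig or path to a manifest TSV
    outdir : output directory (created if needed)
    seed : master seed for the permutation procedures (defaults to the
        simulation seed when a SimulationConfig is given).

    Returns a dict with the panel, per-stage status and output paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    densities = default_density_grid() if densities is None else densities
    log: list[str] = []
    status: dict[str, str] = {}

    def note(msg):
        log.append(msg)

    if isinstance(config, SimulationConfig):
        seed = config.seed if seed is None else seed
        panel = simulate_cohort(config)
        note(f"simulated cohort (seed={config.seed})")
    else:
        panel = rio.load_panel(config)
        seed = 0 if seed is None else seed
        note(f"loaded cohort from {config}")
    note(f"config hash {_config_hash(config)}; master seed {seed}")
    panel.validate()
    status["cohort"] = "ok"

    if write_connectomes:
        rio.write_panel(panel, outdir / "connectomes")
        note("wrote connectomes/")

    t1, t_last = _first_last_time(panel, groups)

    # -- global strength -----------------------------------------------------
    stats_rows = []
    try:
        strengths = panel.global_strengths()
        strengths.to_csv(outdir / "strength.tsv", sep="\t", index=False)
        for tp in sorted(set(panel.manifest["time_point"])):
            a = strengths.query("group == @groups[0] and time_point == @tp")["global_strength"]
            b = strengths.query("group == @groups[1] and time_point == @tp")["global_strength"]
            if len(a) >= 2 and len(b) >= 2:
                res = welch_t(a, b)
                stats_rows.append(
                    (f"strength {groups[0]} vs {groups[1]} at {tp}", res.statistic, res.df, res.p, res.g)
                )
        both = strengths[strengths["time_point"].isin([t1, t_last])]
        if both["time_point"].nunique() == 2:
            res = mixed_anova(both.rename(columns={"global_strength": "value"}))
            stats_rows.append(("strength group x time interaction", res.statistic, str(res.df), res.p, None))
        status["strength"] = "ok"
        note("global strength stage ok")
    except Exception as exc:  # pragma: no cover - defensive
        status["strength"] = f"failed: {exc}"
        note(traceback.format_exc())

    # -- network-based statistic ----------------------------------------------
    nbs_dir = outdir / "nbs"
    nbs_dir.mkdir(exist_ok=True)
    subnet_edges = None
    try:
        comp_rows = []
        for contrast in ("less", "greater"):
            comps = nbs_test(
                panel,
                design="two_sample",
                groups=groups,
                time_point=t1,
                contrast=contrast,
                threshold=nbs_threshold,
                n_perm=n_perm_nbs,
                seed=seed,
            )
            for c in comps:
                comp_rows.append((contrast, c.component_id, len(c.nodes), c.extent, c.p_fwe))
            sig = [c for c in comps if c.p_fwe < 0.05]
            if contrast == "less" and sig:
                subnet_edges = sig[0].edges
                edges = pd.DataFrame(sig[0].edges, columns=["node_i", "node_j"])
                edges.to_csv(nbs_dir / "subnetwork_edges.tsv", sep="\t", index=False)
        pd.DataFrame(
            comp_rows, columns=["contrast", "component_id", "n_nodes", "extent", "p_fwe"]
        ).to_csv(nbs_dir / "components.tsv", sep="\t", index=False)
        status["nbs"] = "ok"
        note(f"nbs stage ok at {t1} (threshold {nbs_threshold}, {n_perm_nbs} permutations)")
    except Exception as exc:
        status["nbs"] = f"failed: {exc}"
        note(traceback.format_exc())

    # -- subnetwork follow-up (depends on nbs) --------------------------------
    if subnet_edges is not None:
        try:
            mc = subnetwork_mean_connectivity(panel, subnet_edges)
            mc.to_csv(nbs_dir / "subnetwork_mean_connectivity.tsv", sep="\t", index=False)
            g0 = groups[0]
            tps = [t for t in panel.time_points if not panel.manifest.query("group == @g0 and time_point == @t").empty]
            for ta, tb in zip(tps, tps[1:]):
                wa = mc.query("group == @g0 and time_point == @ta").set_index("subject_id")["mean_connectivity"]
                wb = mc.query("group == @g0 and time_point == @tb").set_index("subject_id")["mean_connectivity"]
                common = wa.index.intersection(wb.index)
                if len(common) >= 2:
                    res = paired_t(wa[common], wb[common])
                    stats_rows.append((f"subnetwork mean {g0} {ta}->{tb}", res.statistic, res.df, res.p, res.g))
            status["subnetwork_followup"] = "ok"
        except Exception as exc:
            status["subnetwork_followup"] = f"failed: {exc}"
            note(traceback.format_exc())
    else:
        status["subnetwork_followup"] = "skipped (no significant subnetwork or nbs failed)"

    # -- topology curves -------------------------------------------------------
    curves = None
    try:
        curves = metric_curves(panel, densities=densities, seed=seed, n_restarts=n_restarts)
        curves.to_csv(outdir / "topology.tsv", sep="\t", index=False)
        status["topology"] = "ok"
        note("topology stage ok")
    except Exception as exc:
        status["topology"] = f"failed: {exc}"
        note(traceback.format_exc())

    # -- cluster-based permutation (depends on topology) -----------------------
    if curves is not None:
        try:
            results = cluster_fwe_test(
                curves, time_point=t1, groups=groups, n_perm=n_perm_cluster, seed=seed
            )
            pd.DataFrame(
                [
                    (r.metric, r.start_density, r.end_density, r.k, r.p_fwe)
                    for r in results
                ],
                columns=["metric", "cluster_start_density", "cluster_end_density", "k", "p_fwe"],
            ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
            status["clusterperm"] = "ok"
            note(f"cluster permutation ok at {t1} ({n_perm_cluster} permutations)")
        except Exception as exc:
            status["clusterperm"] = f"failed: {exc}"
            note(traceback.format_exc())
    else:
        status["clusterperm"] = "skipped (topology failed)"

    pd.DataFrame(stats_rows, columns=["contrast", "statistic", "df", "p", "g"]).to_csv(
        outdir / "stats.tsv", sep="\t", index=False
    )
    (outdir / "log.txt").write_text("\n".join(log) + "\n")
    (outdir / "status.json").write_text(json.dumps(status, indent=2))
    return {"panel": panel, "status": status, "outdir": outdir}


def _first_last_time(panel: CohortPanel, groups) -> tuple[str, str]:
    common = None
    for g in groups:
        tps = set(panel.manifest.query("group == @g")["time_point"])
        common = tps if common is None else (common & tps)
    ordered = sorted(common)
    return ordered[0], ordered[-1]
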