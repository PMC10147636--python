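# rsconn

Longitudinal resting-state connectomics in Python: Fisher-z connectome
construction, global strength, the network-based statistic (NBS), weighted
graph topology over proportional density thresholds, and cluster-based
permutation inference — together with a seeded synthetic cohort generator so
the whole pipeline can be exercised end to end without any imaging data.

## The problem

Resting-state fMRI studies of clinical groups (the motivating design is a
two-group, three-time-point inpatient study: patients measured at treatment
start, mid-treatment, and discharge; matched controls at the first and last
occasions) summarize each scan as a **connectome**: with regional mean time
series $x_i(t)$ for $N$ parcellation nodes (default $N = 94$), the edge
weight between nodes $i$ and $j$ is the Fisher-transformed Pearson
correlation

$$z_{ij} = \operatorname{atanh}\, r(x_i, x_j).$$

Three families of questions follow, each with its own inference machinery:

1. **Global strength** — the per-subject mean of all positive $z_{ij}$
   (negative edges and the diagonal excluded), compared across groups and
   occasions with two-tailed Welch $t$-tests, a 2×2 group×time mixed ANOVA,
   and Hedges' $g$ effect sizes.
2. **Subnetworks** — the **network-based statistic**: an edge-wise two-sample
   $t$ matrix is thresholded at a primary statistic value (default
   $t = 3.0$, i.e. $d = t\sqrt{1/n_1 + 1/n_2} \ge 0.7$ at $n = 27/40$);
   connected components of the suprathreshold graph are scored by their
   *extent* (number of edges) and assigned family-wise-error-corrected
   p-values from the permutation distribution of the maximal null extent.
   Supported designs: two-sample, paired (sign-flip permutation), and
   group×time interaction (subject-level label permutation).
3. **Topology** — connectomes are thresholded at proportional densities
   0.05–0.45 (step 0.01, 41 points), keeping the strongest positive edges
   with weights preserved, and summarized by weighted characteristic path
   length $L$ (geodesics with length $1/w$), the Onnela global clustering
   coefficient $C$ (weights rescaled by the graph maximum), and Louvain
   modularity $Q$. Group differences in the metric-vs-density curves are
   tested pointwise (Welch) and corrected across the grid with a
   **cluster-based permutation test**: labels are shuffled once per
   permutation and applied across the whole grid, the null statistic being
   the maximal run length $k$ of contiguous significant thresholds.

Regional homogeneity (Kendall's coefficient of concordance $W$ of a voxel
with its 26 neighbors) and the surrounding scalar statistics (Welch tests
from raw data or printed summary statistics, Holm–Bonferroni adjustment,
Pearson correlation reports) are included as well.

The synthetic-data module generates seeded cohorts with the statistical
structure these analyses assume — community-structured correlation matrices
calibrated to group mean strengths (0.29/0.33), a planted underconnected
subnetwork in the patient group, subject-level strength traits, and
within-subject dependence across occasions — so every stage has a
ground-truth test bed.

## Worked example

```python
import numpy as np
from rsconn import (study_config, simulate_cohort, welch_t, nbs_test,
                    metric_curves, cluster_fwe_test)

cfg = study_config(seed=42)          # 94 nodes, 27 patients / 40 controls
panel = simulate_cohort(cfg)

s = panel.global_strengths()
tp1 = s[s.time_point == "TP1"]
an = tp1[tp1.group == "AN"]["global_strength"]
hc = tp1[tp1.group == "HC"]["global_strength"]
print(f"global strength TP1: AN {an.mean():.3f} +/- {an.std():.3f}, "
      f"HC {hc.mean():.3f} +/- {hc.std():.3f}")
res = welch_t(an, hc)
print(f"Welch t({res.df:.2f}) = {res.statistic:.3f}, p = {res.p:.4f}, g = {res.g:.3f}")

comps = nbs_test(panel, groups=("AN", "HC"), time_point="TP1", contrast="less",
                 threshold=3.0, n_perm=1000, seed=42)
c = comps[0]
print(f"NBS (AN<HC, t=3.0): component with {len(c.nodes)} nodes, "
      f"{c.extent} connections, p_fwe = {c.p_fwe:.4f}")

curves = metric_curves(panel, densities=np.round(np.arange(5, 46, 5) / 100, 2),
                       metrics=("L",), seed=42)
for r in cluster_fwe_test(curves, time_point="TP1", n_perm=1000, seed=42):
    print(f"path-length cluster: densities {r.start_density:.2f}-{r.end_density:.2f}, "
          f"k = {r.k}, p_fwe = {r.p_fwe:.4f}")
```

prints

```
global strength TP1: AN 0.292 +/- 0.074, HC 0.343 +/- 0.077
Welch t(57.42) = -2.768, p = 0.0076, g = -0.676
NBS (AN<HC, t=3.0): component with 94 nodes, 2107 connections, p_fwe = 0.0010
path-length cluster: densities 0.05-0.45, k = 9, p_fwe = 0.0020
```

The simulated patient group is globally underconnected (strength 0.29 vs
0.33), so the NBS finds one large significant component of weakened edges and
the patients' path-length curve is significantly elevated across the whole
density grid.

A command-line interface mirrors the library
(`rsconn simulate | connectome | strength | nbs | topology | clusterperm |
stats | run`); `rsconn run --config cfg.yaml --out results/` executes the full
pipeline into one directory of TSV tables.

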