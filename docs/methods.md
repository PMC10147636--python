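# Methods

This note documents the models, numerical choices and known limitations of
`rsconn`. Nothing here reports an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Connectome construction

Edges are Fisher-transformed Pearson correlations between regional mean time
series, $z_{ij} = \operatorname{atanh} r_{ij}$, computed on the raw series
(denoising is upstream and out of scope). $|r|$ is clamped to $1 - 10^{-7}$
before the transform so perfectly correlated (duplicated) series yield a
finite edge rather than an infinity; at realistic correlations the clamp is
inactive. Zero-variance node series are a hard error naming the offending
nodes. The matrix is symmetrized exactly (averaging with its transpose
removes floating-point asymmetry from the correlation routine) and the
diagonal set to zero.

**Global strength** is the mean of the strictly positive upper-triangle
entries; zeros and negatives are excluded from numerator and denominator
alike. A connectome with no positive edge yields 0 with a warning.

**Regional homogeneity** is Kendall's coefficient of concordance across the
27 voxel series of a node's 3×3×3 neighborhood,
$W = 12 S / (m^2 (T^3 - T) - m C)$ with $S$ the squared deviation of rank
sums, mid-ranks for ties and the standard tie correction $C$. Raw $W$ is
used for group comparison without further transformation.

## Network-based statistic

The edge statistic is the pooled-variance two-sample $t$ (the classical NBS
choice); Welch is available via `edge_stat="welch"`. Contrasts are
one-sided: underconnectivity (AN < HC) and overconnectivity (AN > HC) are
separate runs with the statistic's sign arranged so thresholding at $+t$
tests the stated direction. The paired design uses the one-sample $t$ on
edge differences with sign-flip permutation; the group×time interaction uses
$F = t^2$ of the pooled $t$ on per-subject change scores (the exact 2×2
split-plot interaction statistic), permuting group labels with each
subject's occasions kept together — subjects are the exchangeable units.
Component extent is the edge count; p-values use the $+1$ correction
$(1 + \#\{\text{null max extent} \ge k\})/(1 + n_{perm})$ so that p is never
zero (configurable). Components are ordered by extent, ties by smallest node
id, making output deterministic. Edge statistics are computed by a
group-sum matrix identity over all permutations at once; data are centered
per edge first so identical groups give exactly $t = 0$.

## Graph topology

Proportional thresholding keeps the $k = \mathrm{round}(d \cdot N(N-1)/2)$
strongest positive edges (round half away from zero), weights preserved;
ties at the cutoff are broken by (weight descending, node pair ascending).
If fewer positive edges exist than requested, all are kept and the graph is
flagged.

- **Characteristic path length** uses edge length $1/w$; unreachable pairs
  are excluded from the mean (their fraction is reported on request) rather
  than treated as infinite or harmonically averaged. Dense Floyd–Warshall is
  used up to 50 nodes, sparse Dijkstra beyond.
- **Clustering** is the Onnela geometric-mean form after rescaling weights
  by the graph maximum into $(0, 1]$:
  $C_i = \sum_{jh} (\hat w_{ij} \hat w_{ih} \hat w_{jh})^{1/3} / (k_i (k_i - 1))$,
  computed as the diagonal of the cubed cube-root adjacency. $C$ averages
  over all nodes with degree < 2 contributing zero (the contract's "mean
  over nodes with degree ≥ 2" wording is internally inconsistent with its
  "contribute 0" clause; the standard include-as-zero convention is used).
- **Modularity** is weighted Newman–Girvan
  $Q = \sum_c (e_c / m - (d_c / 2m)^2)$ of the best partition over 20 seeded
  Louvain restarts (networkx implementation), never below the trivial
  one-community partition ($Q = 0$). Restart seeds derive from the metric
  seed; per-graph seeds in the curve driver are stable hashes of
  (subject, time, density), so results do not depend on loop order.

Scale behavior: multiplying all weights by a constant leaves $C$ and $Q$
unchanged and divides $L$ by that constant.

## Cluster-based permutation over the density grid

Each metric's per-subject curve over the 41-density grid (0.05–0.45, step
0.01) is compared between groups with two-tailed Welch $t$-tests pointwise;
clusters are maximal runs of contiguous grid points with $p < 0.05$ and are
scored by their size $k$. The null distribution shuffles group labels once
per permutation and applies the same relabeling across the entire grid,
preserving each subject's across-threshold dependency; the null statistic is
the maximal cluster size. Each metric is corrected within itself (no
cross-metric correction). Both the $+1$ p-value convention (default) and the
plain proportion are available, as is a cluster-mass statistic (summed
$|t|$), which is useful when effects span the whole grid and the size
statistic saturates at its maximum. The longitudinal contrast is the
two-sample Welch test on per-subject change curves (last minus first
occasion).

## Scalar statistics

Welch tests accept raw samples or printed summary statistics (mean, SD, n)
and agree between the two routes to machine precision. Hedges'
$g = J \cdot \Delta m / s_{pooled}$ with $J = 1 - 3/(4\,df - 1)$
($= 1 - 3/(4(n_1+n_2) - 9)$ for the two-sample case); the paired version
uses $\bar d / s_d$ with $df = n - 1$. The 2×2 mixed ANOVA interaction is
delegated to `pingouin.mixed_anova` (listwise deletion of incomplete
subjects, reported in the result); its independent check in the tests is the
algebraic identity $F_{interaction} = t^2$ of the pooled two-sample $t$ on
change scores. Holm–Bonferroni goes through
`statsmodels.stats.multitest.multipletests`. Correlation reports use Pearson
$r$ with pairwise deletion and Holm correction within the family of
parameters belonging to one metric (six clinical/psychometric parameters per
graph metric).

## Synthetic cohort generator

The generator works in Fisher-z space.

**Population structure.** Each group has a block (community) correlation
matrix: 7 communities (mirroring the lobe groups of the default 94-node
table; even split otherwise) with a within- and a between-community
correlation level. Defaults encode the patient phenotype as
disproportionately weakened between-community coupling (AN 0.50/0.14 vs HC
0.55/0.24 before calibration): after proportional thresholding this yields
longer characteristic path length, higher modularity and lower clustering in
patients, with the clustering and modularity effects driven by the
within/between contrast (max-rescaled triangle intensities fall when
retained between-community weights are relatively weaker). On the noiseless
target matrices the implied group differences are ΔL ≈ +1.3, ΔC ≈ −0.05,
ΔQ ≈ +0.05; finite-length sampling attenuates the realized ΔC by roughly a
factor of five, which is why the directionality check pools several seeded
cohorts.

**Calibration.** The z-scale is calibrated so the *expected realized* global
strength matches the configured group mean (defaults AN 0.29/0.31/0.29 over
the three occasions, HC 0.33). Because realized edges scatter around their
targets (total spread $\sigma^2 = \sigma_{noise}^2 + \sigma_{subj}^2 +
1/(T-3)$) and negative realizations are excluded from the strength, the
calibration solves for the scale factor using closed-form truncated-normal
moments of the positive part rather than matching raw target means. A
target below the noise floor or above the attainable ceiling raises an
error naming the parameters. Simulated control cohorts at $n = 40$
reproduce the configured 0.33 within ±0.02 (tested).

**Subject heterogeneity and longitudinal dependence.** Three seeded
components, all in z-space: a scalar per-subject strength trait (sd 0.08,
matching per-group strength SDs of ≈0.08–0.10), iid edge perturbations
(sd 0.02), and sampling noise from the finite series (default length 200
samples — a free parameter chosen for stable correlation estimates at 94
nodes, not a claim about any acquisition). Trait and edge perturbations
split into a latent part shared across a subject's occasions and an
occasion-specific part mixed by `longitudinal_rho` (default 0.5), so
`rho = 0` gives zero across-time correlation of a subject's edge weights.
The edge-noise default is deliberately small: perturbing a 94-node
correlation matrix in z-space with iid noise much above sd ≈ 0.02 breaks
positive definiteness, and the eigenvalue repair then shrinks all
correlations and biases the calibration. Remaining indefiniteness (rare) is
repaired by eigenvalue clipping with diagonal renormalization,
deterministically.

**Planted subnetwork.** A node set whose within-set edges are shifted by a
configurable Fisher-z delta per occasion in the patient group only, applied
after calibration (the study-emulating `study_config` plants a 10-node set
at −0.15 in the underweight phase, recovering to −0.10 afterwards).

**Seeding.** All draws derive from
`SeedSequence([master_seed, crc32(labels...)])` keyed by subject and
occasion, so outputs are bit-identical on rerun and independent of
generation order.

**Two generation modes.** The default draws multivariate-normal time series
from the subject's target correlation matrix and correlates them — the
realistic route. Its important side effect: sample correlations share node
signals, so edge noise is *dependent across edges* and contains a
cohort-level common component (at $T = 200$, roughly ±1 $t$-unit on every
edge between two groups of 27/40). The `direct` mode instead emits the
subject's target z-matrix with iid edge noise; it exists for benchmarks that
need exact per-edge effect sizes.

## Validation harnesses and their design

- **Null FWE (NBS and cluster test).** 200 cohorts with both groups drawn
  from one generative process (30-node graphs, $n = 27/40$, the reduced size
  keeping the harness at minutes of CPU), 1,000 permutations each; the
  rejection fraction is compared with the binomial 95% interval around 0.05.
- **Planted recovery.** 50 cohorts in direct mode (iid edge noise, strength
  trait off) with a 10-node planted attenuation of exact per-edge
  $d = 0.75$ at $n = 27/40$. The component-forming threshold is 2.5: the
  alternative's expected edge statistic is $d/\sqrt{1/n_1 + 1/n_2} \approx
  3.0$, so a threshold at 3.0 leaves per-edge power at 1/2 and makes
  edge-level recovery a coin flip regardless of sample size; 2.5 restores a
  power margin while the permutation null still controls FWE. Graphs are 30
  nodes, as in the null harness — on much larger graphs spurious
  suprathreshold edges attach to the detected component and depress the
  edge-Jaccard toward 1/2 (and at low thresholds the null suprathreshold
  graph percolates).
- **Directionality.** Three seeded study-design cohorts (94 nodes, 27/40)
  pooled; patient-minus-control differences of grid-averaged $L$, $C$, $Q$
  and of global strength are checked for sign only.

## What the synthetic tests do and do not show

The generator reproduces the statistical skeleton the inference machinery
assumes: group differences in mean strength, community structure, planted
focal effects, within-subject dependence, realistic between-subject spread.
It does not emulate scanner noise, motion, physiological confounds,
hemodynamics, parcellation error, or empirical fMRI autocorrelation —
passing tests certify the correctness and calibration of the *statistics*,
not robustness to those acquisition-level artifacts. Negative-edge handling
follows the positive-only convention throughout; no conclusions about
anticorrelations are possible. The NBS edge model contains no covariates.

## Degenerate inputs and tie-breaking (summary)

Zero-variance series, empty graphs, empty edge sets, non-square or
asymmetric matrices, out-of-range densities and undersized groups raise
errors with the offending entity named. Ties: mid-ranks in Kendall's W;
(weight, node-pair) ordering at the proportional-threshold cutoff; component
ordering by (extent, smallest node). Identical groups produce exact zero
statistics by prior centering.
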