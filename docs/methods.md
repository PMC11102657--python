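# Methods

`wmtopo` re-implements, as a tested and reusable pipeline, the graph-theory
analysis commonly applied to white-matter structural connectomes in
case–control dementia studies: subject-level streamline-count matrices are
binarized across a sparsity sweep, summarized by global and nodal
topological metrics with random-network normalization, and compared across
groups with covariate adjustment and FDR control, alongside brain–behavior
partial correlations and a hub taxonomy. Because such studies rarely
deposit raw diffusion data, the package ships a synthetic cohort generator
that emulates the study design with known, recoverable effects; validation
is by parameter recovery and calibration rather than by re-analysis of the
original scans.

## Network construction

A subject arrives as a symmetric nonnegative integer matrix `W` of
streamline counts between `n = 90` AAL atlas regions. Construction has two
stages, in this order:

1. **Count threshold.** An entry survives only if its count is *strictly
   greater* than τ (default 3). This removes likely-spurious single-fiber
   connections before any density control.
2. **Sparsity thresholding.** For each sparsity `S` in the sweep (default
   0.05 to 0.50 in steps of 0.05), exactly `k = floor(S·n(n−1)/2)` edges
   are kept — the `k` largest surviving counts — and binarized.

The two rules are not sequenced by the convention this follows; applying
the count threshold first is our documented choice (it means density
control ranks only counts already deemed real). `floor` guarantees the
realized density never exceeds `S`. Ties at the cutoff are broken
lexicographically by (i, j) node pair, ascending, which makes edge sets
deterministic, platform-independent, and nested across the sweep (the
network at 0.05 is a subgraph of the network at 0.10, and so on). If fewer
than `k` counts survive the τ threshold, all survivors become edges and a
saturation warning is recorded.

## Graph metrics

All metrics follow the standard binary-network definitions (the GRETNA /
Brain Connectivity Toolbox conventions):

- degree `k_i` = row sum; nodal clustering `C_i = 2t_i/(k_i(k_i−1))` with
  `t_i` triangles through `i`, defined as 0 for `k_i < 2`; network `Cp` is
  the mean over all nodes (degree-<2 nodes contribute 0, they are not
  excluded);
- hop distances by breadth-first search; characteristic path length `Lp`
  averages over *reachable* ordered pairs and carries a disconnected flag;
- global efficiency `Eg = mean over ordered pairs of 1/d_ij` with
  `1/∞ = 0`; nodal efficiency is the per-row version; nodal local
  efficiency is the global efficiency of the subgraph induced by a node's
  neighbors (0 for `k_i < 2`), and `Eloc` its mean;
- **normalization**: `γ = Cp/⟨Cp_rand⟩`, `λ = Lp/⟨Lp_rand⟩`,
  `σ = γ/λ`, where the averages run over degree-preserving surrogates
  (Maslov–Sneppen double-edge swaps; swaps creating self-loops or
  multi-edges are rejected). Defaults: 100 surrogates, 10 attempted swaps
  per edge; both are configurable and recorded in run metadata, and the
  heavier validation runs in this repository use 10 surrogates — the σ
  estimates then carry Monte-Carlo noise of a few percent, which the
  self-null calibration test quantifies;
- **AUC**: each metric's profile over the sweep is summarized by the
  trapezoidal integral against the sparsity grid, deliberately *not*
  normalized by grid width — a metric pinned at 1.0 integrates to 0.45
  over the default sweep, which is the magnitude regime of published
  aLambda values (≈0.48) and confirms the unnormalized reading.

Disconnected graphs are permitted throughout: efficiency metrics use
`1/∞ = 0`, path lengths average reachable pairs and are flagged, and
nodal path-length AUCs that come out infinite are treated as missing by
the inference stage. Degenerate inputs (empty graphs, zero surrogate
means) raise explicit errors rather than returning NaN silently.

The per-node local-efficiency BFS and the double-edge-swap loop are
numba-compiled; the pure-Python fallbacks consume the identical RNG stream,
so results do not depend on whether numba is present.

## Hub taxonomy

A region is a hub when its value of the hub metric — by default the
group-mean across subjects of the per-node degree-centrality AUC — is at
least `threshold_sd` (default 1.0) standard deviations above the mean over
all 90 regions. The SD uses the population (n) denominator; ties exactly at
the cutoff count as hubs; if all regions are identical (SD = 0) there are
no hubs, by intent of the definition. Whether hub status should be judged
on AUC values or at a single representative sparsity is not settled in the
literature we follow; AUC is the default and a single-sparsity value can be
supplied instead. Comparing the two groups' hub sets yields **lost**
(control-only), **preserved** (both), and **reconfigured** (patient-only)
hubs.

## Group inference

Every AUC metric is compared between groups with a linear model
`value ~ intercept + group + age + sex + education` (ANCOVA); the group
coefficient's t statistic and two-tailed p are reported. A
residualize-then-t mode (regress covariates out, then pooled two-sample
t-test) is provided as an alternative, since published descriptions of
"t-tests with covariates" are ambiguous between the two; both reduce
exactly to the classic pooled t-test when covariates are absent or
constant. Cohen's d is recovered as `d = |t|·√(1/n₁+1/n₂)`, the identity
that reproduces published effect-size tables from their printed t values.

FDR control is Benjamini–Hochberg step-up within declared families: the
global AUC metrics form one family; each nodal metric forms one family
across its 90 regions; brain–behavior correlations are adjusted per node
across that node's tested scores. The per-node correlation family is the
family size implied by published adjusted p-values in this literature
(adjusted p ≈ 2 × raw p for two behavioral subscales); a pooled
all-pairs family is available via configuration. Family membership is a
reporting choice, not a mathematical one, so families are recorded in the
analysis manifest.

Brain–behavior relations are partial Pearson correlations: both variables
are residualized on [intercept, age, sex, education], `r` is the Pearson
correlation of the residuals, `df = n − 2 − k`, and the two-tailed p comes
from `t = r·√(df/(1−r²))`. Correlations are computed within the patient
group by default, because the behavioral scores are near floor in
controls. Sex enters as a binary indicator; age and education as
continuous.

## Synthetic cohort generator

The generator is a pure function of its configuration (including the seed)
and emulates the study design: two groups of 30, 90 nodes, matched
demographics, a clinical battery, and two seeded effects whose recovery the
test suite checks.

**Template.** Nodes sit on a ring. Edge probability decays exponentially
with ring distance (decay length 6 nodes) and is calibrated to a target
density of 0.62; edges incident to a designated 14-region hub set are 3×
likelier. Edge weights (expected streamline counts) also decay with
distance (decay length 12) around a scale of 60 streamlines, with gamma
multiplicative noise (CV ≈ 0.35); hub-incident weights are boosted 1.6×
so hubs keep elevated degree at every sparsity, and the ring-adjacent
backbone carries the largest weights (6× scale) — mirroring the very high
streamline counts between anatomically adjacent regions — so that every
binary network in the 0.05–0.50 sweep is connected, the admissible regime
the analysis assumes. These choices make every generated subject satisfy
the small-world admissibility check σ > 1 at all grid points, with AUC
magnitudes in the regime of published control values (aCp ≈ 0.25,
aEg ≈ 0.26, aLambda ≈ 0.5). Density 0.62 leaves a comfortable margin of
suprathreshold entries above the 2002 edges demanded at sparsity 0.50, so
sweeps do not saturate in either group.

**Patient effect.** Every template weight incident to a designated
8-region anterior target set (the 7 regions intended to be lost hubs, plus
the right superior orbitofrontal gyrus) is multiplied by
`1 − attenuation` (default attenuation 0.4). Setting attenuation to 0
makes the groups identical by construction.

**Counts.** Per upper-triangle entry, counts are gamma–Poisson
(negative-binomial-like) draws with mean equal to the template weight and
dispersion θ = 8 (variance `μ + μ²/θ`); `θ = ∞` gives pure Poisson. A zero
template weight always yields a zero count.

**Scores.** Demographics are drawn from identical distributions in both
groups (matched design). Non-coupled scores are drawn from the published
group means and SDs of the emulated battery. Patients' FBI subscales are
`intercept + β·(nodal-efficiency AUC of the target region, centered) +
covariate effects + Gaussian noise`, with β = −400 and noise SD 2.5 chosen
so the efficiency–apathy partial correlation sits in the reported regime
(r ≈ −0.65); the total is the exact subscale sum. Controls' FBI items are
near-floor Poisson draws.

**What the generator does not emulate.** Subjects within a group differ
only by count noise around a shared template, so between-subject variance
in global metrics is far smaller than in real cohorts (adjusted t
statistics for the seeded deficits are correspondingly large); there is no
per-patient disease-severity gradient, no site or motion artifacts, and no
spatially realistic geometry beyond the ring. Passing recovery tests
therefore demonstrate that the pipeline detects effects of the seeded form
at study scale — not that it would have the study's power on real data.

## Problem sizes used in validation

The test suite and the acceptance script scale the stochastic checks to:
oracle equivalence on 50 random graphs (n ≤ 25); self-null calibration on
100 Erdős–Rényi graphs (n = 60, 10 surrogates each); type-I calibration on
50 null cohorts (full study size, 60 × 90×90 matrices each) testing the
global, nodal-degree and correlation families; and effect recovery on 20
seeded cohorts. The pipeline's small-world normalization in these runs
uses 10 surrogates per network. All random numbers derive from named,
CRC-hashed substreams of a single seed, so every run is exactly
reproducible and independent of subject processing order.

## Known limitations

- Weighted-network, betweenness, modularity and rich-club analyses are out
  of scope; the pipeline is strictly binary/undirected.
- The FDR family for brain–behavior correlations defaults to nodal
  efficiency × two FBI subscales; published work is typically silent on
  this choice, and changing it changes adjusted p-values.
- The generator's ring geometry yields realistic metric magnitudes but not
  realistic anatomy; hub identities are by construction, not emergent.
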