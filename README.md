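# wmtopo — white-matter connectome topology

`wmtopo` is a pipeline for graph-theory analysis of structural brain
connectomes of the kind built from diffusion tractography: each subject is
a symmetric 90×90 matrix of streamline counts between AAL atlas regions,
and the question is whether the *topology* of that network — its
segregation, integration, and hub architecture — differs between a patient
group and controls, and whether nodal topology tracks behavior. It is
aimed at researchers who have connectivity matrices (or want to prototype
against realistic synthetic ones) and need the full chain from matrices to
FDR-corrected group statistics to be reproducible and tested.

## The analysis

For each subject, edges with streamline count ≤ 3 are discarded, and the
remaining counts are thresholded to binary networks at sparsities
S = 0.05, 0.10, …, 0.50 (keeping the `floor(S·n(n−1)/2)` largest counts).
At each sparsity the standard binary-network measures are computed:

- global: clustering coefficient `Cp`, characteristic path length `Lp`,
  global efficiency `Eg`, local efficiency `Eloc`;
- normalized: `γ = Cp/Cp_rand`, `λ = Lp/Lp_rand`, small-worldness
  `σ = γ/λ`, with the random reference from degree-preserving
  (Maslov–Sneppen) rewiring surrogates;
- nodal: clustering, shortest path length, efficiency, local efficiency,
  degree centrality.

Each metric's profile over the sweep is reduced to one scalar per subject
by the (unnormalized) trapezoidal area under the curve, e.g. `aEg`. Hubs
are regions whose group-mean degree-centrality AUC is ≥ 1 SD above the
network average; comparing groups partitions hubs into *lost* (controls
only), *preserved* (both) and *reconfigured* (patients only). Group
differences in every AUC metric are tested with age, sex and education as
covariates (ANCOVA; Cohen's `d = |t|·√(1/n₁+1/n₂)`), with
Benjamini–Hochberg FDR within declared families, and nodal metrics are
related to clinical scores by covariate-adjusted partial correlations.

Because studies of this design rarely deposit raw data, the package also
ships a synthetic cohort generator (`wmtopo.synth`) that emulates the
design — two matched groups of 30, overdispersed streamline counts around
a small-world template, attenuated connectivity of an anterior target set
in patients, and behavioral scores coupled to one region's nodal
efficiency — so the whole pipeline can be validated by parameter recovery.

## Worked example

```python
import wmtopo as wt

cohort = wt.generate_cohort(wt.CohortConfig(seed=1))   # 60 subjects
rec, mat = cohort[0]                                   # HC001, 90x90 counts
nets = wt.sweep_sparsity(mat.counts)                   # 10 nested networks
gp = wt.global_profile(nets, wt.NullModelConfig(n_random=10, seed=0))
print(gp.auc)
```

prints this subject's AUC summary (edges per network run 200 … 2002):

```
     aCp: 0.250      aLp: 0.978      aEg: 0.262    aEloc: 0.335
  aGamma: 1.093   aLambda: 0.517   aSigma: 0.922
```

`aGamma > aLambda·2` reflects σ > 1 at every sparsity — the small-world
admissibility every subject must satisfy. The full pipeline is one
command:

```bash
wmtopo run --out results/demo --seed 1 --n-random 10
```

which simulates the default cohort, computes everything, and prints a
summary like:

```
Global AUC metrics, group mean ± SD:
     aCp: patient 0.248 ± 0.002   control 0.250 ± 0.002  t=-3.17 p_fdr=0.0035 d=0.817
     aLp: patient 1.000 ± 0.010   control 0.984 ± 0.009  t=+6.25 p_fdr=0.0000 d=1.614
     aEg: patient 0.261 ± 0.000   control 0.262 ± 0.001  t=-8.44 p_fdr=0.0000 d=2.178
   ...

Hub partition:
  lost (7): ACG.L, HIP.L, INS.L, MTG.L, ORBinf.R, PUT.R, PreCG.R
  preserved (7): DCG.R, LING.L, LING.R, MOG.L, PCUN.L, PCUN.R, PUT.L
  reconfigured (0):

FDR-significant correlations (alpha=0.05):
  ORBsup.R x FBI_disinhibition: r=-0.7787 p_fdr=3.452e-06 (n=30)
  ORBsup.R x FBI_apathy: r=-0.6607 p_fdr=0.0001763 (n=30)
  ...
```

The seeded effects are recovered: patients show lower clustering,
efficiency and local efficiency and a longer path length; the seven
attenuated anterior regions are exactly the lost hubs; and the right
superior orbitofrontal gyrus — whose efficiency the generator couples to
the FBI subscales — carries the strongest negative correlations. Other
CLI subcommands (`simulate`, `validate`, `construct`, `metrics`, `hubs`,
`analyze`) expose the stages individually; configuration is YAML
(see `wmtopo run --help`).

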