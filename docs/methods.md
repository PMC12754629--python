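# Methods

## The scientific problem

Salinization compresses microbial niche space: as NaCl rises, fewer taxa can
maintain osmotic balance, and community function (here, stationary-phase
biomass yield) comes to depend on which salt-tolerant taxa are present
rather than on how many taxa share the work. This package implements the
quantitative machinery for studying that shift in assembled-community
microcosm experiments: a power-law model of the richness–yield relationship
fit per salinity treatment, the additive partitioning of net biodiversity
effects into selection and complementarity components, treatment-level
trend statistics, and a synthetic-experiment generator whose ground truth is
known in closed form.

## Power-law BEF model

Per salinity treatment, yield is modelled as
`log₁₀ Y = b·x + log₁₀ Y(S_c)` with `x = log₁₀ S − mean(log₁₀ S)`.

- **Centering.** The centering constant is computed once over *all* records
  of the experiment (replicate-weighted mean of log₁₀ richness, i.e. the
  geometric-mean richness, ≈ 14.96 strains for the default 31-community
  design). One shared `S_c` keeps intercepts comparable across salinities;
  per-salinity centering would confound intercept differences with design
  differences.
- **Estimation.** Per-salinity ordinary least squares on the log scale is
  the reported inferential surface (exponent, intercept, their standard
  errors, R², two-sided p for `b = 0`). A linear mixed-effects variant —
  salinity as a fixed categorical factor interacting with the centered
  covariate, random intercept per community, the only unit repeated across
  salinities — is provided for cross-salinity estimation; its Wald p-values
  are normal approximations and flagged as such. With no community-level
  variance the mixed fit reduces to the OLS fits (verified to 1e-6).
- **Zero yields.** Records at or below the detection floor are excluded
  from log-scale fits with a reported count, not offset-transformed: an
  additive offset would manufacture spurious curvature exactly where the
  biology is most interesting (functional collapse near tolerance limits).
  A salinity with fewer than three usable records yields a flagged
  `not-ok` result carrying the reason instead of an exception.
- **Exponent classification.** `b < 1` decelerating (functional
  redundancy), `b = 1` within 1e-6 linear, `b > 1` accelerating.
- **Parameter trends.** Least-squares regression of the exponent or
  intercept on salinity; the quadratic form adds a salinity² term whose
  negative sign tests an inverted-U shape. Reported p is the highest-order
  term's.
- **Exponent contrasts.** A single 31-community experiment rarely resolves
  a difference between two per-salinity exponents (the sampling error of
  `b` under the default noise is ~0.07–0.2, dominated at high salinity by
  the halophile "lottery" across community compositions). Contrasts are
  therefore pooled across replicate simulated experiments by inverse
  variance (`pooled_exponent_difference`, default 20 replicates).

## Additive partitioning

For a mixture of `N` species with monoculture yields `M_i`, inoculated
proportions `RY_{E,i}` and observed per-species yields `Y_{O,i}`:

`ΔY = N·mean(ΔRY)·mean(M) + N·cov(ΔRY, M)`, with
`ΔRY_i = Y_{O,i}/M_i − RY_{E,i}`.

- **Covariance normalizer** is population (1/N): only that choice makes
  `CE + SE = Σ ΔRY_i·M_i = Y_O − Y_E` an exact identity (the module's
  conservation law, held to ≤ 1e-9 relative on randomized sweeps). A single
  species has zero covariance: `SE = 0`, `CE = NBE`.
- **Contributions** are signed percentages `100·SE/NBE`, `100·CE/NBE`; when
  the components have opposite signs one exceeds 100% and the result is
  flagged, not clipped.
- **Non-growers.** Species whose monoculture yield is at or below the
  detection floor are excluded and the inoculated proportions renormalized
  over the retained species (whose count becomes `N`). `Y_{O,i}/M_i`
  diverges as `M_i → 0`, so epsilon-imputation would let measurement floors
  dominate the covariance. If every species is excluded the mixture is
  reported as partition-impossible with the reason.
- **Genus-abundance route.** When mixture composition is known only as
  genus-level relative abundances (typical for sequencing-profiled
  high-diversity mixtures), genus yield = proportion × total yield, split
  across congeneric strains proportionally to their monoculture yields at
  that salinity (maximum-information default) or equally (`rule="equal"`,
  also the fallback when all congeners are non-growers). Observed yield
  assigned to strains that the viability filter then excludes is dropped;
  with congeneric non-growers this loses mass, a known limitation reported
  via the exclusion count.

## Treatment-level statistics

Linear trends of NBE/SE/CE on salinity are restricted to the inclusive
0–15% window by default: the 20% treatment, where the system collapses, is
excluded from trend fits but retained in ANOVA and Tukey comparisons.
ANOVA is classical one-way fixed-effects (homoscedastic, as is standard for
these designs); all-identical data yield a flagged `F = 0` rather than 0/0.
Tukey HSD uses the studentized range; with two groups it reduces to the
pooled t-test (verified to 1e-9). The replicate unit for the effect series
is one partition result per highest-diversity (group D) community ×
salinity — three values per salinity under the default design — since only
those mixtures are composition-profiled in the emulated workflow; other
groups can be included via `groups=`.

## Synthetic-experiment generator

The generator emulates a salt-lake isolate study: 40 strains (32 genera,
so congeneric strains exist), tolerance assayed over 0–30% NaCl, five
culture salinities (0.9, 3.5, 7, 15, 20%), groups A–D at richness
5/10/20/40 with 4/8/16/3 replicate communities, equal-density inoculation
(`RY_E = 1/N`).

- **Tolerance curves** are Gaussian in salinity — the minimal unimodal form
  with interpretable parameters (optimum `s_opt`, breadth `σ_tol`, peak
  yield `y_max`). Optima sit on a jittered stratified grid skewed toward
  low salinity (skew exponent 1.8: most environmental isolates are only
  mildly halotolerant), breadths are uniform on 2–4.5% NaCl, and `y_max`
  declines exponentially with `s_opt` (factor e over the assay range), the
  metabolic cost of osmoadaptation. After drawing, breadths are widened
  minimally so every culture salinity lies within one `σ_tol` of some
  optimum — every treatment supports growth. These choices were made once,
  as the package's default study conditions.
- **Community designs** are distinct member sets sampled without
  replacement from the C(n, N) combination space ("non-overlapping
  combinatorial pools" — disjoint strain pools are impossible since
  8 × 10 > 40); at full richness the single possible composition is
  replicated under distinct community ids. An optional stratified mode
  balances members across salt-tolerance quartiles; the default is uniform
  random, the weaker assumption.
- **Mixture model.** On the viable sub-community (members with monoculture
  yield above the detection floor; non-viable members wash out and their
  inoculated proportions are renormalized):

  `RY_{O,i} = RY_{E,i}·(1 + φ·(1 − 1/N)) + (θ/N)·(M_i/M̄ − 1)`

  with member yields `RY_{O,i}·M_i` times one shared lognormal noise factor
  (log₁₀ sd `noise_sd`, default 0.05). The φ term is a richness-dependent
  complementarity uplift; the θ term is a *mean-zero* tilt of relative
  yields toward high-yielding strains. Under equal inoculation and noise
  off this gives exactly `CE = φ·(1 − 1/N)·M̄` and
  `SE = θ·var_pop(M)/M̄` — each dial moves exactly one component, and
  `θ = φ = 0` is a zero-NBE null. A multiplicative tilt of shares at fixed
  total (the more obvious construction) cannot do this: it forces
  `NBE = 0` and hence `CE = −SE`. The additive tilt keeps all relative
  yields non-negative for `θ ≤ 1` under equal inoculation; larger values
  are clipped at zero with a warning, sacrificing exactness.
- **Noise** is multiplicative lognormal on yields (yields are positive and
  OD-like); the detection floor (default 0.01 OD-equivalent) records
  sub-floor monoculture yields as 0, making the non-grower edge case
  exercisable. An optional per-community lognormal offset (`community_sd`,
  default 0) adds replicate-identity structure, the ground truth for the
  mixed model's random intercept; it multiplies mixture yields but not
  monoculture yields, so it also perturbs partition ground truth — use it
  for mixed-model studies only.
- **Demo scenarios.** `demo.yaml` sets θ rising with salinity to 0.70 at
  15% then dropping to 0.15 at 20%, and φ declining from 0.50 to 0.02 —
  selection dominance grows with stress until the system collapses, while
  complementarity fades. `demo_collapse.yaml` is the hypersaline-collapse
  variant: narrow tolerance breadths (0.9–1.5%), stronger skew (2.6) and
  osmoadaptation cost (1.8), and strong selection at 20% — most
  low-richness communities lack a competent halophile at 20% NaCl, their
  yields collapse by more than an order of magnitude, and the
  diversity–functioning exponent steepens there. Both are versioned
  configs shipped in the package, not hard-coded.

### What the generator does and does not emulate

It reproduces the *design* (richness gradient, replicate structure,
salinity treatments, equal-density inoculation, genus-level composition
profiling of the highest-diversity mixtures) and a *controllable*
biodiversity-effect structure. It does not simulate growth dynamics (only
stationary-phase endpoints), species interactions beyond the two effect
dials, 16S read counts or sequencing error, or salinity-dependent
interaction networks. Passing tests therefore demonstrate that the
estimators recover known structure under the stated noise model — not that
real communities obey that model.

## Determinism and seeds

One experiment seed fans out to fixed per-stage streams (library, design,
monocultures, mixtures) via numpy `SeedSequence`, so stages can be rerun in
isolation and identical config + seed gives bitwise-identical output files.
CSV floats are written as `%.17g` and parsed with round-trip precision, so
write → read is lossless.

## Problem sizes used in tests and the acceptance script

The conservation-law sweep uses 10,000 randomized mixtures (≤ 40 species);
exponent recovery uses 200 replicate 31-community experiments; type-I
calibrations use 1000 replicates each; the exponent-contrast study pools 20
replicate experiments; scaled-down recovery studies (mixed-model random
intercept, quadratic-trend sign) use 12–200 replicates. These sizes give
Monte-Carlo standard errors comfortably inside the asserted bounds.

## Known limitations

- The abundance route assumes the observed total yield is the OD-based
  total; abundance-weighted alternatives would need per-genus calibration.
- Mixed-model p-values are Wald approximations (no Satterthwaite/
  Kenward-Roger degrees of freedom).
- The selection dial θ is exact only up to the non-negativity bound
  (θ ≤ 1 under equal inoculation).
- Classical (homoscedastic) ANOVA/Tukey only; heteroscedasticity across
  salinity treatments is real in collapse regimes, where the trend
  restriction to 0–15% mitigates it.
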