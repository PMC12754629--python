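# salbef

Analysis toolkit for **biodiversity–ecosystem functioning (BEF) along salinity
gradients** in assembled microbial communities. It is written for microbial
ecologists running (or planning) microcosm experiments in which artificial
communities of bacterial isolates with varying salt tolerance are cultured
across a salinity gradient, and who want to ask: *how does salinity stress
reshape the richness–yield relationship, and through which mechanism —
selection or complementarity?*

The package has four parts:

1. **Synthetic experiment generator** (`salbef.simulate`) — microcosm
   experiments with a known biodiversity-effect ground truth: a strain
   library with unimodal (Gaussian) salt-tolerance curves, monoculture yield
   assays, richness-gradient community designs (default 5/10/20/40 strains
   with 4/8/16/3 replicate communities at five salinities), and a generative
   mixture model with independent selection (θ) and complementarity (φ)
   dials.
2. **Power-law BEF model** (`salbef.befmodel`) — per-salinity fits of

   `log₁₀ Y(S) = b·(log₁₀ S − log₁₀ S_c) + log₁₀ Y(S_c)`

   where `S` is species richness, `S_c` the geometric-mean richness, `b` the
   exponent characterizing the diversity–functioning shape (`b < 1`:
   decelerating, functional redundancy), and the intercept is yield at
   average richness. Includes a random-intercept mixed model across
   salinities and trend fits of `b` and the intercept against salinity.
3. **Additive partitioning** (`salbef.partition`) — the exact two-way
   decomposition of the net biodiversity effect,

   `ΔY = Y_O − Y_E = N·ΔRY̅·M̅  +  N·cov(ΔRY, M)`

   (complementarity + selection), with `ΔRY_i = Y_{O,i}/M_i − RY_{E,i}`,
   population covariance so the identity is exact, a viability filter for
   non-growing species, and a genus-abundance → per-strain yield route for
   mixtures profiled by composition rather than per-strain biomass.
4. **Treatment statistics** (`salbef.trends`) — effect-vs-salinity
   regressions over the 0–15% range, one-way ANOVA across salinity
   treatments, and Tukey HSD pairwise comparisons.

A thin CLI (`salbef simulate|fit-bef|partition|trends|run-all`) orchestrates
the stages over plain CSV/YAML files; `examples/` holds narrative scripts,
one per capability.

## Worked example

```python
from salbef import demo_config, simulate_experiment, fit_all_salinities, \
    partition_experiment
from salbef.trends import selection_share

config = demo_config(seed=1).sim
exp = simulate_experiment(config)
for f in fit_all_salinities(exp.observations, floor=config.detection_floor):
    print(f"{f.salinity:5.1f}%  b = {f.b:6.3f}  log10 Y(Sc) = {f.log_y_sc:7.3f}")

table = partition_experiment(exp.designs, exp.monocultures,
                             exp.member_yields, floor=config.detection_floor)
print((100 * selection_share(table, groups=('D',))).round(1))
```

prints

```
  0.9%  b =  0.085  log10 Y(Sc) =   0.004
  3.5%  b =  0.095  log10 Y(Sc) =  -0.020
  7.0%  b =  0.110  log10 Y(Sc) =  -0.285
 15.0%  b =  0.270  log10 Y(Sc) =  -0.337
 20.0%  b = -0.079  log10 Y(Sc) =  -0.515
salinity_pct
0.9      3.7
3.5      6.4
7.0     33.1
15.0    97.0
20.0    63.0
```

Read: the intercept (yield at average richness) declines steadily with
salinity — stress suppresses function; the exponent `b` peaks at 15% NaCl —
richness matters most under severe stress; and the selection effect's share
of the net biodiversity effect climbs from ~4% at physiological salinity to
~97% at 15% — under stress, community function increasingly rides on a few
salt-tolerant, high-yielding strains rather than on complementary resource
use. `examples/02_power_law_fit.py` and `examples/03_partition_effects.py`
print these tables with fuller commentary.

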