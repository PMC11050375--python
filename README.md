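# ecoassembly

Diversity, stability, and community-assembly inference for grid-based
species surveys along environmental gradients.

`ecoassembly` is written for community ecologists who have three things: a
site × species abundance matrix (e.g. butterfly transect counts pooled per
1 × 1 km grid), a rooted phylogeny whose tips are the observed species, and
per-site environmental covariates (elevation, slope, canopy density, EVI,
distance to settlement). From these it answers the classic sequence of
questions about a metacommunity on a mountain gradient:

1. **How does diversity change along the gradient?** Hill numbers
   (⁰D = richness, ¹D = exp Shannon, ²D = inverse Simpson), Faith's
   phylogenetic diversity PD, mean nearest taxon distance (MNTD), Chao
   sample coverage, and Pearson correlations of each metric with elevation.
2. **Is compositional change turnover or nestedness?** Pairwise
   Bray–Curtis (taxonomic) and PhyloSor (phylogenetic) dissimilarity,
   decomposed under both the Baselga (BAS) and Podani/Cardoso (POD)
   frameworks, with gradient-wide component shares.
3. **How complex and how stable are the communities?** Cohesion
   (abundance-weighted, null-corrected pairwise correlation structure) and
   the average variation degree (AVD) per elevation band.
4. **How neutral is the assembly?** The Sloan neutral community model
   fitted to occupancy–abundance data per band: migration rate m, goodness
   of fit R², and over-/neutral-/under-represented taxon classes.
5. **Which processes assemble the communities?** The two-step null-model
   framework: β-NTI (the z-score of βMNTD against a tip-shuffle null)
   combined with the Raup–Crick Bray–Curtis index RC<sub>bray</sub> under a
   richness- and abundance-preserving null, classifying every site pair as
   heterogeneous selection (βNTI > 2), homogeneous selection (βNTI < −2),
   dispersal limitation (|βNTI| ≤ 2, RC > 0.95), homogenizing dispersal
   (|βNTI| ≤ 2, RC < −0.95), or undominated — with Kruskal–Wallis
   comparisons across elevation bands and paired Wilcoxon comparisons of
   β-NTI between alternative phylogenies.

A first-class synthetic-community generator (`ecoassembly.simulate`)
produces Yule trees, Brownian (phylogenetically conserved) niche traits,
and communities assembled under known regimes — pure drift with migration,
Gaussian environmental filtering, or a mixture — so every statistic in the
pipeline can be validated against ground truth.

## Core statistics

For communities *k* and *k′* with relative abundances *f*, patristic
distances *d<sub>ij</sub>*, and *reps* tip-label randomizations:

```
βMNTD = ½ [ Σ_i f_ik  · min_{j∈k′} d_ij  +  Σ_j f_jk′ · min_{i∈k} d_ij ]
βNTI  = (βMNTD_obs − mean βMNTD_null) / sd βMNTD_null
RCbray = 2 · ( [#(null < obs) + ½·#(null = obs)] / reps − ½ )
```

The Sloan model predicts a taxon's occupancy from its metacommunity mean
relative abundance *p* as the upper tail, above a detection limit *d*, of
Beta(*Nm·p*, *Nm·(1−p)*); *Nm* is fitted by least squares and *m = Nm/N*
is the migration rate.

## Worked example

```python
import ecoassembly as ea

# a synthetic 30-site survey assembled under strong environmental filtering
cfg = ea.ScenarioConfig(n_species=120, n_sites=30, regime="filtered",
                        filter_strength=0.4, seed=3)
data = ea.generate_scenario(cfg)

fit = ea.fit_ncm(data.matrix)
print(f"NCM: m = {fit.m:.2f}, R2 = {fit.R2:.2f}, "
      f"neutral share = {100*fit.neutral_abundance_share:.0f}%")

bnti = ea.beta_nti(data.tree, data.matrix, reps=999, seed=3)
rc = ea.rc_bray(data.matrix, reps=999, seed=3)
print(ea.classify_processes(bnti, rc).round(3).to_string())
h, p = ea.compare_bands(bnti, data.meta.bands())
print(f"Kruskal-Wallis across bands: H = {h:.1f}, p = {p:.2g}")
```

prints

```
NCM: m = 0.33, R2 = 0.74, neutral share = 32%
       n_pairs  heterogeneous_selection  homogeneous_selection  dispersal_limitation  homogenizing_dispersal  undominated
group
all        424                    0.212                  0.017                 0.026                    0.17        0.575
Kruskal-Wallis across bands: H = 10.9, p = 0.012
```

Filtering on a phylogenetically conserved trait is detected twice over:
the neutral fit degrades (m = 0.33 despite a large true immigration
pressure, R² = 0.74), and 21% of site pairs — those spanning contrasting
environments — exceed βNTI = 2 (heterogeneous selection), while the
within-band comparisons stay mostly undominated. The Kruskal–Wallis test
confirms that β-NTI differs across elevation bands.

## Command line

Every stage is also a subcommand of the `ecoassembly` CLI:

```bash
ecoassembly simulate --out-dir fixtures --seed 1
ecoassembly alpha    --matrix fixtures/matrix.tsv --tree fixtures/tree.nwk \
                     --meta fixtures/meta.tsv --out alpha.tsv
ecoassembly run      --config pipeline.yaml      # full pipeline + report.json
```

`ecoassembly run` executes simulate → alpha → beta → stability → ncm →
assembly from one YAML config, writes TSV/JSON outputs per stage, and is
resumable: stages whose outputs already exist are skipped unless an
upstream stage was recomputed.

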