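# Methods

This note documents the statistical models implemented in `ecoassembly`,
their assumptions, the defaults and why they were chosen, what the
synthetic-community generator does and does not emulate, and the numerical
conventions used in edge cases.

## Data model and conventions

A survey is a site × species matrix of non-negative integer counts, a
rooted phylogeny with non-negative branch lengths whose tips map onto the
species identifiers, and a per-site covariate table (elevation in m, slope,
canopy density, EVI, distance to nearest settlement). Sites with zero
captures are dropped with a logged warning: an empty transect carries no
community information, and keeping it would silently distort relative
abundances and null models. Species present in the matrix but absent from
the tree are excluded from *phylogenetic* metrics only (with a logged
list); taxonomic metrics always use the full matrix, so tree completeness
cannot silently alter them.

Elevation bands are half-open intervals `[edge_k, edge_{k+1})` with the top
edge closed; the defaults are the four 164-m bands spanning 416–1072 m.
All stochastic operations draw from named, independently seeded generator
streams derived from one global seed (`RunConfig.stream`), so reruns are
bit-reproducible and modules can be called in any order.

## Alpha diversity

Hill numbers are `(Σ p_i^q)^(1/(1−q))`, with the Shannon limit computed in
closed form at q = 1 rather than by a numeric limit. Faith's PD sums the
branch lengths of the minimal spanning subtree of the community and is
rooted by default (the subtree is anchored at the root, so a one-species
community has PD equal to its root-to-tip depth); an unrooted variant that
stops at the MRCA is available by flag, because both conventions circulate
and downstream comparisons must not mix them. MNTD averages each species'
patristic distance to its nearest co-occurring relative; the alpha version
defaults to unweighted averaging, with abundance weighting available for
sensitivity analysis. Sample coverage is the Chao estimator
`1 − (f1/n)·[(n−1)f1/((n−1)f1 + 2f2)]` from singleton and doubleton counts.
Diversity–elevation associations are Pearson correlations with two-sided
p-values; a metric with zero variance is reported as missing rather than
zero.

## Beta-diversity partition

All pairwise indices are built from matching components A (shared), B and
C (unique to each site): abundance components `A = Σ min(x_i, y_i)` for
Bray–Curtis, shared/exclusive spanning-branch length for PhyloSor. Both
partitions share the total `(B+C)/(2A+B+C)` and decompose it additively:

* **BAS**: turnover (balanced variation) `min(B,C)/(A+min(B,C))`,
  nestedness = total − turnover;
* **POD**: replacement `2·min(B,C)/(2A+B+C)`, richness/abundance
  difference `|B−C|/(2A+B+C)`.

Additivity (turnover + nestedness = total) holds to 1e-12 by construction
and is asserted property-wise. Gradient-wide "component shares" are the
means over all site pairs of turnover, nestedness, and similarity
(1 − total); because each pair's three parts sum to one, the three shares
sum to one, which makes them directly comparable across datasets. Note
that when every site holds the same number of individuals the *abundance*
nestedness component is identically zero (B = C for all pairs), which is
why the synthetic fixtures — whose per-site totals are fixed — show zero
taxonomic nestedness while still expressing phylogenetic nestedness.

## Stability: cohesion and AVD

Cohesion starts from pairwise Pearson correlations of species' relative
abundances across sites. Each pair's correlation is corrected by the mean
of a taxon-shuffle null (each species' abundances permuted across sites
independently; 200 iterations by default — enough for the null mean of a
correlation, which converges much faster than a tail quantile). A species'
positive (negative) connectedness is the mean of its positive (negative)
corrected correlations, and a site's positive (negative) cohesion is the
relative-abundance-weighted sum of connectedness over its taxa. Zero-
variance species are excluded with a log entry. Cohesion is invariant to
rescaling any site's counts, because it only ever sees relative abundances.

AVD for a group of k sites and n retained species is
`Σ_i Σ_s |a_is − μ_i| / σ_i / (k·n)` on relative abundances, using the
population standard deviation so that a species whose values sit exactly
±σ from its mean contributes exactly 1, and a standard-normal abundance
matrix converges to E|Z| = √(2/π) ≈ 0.798. Lower AVD = more stable.
Grouping defaults to the elevation band (per-site grouping is available).
The normality filter (Shapiro–Wilk at α = 0.05, on by default) implements
the usual restriction of AVD to approximately normally distributed taxa;
it is aggressive on sparse count data, so the unfiltered mode is provided
and the number of retained species is always reported.

## Sloan neutral community model

The local community of N individuals receives immigrants from the
metacommunity at rate m; at stationarity a taxon with metacommunity
relative abundance p has local relative abundance x ~ Beta(Nm·p,
Nm·(1−p)). Its predicted occupancy is P(x > d) for a detection limit d,
and Nm is estimated by bounded least squares of predicted against observed
occupancy (Nm ∈ (0, N], so m = Nm/N ∈ (0, 1]); R² = 1 − SSE/SST on
occupancies. N is the mean per-site total, estimated per band (fits are
independent across bands).

**Detection limit.** Detection in a finite sample of N individuals is not
a step function: a taxon at relative abundance x appears at least once
with probability 1 − (1−x)^N. The default threshold is therefore placed
at the *half-detection* abundance d = ln 2 / N (where that probability is
½), which parameter-recovery experiments show is close to unbiased —
fitting simulated Beta/binomial data with the conventional one-individual
limit d = 1/N overestimates m by 25–60%, while d = ln 2/N recovers Nm to
within ~10%. The 1/N convention remains available via `detection_limit`
for comparability with other software.

Taxa are classified against a 95% Wilson score band (computed from the
predicted occupancy and the number of sites): above = over-represented,
below = under-represented, inside = neutral; the neutral abundance share
is the summed mean relative abundance of neutral taxa. A Wilson band
centred on a *prediction* under-covers taxa whose predicted occupancy sits
near 0 or 1 (a taxon observed in zero sites always falls below a strictly
positive lower bound), so the ~95% coverage guarantee applies to taxa with
predicted occupancy away from the boundaries; boundary taxa are flagged
conservatively. Note that the estimate is not invariant to rescaling raw
counts: scaling changes N and therefore the detection limit while observed
occupancy stays fixed. At a fixed detection limit the fitted Nm is exactly
scale-invariant, and that is the invariance the tests assert.

## Assembly inference

**Phylogenetic signal.** Niche values are abundance-weighted means of the
standardized environmental covariates over the sites a species occupies;
niche distance is Euclidean over covariates. The Mantel correlogram tests,
per phylogenetic-distance class (Sturges' rule for the default class
count), the point-biserial Mantel correlation between class membership and
niche distance, signed so that positive r means within-class pairs are
more similar in niche than average. p-values are two-sided permutation
tests (species-label permutations) with a progressive correction (the k-th
class corrected for k tests, cumulative-maximum enforced). The framework's
premise — closely related taxa are ecologically similar — is supported
when short-distance classes show significant positive r.

**βMNTD / β-NTI.** βMNTD is the abundance-weighted (by default) mean
nearest-taxon distance between two communities; a species shared by both
contributes zero. The null shuffles species identities across the analysis
tips once per replicate (999 by default) and recomputes βMNTD for every
site pair; β-NTI is the per-pair z-score. Because z-scores are invariant
to uniform rescaling of all branch lengths, β-NTI depends only on tree
*shape*, which is what makes the paired comparison of alternative
phylogenies (`compare_trees`, same seed hence identical shuffles, paired
Wilcoxon per band and overall) meaningful. Pairs with a degenerate null
(zero variance, e.g. on a star tree) are reported as missing with a
warning, guarded by a relative floor on the null standard deviation
because an exactly-degenerate null produces pure floating-point noise.

**RC<sub>bray</sub>.** Each null community preserves its site's observed
richness and total abundance exactly: species are drawn without
replacement with probability proportional to occupancy, then the total is
allocated multinomially with probability proportional to mean relative
abundance. One null community is drawn per site per replicate and
Bray–Curtis is computed for all pairs, which gives each pair the same
marginal null distribution as independent per-pair draws at a fraction of
the cost. Ties count one half: RC = 2·(fraction(null < obs) +
½·fraction(null = obs) − ½) ∈ [−1, 1].

**Classification.** βNTI > 2 → heterogeneous selection; βNTI < −2 →
homogeneous selection; otherwise RC > 0.95 → dispersal limitation,
RC < −0.95 → homogenizing dispersal, else undominated. Fractions are
computed over within-group site pairs and always sum to one. Kruskal–
Wallis compares within-band β-NTI distributions across bands; an all-ties
input returns p = 1 rather than an error. The relation between selection
strength and abiotic vs biotic context is summarized by simple Mantel
tests between pairwise |βNTI| and between-site distances in standardized
environment (abiotic) or cohesion (biotic) — a generic interpretation,
exposed as `mantel_test`, since several constructions are defensible.

## Synthetic communities

The generator emulates a grid survey of a subtropical mountain gradient:
80 sites uniform on 416–1072 m, 237 species on a unit-depth Yule tree,
lognormal (σ = 1.5) metacommunity abundances, and N = 86 individuals per
site (≈ 6905/80, the scale of a two-year pooled butterfly survey).
Niche traits evolve by Brownian motion along the tree (rate 1 per unit
depth), so environmental filtering acting on the trait is phylogenetically
conserved — the property β-NTI needs. The site environment is linear in
elevation on the trait scale, running from the metacommunity trait mean at
the gradient base to `env_span` (default 4) trait standard deviations away
at the top: upslope sites are increasingly stressful, so filtered
scenarios reproduce the canonical declines of richness and PD with
elevation.

Regimes:

* **neutral** — each individual is either an immigrant or the offspring of
  a random local individual. Assembly is a Pólya urn with immigration
  weight θ = N·m_true: the probability that the next individual immigrates
  is θ/(θ+k) when k are already present. This realizes exactly a
  Dirichlet-multinomial community with concentration θ·p — the stationary
  law of the Sloan model — so `fit_ncm` estimates the same m the generator
  wrote down. (A constant-probability replacement process would instead
  equilibrate at concentration m(N−1)/(1−m), making the written m
  unrecoverable for m ≥ 0.5.)
* **filtered** — multinomial sampling with weights
  `metacommunity × exp(−(trait − env)²/(2σ_f²))`; σ_f is in trait units
  (σ_f ≈ 0.4 is strong filtering, σ_f → ∞ recovers neutrality in total
  variation).
* **mixed** (default, σ_f = 1, m = 0.5) — the urn dynamic with the
  filtered weights as immigrant pool: a moderate blend of drift and
  selection, the regime mountain insect surveys most resemble.

Per-site totals equal N exactly, counts are non-negative integers, the
same seed reproduces every artifact bit-identically, and the emitted truth
record (traits, environments, metacommunity, regime parameters, expected
dominant process per stratum) suffices to recompute every expected
quantity used in validation.

**What the generator does not emulate.** Detection error and observer
bias, temporal turnover between survey rounds, spatially autocorrelated
dispersal (sites are exchangeable given their environment), varying
per-site effort (totals are fixed, which also forces the abundance-based
nestedness component to zero), and multi-trait niches. Passing tests on
synthetic data therefore validate the estimators under the stated model,
not robustness to those field realities.

## Problem sizes and numerical choices

Validation experiments are sized to be decisive yet quick: null-model
self-consistency pools ~1,900 site pairs from 12 independent 16-site
surveys at 999 randomizations; permutation-test calibration uses 500
simulations at 99 permutations (the discrete permutation p-value is
exactly uniform, so α = 0.05 is attainable); regime discrimination uses
paired-seed 30-site scenarios at 299 randomizations. The full 80-site
pipeline with 999 randomizations for both β-NTI and RC<sub>bray</sub>
completes in well under a minute.

Ties in RC counting take weight ½ with a 1e-12 equality tolerance;
Bray–Curtis is computed on raw counts (`Σ|x−y| / Σ(x+y)`); correlations of
zero-variance vectors are reported missing; Nm optimization is bounded
scalar minimization on log Nm with 1e-10 tolerance; β-NTI accumulates null
mean and variance in one pass (sample variance, ddof = 1).

## Known limitations

* The Mantel-correlogram progressive correction is the simple progressive
  Bonferroni; with many distance classes it is conservative at long range.
* Cohesion's taxon-shuffle null corrects only the mean of the correlation
  distribution, as in the original method; connectedness retains
  small-sample noise when there are few sites.
* The NCM fit treats taxa as independent observations in the least
  squares; compositional coupling between abundant taxa slightly inflates
  R² on small species pools.
* RC<sub>bray</sub>'s null treats two sites drawn heavily from one shared
  pool as "homogenized" (RC → −1) when local samples are large relative to
  the pool — an interpretation, not an artifact, but worth remembering
  when sampling fractions are high.
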