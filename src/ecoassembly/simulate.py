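"""Synthetic communities with known assembly regimes.

Generates the three inputs the pipeline consumes — a Yule phylogeny, a
site × species count matrix, and a site metadata table — together with a
truth record of the generating parameters, so every downstream statistic
can be checked against a known answer.

The generator emulates a grid-based mountain survey: ~80 sites spread over
an elevation gradient, ~237 species from a tree of unit depth, lognormal
metacommunity abundances, and a per-site community of N individuals
assembled under one of three regimes:

* ``neutral`` — local drift with immigration: each individual is either an
  immigrant from the metacommunity or the offspring of a random local
  individual, with the immigration weight set by the migration rate
  ``m_true`` (the Hubbell/Sloan dynamic, realized as a Pólya urn so the
  stationary occupancy–abundance relationship is exactly the one the
  neutral-model fit assumes).
* ``filtered`` — environmental filtering: sampling weights are the
  metacommunity weights times a Gaussian niche kernel
  ``exp(−(trait − env)²/(2σ_f²))`` on a Brownian (phylogenetically
  conserved) trait, so filtering is heritable along the tree.
* ``mixed`` — the neutral drift dynamic with the filtered weights as the
  immigrant pool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .core import (CommunityMatrix, Phylogeny, SiteMetadata, ValidationError,
                   assign_bands, derive_rng, DEFAULT_BAND_EDGES)


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic scenario.

    Defaults mirror the survey scale the package targets: 80 one-km grids
    between 416 and 1072 m, 237 species, and 6905/80 ≈ 86 individuals per
    site, with a moderate mixture of drift and filtering.
    """

    n_species: int = 237
    n_sites: int = 80
    elevation_range: tuple = (416.0, 1072.0)
    regime: str = "mixed"           # neutral | filtered | mixed
    m_true: float = 0.5             # immigration probability per replacement
    filter_strength: float = 1.0    # niche kernel width σ_f, trait units
    brownian_rate: float = 1.0      # trait variance accumulated root→tip
    community_size: int = 86        # individuals per site (N)
    env_span: float = 4.0           # environmental range in trait sd units
    lognormal_sigma: float = 1.5    # metacommunity abundance spread
    seed: int = 0

    def __post_init__(self):
        if self.community_size < 1:
            raise ValidationError("community size N must be ≥ 1")
        if self.regime not in ("neutral", "filtered", "mixed"):
            raise ValidationError(f"unknown regime {self.regime!r}")
        if not (0.0 < self.m_true <= 1.0):
            raise ValidationError("m_true must be in (0, 1]")


@dataclass
class TruthRecord:
    """Ground truth emitted alongside each synthetic dataset."""

    regime: str
    m_true: float
    filter_strength: float
    brownian_rate: float
    community_size: int
    trait_optima: dict      # species → trait value
    site_environment: dict  # site → environment (trait units)
    metacommunity: dict     # species → relative abundance
    expected_dominant_process: dict  # stratum → process name

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def simulate_tree(n_species: int, seed: int = 0) -> Phylogeny:
    """Pure-birth (Yule) tree with unit root-to-tip depth.

    Starts from the crown split (two lineages), waits Exp(k·λ) between
    speciation events, splits a uniformly chosen lineage, and extends all
    surviving tips to the present; branch lengths are then rescaled so the
    tree is ultrametric with depth exactly 1.
    """
    if n_species < 3:
        raise ValidationError("need at least 3 species")
    rng = derive_rng(seed, "yule-tree")

    root = dendropy.Node()
    birth = {root: 0.0}
    a, b = dendropy.Node(), dendropy.Node()
    root.add_child(a)
    root.add_child(b)
    t = 0.0
    active = [a, b]
    for node in active:
        birth[node] = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / k)
        idx = rng.integers(k)
        parent = active.pop(idx)
        for _ in range(2):
            child = dendropy.Node()
            parent.add_child(child)
            birth[child] = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / len(active))

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    order = rng.permutation(len(active))
    for lab, i in enumerate(order):
        node = active[i]
        node.taxon = taxa.new_taxon(label=f"sp{lab + 1}")
    for node in tree.preorder_node_iter():
        if node is root:
            node.edge.length = None
            continue
        end = t_end if node.is_leaf() else birth[node.child_nodes()[0]]
        node.edge.length = (end - birth[node]) / t_end
    return Phylogeny(tree)


def evolve_trait(tree: Phylogeny, sigma2: float = 1.0,
                 seed: int = 0) -> pd.Series:
    """Brownian-motion trait along the tree, root value 0.

    Tip covariance is proportional to shared root path, giving the
    phylogenetically conserved niche trait the filtering regimes act on.
    """
    if sigma2 < 0:
        raise ValidationError("Brownian rate must be ≥ 0")
    rng = derive_rng(seed, "brownian-trait")
    value = {tree.tree.seed_node: 0.0}
    out = {}
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            continue
        bl = node.edge.length or 0.0
        value[node] = value[node.parent_node] + rng.normal(
            0.0, np.sqrt(sigma2 * bl))
        if node.is_leaf():
            out[node.taxon.label] = value[node]
    return pd.Series(out, dtype=float).reindex(tree.tip_labels)


def _urn_sample(pool_w: np.ndarray, N: int, m: float,
                rng: np.random.Generator) -> np.ndarray:
    """Local community of N individuals under drift with migration rate m.

    Individuals are assembled sequentially: with probability θ/(θ+k), where
    θ = N·m and k individuals are already present, the next individual
    immigrates from the metacommunity pool; otherwise it is the offspring
    of a uniformly chosen local individual (ecological drift).  This Pólya
    urn realizes a Dirichlet-multinomial community with concentration θ·p,
    whose per-taxon relative abundance is exactly the Beta(N·m·p,
    N·m·(1−p)) distribution the Sloan neutral model assumes, so the
    migration parameter written here is the one the fit estimates.
    """
    n_sp = pool_w.size
    theta = m * N
    counts = np.zeros(n_sp, dtype=np.int64)
    immigrants = rng.choice(n_sp, size=N, p=pool_w)  # pre-drawn base samples
    u = rng.random(N)
    for k in range(N):
        if u[k] * (theta + k) < theta or k == 0:
            sp = immigrants[k]
        else:
            # copy a uniform existing individual: choose species ∝ counts
            r = rng.integers(k)
            sp = np.searchsorted(np.cumsum(counts), r, side="right")
        counts[sp] += 1
    return counts


def niche_weights(meta_w: np.ndarray, traits: np.ndarray, env: float,
                  sigma_f: float) -> np.ndarray:
    """Metacommunity weights filtered through a Gaussian niche kernel.

    As σ_f → ∞ the kernel flattens and the weights converge to the
    unfiltered metacommunity weights.
    """
    kernel = np.exp(-(np.asarray(traits, float) - env) ** 2
                    / (2.0 * sigma_f ** 2))
    pool = np.asarray(meta_w, float) * kernel
    if pool.sum() <= 0:
        raise ValidationError("niche kernel annihilated all species; widen σ_f")
    return pool / pool.sum()


def simulate_communities(tree: Phylogeny, traits: pd.Series,
                         config: ScenarioConfig
                         ) -> tuple[CommunityMatrix, SiteMetadata, TruthRecord]:
    """Assemble site communities under the configured regime."""
    rng = derive_rng(config.seed, "simulate-communities")
    n_sp = tree.n_tips
    species = tree.tip_labels
    N = config.community_size

    meta_w = rng.lognormal(0.0, config.lognormal_sigma, n_sp)
    meta_w /= meta_w.sum()

    lo, hi = config.elevation_range
    elev = np.sort(rng.uniform(lo, hi, config.n_sites))
    sites = [f"site{i + 1}" for i in range(config.n_sites)]

    # environment on the trait scale: linear in elevation, starting at the
    # metacommunity trait optimum at the gradient base and moving env_span
    # trait standard deviations away by the top — so filtering imposes
    # increasing environmental stress (and declining richness) upslope
    tvals = traits.to_numpy()
    t_sd = tvals.std() if tvals.std() > 0 else 1.0
    env = tvals.mean() + (elev - lo) / (hi - lo) * config.env_span * t_sd

    counts = np.zeros((config.n_sites, n_sp), dtype=int)
    for i in range(config.n_sites):
        if config.regime == "neutral":
            pool = meta_w
        else:
            pool = niche_weights(meta_w, tvals, env[i],
                                 config.filter_strength)
        if config.regime == "filtered":
            counts[i] = rng.multinomial(N, pool)
        else:
            counts[i] = _urn_sample(pool, N, config.m_true, rng)

    matrix = CommunityMatrix(
        pd.DataFrame(counts, index=sites, columns=species),
        drop_empty_sites=False)

    meta_tab = pd.DataFrame({
        "elevation": elev,
        "slope": rng.uniform(5.0, 40.0, config.n_sites),
        "canopy": rng.uniform(0.4, 0.95, config.n_sites),
        "evi": rng.uniform(0.2, 0.6, config.n_sites),
        "near_dist": 200.0 + 4.0 * (elev - lo)
        + rng.normal(0.0, 150.0, config.n_sites).clip(-180, None),
    }, index=pd.Index(sites, name="site"))
    meta = assign_bands(SiteMetadata(meta_tab), DEFAULT_BAND_EDGES
                        if (lo, hi) == (416.0, 1072.0)
                        else np.linspace(lo, hi, 5))

    expected = {"within_stratum": "undominated"}
    if config.regime == "neutral":
        expected["between_strata"] = "undominated"
    else:
        expected["between_strata"] = "heterogeneous_selection"
    truth = TruthRecord(
        regime=config.regime, m_true=config.m_true,
        filter_strength=config.filter_strength,
        brownian_rate=config.brownian_rate, community_size=N,
        trait_optima={s: float(v) for s, v in traits.items()},
        site_environment={s: float(e) for s, e in zip(sites, env)},
        metacommunity={s: float(w) for s, w in zip(species, meta_w)},
        expected_dominant_process=expected,
    )
    return matrix, meta, truth


@dataclass
class SyntheticData:
    tree: Phylogeny
    traits: pd.Series
    matrix: CommunityMatrix
    meta: SiteMetadata
    truth: TruthRecord
    config: ScenarioConfig


def generate_scenario(config: ScenarioConfig) -> SyntheticData:
    """Tree + traits + communities + metadata + truth from one config."""
    tree = simulate_tree(config.n_species, seed=config.seed)
    traits = evolve_trait(tree, config.brownian_rate, seed=config.seed)
    matrix, meta, truth = simulate_communities(tree, traits, config)
    return SyntheticData(tree, traits, matrix, meta, truth, config)
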