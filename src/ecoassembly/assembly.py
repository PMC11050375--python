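"""Null-model inference of community assembly processes.

The workflow follows the two-step phylogenetic/taxonomic null-model
framework: (1) verify phylogenetic signal in species' environmental niches
with a Mantel correlogram; (2) compute the beta nearest taxon index (β-NTI),
the z-score of observed between-community mean nearest taxon distance
(βMNTD) against a tip-shuffle null; (3) compute the Bray–Curtis-based
Raup–Crick index (RCbray) under a richness- and abundance-preserving null;
(4) classify each site pair into one of five assembly processes —
heterogeneous selection (βNTI > 2), homogeneous selection (βNTI < −2),
dispersal limitation (|βNTI| ≤ 2, RCbray > 0.95), homogenizing dispersal
(|βNTI| ≤ 2, RCbray < −0.95), or undominated — and summarize fractions per
group of sites (e.g. elevation bands).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .core import (CommunityMatrix, Phylogeny, SiteMetadata, ValidationError,
                   derive_rng)

logger = logging.getLogger("ecoassembly")

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95

PROCESSES = ("heterogeneous_selection", "homogeneous_selection",
             "dispersal_limitation", "homogenizing_dispersal", "undominated")


@dataclass
class PairwiseResult:
    """Symmetric site × site matrix of one pairwise statistic."""

    data: pd.DataFrame
    statistic: str
    reps: int = 0
    seed: int | None = None

    def pair_values(self, sites=None) -> np.ndarray:
        """Upper-triangle values, optionally restricted to given sites."""
        df = self.data if sites is None else self.data.loc[sites, sites]
        a = df.to_numpy()
        iu = np.triu_indices(a.shape[0], k=1)
        return a[iu]


# ---------------------------------------------------------------------------
# phylogenetic signal


def niche_distance(matrix: CommunityMatrix, meta: SiteMetadata,
                   factors=("elevation", "slope", "canopy", "evi", "near_dist")
                   ) -> pd.DataFrame:
    """Between-species niche distances from abundance-weighted environments.

    Each factor is standardized across sites; a species' niche value per
    factor is the abundance-weighted mean of that factor over the sites it
    occupies; the distance is Euclidean over factors.
    """
    tab = meta.align_to(matrix.sites).table[list(factors)].astype(float)
    z = (tab - tab.mean()) / tab.std(ddof=0)
    counts = matrix.values.astype(float)
    totals = counts.sum(axis=0)
    keep = totals > 0
    niche = (counts[:, keep].T @ z.to_numpy()) / totals[keep, None]
    species = [s for s, k in zip(matrix.species, keep) if k]
    d = squareform(pdist(niche, metric="euclidean"))
    return pd.DataFrame(d, index=species, columns=species)


@dataclass
class MantelCorrelogram:
    classes: pd.DataFrame  # lower, upper, n_pairs, r, p, p_adj
    permutations: int


def mantel_correlogram(phylo_d: pd.DataFrame, niche_d: pd.DataFrame,
                       n_classes: int | None = None, permutations: int = 999,
                       seed: int = 0) -> MantelCorrelogram:
    """Multivariate Mantel correlogram of niche distance on phylogenetic
    distance classes.

    For each phylogenetic-distance class the statistic is the point-biserial
    Mantel correlation between class membership and niche distance, signed
    so that a positive value means pairs in that class are *more similar*
    in niche than average (positive autocorrelation).  p-values come from
    permutation of species labels (two-sided) with a progressive
    Holm/Bonferroni correction over classes tested so far.
    """
    if permutations < 1:
        raise ValidationError("mantel correlogram needs ≥ 1 permutation")
    common = [s for s in phylo_d.index if s in set(niche_d.index)]
    if len(common) < 10:
        raise ValidationError("mantel correlogram needs ≥ 10 matched species")
    P = phylo_d.loc[common, common].to_numpy()
    E = niche_d.loc[common, common].to_numpy()
    n = len(common)
    iu = np.triu_indices(n, k=1)
    pvec = P[iu]
    if n_classes is None:
        n_classes = int(np.ceil(1 + np.log2(pvec.size)))  # Sturges
    edges = np.linspace(0.0, pvec.max(), n_classes + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)

    memberships = []
    bounds = []
    for k in range(n_classes):
        mem = (pvec >= edges[k]) & (pvec < edges[k + 1])
        if mem.sum() == 0:
            logger.warning("mantel correlogram: empty distance class %d dropped", k)
            continue
        if mem.all():
            logger.warning("mantel correlogram: degenerate full class %d dropped", k)
            continue
        memberships.append(mem.astype(float))
        bounds.append((edges[k], min(edges[k + 1], pvec.max())))
    M = np.array(memberships)  # classes × pairs

    def class_r(evec: np.ndarray) -> np.ndarray:
        # negative point-biserial correlation per class: positive r means
        # within-class niche distances are below average
        ez = (evec - evec.mean()) / evec.std()
        mz = (M - M.mean(axis=1, keepdims=True))
        mz /= M.std(axis=1, keepdims=True)
        return -(mz @ ez) / evec.size

    evec = E[iu]
    r_obs = class_r(evec)

    rng = derive_rng(seed, "mantel-correlogram")
    exceed = np.zeros_like(r_obs)
    for _ in range(permutations):
        perm = rng.permutation(n)
        evec_p = E[np.ix_(perm, perm)][iu]
        r_null = class_r(evec_p)
        exceed += np.abs(r_null) >= np.abs(r_obs) - 1e-12
    p = (exceed + 1.0) / (permutations + 1.0)
    # progressive correction: class k (1-indexed) corrected for k tests
    p_adj = np.minimum(1.0, p * np.arange(1, len(p) + 1))
    p_adj = np.maximum.accumulate(p_adj)

    table = pd.DataFrame({
        "lower": [b[0] for b in bounds],
        "upper": [b[1] for b in bounds],
        "n_pairs": M.sum(axis=1).astype(int),
        "r": r_obs,
        "p": p,
        "p_adj": p_adj,
    })
    return MantelCorrelogram(table, permutations)


def mantel_test(a: np.ndarray, b: np.ndarray, permutations: int = 999,
                seed: int = 0) -> tuple[float, float]:
    """Simple Mantel test (Pearson r between two distance matrices).

    Two-sided permutation p-value.  Used to relate selection strength
    (pairwise |βNTI|) to abiotic or biotic between-site distances.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    av, bv = a[iu], b[iu]
    ok = ~(np.isnan(av) | np.isnan(bv))
    r_obs = stats.pearsonr(av[ok], bv[ok])[0]
    rng = derive_rng(seed, "mantel-test")
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        bp = b[np.ix_(perm, perm)][iu]
        r = stats.pearsonr(av[ok], bp[ok])[0]
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
    return float(r_obs), (count + 1.0) / (permutations + 1.0)


# ---------------------------------------------------------------------------
# βMNTD / β-NTI


def beta_mntd(tree: Phylogeny, x, y, abundance_weighted: bool = True) -> float:
    """βMNTD between two communities given as counts over tree tips.

    0.5·[Σ_i f_i^x · min_{j∈y} d_ij + Σ_j f_j^y · min_{i∈x} d_ij] with f the
    within-community relative abundance (1/S if unweighted).  A species
    shared by both communities contributes distance zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ix = np.flatnonzero(x > 0)
    iy = np.flatnonzero(y > 0)
    if ix.size == 0 or iy.size == 0:
        raise ValidationError("βMNTD undefined for an empty community")
    D = tree.patristic
    dx = D[np.ix_(ix, iy)].min(axis=1)
    dy = D[np.ix_(iy, ix)].min(axis=1)
    if abundance_weighted:
        fx = x[ix] / x[ix].sum()
        fy = y[iy] / y[iy].sum()
    else:
        fx = np.full(ix.size, 1.0 / ix.size)
        fy = np.full(iy.size, 1.0 / iy.size)
    return float(0.5 * (fx @ dx + fy @ dy))


def _bmntd_all_pairs(D: np.ndarray, F: np.ndarray, P: np.ndarray) -> np.ndarray:
    """βMNTD for every site pair.

    D: species × species distances; F: species × sites weights (columns sum
    to 1, zero for absent species); P: species × sites presence.
    """
    n_sites = P.shape[1]
    M = np.empty((D.shape[0], n_sites))
    for t in range(n_sites):
        M[:, t] = D[:, P[:, t]].min(axis=1)
    B = F.T @ M
    return 0.5 * (B + B.T)


def _species_alignment(tree: Phylogeny, matrix: CommunityMatrix,
                       species: list | None):
    if species is None:
        species, _ = tree.match_species(matrix.species)
    if not species:
        raise ValidationError("no matrix species found on the tree")
    col_of = {s: j for j, s in enumerate(matrix.species)}
    cols = np.array([col_of[s] for s in species])
    tips = np.array([tree._tip_index[s] for s in species])
    counts = matrix.values.astype(float)[:, cols].T  # species × sites
    empty = counts.sum(axis=0) == 0
    if empty.any():
        bad = [s for s, e in zip(matrix.sites, empty) if e]
        raise ValidationError(f"site(s) with no tree-matched species: {bad}")
    return species, tips, counts


def beta_nti(tree: Phylogeny, matrix: CommunityMatrix, reps: int = 999,
             seed: int = 0, abundance_weighted: bool = True,
             species: list | None = None) -> PairwiseResult:
    """β-NTI: z-score of observed βMNTD against a tip-shuffle null.

    Each null replicate shuffles species identities across the analysis
    tips of the tree (one shuffle shared by all site pairs, the standard
    taxa-label randomization) and recomputes βMNTD for every pair.
    |βNTI| > 2 is conventionally read as deterministic selection.
    """
    if reps < 99:
        raise ValidationError("β-NTI needs ≥ 99 null replicates")
    species, tips, counts = _species_alignment(tree, matrix, species)
    P = counts > 0
    if abundance_weighted:
        F = counts / counts.sum(axis=0, keepdims=True)
    else:
        F = P / P.sum(axis=0, keepdims=True)

    D = tree.patristic[np.ix_(tips, tips)]
    obs = _bmntd_all_pairs(D, F, P)

    rng = derive_rng(seed, "beta-nti-null")
    n_sp = len(species)
    s = np.zeros_like(obs)
    ss = np.zeros_like(obs)
    for _ in range(reps):
        perm = rng.permutation(n_sp)
        Dp = D[np.ix_(perm, perm)]
        nb = _bmntd_all_pairs(Dp, F, P)
        s += nb
        ss += nb * nb
    mean = s / reps
    var = (ss - reps * mean * mean) / (reps - 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    # relative floor guards degenerate nulls (e.g. star trees) where the
    # accumulated variance is pure floating-point cancellation noise
    z[sd <= 1e-12 + 1e-6 * np.abs(mean)] = np.nan
    if np.isnan(z[np.triu_indices_from(z, k=1)]).any():
        logger.warning("β-NTI undefined for some pairs (null sd = 0)")
    np.fill_diagonal(z, np.nan)
    df = pd.DataFrame(z, index=matrix.sites, columns=matrix.sites)
    return PairwiseResult(df, "beta_nti", reps=reps, seed=seed)


def beta_mntd_matrix(tree: Phylogeny, matrix: CommunityMatrix,
                     abundance_weighted: bool = True) -> PairwiseResult:
    """Observed βMNTD for every site pair."""
    species, tips, counts = _species_alignment(tree, matrix, None)
    P = counts > 0
    if abundance_weighted:
        F = counts / counts.sum(axis=0, keepdims=True)
    else:
        F = P / P.sum(axis=0, keepdims=True)
    D = tree.patristic[np.ix_(tips, tips)]
    obs = _bmntd_all_pairs(D, F, P)
    return PairwiseResult(pd.DataFrame(obs, index=matrix.sites,
                                       columns=matrix.sites), "beta_mntd")


# ---------------------------------------------------------------------------
# Raup–Crick (Bray–Curtis)


def rc_bray(matrix: CommunityMatrix, reps: int = 999,
            seed: int = 0) -> PairwiseResult:
    """RCbray: Raup–Crick index on Bray–Curtis under a constrained null.

    Every null community preserves its site's observed richness and total
    abundance exactly: species identities are drawn without replacement
    with probability proportional to occupancy across sites, then the
    site's total is allocated among the drawn species by a multinomial with
    probabilities proportional to mean relative abundance.  Ties between
    null and observed dissimilarity count one half, giving the symmetric
    rescaling 2·(fraction(null < obs) + 0.5·fraction(null = obs) − 0.5)
    on [−1, 1].
    """
    if reps < 99:
        raise ValidationError("RCbray needs ≥ 99 null replicates")
    counts = matrix.values.astype(float)
    n_sites, n_sp = counts.shape
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1).astype(int)
    occupancy = (counts > 0).sum(axis=0).astype(float)
    p_occ = occupancy / occupancy.sum()
    rel = counts / counts.sum(axis=1, keepdims=True)
    p_ab = rel.mean(axis=0)

    obs = squareform(pdist(counts, metric="braycurtis"))
    iu = np.triu_indices(n_sites, k=1)
    obs_v = obs[iu]

    rng = derive_rng(seed, "rc-bray-null")
    less = np.zeros_like(obs_v)
    equal = np.zeros_like(obs_v)
    null_mat = np.zeros((n_sites, n_sp))
    for _ in range(reps):
        null_mat[:] = 0.0
        for s in range(n_sites):
            chosen = rng.choice(n_sp, size=int(richness[s]), replace=False,
                                p=p_occ)
            w = p_ab[chosen]
            w = w / w.sum()
            null_mat[s, chosen] = rng.multinomial(totals[s], w)
        null_v = pdist(null_mat, metric="braycurtis")
        less += null_v < obs_v - 1e-12
        equal += np.abs(null_v - obs_v) <= 1e-12
    rc_v = 2.0 * ((less + 0.5 * equal) / reps - 0.5)
    rc = np.full((n_sites, n_sites), np.nan)
    rc[iu] = rc_v
    rc[(iu[1], iu[0])] = rc_v
    df = pd.DataFrame(rc, index=matrix.sites, columns=matrix.sites)
    return PairwiseResult(df, "rc_bray", reps=reps, seed=seed)


# ---------------------------------------------------------------------------
# classification and comparisons


def _within_group_pairs(sites: list, groups: pd.Series | None):
    """Yield (label, i_indices, j_indices) of within-group site pairs."""
    if groups is None:
        n = len(sites)
        iu = np.triu_indices(n, k=1)
        yield "all", iu[0], iu[1]
        return
    groups = groups.reindex(sites)
    for label in groups.dropna().unique():
        idx = np.flatnonzero((groups == label).to_numpy())
        if idx.size < 2:
            continue
        ii, jj = np.triu_indices(idx.size, k=1)
        yield label, idx[ii], idx[jj]


def classify_pair(bnti: float, rc: float) -> str:
    """Five-way process assignment for one site pair."""
    if bnti > BNTI_THRESHOLD:
        return "heterogeneous_selection"
    if bnti < -BNTI_THRESHOLD:
        return "homogeneous_selection"
    if rc > RC_THRESHOLD:
        return "dispersal_limitation"
    if rc < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    return "undominated"


def classify_processes(bnti: PairwiseResult, rc: PairwiseResult,
                       groups: pd.Series | None = None) -> pd.DataFrame:
    """Fractions of the five assembly processes per group of sites.

    Fractions are computed over within-group site pairs and sum to one.
    Pairs with an undefined βNTI are dropped (logged).
    """
    sites = list(bnti.data.index)
    if list(rc.data.index) != sites:
        rc_data = rc.data.loc[sites, sites]
    else:
        rc_data = rc.data
    B = bnti.data.to_numpy()
    R = rc_data.to_numpy()
    rows = []
    for label, ii, jj in _within_group_pairs(sites, groups):
        b = B[ii, jj]
        r = R[ii, jj]
        ok = ~np.isnan(b)
        if (~ok).any():
            logger.warning("group %r: dropping %d pair(s) with undefined βNTI",
                           label, int((~ok).sum()))
        b, r = b[ok], r[ok]
        n = b.size
        counts = dict.fromkeys(PROCESSES, 0)
        for bv, rv in zip(b, r):
            counts[classify_pair(bv, rv)] += 1
        row = {"group": label, "n_pairs": n}
        row.update({k: (v / n if n else float("nan"))
                    for k, v in counts.items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def compare_bands(bnti: PairwiseResult,
                  groups: pd.Series) -> tuple[float, float]:
    """Kruskal–Wallis test of within-group βNTI across groups."""
    sites = list(bnti.data.index)
    B = bnti.data.to_numpy()
    samples = []
    for label, ii, jj in _within_group_pairs(sites, groups):
        vals = B[ii, jj]
        vals = vals[~np.isnan(vals)]
        if vals.size >= 2:
            samples.append(vals)
    if len(samples) < 2:
        raise ValidationError("Kruskal–Wallis needs ≥ 2 groups with ≥ 2 pairs")
    all_vals = np.concatenate(samples)
    if np.all(all_vals == all_vals[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def _paired_wilcoxon(da: np.ndarray, db: np.ndarray) -> tuple[float, float]:
    diff = da - db
    diff = diff[~np.isnan(diff)]
    if diff.size == 0 or np.allclose(diff, 0.0):
        return 0.0, 1.0
    stat, p = stats.wilcoxon(diff)
    return float(stat), float(p)


def compare_trees(matrix: CommunityMatrix, tree_a: Phylogeny,
                  tree_b: Phylogeny, reps: int = 999, seed: int = 0,
                  groups: pd.Series | None = None) -> pd.DataFrame:
    """Paired Wilcoxon comparison of βNTI under two trees.

    βNTI is computed under each tree with the same seed — hence identical
    null label shuffles — over the species common to both trees and the
    matrix, so differences reflect tree shape only (βNTI is invariant to a
    uniform rescaling of branch lengths).  Tested per group and overall.
    """
    in_both = [s for s in matrix.species
               if s in tree_a._tip_index and s in tree_b._tip_index]
    dropped = [s for s in matrix.species if s not in in_both]
    if dropped:
        logger.warning("compare_trees: %d species absent from a tree, excluded",
                       len(dropped))
    ra = beta_nti(tree_a, matrix, reps=reps, seed=seed, species=in_both)
    rb = beta_nti(tree_b, matrix, reps=reps, seed=seed, species=in_both)
    sites = list(matrix.sites)
    A = ra.data.to_numpy()
    Bm = rb.data.to_numpy()
    rows = []
    n = len(sites)
    iu = np.triu_indices(n, k=1)
    stat, p = _paired_wilcoxon(A[iu], Bm[iu])
    rows.append({"group": "overall", "n_pairs": len(iu[0]),
                 "wilcoxon_stat": stat, "p": p,
                 "mean_abs_diff": float(np.nanmean(np.abs(A[iu] - Bm[iu])))})
    if groups is not None:
        for label, ii, jj in _within_group_pairs(sites, groups):
            stat, p = _paired_wilcoxon(A[ii, jj], Bm[ii, jj])
            rows.append({"group": label, "n_pairs": ii.size,
                         "wilcoxon_stat": stat, "p": p,
                         "mean_abs_diff": float(np.nanmean(
                             np.abs(A[ii, jj] - Bm[ii, jj])))})
    return pd.DataFrame(rows).set_index("group")
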