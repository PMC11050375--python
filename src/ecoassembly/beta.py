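"""Pairwise beta diversity and its turnover/nestedness decomposition.

Taxonomic beta diversity is the abundance-based Bray–Curtis index; the
phylogenetic analogue is the PhyloSor (shared-branch-length Sørensen)
index.  Both are decomposed into a turnover (replacement / balanced
variation) and a nestedness (richness- or abundance-difference) component
under two frameworks:

* BAS — total = (B+C)/(2A+B+C), turnover = min(B,C)/(A+min(B,C)),
  nestedness = total − turnover.
* POD — same total, replacement = 2·min(B,C)/(2A+B+C),
  richness/abundance difference = |B−C|/(2A+B+C).

A is the matched quantity between the two sites (Σ min of paired
abundances, or shared spanning-branch length), B and C the quantities
unique to each site, so A+B and A+C are the two site totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .alpha import faith_pd
from .core import CommunityMatrix, Phylogeny, ValidationError


@dataclass(frozen=True)
class AbcComponents:
    """Matching components of a site pair: shared A, unique B and C."""

    A: float
    B: float
    C: float


@dataclass(frozen=True)
class BetaPartition:
    total: float
    turnover: float
    nestedness: float
    framework: str
    basis: str


def abc_taxonomic(x, y) -> AbcComponents:
    """Abundance matching components: A = Σ min(x_i, y_i)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("paired communities must share a species universe")
    m = np.minimum(x, y)
    return AbcComponents(float(m.sum()), float((x - m).sum()), float((y - m).sum()))


def abc_phylogenetic(tree: Phylogeny, s1, s2,
                     include_root: bool = True) -> AbcComponents:
    """Branch-length matching components of two spanning subtrees.

    A is the branch length common to both spanning subtrees, B/C the length
    exclusive to each, so A+B = PD(s1) and A+C = PD(s2).
    """
    m1 = s1 if isinstance(s1, np.ndarray) else tree.tip_mask(s1)
    m2 = s2 if isinstance(s2, np.ndarray) else tree.tip_mask(s2)
    if not m1.any() or not m2.any():
        raise ValidationError("PhyloSor components undefined for an empty set")
    below1 = tree.edge_tip @ m1.astype(np.int64)
    below2 = tree.edge_tip @ m2.astype(np.int64)
    in1 = below1 > 0
    in2 = below2 > 0
    if not include_root:
        in1 &= ~(below1 == m1.sum())
        in2 &= ~(below2 == m2.sum())
    b = tree.edge_lengths
    A = float(b[in1 & in2].sum())
    B = float(b[in1 & ~in2].sum())
    C = float(b[in2 & ~in1].sum())
    return AbcComponents(A, B, C)


def _total(abc: AbcComponents) -> float:
    denom = 2 * abc.A + abc.B + abc.C
    if denom == 0:
        raise ValidationError("beta diversity undefined for two empty sites")
    return (abc.B + abc.C) / denom


def partition_bas(abc: AbcComponents, basis: str = "taxonomic") -> BetaPartition:
    """Baselga-family decomposition: balanced-variation turnover."""
    total = _total(abc)
    mn = min(abc.B, abc.C)
    # A + min = 0 forces min = 0: no balanced/replacement component
    turnover = mn / (abc.A + mn) if (abc.A + mn) > 0 else 0.0
    return BetaPartition(total, turnover, total - turnover, "BAS", basis)


def partition_pod(abc: AbcComponents, basis: str = "taxonomic") -> BetaPartition:
    """Podani/Cardoso-family decomposition: replacement + difference."""
    total = _total(abc)
    denom = 2 * abc.A + abc.B + abc.C
    turnover = 2 * min(abc.B, abc.C) / denom
    nestedness = abs(abc.B - abc.C) / denom
    return BetaPartition(total, turnover, nestedness, "POD", basis)


_PARTITIONERS = {"bas": partition_bas, "pod": partition_pod}


def pairwise_tables(matrix: CommunityMatrix, tree: Phylogeny | None,
                    framework: str = "bas") -> dict[str, pd.DataFrame]:
    """Site × site tables of total, turnover and nestedness components."""
    part = _PARTITIONERS[framework.lower()]
    sites = matrix.sites
    n = len(sites)
    x = matrix.values.astype(float)
    basis = "taxonomic"
    masks = None
    if tree is not None:
        basis = "phylogenetic"
        matched, _ = tree.match_species(matrix.species)
        col_of = {s: j for j, s in enumerate(matrix.species)}
        tip_idx = np.array([tree._tip_index[s] for s in matched])
        cols = np.array([col_of[s] for s in matched])
        masks = []
        for i in range(n):
            mask = np.zeros(tree.n_tips, dtype=bool)
            mask[tip_idx[x[i, cols] > 0]] = True
            masks.append(mask)
    tables = {k: np.zeros((n, n)) for k in ("total", "turnover", "nestedness")}
    for i, j in combinations(range(n), 2):
        if tree is None:
            abc = abc_taxonomic(x[i], x[j])
        else:
            abc = abc_phylogenetic(tree, masks[i], masks[j])
        p = part(abc, basis=basis)
        for key, val in (("total", p.total), ("turnover", p.turnover),
                         ("nestedness", p.nestedness)):
            tables[key][i, j] = tables[key][j, i] = val
    return {k: pd.DataFrame(v, index=sites, columns=sites)
            for k, v in tables.items()}


def summarize_components(matrix: CommunityMatrix, tree: Phylogeny | None = None,
                         framework: str = "bas") -> dict[str, float]:
    """Mean pairwise component shares over all site pairs.

    Each pair contributes turnover + nestedness + similarity (1 − total)
    = 1, so the three mean shares sum to 1; reported on [0, 1].
    """
    tables = pairwise_tables(matrix, tree, framework=framework)
    n = len(matrix.sites)
    if n < 2:
        raise ValidationError("need ≥ 2 sites for beta diversity")
    iu = np.triu_indices(n, k=1)
    turnover = float(tables["turnover"].to_numpy()[iu].mean())
    nestedness = float(tables["nestedness"].to_numpy()[iu].mean())
    total = float(tables["total"].to_numpy()[iu].mean())
    return {
        "framework": framework.upper(),
        "basis": "phylogenetic" if tree is not None else "taxonomic",
        "turnover_share": turnover,
        "nestedness_share": nestedness,
        "similarity_share": 1.0 - total,
        "mean_total": total,
        "n_pairs": int(len(iu[0])),
    }


def bray_curtis_matrix(matrix: CommunityMatrix) -> pd.DataFrame:
    """Full pairwise Bray–Curtis dissimilarity table."""
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(matrix.values.astype(float), metric="braycurtis"))
    return pd.DataFrame(d, index=matrix.sites, columns=matrix.sites)
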