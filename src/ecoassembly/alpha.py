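"""Per-site taxonomic and phylogenetic alpha diversity.

Implements Hill numbers of order q, Faith's phylogenetic diversity (PD),
mean nearest taxon distance (MNTD), Chao's sample-coverage estimator, and
the Pearson association of every metric with elevation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .core import CommunityMatrix, Phylogeny, SiteMetadata, ValidationError

logger = logging.getLogger("ecoassembly")

ALPHA_METRICS = ("SR", "abundance", "hill_q0", "hill_q1", "hill_q2",
                 "PD", "MNTD", "coverage")


def hill_number(counts, q: float) -> float:
    """Effective species number of order q.

    ``(Σ p_i^q)^(1/(1−q))`` for q ≠ 1, and the exponential of Shannon
    entropy at q = 1 (the continuous limit).  q = 0 is species richness,
    q = 2 the inverse Simpson concentration.
    """
    x = np.asarray(counts, dtype=float)
    if q < 0:
        raise ValidationError("Hill order q must be ≥ 0")
    x = x[x > 0]
    if x.size == 0:
        raise ValidationError("Hill number undefined for an all-zero community")
    p = x / x.sum()
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p ** q) ** (1.0 / (1.0 - q)))


def faith_pd(tree: Phylogeny, present, include_root: bool = True) -> float:
    """Faith's PD: branch length of the minimal subtree spanning ``present``.

    With ``include_root`` (default) the subtree is anchored at the root, so a
    single tip has PD equal to its root-to-tip depth; the unrooted variant
    spans only the tips (branches above their MRCA are excluded).
    """
    mask = present if isinstance(present, np.ndarray) else tree.tip_mask(present)
    if not mask.any():
        raise ValidationError("Faith's PD undefined for an empty species set")
    below = tree.edge_tip @ mask.astype(np.int64)  # present tips below edge
    spanning = below > 0
    total = float(tree.edge_lengths[spanning].sum())
    if not include_root:
        # edges ancestral to every present tip form the root-to-MRCA path
        on_root_path = spanning & (below == mask.sum())
        total -= float(tree.edge_lengths[on_root_path].sum())
    return total


def mntd(tree: Phylogeny, counts, species=None,
         abundance_weighted: bool = False) -> float:
    """Mean nearest taxon distance within one community.

    For each present species, the patristic distance to its closest
    relative in the same community; averaged equally (default) or with
    relative-abundance weights.  Returns NaN (with a log entry) when fewer
    than two species are present.
    """
    x = np.asarray(counts, dtype=float)
    if species is None:
        if x.size != tree.n_tips:
            raise ValidationError("counts length must equal number of tips")
        idx = np.flatnonzero(x > 0)
    else:
        order = [tree._tip_index[s] for s in species]
        idx_local = np.flatnonzero(x > 0)
        idx = np.array([order[i] for i in idx_local], dtype=int)
        x = np.zeros(tree.n_tips)
        for i, j in zip(idx_local, idx):
            x[j] = counts[i]
    if idx.size < 2:
        logger.warning("MNTD undefined for a community with <2 species")
        return float("nan")
    d = tree.patristic[np.ix_(idx, idx)].astype(float).copy()
    np.fill_diagonal(d, np.inf)
    nearest = d.min(axis=1)
    if abundance_weighted:
        w = x[idx] / x[idx].sum()
        return float(np.sum(w * nearest))
    return float(nearest.mean())


def sample_coverage(counts) -> float:
    """Chao's coverage estimator from singleton and doubleton counts.

    Ĉ = 1 − (f1/n)·[(n−1)f1 / ((n−1)f1 + 2 f2)].
    """
    x = np.asarray(counts)
    x = x[x > 0]
    n = x.sum()
    if n < 1:
        raise ValidationError("coverage undefined for an empty sample")
    f1 = int(np.sum(x == 1))
    f2 = int(np.sum(x == 2))
    if f1 == 0:
        return 1.0
    if n == 1:
        return 0.0
    return float(1.0 - (f1 / n) * ((n - 1) * f1 / ((n - 1) * f1 + 2 * f2)))


def alpha_table(matrix: CommunityMatrix, tree: Phylogeny | None = None,
                include_root: bool = True,
                abundance_weighted_mntd: bool = False) -> pd.DataFrame:
    """One row of alpha-diversity metrics per site.

    Species absent from the tree are excluded from PD/MNTD only; SR,
    abundance, Hill numbers and coverage always use the full matrix.
    """
    rows = {}
    counts = matrix.values
    if tree is not None:
        matched, _ = tree.match_species(matrix.species)
        col_of = {s: j for j, s in enumerate(matrix.species)}
        matched_cols = [col_of[s] for s in matched]
        tip_idx = [tree._tip_index[s] for s in matched]
    for i, site in enumerate(matrix.sites):
        x = counts[i]
        rec = {
            "SR": int(np.sum(x > 0)),
            "abundance": int(x.sum()),
            "hill_q0": hill_number(x, 0),
            "hill_q1": hill_number(x, 1),
            "hill_q2": hill_number(x, 2),
            "coverage": sample_coverage(x),
        }
        if tree is not None:
            full = np.zeros(tree.n_tips)
            for c, t in zip(matched_cols, tip_idx):
                full[t] = x[c]
            if np.any(full > 0):
                mask = full > 0
                rec["PD"] = faith_pd(tree, mask, include_root=include_root)
                rec["MNTD"] = mntd(tree, full,
                                   abundance_weighted=abundance_weighted_mntd)
            else:
                rec["PD"] = float("nan")
                rec["MNTD"] = float("nan")
        rows[site] = rec
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "site"
    return df


def diversity_elevation_correlation(records: pd.DataFrame,
                                    meta: SiteMetadata) -> pd.DataFrame:
    """Pearson r (and two-sided p) of each alpha metric against elevation."""
    elev = meta.align_to(records.index).elevation().to_numpy()
    if len(elev) < 3:
        raise ValidationError("need ≥ 3 sites for a correlation")
    out = {}
    for col in records.columns:
        y = records[col].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        if ok.sum() < 3 or np.std(y[ok]) == 0:
            out[col] = {"r": float("nan"), "p": float("nan")}
            continue
        r, p = stats.pearsonr(elev[ok], y[ok])
        out[col] = {"r": float(r), "p": float(p)}
    df = pd.DataFrame.from_dict(out, orient="index")
    df.index.name = "metric"
    return df
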