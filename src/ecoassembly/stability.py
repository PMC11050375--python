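"""Community complexity (cohesion) and stability (average variation degree).

Cohesion quantifies how strongly taxa co-vary across sites after removing
the correlation expected by chance: pairwise Pearson correlations of
relative abundances are corrected by a taxon-shuffle null, each species'
positive/negative connectedness is the mean of its positive/negative
corrected correlations, and a site's positive/negative cohesion is the
abundance-weighted sum of connectedness over the taxa it contains.

The average variation degree (AVD) measures instability as the mean
absolute standardized deviation of species' relative abundances within a
group of sites; lower AVD means a more stable community.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CommunityMatrix, ValidationError, derive_rng

logger = logging.getLogger("ecoassembly")


@dataclass
class CohesionResult:
    """Per-species connectedness and per-site cohesion (±)."""

    connectedness: pd.DataFrame   # species × (positive, negative)
    cohesion: pd.DataFrame        # site × (positive, negative)
    excluded_species: list
    null_iters: int


def cohesion(matrix: CommunityMatrix, null_iters: int = 200,
             seed: int = 0) -> CohesionResult:
    """Null-corrected abundance-weighted correlation structure.

    The null ("taxon shuffle") permutes each species' relative abundances
    across sites independently, ``null_iters`` times; the corrected
    correlation of a pair is the observed Pearson correlation minus the
    null mean.  Species with zero variance across sites carry no
    correlation information and are excluded (logged).
    """
    if len(matrix.sites) < 5:
        raise ValidationError("cohesion needs ≥ 5 sites")
    rel = matrix.relative_abundance()
    var = rel.var(axis=0)
    keep = var > 0
    excluded = [s for s, k in zip(matrix.species, keep) if not k]
    if excluded:
        logger.warning("cohesion: excluding %d zero-variance species", len(excluded))
    rel = rel[:, keep]
    species = [s for s, k in zip(matrix.species, keep) if k]
    n_sites, n_sp = rel.shape

    obs = np.corrcoef(rel, rowvar=False)

    rng = derive_rng(seed, "cohesion-taxon-shuffle")
    null_sum = np.zeros((n_sp, n_sp))
    for _ in range(null_iters):
        shuffled = np.empty_like(rel)
        for j in range(n_sp):
            shuffled[:, j] = rel[rng.permutation(n_sites), j]
        null_sum += np.corrcoef(shuffled, rowvar=False)
    corrected = obs - null_sum / null_iters
    np.fill_diagonal(corrected, 0.0)

    pos = np.where(corrected > 0, corrected, np.nan)
    neg = np.where(corrected < 0, corrected, np.nan)
    with np.errstate(invalid="ignore"):
        conn_pos = np.nan_to_num(np.nanmean(pos, axis=1))
        conn_neg = np.nan_to_num(np.nanmean(neg, axis=1))

    coh_pos = rel @ conn_pos
    coh_neg = rel @ conn_neg

    connectedness = pd.DataFrame(
        {"positive": conn_pos, "negative": conn_neg}, index=species)
    coh = pd.DataFrame(
        {"positive": coh_pos, "negative": coh_neg}, index=matrix.sites)
    return CohesionResult(connectedness, coh, excluded, null_iters)


def avd_from_values(values: np.ndarray, ddof: int = 0) -> float:
    """AVD of a sites × species array of (relative) abundances.

    Mean over species and sites of |a_is − μ_i| / σ_i, with μ_i and σ_i the
    within-group mean and (population) standard deviation of species i, so
    a species whose values sit exactly ±σ from its mean contributes exactly
    1.  Zero-variance species are excluded.
    """
    a = np.asarray(values, dtype=float)
    mu = a.mean(axis=0)
    sd = a.std(axis=0, ddof=ddof)
    keep = sd > 0
    if not keep.any():
        return float("nan")
    z = np.abs(a[:, keep] - mu[keep]) / sd[keep]
    return float(z.mean())


def avd(matrix: CommunityMatrix, groups: pd.Series,
        normality_filter: bool = True, alpha: float = 0.05) -> pd.DataFrame:
    """Average variation degree per group of sites.

    ``groups`` maps site → group label (typically the elevation band).
    With the normality filter on, species whose within-group relative
    abundances fail a Shapiro–Wilk test at ``alpha`` are excluded, matching
    the usual restriction of AVD to normally distributed taxa.
    """
    rel = pd.DataFrame(matrix.relative_abundance(),
                       index=matrix.sites, columns=matrix.species)
    groups = groups.reindex(rel.index)
    if groups.isna().any():
        raise ValidationError("every site needs a group label for AVD")
    rows = []
    for label, sub in rel.groupby(groups, sort=False):
        a = sub.to_numpy()
        k = a.shape[0]
        if k < 3:
            logger.warning("AVD group %r has <3 sites; skipped", label)
            rows.append({"group": label, "AVD": float("nan"),
                         "n_sites": k, "n_species": 0})
            continue
        sd = a.std(axis=0, ddof=0)
        keep = sd > 0
        if normality_filter:
            for j in np.flatnonzero(keep):
                try:
                    _, p = stats.shapiro(a[:, j])
                except ValueError:
                    keep[j] = False
                    continue
                if p < alpha:
                    keep[j] = False
        n_kept = int(keep.sum())
        value = avd_from_values(a[:, keep]) if n_kept else float("nan")
        rows.append({"group": label, "AVD": value,
                     "n_sites": k, "n_species": n_kept})
    return pd.DataFrame(rows).set_index("group")
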