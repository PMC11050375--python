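"""Sloan neutral community model (NCM) fit to occupancy–abundance data.

The model predicts, for a local community of N individuals receiving
immigrants from a metacommunity at rate m, that the long-run local relative
abundance of a taxon with metacommunity relative abundance p follows a Beta
distribution with shape parameters ``N·m·p`` and ``N·m·(1−p)``.  A taxon is
treated as detected at a site when its relative abundance exceeds a
detection limit d, so its expected occupancy across sites is the upper
Beta tail at d.  The default places d at the half-detection abundance
``ln 2 / N`` — the x at which the probability of appearing at least once
in a sample of N individuals, 1 − (1 − x)^N, equals one half — which makes
the step-threshold prediction an unbiased stand-in for the soft
finite-sample detection curve; the conventional one-individual limit 1/N
is available via ``detection_limit``.  The single free parameter N·m is
estimated by least squares of predicted against observed occupancy; taxa
outside a 95% binomial confidence band around the prediction are
classified as over- or under-represented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import CommunityMatrix, SiteMetadata, ValidationError, derive_rng

logger = logging.getLogger("ecoassembly")


@dataclass
class NCMFit:
    """Result of one neutral-model fit."""

    Nm: float
    m: float
    N: float
    R2: float
    n_sites: int
    taxa: pd.DataFrame  # p, freq, predicted, ci_lower, ci_upper, class
    neutral_abundance_share: float
    group: str | None = None

    def class_shares(self) -> dict[str, float]:
        """Summed mean relative abundance per occupancy class."""
        return self.taxa.groupby("class")["p"].sum().to_dict()


def predicted_occupancy(p: np.ndarray, Nm: float, d: float) -> np.ndarray:
    """Upper Beta tail at the detection limit: P(x > d | p, Nm)."""
    p = np.asarray(p, dtype=float)
    return stats.beta.sf(d, Nm * p, Nm * (1.0 - p))


def _wilson_band(pred: np.ndarray, n_sites: int,
                 level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
    """Wilson score interval for a binomial proportion at each prediction."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    n = float(n_sites)
    denom = 1.0 + z * z / n
    centre = (pred + z * z / (2 * n)) / denom
    half = (z / denom) * np.sqrt(pred * (1 - pred) / n + z * z / (4 * n * n))
    return np.clip(centre - half, 0, 1), np.clip(centre + half, 0, 1)


def fit_ncm(matrix: CommunityMatrix, group: str | None = None,
            detection_limit: float | None = None) -> NCMFit:
    """Fit the NCM to one set of sites.

    N is the mean per-site total count; p_i the mean across sites of each
    taxon's relative abundance; observed occupancy the fraction of sites
    where the taxon was detected.  Nm is found by bounded scalar least
    squares on untransformed occupancies, constrained to (0, N] so that the
    migration rate m = Nm/N stays in (0, 1].  ``detection_limit`` defaults
    to the half-detection abundance ln 2 / N.
    """
    counts = matrix.values.astype(float)
    n_sites, n_taxa = counts.shape
    if n_sites < 5:
        raise ValidationError("NCM fit needs ≥ 5 sites")
    present = counts.sum(axis=0) > 0
    counts = counts[:, present]
    taxa_names = [s for s, k in zip(matrix.species, present) if k]
    if counts.shape[1] < 10:
        raise ValidationError("NCM fit needs ≥ 10 taxa")

    N = float(counts.sum(axis=1).mean())
    d = detection_limit if detection_limit is not None else np.log(2.0) / N
    rel = counts / counts.sum(axis=1, keepdims=True)
    p = rel.mean(axis=0)
    freq = (counts > 0).mean(axis=0)

    def sse(log_nm: float) -> float:
        pred = predicted_occupancy(p, np.exp(log_nm), d)
        return float(np.sum((freq - pred) ** 2))

    res = optimize.minimize_scalar(sse, bounds=(np.log(1e-3), np.log(N)),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    if not res.success:
        raise RuntimeError(
            f"NCM fit failed to converge: residual {res.fun:.4g}, "
            f"bounds (0, {N:.4g}]")
    Nm = float(np.exp(res.x))
    pred = predicted_occupancy(p, Nm, d)
    sst = float(np.sum((freq - freq.mean()) ** 2))
    r2 = 1.0 - res.fun / sst if sst > 0 else float("nan")

    lo, hi = _wilson_band(pred, n_sites)
    cls = np.where(freq > hi, "over", np.where(freq < lo, "under", "neutral"))
    taxa = pd.DataFrame({
        "p": p, "freq": freq, "predicted": pred,
        "ci_lower": lo, "ci_upper": hi, "class": cls,
    }, index=taxa_names)
    neutral_share = float(p[cls == "neutral"].sum())
    return NCMFit(Nm=Nm, m=Nm / N, N=N, R2=float(r2), n_sites=n_sites,
                  taxa=taxa, neutral_abundance_share=neutral_share,
                  group=group)


def ncm_by_band(matrix: CommunityMatrix, meta: SiteMetadata,
                min_sites: int = 5) -> dict[str, NCMFit]:
    """Independent NCM fit per elevation band (N estimated per band)."""
    bands = meta.align_to(matrix.sites).bands()
    fits: dict[str, NCMFit] = {}
    for label in bands.unique():
        sites = bands.index[bands == label]
        if len(sites) < min_sites:
            logger.warning("band %r has %d sites (<%d); NCM skipped",
                           label, len(sites), min_sites)
            continue
        fits[label] = fit_ncm(matrix.subset_sites(sites), group=label)
    return fits


def simulate_ncm_counts(n_sites: int, n_taxa: int, Nm: float, N: int,
                        seed: int = 0,
                        lognormal_sigma: float = 1.5) -> CommunityMatrix:
    """Draw a count matrix from the Beta approximation of the NCM.

    Metacommunity relative abundances are lognormal (normalized); each
    site × taxon relative abundance is an independent Beta(Nm·p, Nm·(1−p))
    draw, and the observed counts are binomial samples of N individuals at
    that relative abundance, so detection follows the finite-sample curve
    1 − (1 − x)^N.
    """
    rng = derive_rng(seed, "ncm-beta-simulation")
    p = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=n_taxa)
    p = np.sort(p / p.sum())[::-1]
    x = rng.beta(Nm * p[None, :], Nm * (1.0 - p[None, :]),
                 size=(n_sites, n_taxa))
    counts = rng.binomial(N, x)
    df = pd.DataFrame(counts,
                      index=[f"site{i+1}" for i in range(n_sites)],
                      columns=[f"sp{j+1}" for j in range(n_taxa)])
    return CommunityMatrix(df)
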