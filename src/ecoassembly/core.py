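"""Core data model and I/O for grid-based community surveys.

The three observational objects every downstream analysis consumes are a
site × species count matrix, a rooted phylogeny whose tips are species
identifiers, and a per-site metadata table carrying elevation and other
environmental covariates.  This module owns their validation, their
round-trippable on-disk formats (TSV and Newick), the elevation-band
assignment, and the shared random-number contract (:class:`RunConfig`).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("ecoassembly")

DEFAULT_BAND_EDGES = (416.0, 580.0, 744.0, 908.0, 1072.0)

METADATA_COLUMNS = ("elevation", "slope", "canopy", "evi", "near_dist")


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


def _check_unique(labels, kind: str) -> None:
    seen, dups = set(), []
    for lab in labels:
        if lab in seen:
            dups.append(lab)
        seen.add(lab)
    if dups:
        raise ValidationError(f"duplicate {kind} identifier(s): {sorted(set(dups))}")


class CommunityMatrix:
    """Site × species matrix of non-negative integer counts.

    Parameters
    ----------
    counts
        DataFrame with site identifiers as the index and species
        identifiers as columns.  Values must be non-negative integers.
    drop_empty_sites
        Sites with no individuals are removed (and logged); a site that
        recorded nothing carries no community information.
    """

    def __init__(self, counts: pd.DataFrame, drop_empty_sites: bool = True):
        _check_unique(counts.index, "site")
        _check_unique(counts.columns, "species")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(values < 0):
            raise ValidationError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValidationError("counts must be integers (individuals observed)")
        counts = counts.astype(np.int64)
        if drop_empty_sites:
            empty = counts.index[counts.sum(axis=1) == 0]
            if len(empty):
                logger.warning("dropping %d all-zero site(s): %s", len(empty), list(empty))
                counts = counts.drop(index=empty)
        if counts.shape[0] == 0:
            raise ValidationError("community matrix has no retained sites")
        counts.index.name = "site"
        counts.columns.name = None
        self.counts = counts

    @property
    def sites(self) -> list:
        return list(self.counts.index)

    @property
    def species(self) -> list:
        return list(self.counts.columns)

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy()

    def relative_abundance(self) -> np.ndarray:
        """Per-site relative abundances (rows sum to 1)."""
        x = self.values.astype(float)
        return x / x.sum(axis=1, keepdims=True)

    def total(self) -> int:
        return int(self.values.sum())

    def subset_sites(self, sites) -> "CommunityMatrix":
        return CommunityMatrix(self.counts.loc[list(sites)], drop_empty_sites=False)

    def write(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="site")

    def __repr__(self) -> str:  # pragma: no cover
        return f"CommunityMatrix({self.counts.shape[0]} sites × {self.counts.shape[1]} species)"


def read_community(path) -> CommunityMatrix:
    """Read a tab-separated site × species count table.

    First column holds site identifiers, header row species identifiers.
    Duplicate identifiers, ragged rows, and non-numeric or negative cells
    are rejected with errors naming the offender.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], "species")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed community table {path}: {exc}") from exc
    _check_unique(df.index, "site")
    try:
        numeric = df.apply(pd.to_numeric)
    except (ValueError, TypeError):
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().nonzero()[0][0]]
                raise ValidationError(
                    f"non-numeric count at site {row!r}, species {col!r}"
                ) from None
        raise
    if numeric.isna().any().any():
        raise ValidationError("missing values in community table (ragged rows?)")
    return CommunityMatrix(numeric)


class Phylogeny:
    """Rooted tree with non-negative branch lengths over species tips.

    Wraps a dendropy tree and caches the numpy structures the null models
    iterate over: the tip-label list, an edge × tip incidence matrix, the
    edge-length vector, and the patristic (tip-to-tip path length) matrix.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        _check_unique(tips, "tip")
        self.tip_labels = tips
        self._tip_index = {lab: i for i, lab in enumerate(tips)}
        n = len(tips)

        edges = []
        lengths = []
        incidence = []
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            bl = node.edge.length if node.edge.length is not None else 0.0
            if bl < 0:
                raise ValidationError(f"negative branch length {bl}")
            mask = np.zeros(n, dtype=bool)
            for leaf in node.leaf_iter():
                mask[self._tip_index[leaf.taxon.label]] = True
            edges.append(node)
            lengths.append(float(bl))
            incidence.append(mask)
        # edge_tip[e, t] is True when tip t lies below edge e
        self.edge_tip = np.array(incidence, dtype=bool)
        self.edge_lengths = np.array(lengths, dtype=float)

        weighted = self.edge_tip * self.edge_lengths[:, None]
        shared = weighted.T @ self.edge_tip  # shared root-path length per tip pair
        depth = np.diag(shared).copy()
        self._depths = depth
        self.patristic = depth[:, None] + depth[None, :] - 2.0 * shared
        np.fill_diagonal(self.patristic, 0.0)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def total_branch_length(self) -> float:
        return float(self.edge_lengths.sum())

    def tip_mask(self, labels) -> np.ndarray:
        """Boolean mask over tips for a collection of species labels."""
        mask = np.zeros(self.n_tips, dtype=bool)
        for lab in labels:
            try:
                mask[self._tip_index[lab]] = True
            except KeyError:
                raise ValidationError(f"unknown tip label {lab!r}") from None
        return mask

    def match_species(self, species) -> tuple[list, list]:
        """Split a species list into (present-on-tree, missing-from-tree).

        Species missing from the tree are reported so callers can exclude
        them from phylogenetic metrics while leaving taxonomic metrics
        untouched.
        """
        matched = [s for s in species if s in self._tip_index]
        missing = [s for s in species if s not in self._tip_index]
        if missing:
            logger.warning(
                "%d species absent from tree, excluded from phylogenetic metrics: %s",
                len(missing), missing,
            )
        return matched, missing

    def write(self, path) -> None:
        self.tree.write(path=str(path), schema="newick", suppress_rooting=True)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny({self.n_tips} tips, length {self.total_branch_length():.4g})"


def read_tree(path) -> Phylogeny:
    """Read a rooted Newick tree with branch lengths."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:
        raise ValidationError(f"unparseable Newick in {path}: {exc}") from exc
    return Phylogeny(tree)


def tree_from_string(newick: str) -> Phylogeny:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return Phylogeny(tree)


def band_label(lo: float, hi: float) -> str:
    def fmt(x: float) -> str:
        return str(int(x)) if float(x).is_integer() else str(x)

    return f"{fmt(lo)}–{fmt(hi)} m"


class SiteMetadata:
    """Per-site environmental covariates and the elevation-band label.

    The table must carry one row per site with columns
    ``elevation`` (m), ``slope`` (degrees), ``canopy`` (fraction),
    ``evi`` (index) and ``near_dist`` (m, distance to nearest settlement).
    """

    def __init__(self, table: pd.DataFrame):
        _check_unique(table.index, "site")
        missing = [c for c in METADATA_COLUMNS if c not in table.columns]
        if missing:
            raise ValidationError(f"metadata missing required column(s): {missing}")
        self.table = table.copy()

    @property
    def sites(self) -> list:
        return list(self.table.index)

    def elevation(self) -> pd.Series:
        return self.table["elevation"].astype(float)

    def bands(self) -> pd.Series:
        if "elevation_band" not in self.table.columns:
            raise ValidationError("bands not assigned; call assign_bands first")
        return self.table["elevation_band"]

    def align_to(self, sites) -> "SiteMetadata":
        missing = [s for s in sites if s not in self.table.index]
        if missing:
            raise ValidationError(f"metadata missing site(s): {missing}")
        return SiteMetadata(self.table.loc[list(sites)])

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="site")


def read_metadata(path) -> SiteMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SiteMetadata(df)


def assign_bands(meta: SiteMetadata, edges=DEFAULT_BAND_EDGES) -> SiteMetadata:
    """Label every site with the elevation band containing it.

    Bands are half-open ``[edge_k, edge_{k+1})``; the top edge is closed so
    the highest site belongs to the last band.  Elevations outside the
    configured range are an error naming the site.
    """
    edges = [float(e) for e in edges]
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValidationError("band edges must be strictly increasing")
    elev = meta.elevation()
    labels = []
    for site, e in elev.items():
        if e < edges[0] or e > edges[-1]:
            raise ValidationError(
                f"site {site!r} elevation {e} outside band range "
                f"[{edges[0]}, {edges[-1]}]"
            )
        if e == edges[-1]:
            k = len(edges) - 2
        else:
            k = int(np.searchsorted(edges, e, side="right")) - 1
        labels.append(band_label(edges[k], edges[k + 1]))
    out = meta.table.copy()
    out["elevation_band"] = labels
    return SiteMetadata(out)


@dataclass
class RunConfig:
    """Global run parameters and the shared random-number contract.

    Every stochastic operation derives its own independent stream from the
    single ``seed`` via :meth:`stream`, keyed by a stable operation label,
    so modules stay reproducible without ordering constraints between them.
    """

    seed: int = 0
    n_null: int = 999
    band_edges: tuple = DEFAULT_BAND_EDGES
    alpha: float = 0.05

    def __post_init__(self):
        if self.n_null < 1:
            raise ValidationError("number of null randomizations must be ≥ 1")
        edges = list(self.band_edges)
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValidationError("band edges must be strictly increasing")

    def stream(self, label: str) -> np.random.Generator:
        """Independent generator for one named stochastic operation."""
        return derive_rng(self.seed, label)


def derive_rng(seed: int, label: str) -> np.random.Generator:
    """Derive a named, reproducible stream from a global seed."""
    key = zlib.crc32(label.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
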