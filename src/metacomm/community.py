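"""Rarefaction, abundance summaries, taxon subsetting, and the community /
environmental / spatial distance matrices."""

from __future__ import annotations

import logging
import re
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io_formats import DistanceMatrix, FormatError, OtuTable, SampleMetadata

__all__ = [
    "rarefy",
    "relative_abundance",
    "subset_by_taxon",
    "bray_curtis",
    "env_distance",
    "spatial_distance",
    "occupancy",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

_TAXON_SPLIT = re.compile(r"[;,|\s]+")


def rarefy(t: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Each retained sample's counts are drawn from a multivariate
    hypergeometric distribution over its reads (classic rarefaction).
    Samples with fewer than ``depth`` total reads are dropped and logged;
    OTUs left with zero total reads are removed.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = t.sample_totals()
    keep_rows = []
    dropped = []
    new_counts = []
    for i, sample in enumerate(t.sample_ids):
        if totals[i] < depth:
            dropped.append(sample)
            continue
        keep_rows.append(sample)
        new_counts.append(rng.multivariate_hypergeometric(t.counts[i], depth))
    if dropped:
        logger.info(
            "rarefy: dropped %d samples below depth %d: %s",
            len(dropped), depth, dropped,
        )
    if not keep_rows:
        raise ValueError("no samples survive rarefaction")
    out = OtuTable(
        keep_rows, list(t.otu_ids), np.array(new_counts, dtype=np.int64), dict(t.taxonomy)
    )
    return out.drop_empty_otus()


def relative_abundance(t: OtuTable) -> np.ndarray:
    """Per-sample relative abundances; each row sums to 1."""
    totals = t.sample_totals().astype(float)
    if np.any(totals <= 0):
        bad = [s for s, tot in zip(t.sample_ids, totals) if tot <= 0]
        raise ValueError(f"zero-sum samples: {bad}")
    return t.counts / totals[:, None]


def taxonomy_tokens(label: str) -> list[str]:
    return [tok for tok in _TAXON_SPLIT.split(label) if tok]


def subset_by_taxon(t: OtuTable, group_label: str) -> OtuTable | None:
    """Retain OTUs whose taxonomy contains ``group_label`` as an exact token.

    Returns None (the not-found marker) when no OTU matches; downstream
    consumers report such cells as NF. Samples with zero remaining reads are
    retained.
    """
    keep = [o for o in t.otu_ids if group_label in taxonomy_tokens(t.taxonomy[o])]
    if not keep:
        return None
    return t.select_otus(keep)


def bray_curtis(t: OtuTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples on counts.

    d(x, y) = sum_i |x_i - y_i| / sum_i (x_i + y_i), in [0, 1].
    """
    if t.n_samples < 2:
        raise ValueError("need >= 2 samples for Bray-Curtis")
    zero_rows = [s for s, tot in zip(t.sample_ids, t.sample_totals()) if tot == 0]
    if len(zero_rows) >= 2:
        raise ValueError(
            f"Bray-Curtis undefined between all-zero samples: {zero_rows}"
        )
    x = t.counts.astype(float)
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(list(t.sample_ids), d)


def env_distance(
    md: SampleMetadata,
    variables: Sequence[str] | None = None,
    standardize: bool = True,
) -> DistanceMatrix:
    """Euclidean distance between samples on environmental variables.

    With ``standardize`` (default) each variable is z-scored across the
    included samples first, so variables on incommensurable unit scales
    contribute equally.
    """
    variables = list(variables) if variables is not None else list(md.env_variables)
    x = md.env_matrix(variables)
    if standardize:
        mu = x.mean(axis=0)
        sd = x.std(axis=0)  # population sd (ddof=0)
        zero = [v for v, s in zip(variables, sd) if s == 0.0]
        if zero:
            raise ValueError(f"zero-variance environmental variables: {zero}")
        x = (x - mu) / sd
    d = squareform(pdist(x, metric="euclidean"))
    return DistanceMatrix(md.sample_ids, d)


def spatial_distance(md: SampleMetadata, mode: str = "euclidean-degrees") -> DistanceMatrix:
    """Pairwise spatial distance between samples.

    ``euclidean-degrees`` (default) is plain Euclidean distance on
    (latitude, longitude) in decimal degrees; ``great-circle`` is the
    haversine distance in kilometres.
    """
    coords = md.coordinates()
    if mode == "euclidean-degrees":
        d = squareform(pdist(coords, metric="euclidean"))
    elif mode == "great-circle":
        lat = np.radians(coords[:, 0])[:, None]
        lon = np.radians(coords[:, 1])[:, None]
        dlat = lat - lat.T
        dlon = lon - lon.T
        a = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
        a = np.clip(a, 0.0, 1.0)
        d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
        np.fill_diagonal(d, 0.0)
    else:
        raise ValueError(f"unknown spatial mode {mode!r}")
    return DistanceMatrix(md.sample_ids, d)


def occupancy(t: OtuTable) -> np.ndarray:
    """Per-OTU fraction of samples with a nonzero count, in [0, 1]."""
    if t.n_samples < 1:
        raise FormatError("need >= 1 sample")
    return (t.counts > 0).mean(axis=0)
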