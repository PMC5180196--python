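"""Levins' niche breadth, generalist/specialist binning, per-bin
environmental/spatial explained variance, and the breadth-vs-variance
regression.

Levins' B for OTU j is 1 / sum_i p_ij^2 where p_ij is the proportion of
OTU j's reads found in sample i; B ranges from 1 (all reads in one sample)
to N (perfectly even across all N samples). High B marks habitat
generalists, low B habitat specialists.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .community import bray_curtis, env_distance, spatial_distance, subset_by_taxon
from .association import mantel
from .io_formats import OtuTable, SampleMetadata

__all__ = [
    "NicheBreadthProfile",
    "NicheConfig",
    "RegressionResult",
    "DEFAULT_BIN_EDGES",
    "BIN_LABELS",
    "levins_b",
    "assign_bin",
    "bin_by_breadth",
    "bin_summary",
    "breadth_partition_analysis",
    "breadth_regression",
]

logger = logging.getLogger(__name__)

# Breadth classes: [1, 3), [3, 6), [6, 10], (10, inf)
DEFAULT_BIN_EDGES = (3.0, 6.0, 10.0)
BIN_LABELS = ("<3", "3–6", "6–10", ">10")  # en-dash labels


@dataclasses.dataclass
class NicheBreadthProfile:
    """Per-OTU Levins' breadth and distribution summaries."""

    otu_id: str
    b: float
    proportions: np.ndarray  # p_ij over the N samples; sums to 1
    n_samples: int
    total_reads: int
    occupancy_pct: float
    mean_rel_abund_pct: float
    bin: str | None = None


def levins_b(t: OtuTable) -> list[NicheBreadthProfile]:
    """Levins' niche breadth B = 1 / sum_i p_ij^2 for every OTU.

    ``p_ij`` normalizes OTU j's counts across samples. Every OTU must have
    a positive total (prune empty OTUs upstream, e.g. after rarefaction).
    """
    totals = t.otu_totals().astype(float)
    if np.any(totals <= 0):
        bad = [o for o, tot in zip(t.otu_ids, totals) if tot <= 0]
        raise ValueError(f"zero-total OTUs (prune before computing B): {bad}")
    p = t.counts / totals[None, :]
    b = 1.0 / np.sum(p * p, axis=0)
    occ = 100.0 * (t.counts > 0).mean(axis=0)
    sample_totals = t.sample_totals().astype(float)
    has_reads = sample_totals > 0
    rel = np.zeros_like(p)
    np.divide(
        t.counts, sample_totals[:, None], out=rel, where=has_reads[:, None]
    )
    # average over samples with reads (all of them after rarefaction)
    mean_rel = 100.0 * rel[has_reads].mean(axis=0)
    return [
        NicheBreadthProfile(
            otu_id=o,
            b=float(b[j]),
            proportions=p[:, j].copy(),
            n_samples=t.n_samples,
            total_reads=int(totals[j]),
            occupancy_pct=float(occ[j]),
            mean_rel_abund_pct=float(mean_rel[j]),
        )
        for j, o in enumerate(t.otu_ids)
    ]


def assign_bin(b: float, edges: Sequence[float] = DEFAULT_BIN_EDGES) -> str:
    """Breadth class of a B value: [1,e1) -> "<3", [e1,e2) -> "3-6",
    [e2,e3] -> "6-10", (e3,inf) -> ">10" (default edges 3, 6, 10)."""
    e1, e2, e3 = edges
    if b < e1:
        return BIN_LABELS[0]
    if b < e2:
        return BIN_LABELS[1]
    if b <= e3:
        return BIN_LABELS[2]
    return BIN_LABELS[3]


def bin_by_breadth(
    profiles: Sequence[NicheBreadthProfile],
    edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> list[NicheBreadthProfile]:
    """Assign each profile to exactly one breadth class (in place; returns
    the same list for convenience)."""
    for prof in profiles:
        prof.bin = assign_bin(prof.b, edges)
    return list(profiles)


def bin_summary(profiles: Sequence[NicheBreadthProfile]) -> pd.DataFrame:
    """Per-bin OTU counts, mean +/- sd of B and occupancy, and percent of
    total sequences (widest breadth class first)."""
    if any(p.bin is None for p in profiles):
        raise ValueError("profiles must be binned first (bin_by_breadth)")
    grand_total = sum(p.total_reads for p in profiles)
    rows = []
    for label in reversed(BIN_LABELS):
        grp = [p for p in profiles if p.bin == label]
        if not grp:
            rows.append({"bin": label, "n_otus": 0, "mean_b": np.nan, "sd_b": np.nan,
                         "mean_occupancy_pct": np.nan, "sd_occupancy_pct": np.nan,
                         "pct_total_sequences": 0.0})
            continue
        bs = np.array([p.b for p in grp])
        occ = np.array([p.occupancy_pct for p in grp])
        reads = sum(p.total_reads for p in grp)
        rows.append({
            "bin": label,
            "n_otus": len(grp),
            "mean_b": float(bs.mean()),
            "sd_b": float(bs.std(ddof=1)) if len(bs) > 1 else 0.0,
            "mean_occupancy_pct": float(occ.mean()),
            "sd_occupancy_pct": float(occ.std(ddof=1)) if len(occ) > 1 else 0.0,
            "pct_total_sequences": 100.0 * reads / grand_total if grand_total else 0.0,
        })
    return pd.DataFrame(rows)


@dataclasses.dataclass
class NicheConfig:
    env_variables: tuple[str, ...] | None = None
    standardize_env: bool = True
    spatial_mode: str = "euclidean-degrees"
    n_perm: int = 999
    seed: int = 0
    alpha: float = 0.05
    min_samples: int = 4


def breadth_partition_analysis(
    t: OtuTable,
    md: SampleMetadata,
    profiles: Sequence[NicheBreadthProfile],
    cfg: NicheConfig | None = None,
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Environmental and spatial explained variance per breadth bin.

    For each bin (and optionally each bin x taxonomic group) the OTU table
    is restricted to the bin's OTUs, Bray-Curtis distances are computed over
    samples with nonzero bin reads, and simple Mantel tests against the
    environmental and spatial distances are run. Explained variance is
    reported as 100*r^2. Bins failing the preconditions are emitted with
    status NF.
    """
    cfg = cfg or NicheConfig()
    if any(p.bin is None for p in profiles):
        raise ValueError("profiles must be binned first (bin_by_breadth)")
    group_scopes: list[str | None] = [None] if groups is None else [None, *groups]
    rows = []
    seed = cfg.seed
    for label in reversed(BIN_LABELS):
        bin_otus = [p.otu_id for p in profiles if p.bin == label]
        for group in group_scopes:
            row = {
                "bin": label,
                "group": group or "All",
                "n_otus": 0, "n_samples": 0,
                "r_env": np.nan, "p_env": np.nan, "var_env_pct": np.nan,
                "r_spatial": np.nan, "p_spatial": np.nan, "var_spatial_pct": np.nan,
                "status": "NF", "reason": "",
            }
            seed += 10
            if not bin_otus:
                row["reason"] = "no OTUs in bin"
                rows.append(row)
                continue
            sub = t.select_otus(bin_otus)
            if group is not None:
                sub = subset_by_taxon(sub, group)
                if sub is None:
                    row["reason"] = f"taxon {group!r} not found in bin"
                    rows.append(row)
                    continue
            sub = sub.drop_empty_samples()
            row["n_otus"] = sub.n_otus
            row["n_samples"] = sub.n_samples
            if sub.n_samples < cfg.min_samples:
                row["reason"] = f"fewer than {cfg.min_samples} usable samples"
                rows.append(row)
                continue
            md_sub = md.subset(sub.sample_ids)
            try:
                d_comm = bray_curtis(sub)
                d_env = env_distance(md_sub, cfg.env_variables, cfg.standardize_env)
                d_spa = spatial_distance(md_sub, mode=cfg.spatial_mode)
                m_env = mantel(d_comm, d_env, n_perm=cfg.n_perm, seed=seed)
                m_spa = mantel(d_comm, d_spa, n_perm=cfg.n_perm, seed=seed + 1)
            except ValueError as exc:
                row["reason"] = str(exc)
                rows.append(row)
                continue
            row.update({
                "r_env": m_env.r, "p_env": m_env.p,
                "var_env_pct": 100.0 * m_env.r**2,
                "r_spatial": m_spa.r, "p_spatial": m_spa.p,
                "var_spatial_pct": 100.0 * m_spa.r**2,
                "status": "ok",
            })
            rows.append(row)
    return pd.DataFrame(rows)


@dataclasses.dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int


def breadth_regression(
    explained_variance: Sequence[float],
    mean_b: Sequence[float],
) -> RegressionResult:
    """Ordinary least squares of per-bin explained variance (%) on per-bin
    mean Levins' B, with a two-sided p-value for the slope."""
    x = np.asarray(mean_b, dtype=float)
    y = np.asarray(explained_variance, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("insufficient bins for regression (need >= 3)")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        p=float(fit.pvalue),
        n=len(x),
    )
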