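"""Patristic distances, mean pairwise distance (MPD), and the net
relatedness index (NRI) with a randomization null.

NRI is the negated standardized effect size of MPD against a null built
from richness-preserving random draws from a taxon pool: positive values
mean the community is phylogenetically clustered (habitat filtering),
negative values mean it is overdispersed (competitive exclusion).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import AlignmentError, DistanceMatrix, PhyloTree, SampleMetadata

__all__ = [
    "NriResult",
    "patristic_matrix",
    "mpd",
    "nri",
    "nri_month_summary",
    "MONTH_SUMMARY_COLUMNS",
]

logger = logging.getLogger(__name__)

DEFAULT_N_NULL = 999
EXHAUSTIVE_CAP = 10_000
TAIL_ALPHA = 0.025  # each of the two one-sided ranks; 5% two-tailed


@dataclasses.dataclass
class NriResult:
    """NRI of one community against its randomization null.

    ``nri = -(mpd_obs - null_mean) / null_sd``; when the null is constant
    (``null_sd == 0``) the result is flagged degenerate and ``nri`` is NaN.
    ``p_low`` / ``p_high`` are rank-based one-sided tail probabilities with
    the (rank+1)/(n+1) correction.
    """

    sample_id: str
    mpd_obs: float
    null_mean: float
    null_sd: float
    nri: float
    n_null: int
    p_low: float
    p_high: float
    significant: bool
    direction: str  # "positive" | "negative"
    degenerate: bool = False


def patristic_matrix(tree: PhyloTree, tips: Sequence[str] | None = None) -> DistanceMatrix:
    """Tip-to-tip path-length (patristic) distances.

    Entry (a, b) is the sum of branch lengths on the path between tips a
    and b. ``tips`` restricts and orders the output; default is all tips.
    """
    if tips is None:
        tips = list(tree.tip_labels)
    missing = sorted(set(tips) - set(tree.tip_labels))
    if missing:
        raise AlignmentError(f"tips absent from tree: {missing}")
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.tree.taxon_namespace if t.label in set(tips)}
    n = len(tips)
    values = np.zeros((n, n), dtype=float)
    for i, a in enumerate(tips):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[a], taxa[tips[j]])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(list(tips), values)


def mpd(members: Iterable[str], d: DistanceMatrix) -> float:
    """Unweighted mean pairwise distance over all unordered distinct pairs."""
    members = list(members)
    if len(members) < 2:
        raise ValueError("MPD undefined for fewer than 2 members")
    idx = d.index()
    missing = [m for m in members if m not in idx]
    if missing:
        raise AlignmentError(f"members absent from distance matrix: {missing}")
    rows = np.array([idx[m] for m in members])
    sub = d.values[np.ix_(rows, rows)]
    k = len(rows)
    return float(sub.sum() / (k * (k - 1)))


def _mpd_rows(values: np.ndarray, rows: np.ndarray) -> float:
    sub = values[np.ix_(rows, rows)]
    k = len(rows)
    return float(sub.sum() / (k * (k - 1)))


def nri(
    members: Iterable[str],
    pool: Iterable[str],
    d: DistanceMatrix,
    n_null: int = DEFAULT_N_NULL,
    seed: int | None = None,
    exhaustive: bool = False,
    exhaustive_cap: int = EXHAUSTIVE_CAP,
    sample_id: str = "",
    tail_alpha: float = TAIL_ALPHA,
) -> NriResult:
    """NRI of ``members`` against random equal-richness draws from ``pool``.

    The null distribution is the MPD of ``n_null`` uniformly random
    size-``|members|`` subsets of the pool (seeded). With ``exhaustive`` and
    C(|pool|, |members|) <= ``exhaustive_cap``, all subsets are enumerated
    instead. Significance is a two-tailed rank test: the observed MPD lies
    outside the central ``1 - 2*tail_alpha`` of the null.
    """
    members = list(dict.fromkeys(members))
    pool = list(dict.fromkeys(pool))
    member_set = set(members)
    pool_set = set(pool)
    if not member_set <= pool_set:
        raise ValueError("members must be a subset of the pool")
    if not pool_set <= set(d.ids):
        missing = sorted(pool_set - set(d.ids))
        raise AlignmentError(f"pool taxa absent from distance matrix: {missing}")
    k = len(members)
    if k < 2:
        raise ValueError("NRI needs >= 2 members")
    idx = d.index()
    member_rows = np.array([idx[m] for m in members])
    pool_rows = np.array([idx[p] for p in pool])
    obs = _mpd_rows(d.values, member_rows)

    n_pool = len(pool)
    n_combos = math.comb(n_pool, k)
    used_exhaustive = exhaustive and n_combos <= exhaustive_cap
    if used_exhaustive:
        null = np.array(
            [_mpd_rows(d.values, np.array(c)) for c in combinations(pool_rows, k)]
        )
    else:
        rng = np.random.default_rng(seed)
        null = np.empty(n_null, dtype=float)
        for b in range(n_null):
            rows = rng.choice(pool_rows, size=k, replace=False)
            null[b] = _mpd_rows(d.values, rows)
    n_used = len(null)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_used > 1 else 0.0

    eps = 1e-10 * max(abs(obs), 1.0)  # tie tolerance for float round-off
    if used_exhaustive:
        # the observed subset is one of the enumerated subsets, so the
        # ranks already include it: exact p = rank / N
        p_low = int(np.sum(null <= obs + eps)) / n_used
        p_high = int(np.sum(null >= obs - eps)) / n_used
    else:
        p_low = (int(np.sum(null <= obs + eps)) + 1) / (n_used + 1)
        p_high = (int(np.sum(null >= obs - eps)) + 1) / (n_used + 1)
    direction = "positive" if obs < null_mean else "negative"
    if null_sd <= 1e-10 * max(abs(null_mean), 1e-30):
        return NriResult(
            sample_id=sample_id, mpd_obs=obs, null_mean=null_mean, null_sd=0.0,
            nri=float("nan"), n_null=n_used, p_low=p_low, p_high=p_high,
            significant=False, direction=direction, degenerate=True,
        )
    z = -(obs - null_mean) / null_sd
    significant = (p_low <= tail_alpha) or (p_high <= tail_alpha)
    return NriResult(
        sample_id=sample_id, mpd_obs=obs, null_mean=null_mean, null_sd=null_sd,
        nri=float(z), n_null=n_used, p_low=p_low, p_high=p_high,
        significant=significant, direction=direction, degenerate=False,
    )


MONTH_SUMMARY_COLUMNS = [
    "month",
    "+ (n)",
    "- (n)",
    "+ (%)",
    "- (%)",
    "Sig + (n)",
    "Sig - (n)",
    "Sig + (%)",
    "Sig - (%)",
]


def nri_month_summary(results: Sequence[NriResult], metadata: SampleMetadata) -> pd.DataFrame:
    """Per-month counts and percentages of (significantly) positive and
    negative NRI values. Months with no usable samples are omitted with a
    logged warning. Degenerate results are excluded from the tallies."""
    month_of = metadata.month_of()
    rows = []
    for month in metadata.months:
        month_results = [
            r for r in results
            if month_of.get(r.sample_id) == month and not r.degenerate
        ]
        if not month_results:
            logger.warning("nri_month_summary: no samples for month %s", month)
            continue
        n = len(month_results)
        n_pos = sum(1 for r in month_results if r.nri >= 0)
        n_neg = n - n_pos
        sig_pos = sum(1 for r in month_results if r.nri >= 0 and r.significant)
        sig_neg = sum(1 for r in month_results if r.nri < 0 and r.significant)
        rows.append({
            "month": month,
            "+ (n)": n_pos,
            "- (n)": n_neg,
            "+ (%)": round(100.0 * n_pos / n, 1),
            "- (%)": round(100.0 * n_neg / n, 1),
            "Sig + (n)": sig_pos,
            "Sig - (n)": sig_neg,
            "Sig + (%)": round(100.0 * sig_pos / n, 1),
            "Sig - (%)": round(100.0 * sig_neg / n, 1),
        })
    return pd.DataFrame(rows, columns=MONTH_SUMMARY_COLUMNS)
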