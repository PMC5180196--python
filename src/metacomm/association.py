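"""Mantel and partial Mantel permutation tests, the months x taxonomic-groups
test battery, and metacommunity-paradigm classification.

The four statistics per community subset are
  [E]   simple Mantel r between community and environmental distances,
  [S]   simple Mantel r between community and spatial distances,
  [E|S] partial Mantel r of community vs environment controlling space,
  [S|E] partial Mantel r of community vs space controlling environment,
and the significance pattern of the two partials maps onto the
metacommunity paradigms (species sorting, mass effect, neutral/patch
dynamics) via a fixed decision table.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np

from .community import bray_curtis, env_distance, spatial_distance, subset_by_taxon
from .io_formats import (
    AlignmentError,
    DistanceMatrix,
    OtuTable,
    SampleMetadata,
)

__all__ = [
    "MantelResult",
    "MetacommunityClass",
    "BatteryConfig",
    "CellResult",
    "mantel",
    "partial_mantel",
    "mantel_battery",
    "classify_metacommunity",
    "classify_dataset",
    "LABELS",
]

logger = logging.getLogger(__name__)

LABELS = ("SS", "SS+ME", "NM/PD", "UD", "NF")

_TIE_TOL = 1e-12


@dataclasses.dataclass
class MantelResult:
    """Outcome of a (partial) Mantel permutation test.

    ``r`` is Pearson's correlation over the strict lower triangles;
    ``partial_r`` carries the first-order partial correlation when
    ``kind == "partial"``. ``p`` is one-sided (greater) with the
    (count+1)/(n_perm+1) correction.
    """

    r: float
    p: float
    n_perm: int
    kind: str  # "simple" | "partial"
    n_samples: int
    partial_r: float | None = None

    @property
    def statistic(self) -> float:
        return self.partial_r if self.kind == "partial" else self.r


@dataclasses.dataclass
class MetacommunityClass:
    label: str  # one of LABELS
    alpha: float
    inputs: dict | None = None


def _align(dx: DistanceMatrix, *others: DistanceMatrix) -> list[DistanceMatrix]:
    out = [dx]
    for o in others:
        if set(o.ids) != set(dx.ids):
            raise AlignmentError("distance matrices cover different id sets")
        out.append(o.subset(dx.ids))
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na = np.sqrt(a @ a)
    nb = np.sqrt(b @ b)
    return float((a @ b) / (na * nb))


def _check_variance(v: np.ndarray, name: str) -> None:
    if np.ptp(v) == 0.0:
        raise ValueError(f"constant distances in {name} matrix")


def mantel(
    dx: DistanceMatrix,
    dy: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """Simple Mantel test: Pearson r over lower triangles, one-sided
    (greater) permutation p from simultaneous row/column permutations of
    ``dx``."""
    dx, dy = _align(dx, dy)
    n = dx.n
    if n < 4:
        raise ValueError("Mantel test needs >= 4 samples")
    ti, tj = np.tril_indices(n, k=-1)
    vx = dx.values[ti, tj]
    vy = dy.values[ti, tj]
    _check_variance(vx, "first")
    _check_variance(vy, "second")
    r_obs = _pearson(vx, vy)
    rng = np.random.default_rng(seed)
    count = 0
    vals = dx.values
    for _ in range(n_perm):
        p = rng.permutation(n)
        vxp = vals[p[ti], p[tj]]
        if _pearson(vxp, vy) >= r_obs - _TIE_TOL:
            count += 1
    pval = (count + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, p=pval, n_perm=n_perm, kind="simple", n_samples=n)


def _partial_r(rxy: float, rxz: float, ryz: float) -> float:
    denom = math.sqrt((1.0 - rxz**2) * (1.0 - ryz**2))
    return (rxy - rxz * ryz) / denom


def partial_mantel(
    dx: DistanceMatrix,
    dy: DistanceMatrix,
    dz: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """Partial Mantel test of dx ~ dy controlling dz.

    The statistic is the first-order partial Pearson correlation
    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2)) over lower
    triangles; permutations rearrange ``dx`` rows/columns and recompute it
    (Legendre-style raw-matrix permutation)."""
    dx, dy, dz = _align(dx, dy, dz)
    n = dx.n
    if n < 4:
        raise ValueError("partial Mantel test needs >= 4 samples")
    ti, tj = np.tril_indices(n, k=-1)
    vx = dx.values[ti, tj]
    vy = dy.values[ti, tj]
    vz = dz.values[ti, tj]
    _check_variance(vx, "first")
    _check_variance(vy, "second")
    _check_variance(vz, "covariate")
    rxy = _pearson(vx, vy)
    rxz = _pearson(vx, vz)
    ryz = _pearson(vy, vz)
    if abs(rxz) >= 1.0 - 1e-12 or abs(ryz) >= 1.0 - 1e-12:
        raise ValueError("covariate collinear with a primary matrix")
    obs = _partial_r(rxy, rxz, ryz)
    rng = np.random.default_rng(seed)
    count = 0
    vals = dx.values
    for _ in range(n_perm):
        p = rng.permutation(n)
        vxp = vals[p[ti], p[tj]]
        stat = _partial_r(_pearson(vxp, vy), _pearson(vxp, vz), ryz)
        if stat >= obs - _TIE_TOL:
            count += 1
    pval = (count + 1) / (n_perm + 1)
    return MantelResult(
        r=rxy, p=pval, n_perm=n_perm, kind="partial", n_samples=n, partial_r=obs
    )


def classify_metacommunity(
    E: MantelResult | None,
    S: MantelResult | None,
    E_given_S: MantelResult | None,
    S_given_E: MantelResult | None,
    alpha: float = 0.05,
) -> MetacommunityClass:
    """Map the four Mantel outcomes of one cell onto a paradigm label.

    Decision table on the two partial tests at ``alpha``:
      [E|S] significant, [S|E] not  -> SS      (species sorting)
      [E|S] and [S|E] significant   -> SS+ME   (sorting plus mass effect)
      [S|E] significant, [E|S] not  -> NM/PD   (neutral / patch dynamics;
                                               not separable from these tests)
      neither significant           -> UD      (undetermined)
      any input missing (NF marker) -> NF
    """
    results = {"E": E, "S": S, "E|S": E_given_S, "S|E": S_given_E}
    if any(v is None for v in results.values()):
        return MetacommunityClass(label="NF", alpha=alpha, inputs=None)
    sizes = {v.n_samples for v in results.values()}
    if len(sizes) != 1:
        raise ValueError(f"mismatched sample sets among the four tests: {sizes}")
    e_sig = E_given_S.p <= alpha
    s_sig = S_given_E.p <= alpha
    if e_sig and s_sig:
        label = "SS+ME"
    elif e_sig:
        label = "SS"
    elif s_sig:
        label = "NM/PD"
    else:
        label = "UD"
    return MetacommunityClass(label=label, alpha=alpha, inputs=results)


def classify_dataset(
    t: OtuTable,
    md: SampleMetadata,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    env_variables: Sequence[str] | None = None,
    standardize_env: bool = True,
    spatial_mode: str = "euclidean-degrees",
) -> MetacommunityClass:
    """Run the four tests on the whole dataset (the all-months x all-groups
    cell) and classify it."""
    md = md.subset(t.sample_ids)
    d_comm = bray_curtis(t)
    d_env = env_distance(md, env_variables, standardize=standardize_env)
    d_spa = spatial_distance(md, mode=spatial_mode)
    e = mantel(d_comm, d_env, n_perm=n_perm, seed=seed)
    s = mantel(d_comm, d_spa, n_perm=n_perm, seed=seed + 1)
    e_s = partial_mantel(d_comm, d_env, d_spa, n_perm=n_perm, seed=seed + 2)
    s_e = partial_mantel(d_comm, d_spa, d_env, n_perm=n_perm, seed=seed + 3)
    return classify_metacommunity(e, s, e_s, s_e, alpha=alpha)


@dataclasses.dataclass
class BatteryConfig:
    env_variables: tuple[str, ...] | None = None  # None -> metadata's set
    standardize_env: bool = True
    spatial_mode: str = "euclidean-degrees"
    n_perm: int = 999
    seed: int = 0
    alpha: float = 0.05
    min_samples: int = 4


@dataclasses.dataclass
class CellResult:
    """One cell of the battery: a month scope x taxon scope."""

    month: str  # month label or "All"
    group: str  # group label or "All"
    n_samples: int
    n_otus: int
    tests: dict[str, MantelResult] | None
    label: str
    reason: str = ""


def mantel_battery(
    t: OtuTable,
    md: SampleMetadata,
    months: Sequence[str],
    groups: Sequence[str],
    cfg: BatteryConfig | None = None,
) -> tuple[list[CellResult], list[dict]]:
    """Run the four-test battery for every cell of
    ({All} + months) x ({All} + groups).

    Returns the cell results and a manifest: one record per cell with its
    scope definition, sample count and status. Cells with fewer than
    ``cfg.min_samples`` usable samples, an unmatched taxon, or degenerate
    distances are reported NF with a logged reason.
    """
    cfg = cfg or BatteryConfig()
    month_scopes: list[str | None] = [None, *months]
    group_scopes: list[str | None] = [None, *groups]
    results: list[CellResult] = []
    manifest: list[dict] = []
    cell_idx = 0
    for month in month_scopes:
        if month is None:
            month_samples = list(t.sample_ids)
        else:
            month_samples = [s for s in md.samples_in_month(month) if s in set(t.sample_ids)]
        for group in group_scopes:
            cell_seed = cfg.seed + 1000 * cell_idx
            cell_idx += 1
            cell = _run_cell(t, md, month, group, month_samples, cfg, cell_seed)
            results.append(cell)
            manifest.append({
                "month": cell.month,
                "group": cell.group,
                "scope": _scope_name(month, group),
                "n_samples": cell.n_samples,
                "n_otus": cell.n_otus,
                "tests": ["E", "S", "E|S", "S|E"] if cell.tests else [],
                "status": "NF" if cell.label == "NF" else "ok",
                "reason": cell.reason,
                "seed": cell_seed,
            })
    return results, manifest


def _scope_name(month: str | None, group: str | None) -> str:
    m = "all_months" if month is None else "single_month"
    g = "all_groups" if group is None else "single_group"
    return f"{m}:{g}"


def _nf(month, group, n_samples, n_otus, reason) -> CellResult:
    logger.info(
        "battery cell (%s, %s) -> NF: %s",
        month or "All", group or "All", reason,
    )
    return CellResult(
        month=month or "All", group=group or "All",
        n_samples=n_samples, n_otus=n_otus, tests=None, label="NF", reason=reason,
    )


def _run_cell(
    t: OtuTable,
    md: SampleMetadata,
    month: str | None,
    group: str | None,
    month_samples: list[str],
    cfg: BatteryConfig,
    seed: int,
) -> CellResult:
    sub = t.select_samples(month_samples) if month_samples else None
    if sub is None or sub.n_samples == 0:
        return _nf(month, group, 0, 0, "no samples in scope")
    if group is not None:
        sub = subset_by_taxon(sub, group)
        if sub is None:
            return _nf(month, group, 0, 0, f"taxon {group!r} not found")
    sub = sub.drop_empty_samples()
    if sub.n_samples < cfg.min_samples:
        return _nf(month, group, sub.n_samples, sub.n_otus,
                   f"fewer than {cfg.min_samples} usable samples")
    md_sub = md.subset(sub.sample_ids)
    try:
        d_comm = bray_curtis(sub)
        d_env = env_distance(md_sub, cfg.env_variables, standardize=cfg.standardize_env)
        d_spa = spatial_distance(md_sub, mode=cfg.spatial_mode)
        tests = {
            "E": mantel(d_comm, d_env, n_perm=cfg.n_perm, seed=seed),
            "S": mantel(d_comm, d_spa, n_perm=cfg.n_perm, seed=seed + 1),
            "E|S": partial_mantel(d_comm, d_env, d_spa, n_perm=cfg.n_perm, seed=seed + 2),
            "S|E": partial_mantel(d_comm, d_spa, d_env, n_perm=cfg.n_perm, seed=seed + 3),
        }
    except ValueError as exc:
        return _nf(month, group, sub.n_samples, sub.n_otus, str(exc))
    cls = classify_metacommunity(
        tests["E"], tests["S"], tests["E|S"], tests["S|E"], alpha=cfg.alpha
    )
    return CellResult(
        month=month or "All", group=group or "All",
        n_samples=sub.n_samples, n_otus=sub.n_otus,
        tests=tests, label=cls.label,
    )
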