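"""Aging-score construction and spatial hotspot analysis.

This module implements the core procedure of the pipeline:

1. Intersect per-type aging DEGs with a curated aging gene list to obtain
   the ovary-specific aging genes (OSAG), split by direction.
2. Per-spot aging score = OSAG-up module score minus OSAG-down score.
3. Screen candidate pathway scores for primary contributors to ovarian
   aging (PCOA): Pearson r > 0.5 with the OSAG-up score at p < 0.05.
4. Call aging hotspots as the intersection of the top-5% spot sets of the
   aging score and every PCOA score.
5. Characterize hotspots by spot-type composition and by the decay of
   scores with distance from the hotspot set (ring binning + Pearson r).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)


@dataclass
class OSAG:
    """Ovary-specific aging genes: aging DEGs found in the curated list."""

    up: list[str]
    down: list[str]
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValueError("OSAG up and down lists must be disjoint")


@dataclass
class DecayResult:
    """Ring-binned distance-decay table with its Pearson statistics."""

    table: pd.DataFrame  # ring_lo_um, ring_hi_um, distance_um, n_spots, mean_score
    r: float
    p: float


@dataclass
class HotspotResult:
    hotspot_spot_ids: list[str]
    top_sets: dict[str, list[str]]
    composition: pd.Series | None = None
    decay: dict[str, DecayResult] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# OSAG and aging score
# ---------------------------------------------------------------------------

def build_osag(aging_deg_table: pd.DataFrame, aging_gene_list) -> OSAG:
    """Intersect per-type aging DEGs with the curated aging gene list.

    up = (union of up-DEGs over spot types) intersect the list; analogously
    for down. A gene appearing in both unions is assigned to the direction
    supported by more spot types and dropped (logged) on a tie.
    """
    aging_set = set(map(str, aging_gene_list))
    if not aging_set:
        raise ValueError("aging gene list is empty")
    if aging_deg_table.empty:
        logger.warning("build_osag: empty DEG table, OSAG is empty")
        return OSAG([], [])

    support: dict[str, dict[str, set]] = {}
    for _, row in aging_deg_table.iterrows():
        g = str(row["gene"])
        if g not in aging_set:
            continue
        support.setdefault(g, {"up": set(), "down": set()})[row["direction"]].add(row["spot_type"])

    up, down, provenance = [], [], {}
    for g, sides in sorted(support.items()):
        n_up, n_down = len(sides["up"]), len(sides["down"])
        if n_up > n_down:
            up.append(g)
            provenance[g] = sorted(sides["up"])
        elif n_down > n_up:
            down.append(g)
            provenance[g] = sorted(sides["down"])
        else:
            logger.info("build_osag: dropping %s (up in %d and down in %d types)", g, n_up, n_down)
    return OSAG(up, down, provenance)


def aging_score(
    scores,
    up_col: str = "OSAG_up",
    down_col: str = "OSAG_down",
) -> pd.Series:
    """Per-spot aging score: OSAG-up score minus OSAG-down score."""
    frame = scores.scores if hasattr(scores, "scores") else scores
    for col in (up_col, down_col):
        if col not in frame.columns:
            raise KeyError(f"score column {col!r} missing")
    out = frame[up_col] - frame[down_col]
    out.name = "aging_score"
    return out


# ---------------------------------------------------------------------------
# correlation screening
# ---------------------------------------------------------------------------

def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson_r needs two equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson_r undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def select_pcoa(
    scores,
    osag_up_score: pd.Series,
    candidate_sets,
    r_thresh: float = 0.5,
    p_thresh: float = 0.05,
) -> pd.DataFrame:
    """Correlate candidate pathway scores with the OSAG-up score.

    A candidate is selected — a primary contributor to ovarian aging —
    when r > r_thresh and p < p_thresh. Degenerate candidates (constant
    scores) are recorded with NaN and never selected.
    """
    frame = scores.scores if hasattr(scores, "scores") else scores
    ref = osag_up_score.loc[frame.index].to_numpy()
    rows = []
    for name in candidate_sets:
        try:
            r, p = pearson_r(frame[name].to_numpy(), ref)
        except ValueError as exc:
            logger.warning("select_pcoa: %s undefined (%s)", name, exc)
            r, p = np.nan, np.nan
        rows.append(
            {
                "set": name,
                "r": r,
                "p": p,
                "selected": bool(not np.isnan(r) and r > r_thresh and p < p_thresh),
            }
        )
    return pd.DataFrame(rows).set_index("set")


# ---------------------------------------------------------------------------
# hotspot calling
# ---------------------------------------------------------------------------

def top_quantile_spots(score: pd.Series, q: float) -> list[str]:
    """The ceil(q*N) highest-scoring spot ids; ties broken by descending
    score then lexicographic barcode."""
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    n_top = math.ceil(q * len(score))
    order = np.lexsort((score.index.astype(str), -score.to_numpy()))
    return [str(s) for s in score.index[order[:n_top]]]


def call_hotspots(
    score_frame: pd.DataFrame,
    q: float = 0.05,
    mode: str = "intersect_all",
    aging_col: str = "aging_score",
) -> HotspotResult:
    """Intersect the top-q spot sets of the aging and PCOA scores.

    ``intersect_all`` (default) takes the strict intersection across every
    column; ``aging_and_any`` intersects the aging top set with the union of
    the pathway top sets.
    """
    if mode not in ("intersect_all", "aging_and_any"):
        raise ValueError(f"unknown mode {mode!r}")
    top_sets = {col: top_quantile_spots(score_frame[col], q) for col in score_frame.columns}
    if mode == "intersect_all":
        spots = set(score_frame.index.astype(str))
        for ids in top_sets.values():
            spots &= set(ids)
    else:
        if aging_col not in top_sets:
            raise KeyError(f"aging column {aging_col!r} not in score frame")
        pathway_union: set[str] = set()
        for col, ids in top_sets.items():
            if col != aging_col:
                pathway_union |= set(ids)
        spots = set(top_sets[aging_col]) & pathway_union
    return HotspotResult(hotspot_spot_ids=sorted(spots), top_sets=top_sets)


def hotspot_composition(hotspot_ids, annotation: pd.DataFrame) -> pd.Series:
    """Spot-type proportions over the called hotspot spots (sums to 1)."""
    ids = list(hotspot_ids)
    if not ids:
        raise ValueError("no hotspot spots to characterize")
    types = annotation.loc[ids, "spot_type"]
    return types.value_counts(normalize=True)


def distance_decay(
    hotspot_ids,
    spot_ids,
    coords: np.ndarray,
    score: pd.Series,
    ring_width_um: float = 100.0,
    min_spots_per_ring: int = 5,
    max_distance_um: float | None = None,
) -> DecayResult:
    """Mean score in concentric distance rings around the hotspot set.

    For every non-hotspot spot, d is the minimum Euclidean distance to any
    hotspot spot; spots fall into rings [k*w, (k+1)*w); rings with fewer
    than ``min_spots_per_ring`` spots are dropped, as are rings beyond
    ``max_distance_um`` when given. Pearson r relates ring midpoints to
    ring mean scores; r is NaN when the ring means are constant.
    """
    spot_ids = np.asarray(spot_ids, dtype=object)
    hot = set(map(str, hotspot_ids))
    mask_out = np.array([str(s) not in hot for s in spot_ids])
    if not mask_out.any():
        raise ValueError("no non-hotspot spots")
    mask_hot = ~mask_out
    if not mask_hot.any():
        raise ValueError("hotspot set is empty")
    tree = cKDTree(coords[mask_hot])
    d, _ = tree.query(coords[mask_out])
    vals = score.loc[spot_ids[mask_out]].to_numpy()

    ring = np.floor(d / ring_width_um).astype(int)
    rows = []
    for k in sorted(set(ring)):
        sel = ring == k
        lo, hi = k * ring_width_um, (k + 1) * ring_width_um
        if sel.sum() < min_spots_per_ring:
            continue
        if max_distance_um is not None and hi > max_distance_um:
            continue
        rows.append(
            {
                "ring_lo_um": lo,
                "ring_hi_um": hi,
                "distance_um": lo + ring_width_um / 2.0,
                "n_spots": int(sel.sum()),
                "mean_score": float(vals[sel].mean()),
            }
        )
    table = pd.DataFrame(rows)
    if len(table) < 3 or table["mean_score"].std() == 0:
        logger.warning("distance_decay: correlation undefined (constant or too few rings)")
        return DecayResult(table, float("nan"), float("nan"))
    r, p = pearson_r(table["distance_um"], table["mean_score"])
    return DecayResult(table, r, p)
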