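"""Rank-sum differential expression, shared-DEG analysis and ORA.

Aging differential expression compares old against young spots within each
spot type using the Wilcoxon rank-sum test with Benjamini-Hochberg FDR
control applied per spot type, the fold change being computed on de-logged
normalized means with a pseudocount. Marker detection reuses the same
machinery one type against the rest.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)

DEG_COLUMNS = ("spot_type", "gene", "log2fc", "pvalue", "fdr", "direction")


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

def _exact_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided permutation p by full enumeration of group assignments.

    p is the fraction of assignments whose U statistic is at least as far
    from its null mean as the observed one.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    mu = n1 * n2 / 2.0
    r1 = ranks[:n1].sum()
    u_obs = r1 - n1 * (n1 + 1) / 2.0
    dev_obs = abs(u_obs - mu)
    hits = total = 0
    base = n1 * (n1 + 1) / 2.0
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - base
        total += 1
        if abs(u - mu) >= dev_obs - 1e-9:
            hits += 1
    return u_obs, hits / total


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U of ``x`` versus ``y`` with a two-sided p-value.

    Exact enumeration over all group assignments when the pooled size is at
    most 12 (handles ties correctly); otherwise the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if len(x) + len(y) <= 12:
        return _exact_rank_sum(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _rank_sum_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized asymptotic rank-sum test applied row-wise (genes)."""
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", use_continuity=True, axis=1)
    return np.asarray(res.statistic, dtype=float), np.asarray(res.pvalue, dtype=float)


# ---------------------------------------------------------------------------
# effect size, multiple testing
# ---------------------------------------------------------------------------

def log_fold_change(
    norm: NormalizedMatrix,
    genes: Sequence[str],
    group_a_spots: np.ndarray,
    group_b_spots: np.ndarray,
    pseudocount: float = 1.0,
) -> pd.Series:
    """log2((mean_a + pc) / (mean_b + pc)) on de-logged normalized values."""
    if np.sum(group_a_spots) == 0 or np.sum(group_b_spots) == 0:
        raise ValueError("both spot groups must be non-empty")
    idx = norm.gene_index(genes)
    y = norm.delogged()[idx]
    ma = y[:, group_a_spots].mean(axis=1)
    mb = y[:, group_b_spots].mean(axis=1)
    return pd.Series(np.log2((ma + pseudocount) / (mb + pseudocount)), index=list(genes))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values), clipped to 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# DEG tables
# ---------------------------------------------------------------------------

def _spot_masks(annotation: pd.DataFrame, spot_ids: np.ndarray) -> pd.DataFrame:
    ann = annotation.loc[list(spot_ids)]
    return ann


def _deg_for_groups(
    norm: NormalizedMatrix,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    spot_type: str,
    lfc_cut: float,
    fdr_cut: float,
    pseudocount: float,
    return_full: bool,
) -> pd.DataFrame:
    a = norm.values[:, mask_a]
    b = norm.values[:, mask_b]
    if a.shape[1] + b.shape[1] > 12:
        _, p = _rank_sum_rows(a, b)
    else:
        p = np.array([wilcoxon_rank_sum(a[i], b[i])[1] for i in range(a.shape[0])])
    lfc = log_fold_change(norm, norm.gene_ids, mask_a, mask_b, pseudocount).to_numpy()
    fdr = bh_adjust(p)
    table = pd.DataFrame(
        {
            "spot_type": spot_type,
            "gene": norm.gene_ids,
            "log2fc": lfc,
            "pvalue": p,
            "fdr": fdr,
            "direction": np.where(lfc > 0, "up", "down"),
        }
    )
    if return_full:
        return table
    keep = (np.abs(table["log2fc"]) > lfc_cut) & (table["fdr"] < fdr_cut)
    return table[keep].reset_index(drop=True)


def aging_degs(
    norm: NormalizedMatrix,
    annotation: pd.DataFrame,
    meta: pd.DataFrame,
    lfc_cut: float = 0.5,
    fdr_cut: float = 0.05,
    pseudocount: float = 1.0,
    min_spots: int = 3,
    return_full: bool = False,
) -> pd.DataFrame:
    """Old-versus-young DEGs within each spot type.

    Per type, every gene is tested old vs young, BH correction runs across
    genes within the type, and records with ``|log2fc| > lfc_cut`` (strict)
    and ``fdr < fdr_cut`` are retained. Types with fewer than ``min_spots``
    spots in either group are skipped with a warning.
    """
    ann = _spot_masks(annotation, norm.spot_ids)
    ages = meta.loc[list(norm.spot_ids), "age_group"].to_numpy()
    tables = []
    for t in sorted(set(ann["spot_type"]) - {"ambiguous"}):
        of_type = (ann["spot_type"] == t).to_numpy()
        old = of_type & (ages == "old")
        young = of_type & (ages == "young")
        if old.sum() < min_spots or young.sum() < min_spots:
            logger.warning("aging_degs: skipping %s (old=%d, young=%d spots)", t, old.sum(), young.sum())
            continue
        tables.append(
            _deg_for_groups(norm, old, young, t, lfc_cut, fdr_cut, pseudocount, return_full)
        )
    if not tables:
        return pd.DataFrame(columns=DEG_COLUMNS)
    return pd.concat(tables, ignore_index=True)


def find_markers_one_vs_all(
    norm: NormalizedMatrix,
    annotation: pd.DataFrame,
    lfc_cut: float = 0.5,
    fdr_cut: float = 0.05,
    pseudocount: float = 1.0,
    min_spots: int = 3,
) -> pd.DataFrame:
    """Marker genes per spot type: each type against all other annotated
    spots, keeping upregulated records only. Ambiguous spots are excluded
    from both sides of every contrast."""
    ann = _spot_masks(annotation, norm.spot_ids)
    labelled = (ann["spot_type"] != "ambiguous").to_numpy()
    tables = []
    for t in sorted(set(ann["spot_type"]) - {"ambiguous"}):
        of_type = (ann["spot_type"] == t).to_numpy()
        rest = labelled & ~of_type
        if of_type.sum() < min_spots or rest.sum() < min_spots:
            logger.warning("find_markers_one_vs_all: skipping %s (%d spots)", t, of_type.sum())
            continue
        table = _deg_for_groups(norm, of_type, rest, t, lfc_cut, fdr_cut, pseudocount, False)
        tables.append(table[table["direction"] == "up"].reset_index(drop=True))
    if not tables:
        return pd.DataFrame(columns=DEG_COLUMNS)
    return pd.concat(tables, ignore_index=True)


def shared_degs(deg_table: pd.DataFrame, min_types: int = 3) -> tuple[list[str], list[str]]:
    """Genes whose aging direction is consistent in at least ``min_types``
    spot types.

    A gene enters the up list when it is up in >= min_types types and in
    strictly more types than it is down (mirror rule for down); a gene up in
    two and down in two types therefore appears in neither list.
    """
    if deg_table.empty:
        return [], []
    counts = (
        deg_table.groupby(["gene", "direction"])["spot_type"].nunique().unstack(fill_value=0)
    )
    n_up = counts.get("up", pd.Series(0, index=counts.index))
    n_down = counts.get("down", pd.Series(0, index=counts.index))
    up = sorted(counts.index[(n_up >= min_types) & (n_up > n_down)])
    down = sorted(counts.index[(n_down >= min_types) & (n_down > n_up)])
    return up, down


# ---------------------------------------------------------------------------
# over-representation analysis
# ---------------------------------------------------------------------------

def ora(
    gene_list: Sequence[str],
    universe: Sequence[str],
    collection,
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each set in ``gene_list``.

    The upper-tail probability of observing at least the overlap given the
    universe is BH-adjusted across sets; the full table is returned with a
    ``significant`` flag at ``q < q_cut``.
    """
    universe_set = set(map(str, universe))
    listed = [str(g) for g in gene_list]
    outside = [g for g in listed if g not in universe_set]
    if outside:
        logger.warning("ora: dropping %d gene(s) not in the universe: %s", len(outside), outside[:5])
    listed_set = set(listed) & universe_set
    rows = []
    for name, genes in collection.sets.items():
        in_universe = set(genes) & universe_set
        overlap = len(in_universe & listed_set)
        p = float(
            stats.hypergeom.sf(overlap - 1, len(universe_set), len(in_universe), len(listed_set))
        )
        rows.append(
            {
                "set_name": name,
                "overlap": overlap,
                "set_size": len(in_universe),
                "list_size": len(listed_set),
                "universe_size": len(universe_set),
                "pvalue": p,
            }
        )
    table = pd.DataFrame(rows)
    table["qvalue"] = bh_adjust(table["pvalue"])
    table["significant"] = table["qvalue"] < q_cut
    return table
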