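"""Gene-set module scoring with expression-binned control genes.

The module score of a gene set in a spot is the mean normalized expression
of the set's genes minus the mean of matched control genes drawn from the
same average-expression bins — the standard control-gene scheme used for
single-cell signature scoring. Scores are therefore centred against the
expression level of the set, and a random gene set scores ~0 on
exchangeable data.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .differential import wilcoxon_rank_sum
from .io_preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene lists, optionally tagged with a category per set.

    Duplicate genes within a set are removed (first occurrence kept); empty
    sets are rejected.
    """

    sets: dict[str, list[str]]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for name, genes in self.sets.items():
            seen: dict[str, None] = {}
            for g in genes:
                seen.setdefault(str(g), None)
            if not seen:
                raise ValueError(f"gene set {name!r} is empty")
            clean[str(name)] = list(seen)
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str | Path, category: str | None = None) -> GeneSetCollection:
    """Read a tab-separated GMT file (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    coll = GeneSetCollection(sets)
    if category is not None:
        coll.categories = {name: category for name in sets}
    return coll


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path, description: str = "") -> None:
    lines = ["\t".join([name, description, *map(str, genes)]) for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class ScoreParams:
    """Control-gene scheme parameters: ``n_bins`` equal-size average-
    expression bins and ``n_ctrl`` control genes drawn per set gene."""

    n_bins: int = 24
    n_ctrl: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 1 or self.n_ctrl < 1:
            raise ValueError("n_bins and n_ctrl must be >= 1")


@dataclass
class ScoreMatrix:
    """Spots x gene-sets module scores."""

    scores: pd.DataFrame
    params: ScoreParams

    def __post_init__(self) -> None:
        if self.scores.columns.duplicated().any():
            raise ValueError("score columns must be unique")
        if not np.all(np.isfinite(self.scores.to_numpy())):
            raise ValueError("scores must be finite")

    def column(self, name: str) -> pd.Series:
        if name not in self.scores.columns:
            raise KeyError(f"score column {name!r} not present")
        return self.scores[name]


def _set_seed(seed: int, name: str) -> int:
    digest = hashlib.blake2b(f"{seed}:{name}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def _expression_bins(norm: NormalizedMatrix, n_bins: int) -> np.ndarray:
    """Assign every gene to one of ``n_bins`` equal-count bins by rank of
    average expression (ties broken by gene id)."""
    avg = norm.values.mean(axis=1)
    order = np.lexsort((norm.gene_ids.astype(str), avg))
    bins = np.empty(len(order), dtype=int)
    splits = np.array_split(order, n_bins)
    for b, idx in enumerate(splits):
        bins[idx] = b
    return bins


def module_score(
    norm: NormalizedMatrix,
    gene_set: Sequence[str],
    params: ScoreParams,
    set_name: str = "<unnamed>",
) -> pd.Series:
    """Per-spot module score of a gene set.

    For each set gene, ``n_ctrl`` controls are drawn uniformly without
    replacement from the other genes of its bin (with replacement when the
    bin is too small); the score is the mean over set genes minus the mean
    over all drawn controls. Deterministic for a fixed seed.
    """
    present = [g for g in gene_set if g in set(norm.gene_ids)]
    if not present:
        raise ValueError(f"no gene of set {set_name!r} is present in the matrix")
    dropped = len(gene_set) - len(present)
    if dropped:
        logger.warning("module_score(%s): dropped %d absent gene(s)", set_name, dropped)

    bins = _expression_bins(norm, params.n_bins)
    gene_pos = {g: i for i, g in enumerate(norm.gene_ids)}
    set_idx = np.array([gene_pos[g] for g in present], dtype=int)

    rng = np.random.default_rng(params.seed)
    members_of_bin = {b: np.flatnonzero(bins == b) for b in range(params.n_bins)}
    ctrl_sum = np.zeros(len(norm.spot_ids))
    n_draws = 0
    for gi in set_idx:
        pool = members_of_bin[bins[gi]]
        pool = pool[pool != gi]
        if len(pool) == 0:
            pool = members_of_bin[bins[gi]]
        replace = len(pool) < params.n_ctrl
        draw = rng.choice(pool, size=params.n_ctrl, replace=replace)
        ctrl_sum += norm.values[draw].sum(axis=0)
        n_draws += params.n_ctrl
    score = norm.values[set_idx].mean(axis=0) - ctrl_sum / n_draws
    return pd.Series(score, index=norm.spot_ids, name=set_name)


def score_collection(
    norm: NormalizedMatrix,
    collection: GeneSetCollection,
    params: ScoreParams,
) -> ScoreMatrix:
    """One score column per set; control draws are independent per set, with
    a per-set seed derived from the set name so permuting sets only permutes
    columns."""
    columns = {}
    failed = []
    for name, genes in collection.sets.items():
        set_params = ScoreParams(params.n_bins, params.n_ctrl, _set_seed(params.seed, name))
        try:
            columns[name] = module_score(norm, genes, set_params, set_name=name)
        except ValueError as exc:
            failed.append(name)
            logger.warning("score_collection: skipping %s (%s)", name, exc)
    if failed:
        logger.warning("score_collection: %d/%d sets failed: %s", len(failed), len(collection), failed)
    if not columns:
        raise ValueError("no gene set could be scored")
    return ScoreMatrix(pd.DataFrame(columns), params)


def compare_scores_by_age(scores: ScoreMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Two-sided rank-sum comparison of each score between age groups.

    Returns one row per set with the group medians and the Wilcoxon p-value;
    p is NaN (with a warning) when either group has fewer than 3 spots.
    """
    ages = meta.loc[scores.scores.index, "age_group"]
    young = scores.scores.loc[ages == "young"]
    old = scores.scores.loc[ages == "old"]
    rows = []
    for name in scores.scores.columns:
        y, o = young[name].to_numpy(), old[name].to_numpy()
        if len(y) < 3 or len(o) < 3:
            logger.warning("compare_scores_by_age(%s): group with < 3 spots, p undefined", name)
            p = np.nan
        else:
            _, p = wilcoxon_rank_sum(o, y)
        rows.append(
            {
                "set": name,
                "median_young": float(np.median(y)) if len(y) else np.nan,
                "median_old": float(np.median(o)) if len(o) else np.nan,
                "wilcoxon_p": p,
            }
        )
    return pd.DataFrame(rows).set_index("set")
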