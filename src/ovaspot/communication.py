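"""Permutation-based ligand-receptor interaction testing between spot types.

A candidate interaction (ligand, receptor, sender type, receiver type) is
tested only when the ligand is expressed in at least a fraction
``frac_cut`` of sender spots and the receptor in at least ``frac_cut`` of
receiver spots. The observed interaction score is the average of the mean
normalized ligand expression in the sender and the mean receptor
expression in the receiver; its null distribution is built by shuffling
spot-type labels across all annotated spots and the permutation p-value is
``(1 + #null >= observed) / (1 + n_perm)``.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .io_preprocess import NormalizedMatrix, SpatialDataset

logger = logging.getLogger(__name__)

RESULT_COLUMNS = (
    "ligand", "receptor", "sender", "receiver",
    "ligand_fraction", "receptor_fraction",
    "tested", "mean_score", "pvalue", "significant",
)


def expressed_fraction(
    ds: SpatialDataset,
    annotation: pd.DataFrame,
    gene: str,
    spot_type: str,
) -> float:
    """Fraction of spots of the type with at least one count of the gene."""
    types = annotation.loc[list(ds.spot_ids), "spot_type"].to_numpy()
    if spot_type not in set(types):
        raise ValueError(f"unknown spot type {spot_type!r}")
    gene_idx = np.flatnonzero(ds.gene_ids == gene)
    cols = np.flatnonzero(types == spot_type)
    if gene_idx.size == 0:
        return 0.0
    row = ds.counts[int(gene_idx[0]), cols]
    return float((row.toarray() > 0).mean())


def _pair_table(pairs) -> pd.DataFrame:
    if isinstance(pairs, pd.DataFrame):
        return pairs[["ligand", "receptor"]].astype(str)
    return pd.DataFrame(pairs, columns=["ligand", "receptor"]).astype(str)


def lr_interaction_test(
    norm: NormalizedMatrix,
    annotation: pd.DataFrame,
    pairs,
    n_perm: int = 1000,
    frac_cut: float = 0.10,
    p_cut: float = 0.01,
    seed: int = 0,
    senders: Sequence[str] | None = None,
    receivers: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Permutation test of every (pair, sender, receiver) combination.

    Expression fractions are computed on the normalized matrix (x > 0 is
    equivalent to a non-zero count). Types with fewer than 3 spots are
    skipped. One record per combination is returned; filtered combinations
    keep ``tested=False`` with NaN statistics.
    """
    if n_perm < 100:
        logger.warning("lr_interaction_test: n_perm=%d is low; p-values are coarse", n_perm)
    table = _pair_table(pairs)
    labels = annotation.loc[list(norm.spot_ids), "spot_type"].to_numpy()
    keep = labels != "ambiguous"
    labels = labels[keep]
    values = norm.values[:, keep]

    type_counts = pd.Series(labels).value_counts()
    types = sorted(t for t in type_counts.index if type_counts[t] >= 3)
    skipped = sorted(set(type_counts.index) - set(types))
    if skipped:
        logger.warning("lr_interaction_test: skipping small type(s): %s", skipped)
    senders = [t for t in (senders or types) if t in types]
    receivers = [t for t in (receivers or types) if t in types]

    gene_pos = {g: i for i, g in enumerate(norm.gene_ids)}
    genes = sorted({g for g in pd.concat([table["ligand"], table["receptor"]]) if g in gene_pos})
    gidx = {g: k for k, g in enumerate(genes)}
    expr = values[[gene_pos[g] for g in genes]] if genes else np.empty((0, len(labels)))

    type_to_col = {t: k for k, t in enumerate(types)}
    onehot = np.zeros((len(labels), len(types)))
    for k, t in enumerate(types):
        onehot[labels == t, k] = 1.0
    counts = onehot.sum(axis=0)
    obs_means = expr @ onehot / counts          # genes x types
    frac = (expr > 0) @ onehot / counts          # expressed fraction per type

    # candidate records
    records = []
    tested_keys = []
    for _, row in table.iterrows():
        lig, rec = row["ligand"], row["receptor"]
        for s in senders:
            for r in receivers:
                lf = frac[gidx[lig], type_to_col[s]] if lig in gidx else 0.0
                rf = frac[gidx[rec], type_to_col[r]] if rec in gidx else 0.0
                tested = lf >= frac_cut and rf >= frac_cut and lig in gidx and rec in gidx
                score = (
                    (obs_means[gidx[lig], type_to_col[s]] + obs_means[gidx[rec], type_to_col[r]]) / 2.0
                    if tested
                    else np.nan
                )
                records.append(
                    {
                        "ligand": lig, "receptor": rec, "sender": s, "receiver": r,
                        "ligand_fraction": float(lf), "receptor_fraction": float(rf),
                        "tested": bool(tested), "mean_score": float(score) if tested else np.nan,
                        "pvalue": np.nan, "significant": False,
                    }
                )
                if tested:
                    tested_keys.append(len(records) - 1)

    result = pd.DataFrame(records, columns=list(RESULT_COLUMNS))
    if not tested_keys:
        return result

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(tested_keys))
    observed = result.loc[tested_keys, "mean_score"].to_numpy()
    lig_idx = np.array([gidx[result.at[i, "ligand"]] for i in tested_keys])
    rec_idx = np.array([gidx[result.at[i, "receptor"]] for i in tested_keys])
    s_idx = np.array([type_to_col[result.at[i, "sender"]] for i in tested_keys])
    r_idx = np.array([type_to_col[result.at[i, "receiver"]] for i in tested_keys])

    perm = np.arange(len(labels))
    for _ in range(n_perm):
        rng.shuffle(perm)
        null_means = expr[:, perm] @ onehot / counts
        null_scores = (null_means[lig_idx, s_idx] + null_means[rec_idx, r_idx]) / 2.0
        exceed += null_scores >= observed - 1e-12
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    result.loc[tested_keys, "pvalue"] = pvals
    result.loc[tested_keys, "significant"] = pvals < p_cut
    return result


def differential_interactions(
    results_young: pd.DataFrame, results_old: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Interactions gained and lost with age.

    Keyed by (ligand, receptor, sender, receiver): gained = significant in
    old but not young; lost = significant in young but not old.
    """
    key = ["ligand", "receptor", "sender", "receiver"]

    def _sig_keys(df: pd.DataFrame) -> set:
        if df.empty:
            return set()
        sig = df[df["significant"]]
        return set(map(tuple, sig[key].to_numpy()))

    young_keys, old_keys = _sig_keys(results_young), _sig_keys(results_old)
    gained = sorted(old_keys - young_keys)
    lost = sorted(young_keys - old_keys)
    return (
        pd.DataFrame(gained, columns=key),
        pd.DataFrame(lost, columns=key),
    )
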