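"""Marker-score-based spot-type assignment and region derivation.

Clusters are annotated by the marker set with the highest mean module score
across the cluster's spots; types then map deterministically onto the two
tissue regions: the follicle region (OO, GC, TC, PPF) and the non-follicle
region (OSE, SC, SMC, IM, MT2high).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .scoring import ScoreMatrix

logger = logging.getLogger(__name__)

AMBIGUOUS = "ambiguous"
FOLLICLE_REGION = ("OO", "GC", "TC", "PPF")
NON_FOLLICLE_REGION = ("OSE", "SC", "SMC", "IM", "MT2high")
REGION_OF_TYPE = {
    **{t: "follicle" for t in FOLLICLE_REGION},
    **{t: "non_follicle" for t in NON_FOLLICLE_REGION},
}

ANNOTATION_COLUMNS = ("cluster", "spot_type", "region")


def assign_spot_types(
    scores: ScoreMatrix,
    clusters: np.ndarray,
    tol: float = 0.01,
    spot_level: bool = False,
) -> pd.DataFrame:
    """Label spots with the marker set of highest mean score.

    By default assignment is cluster-level (every spot of a cluster gets the
    cluster's argmax type); ``spot_level=True`` applies the argmax per spot
    for diagnostics. A cluster (or spot) whose top two marker scores differ
    by less than ``tol`` is labelled ``ambiguous``.
    """
    frame = scores.scores
    clusters = np.asarray(clusters)
    if len(clusters) != len(frame):
        raise ValueError("clusters length does not match score matrix")

    def _argmax_label(means: pd.Series) -> str:
        if means.isna().all():
            raise ValueError("all marker scores undefined")
        ranked = means.sort_values(ascending=False)
        if len(ranked) > 1 and (ranked.iloc[0] - ranked.iloc[1]) < tol:
            return AMBIGUOUS
        return str(ranked.index[0])

    if spot_level:
        types = frame.apply(_argmax_label, axis=1).to_numpy()
    else:
        types = np.empty(len(frame), dtype=object)
        for c in np.unique(clusters):
            mask = clusters == c
            means = frame[mask].mean(axis=0)
            if means.isna().all():
                raise ValueError(f"cluster {c} has all-undefined marker scores")
            types[mask] = _argmax_label(means)

    ann = pd.DataFrame(
        {"cluster": clusters, "spot_type": types, "region": pd.NA},
        index=frame.index,
    )
    return assign_regions(ann)


def assign_regions(annotation: pd.DataFrame) -> pd.DataFrame:
    """Fill the ``region`` column from ``spot_type``.

    The mapping is total and disjoint over the nine types; ambiguous spots
    carry no region; any other unknown type raises.
    """
    out = annotation.copy()
    regions = []
    for t in out["spot_type"]:
        if t == AMBIGUOUS:
            regions.append(pd.NA)
        elif t in REGION_OF_TYPE:
            regions.append(REGION_OF_TYPE[t])
        else:
            raise ValueError(f"unknown spot type {t!r}")
    out["region"] = regions
    return out


def composition_by_group(
    annotation: pd.DataFrame, meta: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Per-age-group spot-type and region proportions, plus per-sample
    proportions for dispersion displays.

    Proportions are taken over non-ambiguous spots and sum to one within
    each group.
    """
    ann = annotation.join(meta[["sample", "age_group"]])
    ann = ann[ann["spot_type"] != AMBIGUOUS]
    if ann.empty:
        raise ValueError("no annotated (non-ambiguous) spots")
    for g, sub in ann.groupby("age_group"):
        if len(sub) == 0:
            raise ValueError(f"age group {g!r} has zero spots")

    by_type = (
        ann.groupby("age_group")["spot_type"].value_counts(normalize=True).unstack(fill_value=0.0).T
    )
    by_region = (
        ann.groupby("age_group")["region"].value_counts(normalize=True).unstack(fill_value=0.0).T
    )
    per_sample = (
        ann.groupby(["sample", "age_group"])["spot_type"]
        .value_counts(normalize=True)
        .rename("proportion")
        .reset_index()
    )
    return {"by_type": by_type, "by_region": by_region, "per_sample": per_sample}
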