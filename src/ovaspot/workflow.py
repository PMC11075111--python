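"""End-to-end orchestration of the standard analysis.

Runs QC, normalization, clustering, marker-based annotation, aging
differential expression, OSAG/aging-score construction, PCOA selection,
hotspot calling and distance-decay analysis in order, returning every
intermediate in a single result object. This is the path the command-line
interface and the acceptance script drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import annotation as ann_mod
from . import differential, hotspot, io_preprocess, scoring


@dataclass
class PipelineResult:
    dataset: io_preprocess.SpatialDataset
    norm: io_preprocess.NormalizedMatrix
    hvg: list[str]
    clusters: np.ndarray
    marker_scores: scoring.ScoreMatrix
    annotation: pd.DataFrame
    aging_deg_table: pd.DataFrame
    osag: hotspot.OSAG
    score_frame: pd.DataFrame          # pathway + OSAG + aging-score columns
    aging_score: pd.Series
    pcoa: pd.DataFrame
    hotspots: hotspot.HotspotResult | None
    composition: pd.Series | None = None
    decay: hotspot.DecayResult | None = None
    warnings: list[str] = field(default_factory=list)


def run_pipeline(
    ds: io_preprocess.SpatialDataset,
    marker_sets: Mapping[str, Sequence[str]],
    pathway_sets: Mapping[str, Sequence[str]],
    aging_gene_list: Sequence[str],
    *,
    seed: int = 0,
    min_spots_per_gene: int = 50,
    scalefactor: float = 6000.0,
    n_hvg: int = 2000,
    n_pcs: int = 25,
    k_neighbors: int = 15,
    resolution: float = 0.2,
    score_params: scoring.ScoreParams | None = None,
    lfc_cut: float = 0.5,
    fdr_cut: float = 0.05,
    r_thresh: float = 0.5,
    p_thresh: float = 0.05,
    q: float = 0.05,
    mode: str = "intersect_all",
    decay_window_um: float | None = 1500.0,
) -> PipelineResult:
    """Run the full aging-hotspot analysis on a dataset."""
    params = score_params or scoring.ScoreParams(seed=seed)
    warnings: list[str] = []

    filtered = io_preprocess.qc_filter(ds, min_spots_per_gene=min_spots_per_gene)
    norm = io_preprocess.normalize(filtered, scalefactor=scalefactor)
    hvg = io_preprocess.select_hvg(norm, n_top=n_hvg)
    clusters = io_preprocess.cluster_spots(
        norm, hvg, n_pcs=n_pcs, k_neighbors=k_neighbors, resolution=resolution, seed=seed
    )

    marker_scores = scoring.score_collection(
        norm, scoring.GeneSetCollection({k: list(v) for k, v in marker_sets.items()}), params
    )
    annotation = ann_mod.assign_spot_types(marker_scores, clusters)

    meta = filtered.meta
    deg_table = differential.aging_degs(norm, annotation, meta, lfc_cut=lfc_cut, fdr_cut=fdr_cut)
    osag = hotspot.build_osag(deg_table, aging_gene_list)

    score_sets = {k: list(v) for k, v in pathway_sets.items()}
    if osag.up:
        score_sets["OSAG_up"] = osag.up
    if osag.down:
        score_sets["OSAG_down"] = osag.down
    score_matrix = scoring.score_collection(norm, scoring.GeneSetCollection(score_sets), params)
    frame = score_matrix.scores.copy()

    if "OSAG_up" in frame.columns and "OSAG_down" in frame.columns:
        a_score = hotspot.aging_score(frame)
    elif "OSAG_up" in frame.columns:
        warnings.append("OSAG down set empty; aging score equals the OSAG-up score")
        a_score = frame["OSAG_up"].rename("aging_score")
    else:
        raise ValueError("no OSAG genes detected; cannot build the aging score")
    frame["aging_score"] = a_score

    pcoa = hotspot.select_pcoa(
        score_matrix,
        frame["OSAG_up"] if "OSAG_up" in frame.columns else a_score,
        list(pathway_sets),
        r_thresh=r_thresh,
        p_thresh=p_thresh,
    )
    selected = [s for s in pcoa.index[pcoa["selected"]]]

    hotspots = None
    composition = None
    decay = None
    if selected:
        call_frame = frame[["aging_score", *selected]]
        hotspots = hotspot.call_hotspots(call_frame, q=q, mode=mode)
        if hotspots.hotspot_spot_ids:
            composition = hotspot.hotspot_composition(hotspots.hotspot_spot_ids, annotation)
            decay = hotspot.distance_decay(
                hotspots.hotspot_spot_ids,
                filtered.spot_ids,
                filtered.coords,
                a_score,
                max_distance_um=decay_window_um,
            )
    else:
        warnings.append("no PCOA pathway selected; hotspot calling skipped")

    return PipelineResult(
        dataset=filtered,
        norm=norm,
        hvg=hvg,
        clusters=clusters,
        marker_scores=marker_scores,
        annotation=annotation,
        aging_deg_table=deg_table,
        osag=osag,
        score_frame=frame,
        aging_score=a_score,
        pcoa=pcoa,
        hotspots=hotspots,
        composition=composition,
        decay=decay,
        warnings=warnings,
    )
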