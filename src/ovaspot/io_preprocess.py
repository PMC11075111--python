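"""Reading Visium-dialect files, QC filtering, normalization, HVG selection and clustering.

The universal carrier is :class:`SpatialDataset`: a sparse genes x spots
count matrix aligned with spot coordinates (micrometres) and per-spot
metadata (sample id and age group). Datasets are exchanged on disk as a
Matrix Market matrix plus feature/barcode TSVs, a tissue-positions CSV and
a metadata TSV, mirroring the 10x Visium file dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

AGE_GROUPS = ("young", "old")

DATASET_FILES = (
    "matrix.mtx",
    "features.tsv",
    "barcodes.tsv",
    "tissue_positions.csv",
    "metadata.tsv",
)


class DuplicateBarcodeError(ValueError):
    """A barcode occurs more than once in one of the dataset files."""


class AlignmentError(ValueError):
    """Barcodes are inconsistent between dataset files."""


@dataclass
class SpatialDataset:
    """Spot-resolved count data with coordinates and per-spot metadata.

    Attributes
    ----------
    counts:
        Sparse non-negative integer matrix, genes x spots.
    gene_ids, spot_ids:
        Unique string identifiers for rows and columns of ``counts``.
    coords:
        ``(n_spots, 2)`` array of spot centre coordinates ``(x_um, y_um)``.
    meta:
        Per-spot frame indexed by barcode with columns ``sample`` and
        ``age_group`` (``young``/``old``).
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    spot_ids: np.ndarray
    coords: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.counts.shape != (len(self.gene_ids), len(self.spot_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.spot_ids)} spots"
            )
        for name, ids in (("gene", self.gene_ids), ("spot", self.spot_ids)):
            if len(set(ids)) != len(ids):
                raise DuplicateBarcodeError(f"duplicate {name} identifiers present")
        if self.coords.shape != (len(self.spot_ids), 2):
            raise ValueError("coords must be (n_spots, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("spot coordinates must be finite")
        if list(self.meta.index) != list(self.spot_ids):
            raise AlignmentError("meta index does not match spot_ids")
        bad = set(self.meta["age_group"]) - set(AGE_GROUPS)
        if bad:
            raise ValueError(f"unknown age_group values: {sorted(bad)}")
        if (self.counts.data < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    def subset_genes(self, mask: np.ndarray) -> "SpatialDataset":
        idx = np.asarray(mask)
        return SpatialDataset(
            self.counts[idx], self.gene_ids[idx], self.spot_ids, self.coords, self.meta
        )

    def subset_spots(self, mask: np.ndarray) -> "SpatialDataset":
        idx = np.asarray(mask)
        return SpatialDataset(
            self.counts[:, idx],
            self.gene_ids,
            self.spot_ids[idx],
            self.coords[idx],
            self.meta.iloc[idx if idx.dtype != bool else np.flatnonzero(idx)],
        )


@dataclass
class NormalizedMatrix:
    """Log-scale library-size normalized expression, genes x spots.

    ``values[g, s] = log2(1 + scalefactor * counts[g, s] / total_s)`` so that
    for every spot ``sum_g (2**x - 1) == scalefactor``.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    spot_ids: np.ndarray
    scalefactor: float = 6000.0
    log_base: int = 2

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.spot_ids)):
            raise ValueError("values shape does not match id lists")
        if self.scalefactor <= 0:
            raise ValueError("scalefactor must be positive")

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def delogged(self) -> np.ndarray:
        """Return the de-logged scaled expression ``2**x - 1``."""
        return np.exp2(self.values) - 1.0


# ---------------------------------------------------------------------------
# disk I/O
# ---------------------------------------------------------------------------

def read_dataset(path: str | Path) -> SpatialDataset:
    """Load a dataset directory written by :func:`ovaspot.synth.write_dataset`.

    All files are aligned by barcode; barcode sets must agree exactly between
    the barcodes TSV, the positions CSV and the metadata TSV.
    """
    path = Path(path)
    missing = [f for f in DATASET_FILES if not (path / f).exists()]
    if missing:
        raise FileNotFoundError(f"dataset directory {path} is missing: {missing}")

    counts = sp.csr_matrix(scipy.io.mmread(path / "matrix.mtx"))
    features = pd.read_csv(path / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    positions = pd.read_csv(path / "tissue_positions.csv", dtype={"barcode": str})
    meta = pd.read_csv(path / "metadata.tsv", sep="\t", dtype=str)

    gene_ids = features[0].astype(str).to_numpy(dtype=object)
    spot_ids = barcodes.to_numpy(dtype=object)
    if counts.shape != (len(gene_ids), len(spot_ids)):
        raise ValueError(
            f"matrix is {counts.shape} but features/barcodes give "
            f"{len(gene_ids)} x {len(spot_ids)}"
        )
    if barcodes.duplicated().any():
        dupes = barcodes[barcodes.duplicated()].tolist()
        raise DuplicateBarcodeError(f"duplicate barcodes: {dupes[:5]}")

    for name, frame_bc in (
        ("tissue_positions.csv", positions["barcode"]),
        ("metadata.tsv", meta["barcode"]),
    ):
        if frame_bc.duplicated().any():
            raise DuplicateBarcodeError(f"duplicate barcodes in {name}")
        absent = set(spot_ids) - set(frame_bc)
        if absent:
            raise AlignmentError(
                f"{name} is missing barcode(s): {sorted(absent)[:5]}"
            )

    positions = positions.set_index("barcode").loc[spot_ids]
    meta = meta.set_index("barcode").loc[spot_ids]
    meta.index.name = None
    coords = positions[["x_um", "y_um"]].to_numpy(dtype=float)
    return SpatialDataset(counts, gene_ids, spot_ids, coords, meta[["sample", "age_group"]])


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------

def qc_filter(
    ds: SpatialDataset,
    min_spots_per_gene: int = 50,
    expr_threshold: int = 1,
) -> SpatialDataset:
    """Drop genes detected (count >= expr_threshold) in too few spots.

    Genes are retained when they reach ``expr_threshold`` in at least
    ``min_spots_per_gene`` spots; spots left with zero total counts are then
    removed. The operation is idempotent: removed spots contribute no
    detections, so a second pass keeps the same genes.
    """
    if min_spots_per_gene < 0 or expr_threshold < 0:
        raise ValueError("thresholds must be non-negative")
    detected = np.asarray((ds.counts >= max(expr_threshold, 1)).sum(axis=1)).ravel()
    if expr_threshold == 0:
        keep_genes = np.ones(ds.n_genes, dtype=bool)
    else:
        keep_genes = detected >= min_spots_per_gene
    if not keep_genes.any():
        raise ValueError("qc_filter removed every gene; thresholds too strict")
    out = ds.subset_genes(keep_genes)
    totals = np.asarray(out.counts.sum(axis=0)).ravel()
    keep_spots = totals > 0
    out = out.subset_spots(keep_spots)
    logger.info(
        "qc_filter: dropped %d/%d genes and %d/%d spots",
        ds.n_genes - out.n_genes, ds.n_genes, ds.n_spots - out.n_spots, ds.n_spots,
    )
    return out


def normalize(ds: SpatialDataset, scalefactor: float = 6000.0) -> NormalizedMatrix:
    """Library-size normalize and log2-transform the counts.

    ``x_gs = log2(1 + scalefactor * c_gs / total_s)``. Every spot must have a
    positive total (run :func:`qc_filter` first).
    """
    totals = np.asarray(ds.counts.sum(axis=0)).ravel().astype(float)
    if (totals <= 0).any():
        bad = ds.spot_ids[totals <= 0]
        raise ValueError(f"zero-total spot(s) cannot be normalized: {list(bad[:5])}")
    dense = np.asarray(ds.counts.todense(), dtype=float)
    x = np.log2(1.0 + scalefactor * dense / totals[None, :])
    return NormalizedMatrix(x, ds.gene_ids, ds.spot_ids, scalefactor=scalefactor)


def select_hvg(norm: NormalizedMatrix, n_top: int = 2000) -> list[str]:
    """Rank genes by variance of normalized expression; return the top n_top.

    Ties are broken lexicographically by gene id so the selection is fully
    deterministic.
    """
    if n_top < 1:
        raise ValueError("n_top must be positive")
    variances = norm.values.var(axis=1, ddof=1) if norm.values.shape[1] > 1 else np.zeros(len(norm.gene_ids))
    if n_top > len(norm.gene_ids):
        logger.warning(
            "select_hvg: n_top=%d exceeds %d genes; returning all", n_top, len(norm.gene_ids)
        )
        n_top = len(norm.gene_ids)
    # sort by descending variance, then ascending gene id
    order = np.lexsort((norm.gene_ids.astype(str), -variances))
    return [str(g) for g in norm.gene_ids[order[:n_top]]]


def cluster_spots(
    norm: NormalizedMatrix,
    hvg: Sequence[str],
    n_pcs: int = 25,
    k_neighbors: int = 15,
    resolution: float = 0.2,
    seed: int = 0,
) -> np.ndarray:
    """Leiden community detection on a kNN graph in PCA space.

    The default resolution (0.2) targets tissue-type granularity: finer
    resolutions additionally resolve within-type substructure (age shifts,
    focus-proximity gradients), which the cluster-then-annotate design
    deliberately treats as one spot type.

    PCA is run on the per-gene-centred HVG submatrix (spots x genes); the
    graph connects each spot to its ``k_neighbors`` nearest neighbours by
    Euclidean distance in PC space; communities maximize modularity at the
    given resolution. Returns consecutive integer labels starting at 0,
    deterministic for a fixed seed.
    """
    import igraph
    import leidenalg

    n_spots = len(norm.spot_ids)
    if k_neighbors >= n_spots:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n_spots={n_spots}")
    idx = norm.gene_index(hvg)
    X = norm.values[idx].T  # spots x genes
    X = X - X.mean(axis=0, keepdims=True)
    n_comp = min(n_pcs, min(X.shape) - 1)
    pcs = PCA(n_components=n_comp, svd_solver="full").fit_transform(X)

    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(pcs)
    _, neigh = nn.kneighbors(pcs)
    edges = set()
    for i in range(n_spots):
        for j in neigh[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    graph = igraph.Graph(n=n_spots, edges=sorted(edges))
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    raw = np.asarray(part.membership)
    # relabel to consecutive integers by order of first appearance
    remap: dict[int, int] = {}
    labels = np.empty(n_spots, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap)
        labels[i] = remap[lab]
    return labels
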