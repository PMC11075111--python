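"""Shared fixtures: small hand-built matrices and session-scoped synthetic runs."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import ovaspot as ov
from ovaspot.io_preprocess import NormalizedMatrix, SpatialDataset


def make_dataset(counts, gene_ids=None, spot_ids=None, coords=None, samples=None, ages=None):
    """Build a SpatialDataset from a dense count array with defaults."""
    counts = np.asarray(counts)
    n_genes, n_spots = counts.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    spot_ids = spot_ids or [f"s{i}" for i in range(n_spots)]
    coords = coords if coords is not None else np.column_stack(
        [np.arange(n_spots, dtype=float) * 100.0, np.zeros(n_spots)]
    )
    samples = samples or ["A"] * n_spots
    ages = ages or ["young"] * n_spots
    meta = pd.DataFrame({"sample": samples, "age_group": ages}, index=spot_ids)
    return SpatialDataset(sp.csr_matrix(counts), gene_ids, spot_ids, coords, meta)


def make_norm(values, gene_ids=None, spot_ids=None, scalefactor=6000.0):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    spot_ids = spot_ids or [f"s{i}" for i in range(values.shape[1])]
    return NormalizedMatrix(values, gene_ids, spot_ids, scalefactor=scalefactor)


@pytest.fixture(scope="session")
def default_sim():
    """The standard synthetic ovary study (beta=1, 2 foci per old sample)."""
    cfg = ov.SimConfig(seed=7)
    ds, truth = ov.simulate_dataset(cfg)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def default_pipeline(default_sim):
    cfg, ds, truth = default_sim
    return ov.run_pipeline(
        ds, truth.marker_sets, truth.pathway_sets, truth.aging_gene_list, seed=cfg.seed
    )


@pytest.fixture(scope="session")
def recovery_sim():
    """Parameter-recovery study: beta=1 aging effects, no senescence foci,
    isolating the planted age contrast."""
    cfg = ov.SimConfig(seed=19, n_foci=0, young_focus_ratio=0.0)
    ds, truth = ov.simulate_dataset(cfg)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def recovery_degs(recovery_sim):
    """QC -> normalize -> cluster -> annotate -> aging DEGs on the recovery study."""
    from ovaspot import io_preprocess as iop
    from ovaspot import annotation as ann_mod
    from ovaspot import differential, scoring

    cfg, ds, truth = recovery_sim
    filtered = iop.qc_filter(ds)
    norm = iop.normalize(filtered)
    hvg = iop.select_hvg(norm)
    clusters = iop.cluster_spots(norm, hvg, seed=cfg.seed)
    marker_scores = scoring.score_collection(
        norm, scoring.GeneSetCollection(truth.marker_sets), scoring.ScoreParams(seed=cfg.seed)
    )
    annotation = ann_mod.assign_spot_types(marker_scores, clusters)
    degs = differential.aging_degs(norm, annotation, filtered.meta)
    return filtered, norm, annotation, degs


@pytest.fixture(scope="session")
def null_sim():
    """Null study: no aging effect, foci balanced across age groups."""
    cfg = ov.SimConfig(seed=13, age_log2fc=0.0, young_focus_ratio=1.0)
    ds, truth = ov.simulate_dataset(cfg)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def flat_prep():
    """Fully exchangeable study (no markers, no aging, no foci): the
    condition under which permutation-test calibration is well-posed."""
    from ovaspot import io_preprocess as iop

    cfg = ov.SimConfig(
        seed=17, age_log2fc=0.0, marker_fold=1.0, n_foci=0, young_focus_ratio=0.0
    )
    ds, truth = ov.simulate_dataset(cfg)
    filtered = iop.qc_filter(ds)
    norm = iop.normalize(filtered)
    lay = truth.layout.set_index("spot_id").loc[norm.spot_ids]
    annotation = pd.DataFrame(
        {"cluster": 0, "spot_type": lay["true_type"].to_numpy(), "region": pd.NA},
        index=norm.spot_ids,
    )
    return cfg, filtered, norm, annotation, truth


@pytest.fixture(scope="session")
def null_prep(null_sim):
    """QC-filtered + normalized null data with true-type annotation."""
    from ovaspot import io_preprocess as iop

    cfg, ds, truth = null_sim
    filtered = iop.qc_filter(ds)
    norm = iop.normalize(filtered)
    lay = truth.layout.set_index("spot_id").loc[norm.spot_ids]
    annotation = pd.DataFrame(
        {"cluster": 0, "spot_type": lay["true_type"].to_numpy(), "region": pd.NA},
        index=norm.spot_ids,
    )
    return cfg, filtered, norm, annotation, truth
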