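"""Synthetic Visium-like ovary datasets with planted ground truth.

The generator emulates the structure of a multi-sample primate-ovary spatial
transcriptomics study: hexagonal-lattice capture areas (100 um pitch), two
age groups of samples, nine spot types (oocyte OO, granulosa GC, theca TC,
primordial/primary-follicle PPF, surface epithelium OSE, stroma SC, smooth
muscle SMC, immune IM and metallothionein-high MT2high), age-dependent
up/down expression programs, and compact senescence foci whose expression
program decays outward with an exponential length scale.

Counts follow a negative-binomial noise model around a per-gene, per-spot
mean built from four multiplicative pieces: a log-normal baseline, a marker
elevation for the spot's type, a 2**(+/-beta) aging effect in old samples,
and a spatial focus factor ``1 + A * exp(-d / lambda)`` for focus-program
genes, where ``d`` is the distance to the nearest focus spot.

Everything planted is recorded in :class:`GroundTruth` so that downstream
stages can be tested for parameter recovery.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .io_preprocess import SpatialDataset

logger = logging.getLogger(__name__)

SPOT_TYPES = ("OO", "GC", "TC", "PPF", "OSE", "SC", "SMC", "IM", "MT2high")
FOLLICLE_TYPES = ("OO", "GC", "TC", "PPF")
NON_FOLLICLE_TYPES = ("OSE", "SC", "SMC", "IM", "MT2high")

# canonical ovary marker symbols seeded into each synthetic marker set
CANONICAL_MARKERS = {
    "OO": ["DDX4", "GDF9"],
    "GC": ["INHBB", "AMH"],
    "TC": ["STAR", "CYP17A1"],
    "PPF": [],
    "OSE": ["ALDH1A1", "KRT19"],
    "SC": ["TCF21", "ARID5B"],
    "SMC": ["TAGLN", "ACTG2"],
    "IM": ["CD68", "LYZ"],
    "MT2high": ["MT2", "TIMP1"],
}

FOCUS_PATHWAYS = ("SASP", "fibrosis", "senescence", "inflammatory_response")
DECOY_PATHWAYS = (
    "autophagy",
    "DNA_repair",
    "lipid_storage",
    "ROS",
    "apoptosis",
    "UPR",
    "TGFb_signaling",
)

# relative propensity of each spot type to carry aging effects: somatic
# non-follicle types (SMC, OSE, MT2high) are the most susceptible, the
# stroma less so, and the oocyte transcriptome is comparatively stable
AGING_SUSCEPTIBILITY = {
    "SMC": 2.0,
    "OSE": 2.0,
    "MT2high": 2.0,
    "TC": 1.0,
    "GC": 1.0,
    "IM": 1.0,
    "PPF": 1.0,
    "SC": 0.75,
    "OO": 0.5,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic ovary study.

    Defaults describe the standard simulated study: 8 samples (4 young,
    4 old) of 20 x 20 hex lattices (~3,200 spots total), 2,000 genes,
    aging log2 fold change beta = 1, focus amplitude A = 3 and decay length
    lambda = 300 um, with two senescence foci per old sample.
    """

    grid_rows: int = 20
    grid_cols: int = 20
    pitch_um: float = 100.0
    n_follicles: int = 3
    n_foci: int = 2                   # foci per old sample
    young_focus_ratio: float = 0.5    # young foci = round(ratio * n_foci)
    decay_length_um: float = 300.0    # lambda
    age_log2fc: float = 1.0           # beta
    focus_amplitude: float = 3.0      # A
    nb_dispersion: float = 2.0        # theta
    marker_fold: float = 4.0
    n_genes: int = 2000
    n_marker_genes_per_type: int = 50
    n_aging_genes: int = 100
    n_pathway_genes: int = 50
    aging_types_per_gene: tuple[int, int] = (2, 5)
    n_samples_per_group: int = 4
    seed: int = 0

    def validate(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.pitch_um <= 0:
            raise ValueError("pitch_um must be positive")
        if self.decay_length_um <= 0:
            raise ValueError("decay_length_um must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_follicles < 0 or self.n_foci < 0:
            raise ValueError("n_follicles and n_foci must be >= 0")
        if not 0 <= self.young_focus_ratio <= 1:
            raise ValueError("young_focus_ratio must be in [0, 1]")
        if self.n_samples_per_group < 1:
            raise ValueError("n_samples_per_group must be >= 1")
        lo, hi = self.aging_types_per_gene
        if not 1 <= lo <= hi <= len(SPOT_TYPES):
            raise ValueError("aging_types_per_gene must satisfy 1 <= lo <= hi <= 9")
        if self.n_follicles > 0 and (self.grid_rows < 8 or self.grid_cols < 8):
            raise ValueError(
                "grid must be at least 8x8 to hold a concentric follicle "
                f"(got {self.grid_rows}x{self.grid_cols})"
            )
        budget = (
            len(SPOT_TYPES) * self.n_marker_genes_per_type
            + self.n_aging_genes
            + len(FOCUS_PATHWAYS + DECOY_PATHWAYS) * self.n_pathway_genes
        )
        if budget > self.n_genes:
            raise ValueError(
                f"gene budget too small: {budget} program genes requested but "
                f"n_genes={self.n_genes}"
            )

    @property
    def n_young_foci(self) -> int:
        return int(round(self.young_focus_ratio * self.n_foci))


@dataclass
class GroundTruth:
    """Record of everything the generator planted."""

    layout: pd.DataFrame
    aging_up_genes: list[str]
    aging_down_genes: list[str]
    aging_log2fc: float
    aging_targets: dict[str, list[str]]
    target_types: list[str]
    focus_spot_ids: list[str]
    focus_program_genes: list[str]
    decay_length_um: float
    focus_amplitude: float
    marker_sets: dict[str, list[str]]
    pathway_sets: dict[str, list[str]]
    aging_gene_list: list[str]
    lr_pairs: list[tuple[str, str]]
    aged_lr_pairs: list[tuple[str, str, str, str]] = field(default_factory=list)
    baseline_means: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "layout": self.layout.to_dict(orient="list"),
            "aging_up_genes": self.aging_up_genes,
            "aging_down_genes": self.aging_down_genes,
            "aging_log2fc": self.aging_log2fc,
            "aging_targets": self.aging_targets,
            "target_types": self.target_types,
            "focus_spot_ids": self.focus_spot_ids,
            "focus_program_genes": self.focus_program_genes,
            "decay_length_um": self.decay_length_um,
            "focus_amplitude": self.focus_amplitude,
            "marker_sets": self.marker_sets,
            "pathway_sets": self.pathway_sets,
            "aging_gene_list": self.aging_gene_list,
            "lr_pairs": [list(p) for p in self.lr_pairs],
            "aged_lr_pairs": [list(p) for p in self.aged_lr_pairs],
            "baseline_means": self.baseline_means,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        payload["layout"] = pd.DataFrame(payload["layout"])
        payload["lr_pairs"] = [tuple(p) for p in payload["lr_pairs"]]
        payload["aged_lr_pairs"] = [tuple(p) for p in payload.get("aged_lr_pairs", [])]
        return cls(**payload)


# ---------------------------------------------------------------------------
# hex lattice helpers ("odd-r" offset rows, odd rows shifted +pitch/2 in x)
# ---------------------------------------------------------------------------

def _offset_to_axial(row: int, col: int) -> tuple[int, int]:
    q = col - (row - (row & 1)) // 2
    return q, row


def hex_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Lattice distance between two (row, col) offset coordinates."""
    aq, ar = _offset_to_axial(*a)
    bq, br = _offset_to_axial(*b)
    return (abs(aq - bq) + abs(ar - br) + abs(aq + ar - bq - br)) // 2


_AXIAL_DIRS = ((1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1))


def _axial_to_offset(q: int, r: int) -> tuple[int, int]:
    return r, q + (r - (r & 1)) // 2


def hex_neighbors(row: int, col: int) -> list[tuple[int, int]]:
    """The six lattice neighbours of a spot (may fall outside the grid)."""
    q, r = _offset_to_axial(row, col)
    return [_axial_to_offset(q + dq, r + dr) for dq, dr in _AXIAL_DIRS]


def _hex_disc(center: tuple[int, int], radius: int) -> list[tuple[int, int]]:
    q0, r0 = _offset_to_axial(*center)
    out = []
    for dq in range(-radius, radius + 1):
        for dr in range(max(-radius, -dq - radius), min(radius, -dq + radius) + 1):
            out.append(_axial_to_offset(q0 + dq, r0 + dr))
    return out


def _hex_ring(center: tuple[int, int], radius: int) -> list[tuple[int, int]]:
    return [s for s in _hex_disc(center, radius) if hex_distance(center, s) == radius]


def _focus_shape(center: tuple[int, int]) -> list[tuple[int, int]]:
    """A compact 13-spot cluster: radius-1 disc plus the six ring-2 corners."""
    q0, r0 = _offset_to_axial(*center)
    corners = [_axial_to_offset(q0 + 2 * dq, r0 + 2 * dr) for dq, dr in _AXIAL_DIRS]
    return _hex_disc(center, 1) + corners


def spot_coordinates(row: int, col: int, pitch_um: float) -> tuple[float, float]:
    x = pitch_um * (col + 0.5 * (row % 2))
    y = pitch_um * row * np.sqrt(3.0) / 2.0
    return x, y


# ---------------------------------------------------------------------------
# tissue layout
# ---------------------------------------------------------------------------

def build_tissue_layout(
    config: SimConfig,
    n_foci: int | None = None,
    seed: int | None = None,
    sample: str = "S1",
) -> pd.DataFrame:
    """Lay out one capture area: assign a spot type to every lattice spot.

    The boundary ring (spots with fewer than six in-grid neighbours) is OSE;
    follicles are concentric discs (OO centre, GC ring, TC ring); PPF forms
    small clusters near the boundary; MT2high foci are compact 13-spot
    clusters (the first placed adjacent to a follicle when possible); SMC is
    laid down as line segments; IM is scattered; everything else is stroma.

    Deterministic for a fixed (config, seed).
    """
    config.validate()
    if n_foci is None:
        n_foci = config.n_foci
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows, cols = config.grid_rows, config.grid_cols

    spots = [(r, c) for r in range(rows) for c in range(cols)]
    in_grid = set(spots)
    assigned: dict[tuple[int, int], str] = {}

    def unassigned(cands):
        return [s for s in cands if s in in_grid and s not in assigned]

    # boundary ring -> OSE
    boundary = [s for s in spots if sum(n in in_grid for n in hex_neighbors(*s)) < 6]
    for s in boundary:
        assigned[s] = "OSE"
    boundary_set = set(boundary)
    interior = [s for s in spots if s not in boundary_set]
    dist_to_boundary = {
        s: min(hex_distance(s, b) for b in boundary) for s in interior
    }

    # follicles: OO centre, GC at distance 1, TC at distance 2
    follicle_centers: list[tuple[int, int]] = []
    if config.n_follicles > 0:
        candidates = [s for s in interior if dist_to_boundary[s] >= 3]
        candidates = [
            s for s in candidates if all(t in in_grid and t not in boundary_set for t in _hex_disc(s, 2))
        ]
        if not candidates:
            raise ValueError(
                "impossible geometry: follicle radius 2 does not fit inside "
                f"a {rows}x{cols} grid interior"
            )
        order = rng.permutation(len(candidates))
        for i in order:
            c = candidates[i]
            if len(follicle_centers) == config.n_follicles:
                break
            if all(hex_distance(c, f) >= 6 for f in follicle_centers):
                follicle_centers.append(c)
        if len(follicle_centers) < config.n_follicles:
            raise ValueError(
                f"impossible geometry: could not place {config.n_follicles} "
                f"non-overlapping follicles on a {rows}x{cols} grid"
            )
        for c in follicle_centers:
            assigned[c] = "OO"
            for s in _hex_ring(c, 1):
                assigned[s] = "GC"
            for s in _hex_ring(c, 2):
                assigned[s] = "TC"

    # PPF: three small clusters hugging the boundary
    ppf_eligible = unassigned([s for s in interior if dist_to_boundary[s] <= 2])
    for _ in range(3):
        pool = unassigned(ppf_eligible)
        if not pool:
            break
        seed_spot = pool[rng.integers(len(pool))]
        cluster = [seed_spot]
        for nb in hex_neighbors(*seed_spot):
            if len(cluster) >= 4:
                break
            if nb in in_grid and nb not in assigned and nb not in cluster and nb in dist_to_boundary and dist_to_boundary[nb] <= 2:
                cluster.append(nb)
        for s in cluster:
            assigned[s] = "PPF"

    # MT2high foci: compact 13-spot clusters
    if n_foci > 0:
        focus_centers: list[tuple[int, int]] = []
        eligible = [
            s
            for s in interior
            if dist_to_boundary[s] >= 2
            and all(t in in_grid and t not in assigned for t in _focus_shape(s))
        ]
        if not eligible:
            raise ValueError(
                "impossible geometry: no room for a 13-spot focus cluster on "
                f"a {rows}x{cols} grid with the requested follicles"
            )
        # first focus near a follicle when follicles exist
        if follicle_centers:
            near = [
                s
                for s in eligible
                if any(3 <= hex_distance(s, f) <= 5 for f in follicle_centers)
            ]
            if near:
                focus_centers.append(near[rng.integers(len(near))])
        attempts = rng.permutation(len(eligible))
        for i in attempts:
            if len(focus_centers) == n_foci:
                break
            s = eligible[i]
            if s in assigned:
                continue
            if all(hex_distance(s, f) >= 6 for f in focus_centers) and all(
                t not in assigned for t in _focus_shape(s)
            ):
                focus_centers.append(s)
        if len(focus_centers) < n_foci:
            raise ValueError(
                f"impossible geometry: only {len(focus_centers)} of {n_foci} "
                "foci fit on the grid"
            )
        for c in focus_centers:
            for s in _focus_shape(c):
                assigned[s] = "MT2high"

    # SMC: two straight line segments along a lattice axis
    for _ in range(2):
        pool = unassigned(interior)
        if not pool:
            break
        start = pool[rng.integers(len(pool))]
        dq, dr = _AXIAL_DIRS[rng.integers(len(_AXIAL_DIRS))]
        q, r = _offset_to_axial(*start)
        for step in range(8):
            s = _axial_to_offset(q + step * dq, r + step * dr)
            if s in in_grid and s not in assigned:
                assigned[s] = "SMC"

    # IM: 5% of remaining interior spots, scattered
    pool = unassigned(interior)
    n_im = max(1, int(round(0.05 * len(pool)))) if pool else 0
    if n_im:
        for i in rng.choice(len(pool), size=min(n_im, len(pool)), replace=False):
            assigned[pool[i]] = "IM"

    # stroma fills the rest
    for s in unassigned(interior):
        assigned[s] = "SC"

    records = []
    for r, c in spots:
        x, y = spot_coordinates(r, c, config.pitch_um)
        t = assigned[(r, c)]
        records.append(
            {
                "spot_id": f"{sample}_{r:02d}_{c:02d}",
                "array_row": r,
                "array_col": c,
                "x_um": x,
                "y_um": y,
                "true_type": t,
                "is_focus": t == "MT2high",
            }
        )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# gene panel
# ---------------------------------------------------------------------------

@dataclass
class _GenePanel:
    gene_ids: list[str]
    baselines: np.ndarray
    marker_sets: dict[str, list[str]]
    aging_up: list[str]
    aging_down: list[str]
    aging_targets: dict[str, list[str]]
    pathway_sets: dict[str, list[str]]
    focus_program: list[str]
    aging_gene_list: list[str]
    lr_pairs: list[tuple[str, str]]
    aged_lr_pairs: list[tuple[str, str, str, str]]

    def index_of(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=int)


def _build_gene_panel(config: SimConfig) -> _GenePanel:
    """Deterministic gene panel shared by every sample of a study.

    Program genes (markers, aging, pathway) draw their baseline means from
    log-normal(1.0, 0.5); background genes from log-normal(0.5, 1.0). The
    planted programs thus live among expressed genes, as real marker and
    aging genes do.

    Each aging gene targets a random subset of spot types (size drawn from
    ``aging_types_per_gene``), mirroring the partially shared per-type aging
    programs of real tissue, so that only a minority of aging genes shift in
    any single type.
    """
    rng = np.random.default_rng([config.seed, 990_001])
    marker_sets: dict[str, list[str]] = {}
    for t in SPOT_TYPES:
        names = list(CANONICAL_MARKERS[t])
        while len(names) < config.n_marker_genes_per_type:
            names.append(f"{t}_M{len(names) + 1:02d}")
        marker_sets[t] = names[: config.n_marker_genes_per_type]

    n_up = config.n_aging_genes // 2
    n_down = config.n_aging_genes - n_up
    aging_up = [f"AGEUP_{i + 1:03d}" for i in range(n_up)]
    aging_down = [f"AGEDN_{i + 1:03d}" for i in range(n_down)]
    lo, hi = config.aging_types_per_gene
    weights = np.array([AGING_SUSCEPTIBILITY[t] for t in SPOT_TYPES])
    aging_targets = {}
    for g in aging_up + aging_down:
        k = int(rng.integers(lo, hi + 1))
        # weighted sampling without replacement (Efraimidis-Spirakis keys)
        keys = rng.random(len(SPOT_TYPES)) ** (1.0 / weights)
        chosen = np.argsort(keys)[-k:]
        aging_targets[g] = sorted(SPOT_TYPES[i] for i in chosen)

    pathway_sets = {
        p: [f"{p}_{i + 1:02d}" for i in range(config.n_pathway_genes)]
        for p in FOCUS_PATHWAYS + DECOY_PATHWAYS
    }

    program = (
        [g for t in SPOT_TYPES for g in marker_sets[t]]
        + aging_up
        + aging_down
        + [g for p in FOCUS_PATHWAYS + DECOY_PATHWAYS for g in pathway_sets[p]]
    )
    n_background = config.n_genes - len(program)
    background = [f"BG_{i + 1:04d}" for i in range(n_background)]
    gene_ids = program + background

    # markers and aging genes are well expressed (log-normal(1.0, 0.5));
    # pathway program genes (SASP, fibrosis, ...) are low-abundance
    # transcripts (log-normal(0.3, 0.5)) as inflammatory and senescence
    # effectors typically are; background spans the full dynamic range
    n_marker_aging = len(program) - len(pathway_sets) * config.n_pathway_genes
    baselines = np.empty(config.n_genes)
    baselines[:n_marker_aging] = rng.lognormal(mean=1.0, sigma=0.5, size=n_marker_aging)
    baselines[n_marker_aging: len(program)] = rng.lognormal(
        mean=0.3, sigma=0.5, size=len(program) - n_marker_aging
    )
    baselines[len(program):] = rng.lognormal(mean=0.5, sigma=1.0, size=n_background)

    # curated aging-list stand-in: the planted aging genes plus decoys
    n_decoys = min(100, n_background)
    decoys = [background[i] for i in rng.choice(n_background, size=n_decoys, replace=False)]
    aging_gene_list = aging_up + aging_down + decoys

    # ligand-receptor table: planted marker-marker pairs plus background pairs
    planted_pairs = [
        (marker_sets["MT2high"][i + 2], marker_sets[t][i + 2])
        for i, t in enumerate(("SC", "GC", "TC", "IM", "SMC", "OSE"))
    ] + [
        (marker_sets["GC"][8], marker_sets["TC"][8]),
        (marker_sets["TC"][9], marker_sets["GC"][9]),
        (marker_sets["IM"][8], marker_sets["SC"][8]),
        (marker_sets["OSE"][9], marker_sets["SC"][9]),
    ]
    n_bg_pairs = min(200, n_background // 2 - n_decoys // 2)
    perm = rng.permutation(n_background)
    bg_pairs = [
        (background[perm[2 * i]], background[perm[2 * i + 1]])
        for i in range(max(n_bg_pairs, 0))
    ]

    # age-gained pairs: ligand and receptor are aging-up genes in their
    # targeted types, so the pair only scores high in old samples
    aged_lr_pairs: list[tuple[str, str, str, str]] = []
    used: set[str] = set()
    for sender, receiver in (("SC", "TC"), ("OSE", "IM"), ("GC", "SMC"), ("TC", "SC")):
        lig = next((g for g in aging_up if sender in aging_targets[g] and g not in used), None)
        if lig is None:
            continue
        used.add(lig)
        rec = next((g for g in aging_up if receiver in aging_targets[g] and g not in used), None)
        if rec is None:
            continue
        used.add(rec)
        aged_lr_pairs.append((lig, rec, sender, receiver))

    lr_pairs = planted_pairs + [(l, r) for l, r, _, _ in aged_lr_pairs] + bg_pairs

    focus_program = [g for p in FOCUS_PATHWAYS for g in pathway_sets[p]] + aging_up
    return _GenePanel(
        gene_ids=gene_ids,
        baselines=baselines,
        marker_sets=marker_sets,
        aging_up=aging_up,
        aging_down=aging_down,
        aging_targets=aging_targets,
        pathway_sets=pathway_sets,
        focus_program=focus_program,
        aging_gene_list=aging_gene_list,
        lr_pairs=lr_pairs,
        aged_lr_pairs=aged_lr_pairs,
    )


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

def expected_mean_matrix(
    layout: pd.DataFrame,
    config: SimConfig,
    panel: _GenePanel,
    old: bool,
) -> np.ndarray:
    """Noise-free negative-binomial mean matrix (genes x spots) for one sample."""
    n_spots = len(layout)
    mu = np.repeat(panel.baselines[:, None], n_spots, axis=1)

    types = layout["true_type"].to_numpy()
    for t in SPOT_TYPES:
        cols = np.flatnonzero(types == t)
        if cols.size:
            mu[np.ix_(panel.index_of(panel.marker_sets[t]), cols)] *= config.marker_fold

    # the MT2high identity program includes the senescence pathway programs
    # (inflammation / SASP / fibrosis / senescence), as in the tissue
    mt2_cols = np.flatnonzero(types == "MT2high")
    if mt2_cols.size:
        pathway_idx = panel.index_of(
            [g for p in FOCUS_PATHWAYS for g in panel.pathway_sets[p]]
        )
        mu[np.ix_(pathway_idx, mt2_cols)] *= config.marker_fold

    if old and config.age_log2fc != 0:
        beta = config.age_log2fc
        for t in SPOT_TYPES:
            cols = np.flatnonzero(types == t)
            if not cols.size:
                continue
            up_t = [g for g in panel.aging_up if t in panel.aging_targets[g]]
            down_t = [g for g in panel.aging_down if t in panel.aging_targets[g]]
            if up_t:
                mu[np.ix_(panel.index_of(up_t), cols)] *= 2.0 ** beta
            if down_t:
                mu[np.ix_(panel.index_of(down_t), cols)] *= 2.0 ** (-beta)

    focus_xy = layout.loc[layout["is_focus"], ["x_um", "y_um"]].to_numpy()
    if len(focus_xy):
        tree = cKDTree(focus_xy)
        d, _ = tree.query(layout[["x_um", "y_um"]].to_numpy())
        factor = 1.0 + config.focus_amplitude * np.exp(-d / config.decay_length_um)
        mu[panel.index_of(panel.focus_program)] *= factor[None, :]
    return mu


def _sample_counts(mu: np.ndarray, theta: float, rng: np.random.Generator) -> np.ndarray:
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p)


def sample_plan(config: SimConfig) -> list[tuple[str, str, int]]:
    """(sample name, age group, foci count) for every sample of the study."""
    plan = []
    for i in range(config.n_samples_per_group):
        plan.append((f"Y{i + 1}", "young", config.n_young_foci))
    for i in range(config.n_samples_per_group):
        plan.append((f"O{i + 1}", "old", config.n_foci))
    return plan


def build_layouts(config: SimConfig) -> dict[str, pd.DataFrame]:
    """Per-sample tissue layouts; old samples receive ``n_foci`` foci and
    young samples ``round(young_focus_ratio * n_foci)``."""
    layouts = {}
    for idx, (name, _age, foci) in enumerate(sample_plan(config)):
        layouts[name] = build_tissue_layout(
            config, n_foci=foci, seed=np.random.default_rng([config.seed, 100 + idx]).integers(2**31), sample=name
        )
    return layouts


def simulate_counts(
    layouts: Mapping[str, pd.DataFrame],
    ages: Mapping[str, str],
    config: SimConfig,
) -> tuple[SpatialDataset, GroundTruth]:
    """Draw negative-binomial counts for every sample and assemble the study.

    Each sample uses its own RNG stream derived from the master seed and the
    sample index, so results do not depend on iteration order. Samples are
    tiled along x with a wide gap so spot coordinates are globally unique
    and cross-sample distances are much larger than any decay length.
    """
    config.validate()
    panel = _build_gene_panel(config)
    names = list(layouts)
    x_step = config.pitch_um * (config.grid_cols + 50)

    blocks, layout_frames = [], []
    for idx, name in enumerate(names):
        layout = layouts[name].copy()
        age = ages[name]
        if age not in ("young", "old"):
            raise ValueError(f"unknown age group {age!r} for sample {name!r}")
        mu = expected_mean_matrix(layout, config, panel, old=(age == "old"))
        rng = np.random.default_rng([config.seed, 1 + idx])
        counts = _sample_counts(mu, config.nb_dispersion, rng)
        blocks.append(sp.csr_matrix(counts))
        layout["x_um"] = layout["x_um"] + idx * x_step
        layout["sample"] = name
        layout["age_group"] = age
        layout_frames.append(layout)

    layout_all = pd.concat(layout_frames, ignore_index=True)
    counts_all = sp.hstack(blocks, format="csr")
    spot_ids = layout_all["spot_id"].to_numpy(dtype=object)
    coords = layout_all[["x_um", "y_um"]].to_numpy(dtype=float)
    meta = layout_all.set_index("spot_id")[["sample", "age_group"]]
    meta.index.name = None
    ds = SpatialDataset(counts_all, np.array(panel.gene_ids, dtype=object), spot_ids, coords, meta)

    truth = GroundTruth(
        layout=layout_all,
        aging_up_genes=list(panel.aging_up),
        aging_down_genes=list(panel.aging_down),
        aging_log2fc=config.age_log2fc,
        aging_targets={g: list(ts) for g, ts in panel.aging_targets.items()},
        target_types=list(SPOT_TYPES),
        focus_spot_ids=layout_all.loc[layout_all["is_focus"], "spot_id"].tolist(),
        focus_program_genes=list(panel.focus_program),
        decay_length_um=config.decay_length_um,
        focus_amplitude=config.focus_amplitude,
        marker_sets={k: list(v) for k, v in panel.marker_sets.items()},
        pathway_sets={k: list(v) for k, v in panel.pathway_sets.items()},
        aging_gene_list=list(panel.aging_gene_list),
        lr_pairs=list(panel.lr_pairs),
        aged_lr_pairs=list(panel.aged_lr_pairs),
        baseline_means={g: float(b) for g, b in zip(panel.gene_ids, panel.baselines)},
    )
    return ds, truth


def simulate_dataset(config: SimConfig) -> tuple[SpatialDataset, GroundTruth]:
    """Build per-sample layouts and simulate the full multi-sample study."""
    layouts = build_layouts(config)
    ages = {name: age for name, age, _ in sample_plan(config)}
    return simulate_counts(layouts, ages, config)


# ---------------------------------------------------------------------------
# disk output
# ---------------------------------------------------------------------------

def write_dataset(ds: SpatialDataset, truth: GroundTruth | None, path: str | Path) -> None:
    """Write the Visium-dialect file set (and truth.json when truth given)."""
    if ds.n_spots == 0 or ds.n_genes == 0:
        raise ValueError("refusing to write an empty dataset")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(ds.counts.astype(int)), field="integer")
    pd.DataFrame({0: ds.gene_ids, 1: ds.gene_ids, 2: "Gene Expression"}).to_csv(
        path / "features.tsv", sep="\t", header=False, index=False
    )
    pd.DataFrame({0: ds.spot_ids}).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)

    if truth is not None:
        lay = truth.layout.set_index("spot_id").loc[ds.spot_ids]
        arr_row = lay["array_row"].to_numpy()
        arr_col = lay["array_col"].to_numpy()
    else:
        arr_row = np.zeros(ds.n_spots, dtype=int)
        arr_col = np.arange(ds.n_spots)
    pd.DataFrame(
        {
            "barcode": ds.spot_ids,
            "in_tissue": 1,
            "array_row": arr_row,
            "array_col": arr_col,
            "x_um": ds.coords[:, 0],
            "y_um": ds.coords[:, 1],
        }
    ).to_csv(path / "tissue_positions.csv", index=False)

    meta = ds.meta.copy()
    meta.insert(0, "barcode", ds.spot_ids)
    meta.to_csv(path / "metadata.tsv", sep="\t", index=False)

    if truth is not None:
        truth.to_json(path / "truth.json")


def write_gene_sets(truth: GroundTruth, path: str | Path) -> None:
    """Emit the study's gene-set inputs: marker/pathway/aging GMTs and the
    ligand-receptor pair table."""
    from .scoring import write_gmt

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_gmt(truth.marker_sets, path / "markers.gmt", description="synthetic marker set")
    write_gmt(truth.pathway_sets, path / "pathways.gmt", description="synthetic pathway set")
    write_gmt(
        {"aging_atlas_like": truth.aging_gene_list},
        path / "aging.gmt",
        description="synthetic curated aging gene list",
    )
    pd.DataFrame(truth.lr_pairs, columns=["ligand", "receptor"]).to_csv(
        path / "lr_pairs.tsv", sep="\t", index=False
    )
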