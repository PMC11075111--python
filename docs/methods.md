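# Methods

## The analysis model

`ovaspot` operates on spot-resolved count data: each observation is a
capture spot (~55 µm, several cells) on a hexagonal lattice, carrying a
sparse gene-count vector, a position in µm, and sample/age metadata. The
pipeline's claims are about *where* aging-associated transcription
concentrates, so every statistic is either per-spot (module scores, the
aging score) or about sets of spots (differential expression per spot
type, top-quantile hotspot sets, ring-binned decay curves).

Normalization is library-size scaling to a fixed total followed by a log2
transform, `x = log2(1 + s·c/total)` with scale factor `s = 6000`. The
per-spot identity `Σ_g (2^x − 1) = s` is exact by construction and is
asserted in the tests. Fold changes are computed on de-logged normalized
means with a pseudocount of 1 (`log2((m_a + 1)/(m_b + 1))`), which shrinks
fold changes of weakly expressed genes toward zero — deliberate, since
unshrunken ratios of near-zero means are noise.

Module scores use the control-gene scheme standard in single-cell
signature scoring: genes are ranked by average normalized expression and
split into 24 equal-count bins (ties broken by gene id so binning is
deterministic); each set gene contributes 100 control draws from the other
genes of its bin, without replacement when the bin allows it, with
replacement otherwise. A gene is never its own control. Scores are
therefore location-invariant and centre at zero for random sets on
exchangeable data. Control draws are seeded per set by hashing the set
name with the master seed, so reordering a collection permutes columns
without changing values.

Differential expression uses the Wilcoxon rank-sum test: exact enumeration
over all group assignments when the pooled sample size is at most 12
(correct under ties), and the tie- and continuity-corrected normal
approximation otherwise. The exact two-sided p-value is the fraction of
assignments whose U statistic deviates from its null mean at least as much
as the observed one, which equals 1 for identical samples.
Benjamini–Hochberg correction runs across genes *within* each spot type;
the per-type DEG tables this produces are the natural input to the
shared-DEG and OSAG intersections. Spot types with fewer than 3 spots in
either age group are skipped with a warning rather than tested.

Hotspots are the strict intersection of the top `ceil(0.05·N)` spots of
the aging score and of every selected pathway (PCOA) score, pooled across
samples. Ranking ties break by descending score then lexicographic
barcode, so the top sets have exactly the nominal cardinality. A looser
`aging_and_any` mode (aging top set ∩ union of pathway top sets) is
provided because "conjoint analysis" of co-localized score peaks admits
both readings.

### Distance decay and its analysis window

For each non-hotspot spot, the distance to the hotspot set is the minimum
Euclidean distance to any hotspot spot; spots are binned into 100 µm rings
(one lattice pitch), rings with fewer than 5 spots are dropped, and
Pearson correlation relates ring midpoints to ring mean scores. Two window
choices matter:

- A pure exponential field `exp(−d/λ)` sampled over many decay lengths has
  ring-mean correlation around −0.82, not −1: the flat far tail carries no
  linear information. Over a window of 2.5 decay lengths the closed-form
  correlation is ≈ −0.97. The planted-field checks therefore evaluate the
  decay statistic within 2.5·λ.
- On pooled multi-sample data, samples are tiled along x with a wide gap;
  distances beyond the hotspot neighbourhood mostly cross sample
  boundaries and carry no decay signal. The workflow therefore evaluates
  decay within 1,500 µm (5 e-folding lengths of the default λ = 300 µm,
  15 lattice pitches) by default. `distance_decay` itself defaults to no
  cap; the window is an explicit argument.

### Ligand–receptor permutation test

A candidate (ligand, receptor, sender type, receiver type) is tested only
if ligand and receptor are expressed (count ≥ 1) in at least 10% of
sender and receiver spots respectively. The score is the mean of the two
type-mean normalized expressions; the null shuffles type labels over all
annotated spots 1,000 times; `p = (1 + #{null ≥ obs})/(1 + n_perm)`, so p
is bounded below by 1/1001 and the test is deterministic under a fixed
seed. Age contrast runs the test separately per age group and takes set
differences of the significant keys.

One calibration caveat is inherent to this family of tests: on data with
real cell-type structure, library-size normalization couples type labels
to the normalized level of *every* gene, so label permutation is not an
exact null even for genes with no planted type association. Calibration
(p-value uniformity) is therefore checked on exchangeable data — no
marker, aging or focus structure — where the permutation null is the true
data-generating symmetry.

## The synthetic ovary generator

The generator emulates the structure of an eight-sample (4 young, 4 old)
Visium study of primate ovary at desk scale and is the test bed for every
downstream stage. Defaults, with units and rationale:

| parameter | default | meaning |
|---|---|---|
| `grid_rows × grid_cols` | 20 × 20 | one capture area per sample (400 spots; study ≈ 3,200) |
| `pitch_um` | 100 | Visium centre-to-centre spot pitch |
| `n_genes` | 2,000 | desk-scale panel (≈ median genes per spot in real data) |
| `n_follicles` | 3 | concentric follicles: OO centre, GC ring, TC ring |
| `n_foci` | 2 | senescence foci per old sample (13-spot MT2high clusters) |
| `young_focus_ratio` | 0.5 | young samples carry half as many foci — MT2high accumulates with age |
| `decay_length_um` (λ) | 300 | e-folding length of the focus expression field |
| `focus_amplitude` (A) | 3 | focus field is `1 + A·exp(−d/λ)`, d = distance to nearest focus spot |
| `age_log2fc` (β) | 1.0 | planted log2 fold change of aging genes in old samples |
| `nb_dispersion` (θ) | 2 | negative-binomial size; Var = µ + µ²/θ |
| `marker_fold` | 4 | marker elevation of a type's identity genes |
| `n_marker_genes_per_type` | 50 | identity program per type |
| `n_aging_genes` | 100 | 50 up, 50 down |
| `n_pathway_genes` | 50 | per pathway set, 11 sets (4 focus + 7 decoys) |
| `aging_types_per_gene` | (2, 5) | each aging gene targets 2–5 spot types |

Counts are `NB(µ, θ)` with
`µ = baseline · marker_fold^[marker] · 2^(±β·[aging, old, targeted type]) ·
(1 + A·exp(−d/λ))^[focus program]`. Each sample draws from its own RNG
stream derived from the master seed and sample index, so results are
independent of iteration order. Samples are tiled along x with a 5,000 µm
gap; coordinates are globally unique and cross-sample distances dwarf λ.

Design choices that the pilot phase fixed, and why:

- **Aging effects target type subsets.** Each aging gene affects 2–5
  types, drawn with susceptibility weights (SMC, OSE, MT2high highest;
  stroma lower; oocyte lowest — the oocyte transcriptome is the most
  age-stable compartment in this tissue). This reproduces the
  partially-shared per-type aging programs seen in real ovary data and
  keeps within-type age variation below type-identity variation, so that
  unsupervised clustering resolves types, not type × age products. It also
  gives the shared-DEG analysis non-trivial structure.
- **MT2high identity includes the senescence programs.** The hotspot spot
  type is, biologically, *defined* by elevated inflammation/SASP/fibrosis
  expression; in the generator the four focus pathway programs receive the
  marker-fold elevation in MT2high spots on top of the spatial field.
  Without this, focus-cluster members and their first-ring neighbours are
  statistically interchangeable under λ = 300 µm and top-quantile
  intersection cannot separate them.
- **Pathway programs are low-abundance.** Pathway genes draw baselines
  from log-normal(0.3, 0.5) (markers and aging genes from
  log-normal(1.0, 0.5), background from log-normal(0.5, 1.0)). At desk
  scale, a strongly expressed 200-gene elevated program would inflate
  member-spot library sizes several-fold and library-size normalization
  would then erase the planted aging-score elevation — an artifact a
  20,000-gene transcriptome does not show. Keeping the elevated programs
  a small share of the library preserves realistic normalization
  behaviour; it also matches the low abundance of inflammatory and
  senescence effector transcripts.
- **Program genes are expressed.** Marker/aging/pathway baselines exclude
  the barely-detectable regime, as real curated gene sets do; planted
  effects are therefore detectable in principle, and failures to recover
  them indict the method, not the data.
- **Clustering granularity.** The default Leiden resolution is 0.2. At
  resolution 1.0 the communities track within-type substructure (the age
  shift and the focus-proximity gradient — both real, planted structure),
  which the cluster-then-annotate design deliberately treats as one spot
  type. 0.2 recovers the nine-type partition across pilot seeds while
  leaving the two-blob and separability contracts intact.
- **PPF is a distinct program.** Real primordial/primary-follicle spots
  express oocyte and granulosa markers; the generator gives PPF its own
  disjoint marker set. The annotation tie rule (top-two marker scores
  within 0.01 → ambiguous) is still exercised by dedicated fixtures, but
  synthetic PPF recovery does not test the real marker-overlap ambiguity.
- **Age-gained interactions.** The ligand–receptor table plants pairs of
  aging-up genes in their targeted types: flat in young samples, jointly
  elevated in old, hence significant only in the aged group. MT2high
  marker pairs, by contrast, are significant in both groups (young
  MT2high spots are fewer but identical in profile), which is why gained
  pairs are not keyed to the hotspot type in the synthetic study.

### What the generator does not emulate

No batch or sample effects (integration is out of scope), no per-spot
cell-count mixing or deconvolution, no spatial autocorrelation beyond the
focus field, no gene–gene correlation beyond the planted programs, a
single NB dispersion for all genes and types, and no tissue image. Tests
passing on this generator show the pipeline recovers the planted effects
under its stated noise model; they do not certify behaviour under batch
structure, segmentation artifacts, or overdispersion heterogeneity of
real data.

## Numerical and edge-case conventions

- All randomness flows from integer seeds through `numpy` generators;
  per-sample and per-set streams are derived, never shared.
- HVG ranking, expression binning and top-quantile ranking all break ties
  lexicographically by gene/barcode id — every ranking in the package is
  deterministic.
- `qc_filter` is one pass (genes, then zero-count spots) and idempotent.
- Degenerate inputs raise with named constraints: zero-total spots at
  normalization, empty groups in rank-sum tests, constant vectors in
  Pearson correlation, empty hotspot sets, unwritable or incomplete
  dataset directories (missing files, duplicate or unaligned barcodes are
  distinct errors).
- `distance_decay` reports NaN correlation (with a warning) for constant
  ring means or fewer than 3 rings rather than raising.
- OSAG direction conflicts resolve by majority of supporting spot types;
  ties are dropped and logged.

## Problem sizes

The test suite and the acceptance script run the full pipeline on studies
of ~3,200 spots × 2,000 genes (eight samples), the generator's default
study size; the permutation test uses 1,000 permutations over ~200
background pairs; oracle-equivalence checks run on enumerable sizes
(pooled n ≤ 12, 6 × 4 score fixtures, 10,000-spot quantile fixtures).
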