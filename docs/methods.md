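# Methods

## Preprocessing

Input is a cells × genes UMI count matrix (MatrixMarket triplets with
barcode/feature sidecars, both 10x genes-as-rows and transposed dialects
accepted via an orientation flag) plus a gene annotation assigning every
gene a chromosome class (MT / X / Y / autosome) and per-cell condition
labels.  Filtering applies the cell rule first (≥ 500 detected genes,
inclusive, evaluated on the input matrix), then the gene rule (detected in
strictly more than 10 of the retained cells), one pass each.  The order
matters only marginally in practice, but fixing it makes the report
deterministic; a second pass with the same thresholds removes nothing
(tested).  "Detected" means count > 0 — the UMI convention.

Normalization divides each cell by `total_c / median(totals)` (standard
midpoint median over cells) and applies log2(x + 1).  After scaling, every
cell's pre-log total equals the median raw total exactly (checked to
1e-9 relative tolerance); the transform is monotone within a cell, so rank
structure is preserved.  Cells with zero totals must be filtered first —
normalization refuses them rather than guessing.

## Permutation typing

All scores are computed on the normalized log2 values, not raw counts:
downstream analyses operate on the normalized layer, and using the same
layer keeps the enrichment score comparable with the expression values the
marker and DEG callers see.

For each cell and marker set of size *k*, the background is the mean of
*k* expression values drawn uniformly without replacement from the cell's
own vector, repeated `n_perm` (1000) times — equivalent to shuffling the
cell's values onto the marker slots.  ES is observed mean over background
mean; the empirical FDR counts backgrounds *strictly* greater than the
observed mean, with no pseudocount, so every FDR is a multiple of
1/`n_perm` and, at the default 0.001 threshold, a cell passes only when
zero of the 1000 permutations beat it.  Degenerate cells: a zero background
with positive signal scores +inf (passes the ES rule), a zero signal scores
0 (fails) — all-zero cells can never be typed.

The reference implementation (`assign_cell_type`) draws a fresh background
per cell.  The batch path (`type_cells`) draws one panel of `n_perm`
gene subsets per distinct set size per run, with the run seed, and applies
it to every cell's own expression vector; this mirrors the design of the
shared 500-gene negative control (drawn once per run, shared by all cells,
keeping control ES comparable across cells) and turns the background into a
single dense matrix product — the 1000-cell null-calibration experiment
runs in seconds on one core.  Marginally, each cell's statistics are
unchanged; only the (irrelevant) cross-cell correlation of backgrounds
differs.  Both paths are deterministic given the seed, and a spot-check
test asserts they agree on the final labels.

Assignment: candidates must satisfy marker fraction > 0.20, FDR < 0.001
and ES ≥ 5; the highest-ES candidate wins; a best candidate scoring below
the negative-control ES is demoted to `random_others`; no candidate means
`no_type_match`.  Ties on ES (measure-zero with continuous data) resolve
to the later type in panel order.

### Consistency filter

Published pipelines of this style remove visually separated cells after
inspecting the embedding; this package replaces the visual step with an
explicit rule so the removal is reproducible.  Per assigned type, the
type's cells are density-clustered in the 2-D embedding with DBSCAN using
an adaptive radius (3× the median distance to the 10th nearest same-type
neighbour), which is invariant to the embedding's scale and — unlike
excess-of-mass HDBSCAN — keeps a single Gaussian-like blob intact instead
of shaving its tails into noise.  Cells in noise, in clusters smaller than
`min_cluster_size`, or outside the type's largest cluster are flagged, and
whole clusters are flagged when a k-NN vote over all cells shows the type
is not the locally dominant label.  Types with fewer cells than
`min_cluster_size` are left unflagged (insufficient evidence).  The filter
only flags; removal is the caller's decision.

## Per-cell attributes

The Gini index is computed over the cell's expressed (value > 0)
normalized values with the rank-weighted estimator
`G = (1/n)(n + 1 − 2 Σᵢ (n + 1 − i) yᵢ / Σᵢ yᵢ)` (y ascending), no
small-sample correction.  It is algebraically identical to the
mean-absolute-difference form `Σᵢⱼ|yᵢ − yⱼ| / (2n²ȳ)`; the test suite
checks agreement to 1e-12 on a thousand random vectors, together with
scale invariance and the transfer (inequality-increasing) property.  The
function itself tolerates zeros so the closed forms (equal vector → 0,
one-hot length n → (n−1)/n) evaluate directly; the attribute pipeline
applies the expressed-genes restriction before calling it.

Chromosome-class percentages are computed on raw UMIs ("UMIs mapped to"),
never normalized values, and the class counts come from the annotation as
data — nothing is hard-coded, since MT/X/Y gene counts are
annotation-specific.  Diversity is per cell: 1 − mean Pearson r against
every other cell of the same assigned type; singleton types are undefined
(NaN), and zero-variance cells are excluded from the means with a warning
rather than silently contributing r = 0.  Gene-vs-attribute correlations
(e.g. an *Asxl2*-like repressor against detected-gene count) are Pearson r
restricted to cells expressing the gene, pooled and per type stratum;
strata under 3 expressing cells are skipped.

## Marker and DEG calling

Both callers use the classic pooled-variance two-sided Student's t-test
(`scipy.stats.ttest_ind`, equal variances — "Student", not Welch), with
sentinels for the zero-pooled-variance degenerate cases (equal means → p=1,
unequal → p=0).  log2 fold change is the *difference of group means of the
already-log2 values* — the data are log-transformed upstream and no
pseudocount is defined, so a ratio-of-means alternative would be a
different statistic; users comparing with count-scale folds should note
this compresses large folds at low expression.  No multiple-testing
correction is applied beyond the fixed p < 1e-10 cutoff — the procedure is
a hard threshold rule, not an FDR procedure.

Marker criteria, in order: pct_in ≥ 0.20; detection-rate difference
pct_in − pct_out ≥ 0.10 (the "≥10% detected for the given type vs others"
wording is ambiguous — a config switch `pct_rule="overall"` provides the
alternative reading "detected in ≥10% of all cells"); p < 1e-10;
log2FC ≥ 2; overall mean above the median of all genes' overall means.
DEG criteria within a type: p < 1e-10; |log2FC| ≥ 1 (both directions are
reported, so the absolute value is thresholded and the sign becomes the
up/down call in the second condition); the same overall-mean rule,
evaluated over the type's cells.  All flags are evaluated for every gene
and reported individually, so relaxing any single threshold can only grow
the passing set (tested per parameter).

## Synthetic data generator

Counts are gamma-Poisson (negative binomial, shared size parameter r = 2):
gene g in cell c has expectation `lib_c · w_{cg} / Σ_g w_{cg}` with
lognormal(0, 1) base gene weights and lognormal library sizes
(median 1200 UMIs, σ_log 0.35) over 3000 genes — a deliberately
downsampled transcriptome whose per-gene depth (~0.4 UMIs/gene, ~900
detected genes per cell) matches the sparsity regime of real droplet data,
which is what makes the permutation background small relative to marker
signal.  Planted markers (20 per type) get base weights from a narrow,
well-expressed band (lognormal(2.2, 0.15)), as curated lineage panels do
(canonical markers such as *Prm2* are among the strongest genes in their
type), and are multiplied by 2^3 in their own type.  Condition effects
scale programmed genes (base ≈ 6 counts at the median library) by
2^(±2) in the perturbed condition — planting at the DEG caller's literal
minimum |log2FC| = 1 would be undetectable after the log-scale compression
described above, so programmed effects sit at 2 on the count scale, which
measures ≈ 1.5 on the log scale.  Doublets sum two singlet expectation
profiles and rescale the total to 1.4× the mean library size.  The default
composition encodes an adult-testis mix dominated by elongating spermatids
(50.4% normoxia) and shifts it under hypoxia (42.4% elongating, round
spermatids 8.8% → 11.2%), so the pipeline's typed per-type percentages
mirror the direction of a real composition shift across seeds.

The optional attribute coupling plants a "repressor": a latent uniform per
cell tempers half the gene weights (`w^(1+s(u−1/2))`) while scaling the
coupled gene by `2^(a(2u−1))`, producing a negative correlation between
the gene's expression and the detected-gene count that the correlation
report recovers with the planted sign.

What the generator does *not* emulate: batch effects beyond condition,
ambient RNA, gene-gene correlation modules, continuous differentiation
trajectories (types are discrete), or empirical mean-variance trends
beyond the single shared dispersion.  Passing tests therefore demonstrate
correctness of the statistical machinery under a clean generative model,
not robustness to every artifact of real libraries.

## Pipeline, determinism and glue stages

UMAP (n_neighbors 100, n_components 2, min_dist 0, random init, Euclidean,
random_state 123, 1000 epochs) and HDBSCAN (min_cluster_size 100) are
pluggable backends, contract-tested (shape, determinism, separation /
blob-count sanity) but not re-implemented; a PCA backend offers a fast
deterministic embedding alternative.  One run seed controls the generator,
the permutation subsets, the control-gene draw and (unless overridden) the
embedding state.  The run manifest records versions, seed, all thresholds,
per-stage row counts and SHA-256 hashes of every output; it contains no
timestamps, and the manifest hash excludes the output directory, so
identical (config, seed) runs are byte-identical wherever they write.
Tabular outputs carry a `#` comment line with the run id (a hash of the
configuration minus the output path).

Problem sizes used by the test suite and the acceptance script — 5 cell
types, 100–300 cells per type and condition, 3000 genes (8000 for the
negative-control inflation experiment), 20 seeds for the composition
mirror — were chosen as the smallest sizes at which the planted effects
are comfortably separated from sampling noise under the generative model
above.

## Known limitations

* With 1000 permutations the smallest nonzero FDR is 0.001, so the
  FDR < 0.001 criterion is exactly "no permutation exceeded the signal";
  finer thresholds require more permutations.
* ES is undefined-by-sentinel (+inf) for cells whose background mean is
  zero; such cells only arise in near-empty matrices that the filters
  would normally remove.
* The log-scale fold-change definition compresses count-scale folds at low
  expression (a 4× drop in a gene at 1–2 UMIs measures well under
  log2FC = 2); threshold choices should account for this.
* The consistency filter's DBSCAN radius heuristic assumes the embedding
  places most of a type in one dense region; pathological embeddings
  (e.g. a type split across two equal distant islands) flag the smaller
  half by construction.
* Marker panels are user-supplied; the bundled 22-gene lineage panel is
  illustrative, not a validated annotation reference.
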