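# Methods

This note documents the models implemented in `xenopsc`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that matter for reproducibility.

## Species demultiplexing

Each barcode's human and mouse UMI totals are taken over the corresponding
genome blocks of the combined reference; the transgene is excluded from
both totals because it belongs to neither genome. With
`f = human/(human+mouse)`, the call is human if `f >= t_high` (default
0.9), mouse if `f <= t_low` (default 0.1), otherwise ambiguous; zero-total
cells are ambiguous. The 0.9/0.1 cutoffs are standard barnyard practice —
genuine singlets sit near 0 or 1, and ambient contamination of a few
percent does not cross them — and both are exposed in the API and CLI.
Ambiguous cells (which include most heterotypic doublets) are excluded
downstream rather than modelled.

The ortholog crosscheck is an intentionally independent second classifier:
counts-per-10k log1p expression is summed over the human and the mouse
members of a one-to-one ortholog map, and the sign of the difference gives
a call. Cells with exactly tied sums are excluded from the agreement
denominator. On noise-free synthetic data the two classifiers agree on
100% of comparable cells; on real data the agreement fraction is a useful
QC number for the chosen thresholds.

## Preprocessing

Cells below `min_genes_per_cell` (default 200) are removed first, then
genes below `min_cells_per_gene` (default 3); the order matters and makes
the filter idempotent. `max_fraction_top_gene` guards against degenerate
single-gene cells and stands in for a mitochondrial-fraction filter when
genes carry no mito annotation (synthetic data). Normalisation is
counts-per-`S` (default 10⁴) followed by log1p; highly variable genes are
ranked by within-mean-bin z-scored dispersion (var/mean of the normalised
expression, 20 bins); PCA (default 30 components) centres genes and fixes
each component's sign so its largest-magnitude loading is positive, making
scores reproducible run to run. The 2-D view is seeded UMAP; graph
clustering is Leiden (RB configuration, default resolution 0.8) on an
undirected exact kNN graph with no self-loops.

## Rare-cell classification

**Integration (approaches 1–2).** All samples are pooled on the shared
gene axis, log-normalised, reduced to PCs over pooled HVGs, and each
non-reference sample is corrected toward the cultured reference by
mutual-nearest-neighbour anchors: each anchor contributes a displacement
vector (reference position minus query position), and every query cell is
shifted by a Gaussian-distance-weighted average of anchor displacements
(kernel width = median squared anchor distance). A sample sharing no
anchors passes through uncorrected with a warning; a single sample is the
identity. This is deliberately a minimal anchor scheme: the contract is
that a planted constant batch displacement shrinks at least ten-fold,
which the tests verify, not coefficient-level equivalence with any
particular integration package.

**Approach 1** labels each query cell by the majority type of its k = 15
nearest cultured cells in the joint 2-D embedding (ties → unassigned).
A k-NN vote is used because a published gating "by embedding coordinates"
is not a reproducible rule; k-NN is its closest automatic analogue.

**Approach 2** clusters the pooled graph and labels each cluster by the
majority cultured type among its members; clusters without cultured
members stay unassigned. Pooled (rather than blood-only) clustering is
used so that cluster identities are anchored by the reference cells.

**Approach 3** never integrates: a reference signature of the top N = 500
genes per cultured type (rank-sum screen at p < 0.05, ranked by p, ties by
|log-fold-change| then gene id; fewer significant genes than N → take all,
warn) restricts the blood cells, which are then split by seeded 2-means.
Each group is labelled by whichever signature's mean score dominates among
its members; a group with exactly zero margin is unassigned.

**Consensus** requires unanimity among available (non-unassigned) labels
with at least two approaches reporting; anything else is discordant. This
guarantees the consensus cPSC set is a subset of every approach's cPSC set
— an invariant the test suite asserts on every synthetic run.

**Transgene test.** Detection is ≥ 1 transgene UMI. The 2×2 table
(cPSC/cancer × detected/not) is tested with a two-sided Fisher exact test
— the package's explicit choice of test, labelled as such in reports. The
comparison population is the cancer-labelled cells of the three
mouse-model samples (which includes CTCs); cultured cells are excluded
because their uniform transgene carriage would only inflate the
denominator. The exact p is verified against brute-force hypergeometric
enumeration for every table with total ≤ 40.

**Marker ranking** between blood CTCs and cPSCs uses the same rank-sum
statistic per gene with Benjamini–Hochberg adjustment (default FDR 10%);
groups of size one fall back to the exact rank distribution with a
warning.

## Trajectory

The principal tree is a simplified reversed graph embedding: vertices are
initialised by seeded k-means in the reduced space, then alternately (i)
cells are softly assigned to vertices with a Gaussian kernel whose width
is the mean nearest-vertex squared distance, (ii) vertices move to the
smoothness-penalised weighted mean of their assigned cells and tree
neighbours (penalty weight 1), and (iii) edges are re-linked as the
Euclidean minimum spanning tree. Convergence is a maximum vertex movement
below 1e-4 (up to 200 iterations; non-convergence returns the best tree
with a warning). The spanning-tree property |E| = |V|−1 holds by
construction. Default vertex count is ⌈cells/10⌉.

The root is the leaf whose assigned cells have the highest primary-tumour
fraction (ties → more cells), encoding the biological expectation that the
trajectory originates in the primary tumour. Pseudotime is geodesic
distance along edges plus the projection of each cell on its vertex's
incoming edge direction, floored at zero; vertices of degree ≥ 3 are
branch points, and maximal unbranched segments define branch ids.

Differential tests use a quasi-Poisson GLM with log library-size offset
and a natural cubic spline of pseudotime (df = 3). The covariate is
rescaled to [0, 1] and the basis columns are standardised before IRLS —
without this the cubic terms overflow for pseudotime in embedding units.
Dispersion is moment-estimated from the Pearson chi-square of the richer
model and floored at 1, and the deviance difference divided by the
dispersion is referred to a chi-square — under a Poisson global null the
resulting p-values are uniform (KS-checked in the tests). Branch analysis
compares a shared curve against fate main + fate×spline interaction on the
cells of the two limbs below the branch point (limbs under 10 cells are
skipped with a warning); the fate direction is the limb with the higher
fitted terminal mean, and significant genes are arranged into the mirrored
pre-branch→fate heatmap and clustered by seeded k-means (default k = 4;
genes whose fitted curves diverge numerically are kept in the result table
but dropped from the heatmap).

Caveat: with small gene panels the library-size offset couples a strongly
regulated gene to every other gene's apparent expression (composition
effect); the tests therefore use panels of ≥ 200 genes, and analyses of
few selected genes should supply library sizes computed on the full
matrix.

## Cohort statistics

Counts are adjusted as `raw / n_lpf / (volume_µl/200)` — counts per
low-powered field per 200 µL of blood. The Poisson count model uses the
log of that exposure as offset, so exponentiated coefficients are rate
ratios on the adjusted scale; variance is the HC0 sandwich, with Wald CIs.
The progression model is a plain logistic fit; the G×HiCi first-order
interaction is fitted first and dropped when p > 0.1, the pre-specified
rule for the 2×2 factorial. Perfect separation raises with a message
suggesting exact/penalised alternatives. The longitudinal model is
`log10_flux ~ week·(1 + G + HiCi + baseline_c)` with an animal-level
random intercept fitted by ML; singular random-effect variance (or an
ill-conditioned mixed fit) falls back to OLS with a warning. An optional
set-level variance component accounts for animal-set clustering (off by
default for the synthetic cohort, which plants no set effect). Doubling
time is `7·log10(2)/slope` days; non-positive slopes report no doubling.
AUC is the midrank Mann–Whitney statistic (identical by construction,
asserted exhaustively in tests) with a DeLong-component normal CI.

Progressive disease has no closed definition here; the generator treats it
as a latent Bernoulli driven by the treatment odds ratios, and when
deriving it from data the package's documented rule would be a sustained
≥ 0.5 log10 increase over the post-resection baseline for ≥ 2 consecutive
weeks (configurable).

## Synthetic generator

Per-gene baseline expression is log-normal; the two human programs
up/down-weight the epithelial and myofibroblast/ECM marker blocks (default
300 genes each out of 800 per species) by 2^±2; counts are gamma-Poisson
(negative binomial, θ = 10) with log-normal library sizes around 2000
UMIs. Cancer cells carry the transgene with per-cell detection probability
0.6 (detected count 1 + Poisson(2)); PSC and mouse cells carry none before
contamination. Ambient contamination replaces a fraction α (default 0.02)
of each cell's depth with multinomial draws from the sample-wide pooled
profile — the cross-species route by which mouse UMIs appear in human
cells. Doublets (rate δ = 0.01) are sums of two independent singlet draws,
labelled in truth only. Mouse-model samples get a log-normal per-gene
batch shift (sd 0.3) relative to the cultured reference, which is what the
anchor integration has to remove. Default compartment sizes mirror the
structure of a real experiment at desk scale — blood with 62 CTCs and 16
cPSCs among ~300 mouse leucocytes, a cultured reference of 700 cells — so
the full pipeline runs in seconds.

The cohort generator plants Poisson counts with blood-volume exposure,
treatment rate ratios (defaults: G 0.4 / HiCi 0.5 on CTCs, HiCi 0.25 on
cPSCs), and a per-animal log-normal frailty (sd 1.6, mean 1) making counts
overdispersed. The frailty is deliberate: pure Poisson counts at realistic
exposures are nearly deterministic, which would make recurrence ROC
trivially perfect and sandwich standard errors indistinguishable from
model-based ones; the frailty produces the heavy-tailed, zero-inflated
counts rare-cell assays actually show and is exactly the misspecification
the robust variance is for. Under the overdispersed default, HC0 CIs at
n = 400 sit a couple of points below nominal (a known finite-sample
property, shown in the tests against model-based CIs that collapse to
≤ 70% coverage); coverage calibration at nominal 95% is asserted under the
Poisson sub-model (frailty 0). Flux series are linear in week on the log10
scale with random intercepts (sd 0.3) and residual sd 0.15; default slopes
correspond to doubling times of 10.6 (control), 14.1 (G) and 18.5 (HiCi)
days, treatment effects entering additively on the slope (the observed
non-additivity of combined treatment is not modelled).

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: immune-population structure of mouse blood
(host cells are one homogeneous program), UMI-level sequencing error,
empty droplets and ambient profiles estimated from them, batch chemistry
differences beyond a multiplicative gene shift, and any coupling between
the single-cell and cohort layers.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
~1600–2000 cells per synthetic experiment, 600-cell manifolds over 20
seeds for trajectory recovery, 500 simulation replicates at n = 400
animals for coverage, and the exhaustive Fisher sweep over all 2×2 tables
with total ≤ 40 (via their canonical representatives under row/column
swaps, whose invariance is itself tested). Everything completes in a few
minutes on one CPU.
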