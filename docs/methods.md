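# Methods

`drpkit` classifies cancer cell line-drug pairs as *sensitive* or
*resistant* (IC50 below / at-or-above 1 µM) from multi-omics profiles and
explicit drug structure, and explains its predictions. This note records
the models, the parameter choices that matter, the numerical decisions,
and what the synthetic benchmark does and does not demonstrate.

## Cohort curation and labeling

A raw cohort passes three sequential exclusion filters: (1) pairs without
a usable IC50 (missing, non-positive, or non-finite); (2) pairs whose
cell line lacks any required omics block — mutation calls, copy number,
or expression; the protein block is optional and never excludes; (3)
pairs whose drug has neither a SMILES nor an InChI encoding. The audit
log telescopes (retained_k = retained_{k-1} − excluded_k). Labels use a
strict threshold: sensitive iff IC50 < 1 µM, so the boundary value is
resistant. Percentages are reported to two decimals with half-up
rounding. IC50 is always micromolar at the I/O boundary; molar and
natural-log inputs must be converted explicitly by the reader flag.

## Sequence representations

Each gene sequence is cut into sliding windows of length `L_w` with step
`S_w` (1-based starts `p = 1 + m·S_w`); sequences shorter than `L_w`
yield an empty window set with a warning rather than an error, since
real panels mix lengths. Within a window (or a whole variant sequence)
five structural events are called relative to a per-gene reference:

- **duplication** — a maximal substring of length ≥ `k_min` occurring at
  least twice in the window;
- **mirror** — a maximal substring equal to its own reverse;
- **inversion** — a maximal reference substring whose reverse occurs in
  the window while the forward form does not (palindromes excluded, so
  mirror and inversion are disjoint calls);
- **insertion / deletion** — gap runs in the global edit alignment of
  window against reference (computed with `edlib`).

Mirror vs. inversion is a declared disambiguation: mirror is a
reference-free palindrome property of the window, inversion is a
reversed occurrence relative to the reference. The event caller needs a
reference; the package requires a reference FASTA alongside variant
sequences (the generator plants both). `k_min` defaults to 4: shorter
motifs are overwhelmingly chance matches in four-letter sequence.

Each segment becomes a 12-value descriptor: length, GC fraction, base
composition (4), one-hot event label (5), and 2-mer Shannon entropy
(bits). This descriptor set is a design choice, not a canonical one; it
is deliberately cheap, deterministic, and separates event classes.

Segments are organized by neighbor joining on Euclidean descriptor
distances: the standard Q-criterion `Q_ij = (n−2)d_ij − r_i − r_j`,
classical branch-length and reduction formulas, ties broken toward the
lowest index pair, negative branch lengths clipped to zero. The
"modified" part is an engineering acceleration — row sums are cached and
updated incrementally instead of recomputed per merge — and does not
change merge semantics, so additive matrices are reconstructed exactly
(verified against scikit-bio's NJ). The tree is *not* a phylogeny; it is
a topological organization of segments.

A tree becomes an image channel as the leaf-by-leaf patristic (path
length) distance matrix, leaves ordered by a deterministic depth-first
traversal, min-max normalized to [0, 1] and zero-padded to the tensor
size. A binary companion channel bands leaf rows by event type.

## Drug representations

SMILES is preferred, InChI is the fallback; structures are canonicalized
through RDKit before graph extraction, so parse→canonicalize→parse is a
fixed point. The 2D depiction is a grayscale raster drawn from RDKit's
deterministic 2D coordinates (antialiased bond lines, small atom discs),
normalized to [0, 1]. Drug descriptors: heavy atoms, bonds, rings,
aromatic rings, molecular weight, TPSA, rotatable bonds, and a binary
drug-target match against the cell line's mutated genes. A cytotoxicity
index, when present, is a pass-through annotation column, not a computed
quantity.

## Tensor fusion and feature extraction

Per pair, channels (tree map, event indicators, depiction) are stacked
without mixing into a size×size×3 tensor (224 in the full configuration,
56 in the mini configuration used for desk-scale runs). The deep branch
is an Inception-style numpy network: parallel 1×1/3×3/5×5 convolutions,
**decimal scaling** of each pre-activation map (divide by the smallest
power of ten bringing the maximum magnitude below one) before ReLU,
average pooling with a learnable linear channel map, global average
pooling, and a linear projection to the penultimate width. Convolution
filters are fixed seeded He-style draws; the softmax head on top is a
multinomial logistic regression fitted on training-fold features only
(the package's pretraining). Decimal scaling guarantees every
instrumented pre-activation magnitude stays below one; exact float
reconstruction after rescaling holds to ~1e-12 relative error (binary
floats cannot divide by ten exactly).

Handcrafted descriptors per continuous channel: GLCM Haralick statistics
(contrast, correlation, energy, homogeneity at four unit offsets, eight
gray levels), a 59-bin uniform LBP histogram (P=8, R=1; the one-pixel
border is excluded because its neighborhoods are undefined), and local
tetra patterns (first-derivative quadrant direction coding, one uniform
pattern histogram per direction plus a magnitude histogram, 295 values).

The full feature matrix concatenates deep ‖ handcrafted ‖ attributes
with provenance-tagged columns. The attribute block carries per-gene
expression, mutation and CNV columns plus the drug descriptors. Block
widths are configurable; the full configuration pins (1024, 354, 1000)
= 2,378 columns by truncation/zero-padding, since only the total is
fixed by the design. All standardization uses training-fold statistics
only.

## Wrapper feature selection (SKOA)

Candidate positions live in [0, 1]^k; a coordinate above 0.5 selects its
feature (an all-zero mask falls back to the single largest coordinate).
Fitness is the inner-validation accuracy of a regularized logistic
surrogate on the masked columns — a deliberate surrogate for the final
classifier to keep per-candidate cost desk-scale; the final mask then
trains the graph-attention classifier. Each iteration selects a prey
position by sampling members with probability ∝ fitness ×
exp(−‖x − x*‖²/(2σ_t²)), σ_t² = σ0²/t (σ0 = √k/2): an
Einstein-Smoluchowski diffusion schedule that starts near-fitness-
proportional and concentrates around the incumbent best as the search
cools. The selection kernel is isolated behind an interface; the plain
baseline (prey = global best, no kernel) is one flag. Moves are
exploration `x + C1(P − x)` with `C1 ~ U(0, 2)` per member and
exploitation `p + C2(x − p)` with `C2 = 2(1 − t/T_max)` — both schedules
are config-exposed since only their existence, not their values, is
fixed by the design — accepted greedily, clipped to bounds, with an
elitist best. Defaults a = 30, T_max = 50.

Because wrapper search over thousands of columns with a graph classifier
per candidate is not desk-scale, the pipeline pre-screens candidates by
point-biserial |correlation| with the training labels (training rows
only, default pool 60) before running the wrapper. This is a standard
filter-then-wrapper arrangement and keeps the downstream feature graph
small.

## Classifier (EA-GAT)

Selected features are graph nodes; one graph is shared by all samples
and each node carries the sample's scalar feature value. Adjacency is a
|Pearson| k-NN graph (k = 10) on training rows, symmetrized, with
self-loops; fully connected is available for small node counts. The
model is

    H0_u = x_u · Wg_u + bg_u            (per-node embedding, width h)
    α_uv = softmax_v LeakyReLU(a·[H0_u ‖ H0_v])   (slope 0.2)
    H1_u = φ_λ( Σ_v α_uv H0_v )
    ŷ    = softmax(Wo · mean_u H1_u + bo)

with φ_λ the Aranda-Ordaz asymmetric link, φ(z) = 1 − (1 + λe^z)^(−1/λ)
(λ = 1 is exactly the logistic; default λ = 2), evaluated in log space.
Per-node embedding weights matter: with a single shared weight the
architecture is permutation-invariant over features and can only express
symmetric functions of the feature values, which caps planted-signal
recovery; per-node weights restore feature identity. Training is
full-batch Adam on cross-entropy with L2 (default 1e-4 standalone;
1e-3 in the pipeline, where heavier weight decay spreads weight across
correlated omics columns and stabilizes attributions), early stopping on
a stratified inner validation split with best-checkpoint restore. All
gradients are hand-derived and verified against finite differences in
the test suite. Ablation flags: ReLU in place of Aranda; a plain MLP in
place of the graph head.

## Attribution and enrichment

Kernel SHAP explains the classifier's sensitivity probability against a
training-fold background (default 200 rows; backgrounds overlapping
explained rows raise a leakage error keyed on pair identifiers). Up to
12 features, every coalition is enumerated — exact Shapley values under
the background distribution, so efficiency, symmetry and null-feature
axioms hold to numerical precision. Above that, coalitions are sampled
with probability proportional to the Shapley kernel and attributions
solve a weighted least squares with the efficiency constraint imposed
exactly (KKT elimination), so local accuracy is preserved by
construction. Features are ranked by mean |φ| (ties lexicographic); the
top-K distinct genes (K = 50 by default) feed an upper-tail
hypergeometric over-representation test against GMT gene sets, with
Benjamini-Hochberg control and significance at FDR < 0.05. The gene
universe is the genes represented in the feature matrix — the pool
attribution could actually choose from — not the genome.

## Dose-response analysis

Viability follows the four-parameter logistic
`v(c) = B + (T − B)/(1 + (c/IC50)^(−h))` with T fixed at 100,
B ∈ [0, 100], and h the Hill slope. The exponent orientation is chosen
so that the negative Hill slopes conventional in pharmacology reports
produce decreasing curves (v → 100 as c → 0); the algebraically
equivalent positive-exponent form describes the same family. Fitting is
bounded nonlinear least squares over (log10 IC50, h, B), multi-start
over seven log-spaced IC50 initial values, best sum-of-squares wins;
flat curves are flagged degenerate (parameters unidentifiable, AUC still
valid). Normalized AUC is the trapezoid of v/100 over log10
concentration divided by the log-range span: 1 = complete resistance,
0 = full sensitivity.

Agreement between continuous model scores and measured IC50s: confusion
metrics at score > 0.5 vs IC50 < 1 µM; Spearman correlations with an
exact permutation p for n ≤ 8 (t-approximation otherwise, ties fall back
to the asymptotic p); Mann-Whitney U reported as min(U1, U2) with the
exact distribution for group sizes ≤ 10. Degenerate predictions (one
group empty) flag the undefined metrics rather than failing.

Known discrepancies of the printed six-line panel, all reproducible from
its own numbers: the panel's mean IC50s are perfectly anti-monotone in
the scores, so the score-IC50 Spearman computed from them is exactly
−1.0, not the printed −0.89 (which presumably used unprinted
replicate-level data); the printed MCC 0.67 differs from the 0.707
implied by the printed confusion counts (TP=3, FP=1, TN=2, FN=0); the
printed exact-test p-values (0.024, 0.018) and the predicted-sensitive
group mean (0.73 µM vs the arithmetic 0.5825 µM of the printed values)
are likewise not recoverable. The package reports what it computes; the
reproducible quantities (accuracy 5/6, TPR 3/3, TNR 2/3, U = 0,
resistant-group mean 3.14 µM, the 12% boundary margin) are asserted in
the acceptance suite.

## Evaluation protocol

Stratified k-fold (default 10; the desk-scale benchmark uses 5) with
per-fold fitting of everything fit-capable: standardization, screening,
the CNN head, wrapper selection, classifier training, SHAP background.
Entity-level representations (windows, segments, trees, depictions) are
deterministic functions of single entities with no cross-sample fitting,
so they are computed once. The leakage sentinel refits a fold after
overwriting the test rows with an extreme constant and asserts that the
fitted scaler statistics, screened column list, selected mask, and model
parameters are bit-identical. Ablation variants (`no_skoa`, `no_mnja`,
`no_drug_structure`, `non_graph_classifier`, `no_aranda`) reuse one fold
plan for controlled comparison. `no_drug_structure` drops every
drug-descriptor column including the target-match term, treating it as
part of the drug-context block. No oversampling or class weighting is
applied.

## Synthetic benchmark: what it shows and what it does not

The generator plants a fully known mechanism: latent pathway activity
z ~ N(0,1) per cell line; causal-gene expression correlated with z
(loading 0.9); causal-gene mutation probability increasing with z; drugs
annotated with causal targets; score = effect_size · z · match with
match 1.0 on a target hit and 0.3 baseline; log10 IC50 = μ0 − score +
N(0, noise_sd), with μ0 set to the empirical quantile that yields the
configured prevalence under the 1 µM threshold. Defaults: 100 cell
lines × 10 drugs (1,000 pairs), 100 genes, 10 causal, effect size 2.0,
noise 0.3, prevalence 0.5 — chosen once as a cohort in which the planted
signal is strong but not trivial (a plain linear probe on the causal
features reaches AUROC ≈ 0.95, leaving the pipeline headroom to fail).
Sequences are 160 bp with two planted events of length 10 per gene.

Passing the benchmark shows the machinery is wired correctly end to end
— selection finds planted columns, the classifier generalizes, SHAP
concentrates on planted genes, enrichment flags the planted set, no fold
leaks. It does **not** show performance on real pharmacogenomic data:
real cohorts have correlated omics blocks, batch structure, measurement
error in IC50, many weak effects instead of ten strong ones, and drugs
whose structure actually matters. The texture/CNN branch in particular
carries planted signal only insofar as the segment trees reflect
mutation status; its role here is plumbing verification, not a claim of
image-feature usefulness.

## Problem sizes

Routine runs use the sizes above (1,000-pair benchmark, 5 folds, 30-
column screened pool, mini 56×56 tensors, SKOA 10×10 in the pipeline,
Kernel SHAP with ≤ 1,000 sampled coalitions over ≤ 40 features), chosen
as the package's desk-scale defaults; every size is a config field and
scales up unchanged.

## Known limitations

- The deep branch uses fixed random convolution filters with a trained
  softmax head; it is a random-feature extractor, not a fully trained
  CNN, and its features are weak compared to the attribute block.
- The Smoluchowski selection function and the C1/C2 schedules are
  declared interpretations of an underspecified design; both sit behind
  interfaces and config fields.
- Exact Kernel SHAP is exponential in features (capped at 12); above
  that the sampled estimator has Monte-Carlo noise, so rankings of
  near-tied features are unstable at small coalition budgets.
- NJ branch lengths are clipped at zero on non-additive inputs, which
  slightly distorts patristic distances for noisy descriptor sets.
- The curation fixture reproduces published-style exclusion counts by
  construction; intermediate counts of any real snapshot are properties
  of that snapshot and are not claimed.
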