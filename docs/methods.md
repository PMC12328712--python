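# Methods

## The model

`cellmkl` classifies single cells into two phenotypes (tumor vs. healthy,
treated vs. control, high- vs. low-grade) from one or two omics
modalities — scRNA-seq counts and/or scATAC-seq peak counts — while
reporting *which biological feature groups* drive the distinction.

Given cells (x_i, y_i), y_i ∈ {−1, +1}, and P prior-knowledge feature
groups G_1 … G_P (pathway gene sets for RNA; peak sets for ATAC), the
model is a multiple-kernel machine with one shift-invariant kernel per
group, combined linearly with learned non-negative importances.  Three
kernels are supported (width s > 0):

* Gaussian k(Δ) = exp(−‖Δ‖₂²/s²) — default for RNA, gene-activity
  scores, and TF-IDF ATAC;
* Laplacian k(Δ) = exp(−‖Δ‖₁/s) — default for binary ATAC, where it
  yields sparser solutions;
* Cauchy k(Δ) = ∏_d 1/(1 + (Δ_d/s)²).

Each kernel is approximated by random Fourier features: with ω_1 … ω_D
drawn i.i.d. from the kernel's spectral density (Gaussian kernel →
ω ~ N(0, 2/s² I); Laplacian → per-coordinate Cauchy(0, 1/s); Cauchy →
per-coordinate Laplace(0, 1/s)),

    z(x) = √(1/D) [cos(ω₁ᵀx) … cos(ω_Dᵀx), sin(ω₁ᵀx) … sin(ω_Dᵀx)],

so z(x)·z(y) is an unbiased estimate of k(x, y), ‖z(x)‖₂ = 1 exactly,
and an N×N kernel matrix is replaced by an N×2D feature block.  The
per-group blocks are concatenated into a design Z (across modalities
for multimodal runs) and a group-lasso regression is solved:

    min_β  (1/2)‖ỹ − Z̃β‖₂² + λ Σ_g ‖β_g‖₂ ,

with ỹ, Z̃ the label- and column-centered data (equivalent to an
unpenalized intercept).  A group's kernel weight η_g = ‖β_g‖₂ is
exactly zero when the group is excluded; nonzero η_g measures its
contribution.  Classification is sign(Zβ + b).

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| kernel width s | mean pairwise distance (euclidean for Gaussian, L1 otherwise) over ≤ 2000 training cells × ≤ 200 group features | puts the kernel at the data's own scale; estimated per group, per training split |
| D (frequencies per group) | ceil(√N·ln ln N) for N training cells; "auto" | past this, held-out accuracy saturates; set to a fixed small value (e.g. 100) when the number of groups is very large |
| λ grid | 10 values: λ_all, 8 linear interior points, λ_one | λ_one = largest λ keeping exactly one group (bisection below λ_max to 1% width); λ_all = largest λ keeping all groups (geometric descent, factor 0.7, floored at 1e-4·λ_max) |
| CV | stratified 4-fold, AUROC, one-SE rule | widths, bases, preprocessing statistics and centering are refit inside each fold |
| replicates | 100 × stratified 80/20 (20 in the desk-scale experiments here) | all downstream statistics (selection frequencies, weights) are over these replicates |
| preprocessing | RNA/GAS: per-cell scaling to 1e4 + ln(1+·) + per-feature z-score (train stats); ATAC: binarize (or TF-IDF, idf = ln((1+N)/(1+nnz_f)+1) from training cells) | leakage-free by construction |
| peak→gene window | 5 kb on both sides of the gene body | a peak may map to several genes; ≥1 bp half-open overlap, no fractional threshold |
| GAS promoter | 2000 bp upstream of the TSS on the annotated strand | promoter length is a convention, exposed as a parameter |
| TF peak sets | per TF keep the study with the most regions; drop TFs with < 500 regions before overlap | mirrors how published TF binding compendia are consolidated |

Numerical choices: the solver is FISTA with block soft-threshold prox,
step 1/L with L the largest eigenvalue of Z̃ᵀZ̃ (power iteration, 1%
margin), momentum restart whenever the objective would increase (the
trace is therefore non-increasing), and convergence at relative
objective change < 1e-6.  β ≡ 0 exactly at λ ≥ λ_max = max_g ‖Z̃_gᵀỹ‖₂
(KKT).  Degenerate width estimates (all-zero distances) fall back to
s = 1 with a warning.  Constant features z-score to 0.  Group members
are ordered lexicographically when columns are extracted so that basis
rows and data columns always align.

Design choices where the design was genuinely open:

* **Kernel widths for the Laplacian/Cauchy family.**  Both are
  parameterized with the same width s as the Gaussian (‖Δ‖₁/s and
  (Δ_d/s)²) so the distance-scale heuristic applies uniformly; the
  Cauchy kernel uses the normalized form ∏ 1/(1+(Δ_d/s)²), the unique
  version with k(x,x)=1 realizable by a spectral density.
* **CV one-SE rule.**  λ is the largest value whose mean validation
  AUROC is within one standard error of the best.  A plain argmax
  drifts to the densest λ whenever performance saturates, defeating the
  sparsity that makes the weights interpretable; exact ties also
  resolve toward the sparser model under this rule.
* **Intercept via centering; no 1/N loss scaling; no group-size
  weights** — all blocks share width 2D, so size weights would fold
  into λ.
* **Ablation-stable seeding.**  Each group's frequency matrix is seeded
  by a digest of (modality, group name) under the replicate seed, so
  removing groups never changes the survivors' kernels.
* **Classification threshold** is score ≥ 0 (the centered decision
  score), used for F1/precision/recall/G-mean; AUROC is
  threshold-free.

## Interpretation and perturbation protocols

Selection frequency of group g at λ is the fraction of replicates with
η_g > 0; dot-plot tables average frequencies and weights over the λ
grid, keep the top 8 groups per modality, and min-max scale within each
modality (a degenerate range scales to 0).  Ablation reruns the
experiment with named groups removed under the same seeds and reports,
per surviving group, Δmean-η with a two-sided Wilcoxon rank-sum test on
per-replicate λ-averaged weights (Benjamini–Hochberg corrected), plus a
one-sided paired signed-rank test that ablation worsened AUROC.
Grouping perturbations either *corrupt* (replace floor(f·|G|) members
with random features outside the group, f ∈ {0, .2, .4, .6, .8, 1};
size preserved) or *pad with noise* (append round(l·|G|) cell-permuted
copies of randomly chosen member columns, l ∈ {0, .5, 1, 2, 4, 8}).

## The synthetic-data generator

The generator produces the statistical structure the method assumes:
two classes whose difference lives in a few informative groups among
many.

* RNA: negative-binomial counts, var = μ + αμ² with dispersion α = 0.5;
  gene base means lognormal with median 2 counts/cell and σ = 1 ln-unit
  (pathway collections are biased toward moderately expressed genes).
  Ungrouped background genes (default 15× the grouped count) emulate
  that curated collections cover a minority of the transcriptome —
  essential for the corruption protocol, whose replacement features
  come from the whole matrix.
* Class effect: each informative gene's mean is shifted by a log-fold
  change of effect/√|G| (and each informative peak's accessibility by
  min(0.4, effect/√(peaks per group))), so the *aggregate* signal a
  group kernel carries is on the scale of `effect` regardless of group
  size.  The class difference is a group property built from
  individually modest features — the regime the method is designed
  for, and the regime in which scattering a group's members destroys
  its value.  effect = 0 is an exact null.
* ATAC: Bernoulli peaks (base accessibility uniform on [0.05, 0.25]) on
  a toy genome of non-overlapping stranded genes whose ±5 kb
  neighborhoods are disjoint; each gene gets 2 peaks inside its window,
  plus intergenic decoys placed beyond every window.  The placement
  record is the ground-truth peak→gene map, so the mapping code is
  testable against construction, and informative peaks belong to
  informative genes so the gene-set→peak-group pipeline carries the
  signal end-to-end.
* The `complementary` plan gives disjoint halves of the informative
  groups to RNA and ATAC, so neither modality alone sees everything.

What the generator does **not** emulate: batch effects, doublets,
ambient RNA, depth confounds, unbalanced library sizes, overlapping
gene bodies, or realistic linkage between expression and accessibility.
Passing tests therefore demonstrate correctness of the algorithms and
recoverability of group-structured signal under clean conditions, not
performance on real tissue.

## Problem sizes used in the shipped experiments

The recovery experiment uses 600 cells, 20 groups × 25 features,
3 informative, effect 2.0, 20 replicates; perturbation curves use the
same data at 10 replicates per level; the multimodal comparison uses
600 cells with 4 informative groups under the complementary plan at 10
replicates per arm.  Kernel-fidelity checks use 300 cells × 40 features
with D up to 5000 over 10 bases.  These sizes give stable statistics
(selection frequencies at 0.05 resolution) on a single CPU.

## Known limitations

* Binary phenotypes only; no multiclass or survival endpoints.
* Squared loss on ±1 labels (as in the objective above), not logistic.
* The λ endpoints are searched per replicate; grids are therefore not
  identical across replicates (values are recorded per replicate).
* TF-IDF is computed with natural logarithm; tools using log₂ will
  differ by a constant factor per feature.
* Feature identifiers are opaque strings; mapping between gene symbol
  and Ensembl namespaces is the caller's responsibility.
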