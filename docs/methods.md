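# Methods

## The prediction problem

Developmental enhancers are distal regulatory regions that activate
transcription in specific embryonic tissues. No single data type identifies
them reliably: enhancer-associated chromatin marks (H3K4me1, H3K27ac, p300
binding) are neither necessary nor sufficient, sequence composition carries
weak tissue-specific signal, and evolutionary conservation is informative
but heavily ascertained in the available training data. `enhancerscan`
integrates these signals in a two-step classifier:

* **Step 1** separates enhancers from genomic background.  Positives are
  experimentally validated enhancers (a VISTA-style truth table of tested
  regions with per-tissue activity calls); negatives are random genomic
  regions matched one-to-one to the positives in chromosome and length,
  excluding every tested region and assembly gaps.  Tested-but-inactive
  regions are *not* used as Step-1 negatives — they resemble enhancers in
  most measured features.
* **Step 2** assigns tissue specificity.  For each tissue, positives are
  the tested regions active in that tissue (activity elsewhere is allowed)
  and negatives are all remaining tested regions, including inactive ones.
  A combined brain task pools forebrain, midbrain and hindbrain.

## Model

Both steps use a soft-margin SVM whose kernel is a learned convex
combination of per-data-type kernels (1-norm multiple kernel learning).
The discrimination function for a region x is

    f(x) = Σ_i α_i Σ_j β_j k_j(x_i, x) + b,      β_j ≥ 0,  Σ_j β_j = 1,

with signed example weights α_i (the label is absorbed: α_i = y_i λ_i,
λ_i ∈ [0, C_class]), kernel weights β_j, and bias b.  A positive score
predicts the positive class.  The three kernels are:

* **spectrum** — the 4-spectrum string kernel, the dot product of 4-mer
  occurrence-count vectors of the two sequences.  k-mers are counted on
  the given strand, case-insensitively; windows containing a non-ACGT
  character are skipped so scans can cross assembly gaps.
* **functional** — a linear kernel over binary vectors of overlap (≥1 bp,
  half-open coordinates) with each functional-genomics peak track.
  Presence/absence only; peak heights and read densities are not used.
* **conservation** — a linear kernel over a single scalar per region: the
  maximum score of any overlapping conservation element, zero if none.

Each training kernel K is divided by the feature-space variance of the
training points, v = mean(diag K) − mean(K), so differently scaled
families are comparable; test-vs-train blocks reuse the training
normalizer and are never re-estimated on test data.  Misclassification
costs are balanced by class size, C_+ = C·N/(2N_+), C_− = C·N/(2N_−),
with C = 1 by default.

### Optimization

Training alternates two convex steps until the kernel weights stabilize
(SimpleMKL-style): with β fixed, the combined kernel Σ_j β_j K_j is handed
to a dense dual SVM solve (scikit-learn's precomputed-kernel `SVC`,
i.e. libsvm); with α fixed, β takes a projected-gradient step on the
probability simplex using the Danskin gradient ∂J/∂β_j = −½ αᵀK_jα, with
backtracking line search so the objective never increases.  Iteration
stops when the largest β change falls below `beta_tol` (1e-4), when no
descent step exists, or when the objective improvement becomes numerically
idle (relative change ≤ 1e-7); hitting `max_outer_iter` (100) returns the
best iterate with `converged=False` and a warning.  The problem is convex,
so the optimum — not the path — is the contract; β is initialized uniform
and ties among equally optimal β are resolved by whichever iterate is
reached first (the optimum is not always unique, e.g. duplicated kernels).

## Evaluation

All classifiers are evaluated by stratified 10-fold cross-validation with
kernels and normalizers estimated on training folds only.  Pooled
out-of-fold scores feed: ROC AUC (the Mann–Whitney probability, ties ½),
precision–recall curves, power at a fixed false positive rate (the
fraction of positives at or above the smallest observed score threshold t
with frac(neg ≥ t) ≤ target), and McNemar's test for paired classifier
comparison (classification at score 0; continuity-corrected χ² for ≥ 25
discordant pairs, exact two-sided binomial below).

The genome-wide false discovery rate is prior-dependent.  With an assumed
fraction π of 1.5 kb windows truly containing an enhancer and an operating
point (FPR, TPR),

    FDR = FPR·(1−π) / (FPR·(1−π) + TPR·π).

At FPR 0.05 and TPR 0.50 this gives 9% for π = 0.5 and 47% for π = 0.1.

## Genome-wide scan

Chromosomes are tiled into 1500 bp windows every 500 bp, anchored at
position 0, trailing partial windows dropped.  Windows are scored by a
Step-1 model trained *without* the conservation kernel: tested training
regions are strongly ascertained for conservation (nearly all of them,
active or not, overlap a conserved element), so a conservation feature
learned there would not transfer to the unascertained genome.  Windows at
or above a cross-validation-derived threshold (5% FPR against the matched
genomic background by default) are merged — overlapping or book-ended
survivors become one call carrying the maximum member score.  Step-2
tissue models score every window with a *positive* Step-1 score (the sign
contract, deliberately distinct from the 5%-FPR merge threshold), are
thresholded per tissue at their own 5% FPR, and merged per tissue.  Tissue
calls are independent: one window may be called in several tissues.

## Baselines and enrichment

The GC-content baseline scores a region by its GC fraction alone.
Overlap-rule baselines call a region positive if it overlaps ≥1 peak of
any mark group (union) or of every mark group (intersection).  The
GWAS-SNP enrichment test counts SNPs inside predicted regions and compares
against re-placements of every region (same chromosome, same length,
avoiding assembly gaps; mutual overlap of the randomized regions is not
prevented), with the add-one p-value (1 + #{null ≥ obs})/(P + 1).

## Synthetic data

The generator produces a complete, self-contained dataset: FASTA genome,
peak tracks, scored conservation elements, a truth table, and SNPs.  It
emulates the statistical structure the classifier exploits, at toy scale:

* Two 1 Mb chromosomes of i.i.d. bases at GC 0.40.  Sequences have no
  Markov structure, repeats, or CpG islands — sufficient for 4-mer and GC
  signal, and the simplest defensible composition model.
* 200 planted enhancers of 1500 bp, non-overlapping, ≥ 5 kb apart (the
  spacing prevents window-merge artifacts in scan tests), tissue labels
  drawn uniformly from heart/limb/brain.  Heart enhancers use GC 0.49 —
  the empirical contrast that makes embryonic heart enhancers uniquely
  easy to classify from sequence — and each tissue plants 2 copies of a
  6-mer motif (CACGTG / TGACAG / CAGCTG).  Two copies keep tissue AUCs
  below ceiling so that the heart-vs-other ordering reflects the GC
  contrast rather than saturating at 1.0 for every tissue.
* 200 tested-negative regions placed like enhancers but with background
  composition and no planted marks.
* 12 peak tracks, 4 affiliated with each tissue.  A track covers a
  matching-tissue enhancer with probability 0.8 and an off-tissue enhancer
  with probability 0.2 (peaks extend the enhancer by up to 250 bp on each
  side), plus Poisson background peaks at 30/Mb of 400 bp.
* Conservation elements cover 95% of enhancers and 90% of tested-negative
  regions with high scores (350–650) — mirroring the ascertainment of real
  tested regions, which makes conservation informative in Step-1
  cross-validation yet rightly excluded genome-wide — plus background
  elements at 20/Mb with low scores (50–300).
* 300 SNPs scattered uniformly (a null configuration; a fraction inside
  enhancers is configurable for enrichment demonstrations).

Identical seeds give byte-identical output files.  What passing on this
data does *not* show: robustness to correlated peak calls across cell
types, repeat-driven composition artifacts, length variation of real
tested regions, or genome-scale class imbalance in the scan.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open everywhere; overlap means ≥ 1 shared
  bp; strand is carried but ignored.
* A constant kernel (feature-space variance ≤ 0) is an error, not a
  silent pass-through.
* `threshold_at_fpr` returns +∞ when no observed score meets the target
  (e.g. target FPR 0 with finite scores).
* All-N windows score through the overlap bits and bias alone (zero
  spectrum); the GC fraction of an all-N sequence is an error where GC is
  the statistic, NaN where it is incidental.
* Random-region placement rejection-samples up to 10,000 attempts per
  region and then fails loudly, naming the region.

## Problem sizes

The shipped tests and examples run the full pipeline at the generator's
default scale — 2 Mb of genome, 400 tested regions, 10-fold CV with three
kernels, ~4,000 scan windows — which exercises every code path at desk
scale.  The permutation-calibration check uses 200 independent runs of 99
permutations on a 1 Mb toy with 2,000 SNPs, enough expected SNPs per draw
that the discrete add-one p-value can approach uniformity (with few
expected counts the ≥-tie mass makes it intrinsically conservative).

## Known limitations

* The spectrum kernel is computed through explicit 4^k count vectors —
  fine for k ≤ 8, not meant for large k.
* The MKL optimizer returns one optimal β; when several β are equally
  optimal the reported weights are tie-broken by the optimization path.
* The scan featurizes windows densely; whole-mammalian-genome runs should
  shard by chromosome externally (per-chromosome results are
  deterministic, so sharding is exact).
* FDR estimates take TPR as an explicit argument rather than re-deriving
  it from a particular cross-validation run.
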