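# Methods

`trnacif` estimates clade-specific tRNA *function logos*, scores genome
tRNA gene complements against them, and classifies genomes to clades with
a small multilayer perceptron. This note documents the model, the
estimators, the synthetic benchmark, the numerical choices, and the known
limitations — including one subtle artifact of the leave-one-out scoring
construction that shapes how the validation studies are designed.

## Data model

A dataset is a set of tRNA genes aligned in a common *Sprinzl coordinate*
frame: an ordered list of coordinate labels (opaque strings; insertion
codes allowed) such that homologous structural positions line up across
genes. Each gene carries a genome of origin and a *functional class*
`i ∈ I`, where `I` is the 22-class set of the 20 elongator isoacceptor
families (one-letter amino-acid symbols), the initiator class `X`, and the
tRNA-Ile(CAU) class `J`. Elongator classes are derivable from the
anticodon through the standard genetic code; the three CAU-anticodon
classes (`X`, elongator `M`, `J`) are not, and must come from explicit
labels (an external discriminator such as a TFAM-style model) or a
configurable fallback policy.

All input is normalized to the RNA alphabet (case-folded, T→U). IUPAC
ambiguity codes are treated as gaps: features are defined only over
`{A, C, G, U}`, so an ambiguous base carries no feature. Columns with a
gap fraction at or above a threshold (default 0.99, inclusive) can be
pruned, as can explicitly listed coordinates (variable arm, CCA tail).

Genomes are partitioned into clades by a user-supplied map; clades whose
pooled gene count falls below `min_gene_count` (default 120) are excluded
from training. Clade fusion (e.g. two sister clades merged into one
training clade) is expressed through map aliases.

## Function logos and class-informative features

For a clade `X` with pooled gene set `T_X`, every feature
`f = (base, coordinate)` carried by `n_f ≥ 1` genes gets:

* the class-conditional distribution `p(i|f)`: the class composition of
  the genes carrying `f`;
* the feature information `D_f = max(KL(p‖q) − c(n_f), 0)` in bits, where
  `q` is a background class distribution and `c` a sample-size bias
  correction;
* Gorodkin heights `h^i_f = D_f · (p_i/q_i) / Σ_j (p_j/q_j)`, which
  apportion `D_f` over classes by background-normalized odds and satisfy
  `Σ_i h^i_f = D_f` exactly.

A large `h^i_f` marks a *class-informative feature* (CIF): seeing `base`
at `coordinate` in a gene of clade `X` is strong evidence that the gene
belongs to class `i`.

**Background `q`.** Default: the clade's own class frequencies (fraction
of `T_X` genes in each class), so heights measure information beyond the
clade's class composition. Options: uniform over the clade's observed
classes, or pooled frequencies over all training clades. Classes absent
from a clade are dropped from its background support; genes of such
classes score zero against that clade's logo.

**Correction `c(n)`.** Default Miller–Madow style:
`(m−1)/(2·ln2·n)` with `m` the number of classes observed among the `n`
carriers, subtracted and clamped at zero. The `exact_small_n` option
replaces this for `n ≤ 8` with the exact null expectation of the plug-in
KL statistic under `p = q`. That expectation separates over classes
(each class count is Binomial(n, q_i)), so it is computed in closed form
from binomial probabilities — no enumeration of multinomial outcomes is
needed. `none` disables correction.

## Genome scoring

The score of genome `g` against clade `X` is the per-gene average of the
summed heights of the features each gene carries, taken at the gene's own
class:

    S_g^X = (1/|T_g|) Σ_{t∈T_g} Σ_{f∈t} h^{i_t}_{f,X}     [bits/gene]

Gaps contribute nothing; features, coordinates, or classes unknown to a
logo contribute zero (query complements may be reduced subsets of the
training universe). Scores are invariant to gene order and to duplicating
the whole complement.

**Leakage hygiene.** Training genomes are never scored against logos that
contain their own genes: for genome `g` of clade `X`, the clade-`X` logo
is re-estimated from `T_X − T_g` before scoring `g` (other clades' logos
are unaffected since `T_g` does not intersect them). Query genomes are
scored against full-data logos. Every resampling procedure in the
robustness battery (LOOCV folds, bootstrap replicates, balanced variants)
refits the standardizer — and retrains the network — strictly inside the
training side of each split.

Score vectors are standardized per clade element (subtract training mean,
divide by training SD; population SD, ddof=0). A zero-SD column divides
by 1 with a warning, standardizing to identically zero.

## Phyloclassifier

A scikit-learn `MLPClassifier` with rectifier hidden units, soft-max
output, L2 penalty α = 0.01, optimized full-batch by L-BFGS for up to
2000 iterations with tolerance 1e-4. Predictions use the package's own
forward pass on the stored weights (verified to match sklearn's
`predict_proba` to 1e-12), so fitted models serialize to plain JSON.
The quasi-Newton optimizer's own convergence test subsumes a
patience-style early stop; the `patience` field is retained in
`NetworkSpec` for completeness. The random seed governs weight
initialization only; everything is bit-deterministic given the seed.

Architecture search enumerates all hidden-layer configurations within
bounds (default 1–4 layers, widths 8–16, each layer independent) and
ranks by LOOCV accuracy; ties break to fewest parameters, then fewest
layers, then enumeration order. LOOCV caches per-genome leave-one-out
score vectors once and refits only the standardizer and network per fold
(the vectors do not depend on the fold).

A classification is *equivocal* ("none of the above") when the top
probability falls below a threshold (default 0.80). Argmax ties resolve
to the first clade in clade order and are flagged.

## Robustness battery

* **Permutation test** — clade labels are permuted over training genomes
  B times; each replicate re-runs LOOCV (score vectors fixed — relabeling
  does not change them). p = (b+1)/(B+1), b = #{null ≥ observed}: the
  standard positively biased permutation estimator.
* **Site bootstrap** — alignment columns are drawn with replacement to
  the original count; a column drawn twice contributes its features
  twice; the same column multiset applies to training and query genes.
  Per replicate the full pipeline re-runs (logo estimation, training
  matrix, standardizer, network, classification). Implemented by slicing
  cached per-genome count tensors along the coordinate axis, so
  replicates are cheap.
* **Leave-clade-out** — one clade's genomes become queries; the model's
  input/output dimension shrinks, so the excluded label cannot be
  predicted; reports carry equivocality flags.
* **Oversampling balance** — training score vectors are resampled with
  replacement within each clade up to the best-sampled clade's size;
  originals always retained. In balanced LOOCV the balancing happens
  inside each fold after the held-out genome is removed.
* **Confusion metrics** — one-vs-all precision, recall, and balanced
  accuracy ((TPR+TNR)/2) per clade; precision is 0 when a clade is never
  predicted.

## Synthetic benchmark generator

The generator emulates clade-partitioned tRNA data: K clades of genomes,
each genome with 30–55 genes (default) covering the 22-class repertoire
(every class at least once when the gene count allows, remainder uniform)
over 72 coordinates. Sequence content layers:

1. *shared identity determinants* — per-class (coordinate, base)
   determinants common to all clades (default 3 per class), emulating
   universal tRNA identity elements;
2. *clade-planted determinants* — per-clade (class, coordinate, base)
   determinants (default 20 per clade), the ground-truth CIFs; the
   (class, coordinate) slots are disjoint across clades and from the
   shared determinants;
3. *background* — gap with probability `gap_rate` (default 0.05), else a
   uniform base.

Each determinant is respected with probability `signal`; at `signal=1`
every planted determinant is exactly recoverable, at `signal=0` clades
are statistically exchangeable and global composition is uniform. A truth
record lists every determinant. Novel-clade queries draw a (K+1)-th clade
whose determinants are provably disjoint from the training clades'
(the sampling replays the same stream and continues past them).

What the generator does **not** emulate: phylogenetic (tree-correlated)
covariation between clades, secondary-structure base-pair covariation,
non-uniform base composition, and the nested similarity structure of real
clades. Passing recovery benchmarks therefore demonstrates correctness of
the estimators and the pipeline's discriminative machinery, not
performance on real genomes.

## A known artifact of leave-one-out scoring, and how studies are sized

The training vector of genome `g` scores its own clade against a logo
built from `T_X − T_g`, but other clades against their full logos. With
clamping at zero, the residual small-sample bias of the corrected
information is positive and decreases with sample size — so the own-clade
column of every training vector is *mechanically elevated*, by an amount
that grows with the fraction of its clade's genes that one genome
represents. When clades contain only a handful of genomes, a classifier
can read clade identity off this elevation alone: with 3-genome clades
and no planted signal at all, LOOCV "accuracy" reaches 1.0. The effect
shrinks roughly like (features per genome)^{1/2} / (genomes per clade)
and is negligible at the benchmark's 25 genomes per clade (permuted-label
accuracy ≈ 1/K there), but real datasets with 3–5-genome clades sit in
the affected regime — a caution for interpreting accuracy on such clades.

Consequences for study design:

* the **permutation-calibration study** (20 runs × B=200) uses a null
  design in the artifact-negligible regime (2 clades × 10 genomes, 4
  genes × 6 coordinates, 8 classes, signal 0), where the label-permutation
  exchangeability assumption genuinely holds; the optimizer cap is 25
  iterations, since chance-level fits gain nothing from deep convergence.
  The high-signal arm uses 3 clades × 4 genomes: with only 2 clades the
  global label swap is itself learnable and is occasionally drawn among
  200 random permutations, blocking the exact minimal p.
* the **recovery benchmark** (8 clades × 25 genomes × 40 genes, 20
  planted CIFs per clade, signal 0.9) sits where elevation is negligible
  and planted signal dominates.

## The oversampling-balance study

The balance study uses an imbalanced 4-clade design (30/27/11/5 genomes)
in a moderately confusable regime (12 genes × 20 coordinates, 10 classes,
3 planted determinants per clade over a shared-identity background,
signal 0.7, optimizer cap 500), the regime where clade clusters genuinely
overlap and class priors can matter. Its outcome metric is the mean
recall of the two under-sampled clades under unbalanced vs clade-balanced
LOOCV, over 10 seeded datasets.

In practice the improvement is *not* reproducible under strict leakage
hygiene: the L-BFGS network interpolates the training score vectors
(training accuracy 1.0 in every inspected fold), so duplicating minority
vectors barely changes the fitted function, and the balanced-vs-unbalanced
difference is seed noise (win rate ≈ 0.5). Balancing *does* reliably lift
minority recall if the data are balanced once and LOOCV is run afterwards
— but then duplicate copies of the held-out genome's vector remain in its
training fold, a self-leakage this package refuses by design. The study
is reported honestly either way.

## Numerical and policy choices

* Gap-threshold comparison is inclusive (`≥`), so threshold 0.99 removes
  a column with exactly 99% gaps.
* Coordinate labels are opaque; no numeric ordering is assumed. Bootstrap
  replicate frames disambiguate repeated coordinates with a draw index.
* `0·log 0 := 0` throughout; information clamped at 0; heights ≥ 0.
* Permutation p-values use (b+1)/(B+1), never 0.
* Synthetic clade maps use `min_gene_count=1`; the 120-gene exclusion
  rule targets real-data scale.
* Worked-example arithmetic (genes/genome, bases/gene, percentages) is
  rounded to two decimals for display; full precision is kept internally.

## Study sizes

Validation studies are sized for a single CPU: the recovery benchmark is
8×25 genomes (one LOOCV pass ≈ 1 s; its permuted-label control, run at
the full 2000-iteration budget, ≈ 75 s); permutation calibration is 20
runs × 200 replicates (≈ 7 min); bootstrap consistency is 100 replicates
on a 4×6-genome design (seconds); the balance study is 10 datasets × two
73-fold LOOCVs (≈ 4 min). The full-scale 100,000-replicate permutation
test of the original analysis is supported by the same API
(`permutation_test` with B=100000) but is not part of the desk-scale
studies.
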