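# Methods

## The study design being emulated

Seven sample groups over two brain regions: symptomatic disease (HD) and
control (C) prefrontal cortex (BA9, 26 and 56 samples), asymptomatic
gene-positive (HD+) cortex and caudate (3 and 2), control caudate (2), and
a large reference population (GTEx, 90 BA9 / 102 CAU). Five pairwise
contrasts are fit: (1) HD BA9 vs C BA9, (2) HD+ BA9 vs C BA9, (3) HD+ CAU
vs HD+ BA9, (4) HD+ CAU vs C CAU, (5) GTEx CAU vs GTEx BA9. Contrast (5)
is oriented caudate-over-cortex so that (3) and (5) estimate the same
region axis; (3)−(5) then isolates what the disease does to the caudate
beyond the ordinary region difference.

## Synthetic data generator

Counts for gene *g* in sample *j* are negative binomial with mean
`depth_j · q_g · 2^(x_j'β_g)` and variance `μ + α_g μ²`. The design row
`x_j` carries disease (HD and HD+ groups), region (CAU), their product,
age and sex. Defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| group sizes | the seven study sizes above | the design under study |
| `n_genes` | 2000 | enough for stable FDR behaviour, minutes of runtime |
| `frac_de`, `frac_region` | 0.10 each | sparse signal, independent draws |
| `frac_interaction` | 0.05 | the rare caudate-specific response |
| disease/region \|L2FC\| | ~ \|N(2, 0.5)\| | typical strong DE effects |
| interaction \|L2FC\| | ~ \|N(4, 0.5)\| | the scale of the published caudate-specific Δ values (≈2.3–6.2) |
| dispersion α | log-normal, median 0.1, σ = 1 | spans ≈0.01–1, well-behaved to noisy genes |
| baseline mean | log-uniform 20–2000 | moderately to highly expressed genes |
| depth factors | uniform 0.5–2 | realistic library-size spread |
| age | uniform 40–90 y; sex Bernoulli(½) | only means±sd are published; simplest structure that exercises the adjustment |

Effects are sign-symmetric; interaction effects apply only to the
disease×CAU cell, so they cancel from contrast (5) and from the disease
term of (3), making them exactly the ground truth the Welch comparison
must recover. Gene sets: enriched sets over-sample flagged genes **of one
effect sign** (real pathways move coherently; sign-agnostic sets place
hits at both ends of a fold-change ranking and cancel the enrichment
walk); non-enriched sets are uniform draws.

What the generator does *not* emulate: batch effects, PMI/RIN covariation,
count outliers, correlated genes within pathways beyond shared membership,
and library-specific GC/length biases. Passing tests therefore demonstrate
statistical correctness of the machinery under a clean NB world, not
robustness to real-data artefacts.

## Differential expression

Size factors are median-of-ratios over genes with no zero in any sample,
computed once on the full matrix; filters are then per contrast ("more
than" semantics, strict inequality): fraction-based (gene removed if >50%
zeros in any group) for the large contrasts, absolute zero budgets (>2,
>4 zeros) for the tiny ones.

The per-gene model is an NB GLM with log link and log-size-factor offset
(statsmodels IRLS), Wald test on the condition coefficient, natural-log
coefficients converted to log2, BH over all tested genes. Deliberate
simplifications relative to DESeq2: no Cox–Reid adjustment, no LFC prior,
no independent filtering, no outlier replacement — downstream consumers
use only (l2fc, se, padj, n_total).

Dispersions are method-of-moments with trend shrinkage: the raw (possibly
negative, hence unbiased) gene-wise estimate from design residuals is
combined on the log scale with a binned mean-dispersion trend, weighted
`dof : prior_df` with `prior_df = 10`. With 1–2 residual df (the 5- and
4-sample contrasts) the trend dominates — the same strength-borrowing that
makes small-n NB inference possible anywhere; with ~80 samples the
gene-wise estimate dominates. Measured on fully null simulations this
yields ≈5% rejections at p<0.05 in both the 82-sample and the 5-sample
contrast.

Design guards, in order: two-level factors are 0/1-coded and numeric
covariates z-scored; covariates collinear with the existing columns are
dropped; the design must keep ≥1 residual df (otherwise covariates are
dropped last-first — a 2-vs-2 contrast cannot carry both age and sex, and
a zero-residual-df design would silence the dispersion estimate entirely);
and covariates whose inclusion pushes the condition coefficient's VIF
above 5 (the usual convention) are dropped worst-first, since an unlucky
age or sex split in a 2-vs-3 contrast can otherwise multiply the condition
SE severalfold. Fits with natural-log SE > 10 (quasi-separation: a
condition cell of all zeros) are flagged as non-converged rather than
reported as huge pseudo-estimates.

## Welch comparison of fold changes

Implemented exactly as displayed in the motivating study: standard
deviations are recovered from reported standard errors as `s = se·√n`,
`s_Δ = sqrt(s1²/n1 + s2²/n2)` (algebraically `sqrt(se1² + se2²)`), two-sided
p from the t distribution at Welch–Satterthwaite df. The Δ sign convention
is first-argument-minus-second; its own worked example ("−0.13 −
4.3 = −4.43") fixes this, against its table caption which states the
opposite. With one contrast of 5 samples the df is ≈4 regardless of the
other side's 192.

Between-contrast significance defaults to **raw p < 0.05** (BH-adjusted p
is computed, reported, and selectable). Two reasons: at df≈4 the
t-distribution's tails make genome-wide FDR-adjusted detection essentially
impossible even with oracle dispersions, and the published partition counts
(≈7.0% of genes "significant between", barely above the 5% null rate) are
only consistent with a raw-p threshold. Within-analysis DE status stays
FDR-based.

The early/late partition classifies every gene shared by two analyses into
{DE in 1} × {DE in 2} × {significant between}; genes DE in the second
analysis with a significant between-difference get fold-change-sign
quadrants (II and IV — sign flips — being the differential-behaviour
candidates). Genes filtered from exactly one analysis are reported in side
tables, never dropped silently.

## Preranked GSEA

Weighted KS walk with exponent p=1 (the field default; the motivating study does not
state it), gene-sampling permutation null (forced by preranked input),
null sharing across sets of equal size, NES = ES / mean(|null ES| of the
matching sign), add-one permutation p, BH across sets, size bounds 15–500.
Permutation subsets are drawn as the k smallest of n iid uniforms per
row, which vectorizes the null cleanly; the per-permutation ES uses the
piecewise-linear structure of the walk (extrema occur only at hit
positions). The implementation is cross-checked in the test suite against
the Bioconductor reference implementation on a fixed instance. `n_perm`
defaults to 10,000 (unstated in the motivating study); the pipeline default is 1000
— permutation resolution 1/(n+1) ≈ 0.001, ample for FDR 0.05 over ~100
sets.

## Agreement classes and graphs

Class from the significance pattern at FDR<0.05: only (3)vs(5) → CAU
Unique; (1) and ((4) or (3)vs(5)) → CAU Enhanced; only (1) → BA9 Unique;
anything else → Unclassified (reported, never guessed). Note that under
the synthetic defaults the tiny contrast (4) is *better* powered relative
to its world than the real one was, so interaction-driven sets typically
show in both (4) and (3)vs(5) and land in Unclassified — the classes are a
pure function of the flag pattern, not of intent. The
leading-edge graph joins sets whose leading edges share more than the
threshold (default 0.25) under the overlap coefficient
|A∩B|/min(|A|,|B|) — "share more than 25% of their leading edge genes"
most plausibly protects the smaller set — with Jaccard as the alternative.
The 10 functional categories are a user-supplied pattern→label map (the
original curation was manual); the synthetic default assigns round-robin.

## Random-forest consistency

Per repetition: stratified 75/25 split mirroring class ratios; a gene panel
(top-`250` by padj, ties by |L2FC| then gene id; or random; or random with
randomized training labels); a forest (default 20,000 trees, √panel
features per split — tests and the pipeline scale trees down since vote
fractions converge far earlier); vote-weighted test metrics (mean fraction
of trees voting the true label, i.e. the same "fraction of trees" currency
used for query consistency) and hard-vote training accuracy (fully grown
trees memorize, so this is 1 even under the null — as published). Query
samples are pushed through every repetition's forest and their vote
fractions averaged.

The null mode draws training labels **iid uniform** over the two classes
rather than permuting them: a permutation preserves the 26:56 class prior,
and a fully grown forest's votes then track that prior (≈0.32/0.68),
which contradicts the published null behaviour (accuracy 0.489,
sensitivity ≈ specificity ≈ 0.49, votes 0.485/0.515). Severing the prior
as well as the signal reproduces it; `null_label_mode="permute"` restores
the pure permutation.

## Problem sizes and determinism

Default analysis scale: 2000 genes, 120 gene sets, 1000–2000 permutations,
100 forest repetitions × 1000 trees — chosen so the complete analysis runs
in minutes on one CPU while keeping every calibration within Monte-Carlo
noise of its asymptote. All stages draw from `numpy` Generators seeded via
`SeedSequence([global_seed, stage_index])`; identical configs reproduce
byte-identical outputs, and any stage can be rerun alone from cached
upstream tables.

## Known limitations

- The NB Wald p-values in 4–5-sample contrasts lean entirely on the
  dispersion trend; gene-specific dispersion outliers there are invisible,
  exactly as in any small-n RNA-seq analysis.
- The Welch comparison treats the two DE tables' standard errors as known
  standard deviations through the `se·√n` convention of the motivating study; it
  inherits that convention's df behaviour (df pinned near the smaller
  contrast) rather than re-deriving an effective df from the GLM.
- Agreement classes replicate the published flag patterns verbatim;
  patterns outside them are Unclassified by design.
- GSEA omits the multilevel p-refinement of modern fgsea; permutation
  resolution bounds the smallest attainable p.
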