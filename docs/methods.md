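# Methods

This note documents the models implemented in `bescope`, the
assumptions behind them, the defaults that matter, and the numerical
choices a user may want to audit.

## Coordinates and quantification

All user-facing positions are 1-based protospacer coordinates
(positions 1–20, PAM at 21–23); internally slices are 0-based
half-open. The convention is defined once, in `bescope.sites`, and a
site's 40-nt context is fixed as 10 nt upstream + 20 nt protospacer +
3 nt PAM + 7 nt downstream. Reverse-strand sites are stored already
oriented to the protospacer strand, so none of the downstream maths
ever sees genome orientation.

Quantification starts from allele-frequency tables (CRISPResso2
column dialect). The reference may be the 40-nt context or a longer
amplicon; positions are always computed relative to where the
protospacer occurs in the reference. Per-read events are classified
once (`decompose_read`) and every statistic is a read-count-weighted
sum over alleles:

- **overall efficiency** = reads with the intended transition (A→G for
  ABE, C→T for CBE) at ≥1 target base inside the editing window / total
  reads. Default windows: 5–7 (ABE), 4–8 (CBE).
- **per-position efficiency** = reads with the intended transition at
  that position / total reads; defined only where the reference base is
  the editor's target base. The denominator is deliberately *total*
  reads, not position-covering reads: an allele whose deletion spans the
  position counts as not edited there.
- **modified efficiency** = reads with any substitution or indel / total
  reads.
- **purity** — for each of the 12 transitions X→Y, the fraction of
  reads carrying it, normalised so the 12 proportions sum to 1 within
  each scope. Scopes are taken over the protospacer: *overall*
  (positions 1–20), *in-window*, *outside-window* (protospacer minus
  window). A read carrying two different transitions contributes to
  both; a read carrying the same transition twice counts once.
- **indels** — 1-bp-resolution (position, signed length) events.
  Deletion runs are attributed to their first deleted base inside the
  protospacer; insertions to the position of the base immediately 3' of
  the insertion point (so the nick-site insertion between 17 and 18
  lands at 18). Regions: deaminase-attributed 1–11, nCas9-attributed
  14–20; positions 12–13 belong to neither, matching the region
  definitions. Cross-site indel profiles retain, per indel length, only
  sites inside the 25th–75th percentile band of that length's frequency
  (linear-interpolation quantiles, boundaries inclusive) and divide
  event frequencies by |length| (a config switch, since the exact
  normalisation is a judgement call).

Replicates below 100× coverage are excluded and the rest averaged
field-wise; a site with no surviving replicate is dropped and logged.
Editing:indel ratios are summarised by the geometric mean (ratios are
roughly log-normal across sites); zero-efficiency or zero-indel sites
are excluded before taking logs.

## Outcome distributions

For outcome analysis a replicate must have edited-read fraction
Ne/Nt ≥ 0.9, and replicates whose mean pairwise KL divergence between
allele distributions (pseudocount 0.5 per allele before normalising)
exceeds the Tukey fence Q3 + 1.5·IQR are removed as discordant.
Surviving replicates are pooled; reads with indels are excluded
(outcome products are editing alleles), the wild type is removed,
proportions are normalised, alleles at or below 5% are dropped, and the
rest renormalised. An allele is identified by its *edit pattern* —
which target bases carry the intended transition — with other
substitutions kept as a side annotation; pattern-level aggregation is
used whenever predictions are compared to observations. The procedure
is idempotent: collapsing its own output reproduces it.

Paired endogenous/integrated comparisons use two groupings:

- **efficiency bias** — OLS of endogenous on integrated efficiency;
  residual μ ± σ (population σ) defines Endo-bias (> μ+σ), Inte-bias
  (< μ−σ), Consistent (the rest). A numerically zero σ collapses to
  all-Consistent (a zero-width band cannot exclude anything).
- **outcome consistency** — set comparison of allele sets: equal →
  Consistent; strict superset on either side → Endo-/Inte-bias; alleles
  unique to both → Discordant.

## Sequence-motif model

One example per window target base: the 7-nt context (3 up + target +
3 down), one-hot encoded over the 6 flanking positions (24 features;
the centre base is constant per editor). Efficiencies are fractional
responses, so the "logistic regression" is a fractional logit: a GLM
with binomial family and logit link fit by IRLS, treating the deviance
as a quasi-likelihood. Responses at exactly 0 or 1 are nudged by
ε = 1e-6 to keep the logit finite. When the likelihood surface is
nearly flat (e.g. label-shuffled nulls) IRLS can enter a shallow limit
cycle; the fit then warm-restarts once and falls back to L-BFGS,
accepting the result only if its deviance is at least as good. The
70/30 train/test split is a seeded shuffle; reported variance explained
is the square of the held-out Pearson R. Per-position fits and a pooled
fit are both available, since pooling window positions without a
position covariate would confound motif and position effects.

## Endogenous-factor annotation

Peak overlap uses BED half-open semantics; ≥1 bp counts. H3K27ac is
queried over a widened interval (protospacer ± 65 bp, or ± 500 bp via
config) because acetylation domains extend over one or more
nucleosomes. Expression is log₂(TPM+1); the high/low threshold (1.5)
applies on that scale *before* min–max scaling — a min–max value cannot
exceed 1, so the threshold is only meaningful pre-scaling. Methylation
is the mean beta over covered protospacer bases, flagged methylated
strictly above 0.75; per-base flags mark targeted Cs (CBE) or
CpG-context As (ACG/CGA motifs, ABE) in the window that intersect a
covered record; uncovered means unmethylated. Min–max normalisation is
log₂(x+1)-then-scale for signal-like tracks and scale-only for beta
values. The CRE flag is the union of DHS, H3K4me3, H3K27ac and CTCF
flags unless an explicit CRE track is supplied; the union rule is a
stand-in for a full regulatory-element catalogue and is recorded in the
annotation metadata. Factor-vs-efficiency tests regress efficiency on
the factor with the window target-base count as confounder (OLS,
two-sided p). The promoted-motif ratio uses the fixed promoted
{TAT, TAC, CAT, GAC, GAT} and inhibited {CAG, AAG, CAA, AAA} lists with
a 2×2 χ² test *without* continuity correction (recorded so the printed
statistic is reproducible).

## Efficiency network

The per-position efficiency model maps a 40 × (4+k) input — one-hot
sequence plus k factor channels — to 20 sigmoid outputs. Factor
channels broadcast the per-site normalised value down the 40-nt axis,
except per-base methylation, which is laid along covered protospacer
positions. Default channel sets: H3K27ac only for ABE, all ten factors
for CBE, reflecting which factors measurably modulate each editor.

Architecture: five parallel 1-D convolution branches (kernel widths
1–5, 8 filters each, ReLU, He initialisation), channel concatenation,
one width-2 max-pool, and a dense sigmoid head — an inception-style
arrangement in which each branch sees the same sequence at a different
receptive width. Branch widths and filter counts are config-exposed.
The loss is mean-squared error masked to target-base positions;
perturbing labels anywhere else provably leaves gradients unchanged
(checked by an exact-equality test and finite differences). Training is
Adam (lr 3e-3, batch 128, ≤80 epochs) with a per-epoch 20% validation
split, early stopping at patience 10, and best-parameter restoration.
The network is implemented directly on NumPy with analytic backprop:
at these problem sizes (thousands of length-40 inputs) it trains in
seconds to minutes on one CPU and is bit-reproducible for a fixed seed.
A logit-scale MSE is available as a config alternative; plain MSE on
[0,1] efficiencies matches the Pearson-R evaluation used throughout.

The training protocol draws six independent seeded 80/20 splits,
stratified by presence/absence of any endogenous-factor flag (with an
unstratified fallback if a stratum side would be empty), and reports
per-shuffle and pooled held-out Pearson R (Fisher-z confidence
intervals). Paired model comparisons on shared observations use
Steiger's Z for dependent correlations.

## Chain proportion model

Editing at editable position i is Bernoulli(m_i); adjacent positions
couple through the odds ratio c = p₁₁p₀₀/(p₀₁p₁₀). The 2×2 joint is
reconstructed from (p, q, c) by the Plackett inversion: for c ≠ 1,
p₁₁ is the *smaller* root of (c−1)p₁₁² − Sp₁₁ + cpq = 0 with
S = 1 + (p+q)(c−1) — the only root inside the Fréchet bounds
max(0, p+q−1) ≤ p₁₁ ≤ min(p, q), which a randomized property test
re-verifies. The joint over all positions factorises as a chain,
P(X₁…X_n) = P(X₁)∏P(X_i|X_{i−1}), i.e. distant-position dependence is
carried only through adjacent links; the mutual-information audit
reports pairwise MI (bits) and the conditional MI of distant pairs
given the intermediate position to quantify what that first-order
assumption misses. Marginals are clamped to [1e-6, 1−1e-6] before
conditioning so conditionals stay finite at observed 0/1 efficiencies.
Enumeration is guarded at 12 editable positions (4096 outcomes);
real windows contain far fewer target bases.

c is estimated from observed pattern distributions as a pooled
2×2 with pseudocount 0.5 per cell; proportions are scaled by the
per-site read depth when known (with pure unit-weight proportions the
pseudocount would swamp single-site estimates). Estimation can pool per
position pair across sites or per site; note the odds ratio is not
collapsible, so cross-site pooling over heterogeneous marginals
estimates a population-level working parameter rather than the common
per-site c. Never-observed pairs default to c = 1 with a warning.
Max-form ties break deterministically: fewest edited bases, then
leftmost edited position, then lexicographic pattern.

## Synthetic-data generator

The generator is the package's test bed and defines its study
conditions. Per-site true marginals are a logistic function of a base
logit (−0.8), a 3-mer motif effect (Gaussian, σ = 0.8, fixed per seed),
a position effect (0 inside the window, −2.5 one position outside,
−4.5 beyond — editing collapses outside the window), and factor effects
on the logit scale (e.g. methylation −0.8 and expression +0.6 for CBE,
H3K27ac −0.4 for ABE — signs chosen to mirror the direction each factor
pushes editing). Co-editing uses a single adjacent odds ratio c = 4.
Bystander (unintended) transitions occur at a flat 0.002/read/position
so purity scopes are non-trivial; 1-bp insertions between positions 17
and 18 at 0.008 and window 1-bp deletions at 0.003/position give the
characteristic indel profile. Reads are multinomial at fixed depth per
replicate (an overdispersion knob widens depth variation); factor
tracks (peaks, expression, per-base methylation) are emitted as real
BED/TSV/bedGraph files and the annotations are derived from those files
through the annotation module itself, so track round-trips are
self-consistent by construction.

What the generator does *not* emulate: sequencing error, PCR chimeras
and amplification bias, multi-bp indels, microhomology effects,
correlated factor co-occurrence, and integration-site effects. Passing
tests therefore demonstrate that the estimators and models recover the
quantities they target under the stated generative assumptions — not
that those assumptions exhaust real endogenous data.

## Problem sizes and verification

The test suite and the acceptance script use a closure experiment of
2000 CBE sites at 10⁴ reads per site — large enough that marginal
recovery error is dominated by model fit rather than counting noise,
while a full run (simulation, quantification, six-shuffle network
training) completes in minutes on one CPU. Odds-ratio recovery is
verified two ways: a 10⁶-read single-model round trip against a
3-analytic-σ band (σ from the inverse-cell-count formula for the
log odds ratio), and the closure-wide median per-site estimate against
a ±10% Monte-Carlo band — the pooled per-site estimator carries a small
pseudocount-induced shrinkage toward 1 (fractions of a percent at this
depth) that a band tied to the pooled standard error alone would
misread as failure. Exact oracles back the formula-level checks:
a read-by-read recount for quantification, explicit Markov-chain
enumeration for the chain model, and an independent covariance-form
implementation for Steiger's Z.

## Known limitations

- The chain model ignores residual distant-pair dependence beyond the
  first-order links; the MI audit measures, but does not correct, it.
- The fractional logit treats per-base efficiencies as independent
  observations; within-site correlation is not modelled.
- Cross-site pooled odds ratios are working parameters (see above).
- The annotation module consumes pre-computed tracks; it does not
  process raw sequencing assays, and the exact composition of a
  regulatory-element catalogue is left to the user (union rule by
  default).
- Indel taxonomy stops at (position, signed length); no microhomology
  or multi-bp structure.
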