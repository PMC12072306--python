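# Methods

This note documents the models, algorithms and numerical choices behind
`simplihit`, what the synthetic benchmark does and does not emulate, and
the design decisions taken where the design was genuinely open.

## Library enumeration

A scaffold is a SMILES string with numbered wildcard atoms `[*:i]`
(i = 1..k in declared position order); fragments carry one unnumbered
`[*]`. Products are assembled with RDKit's `molzip` on matching atom-map
numbers and canonicalised; the hydrogen fragment `[*][H]` attaches an
explicit H that is folded back into the implicit count, so "unsubstituted"
is an ordinary library member — a requirement of the simplification
stage, whose products are mostly-hydrogen assignments.

Enumeration order is an odometer over the declared positions with the
rightmost position varying fastest, which fixes library ids and makes
runs byte-reproducible. Counting is by assignment (the combinatorial
product of list lengths), not by distinct structure: two assignments that
collapse to the same molecule (e.g. symmetric para-substitution) are both
kept and flagged in the rejection/duplicate log when duplicate tracking
is on. Tracking is off by default because it needs a seen-set, and the
enumeration contract is otherwise constant-memory streaming. Chemically
invalid attachments (e.g. a double-bonded fragment marker onto an
aromatic carbon) are logged with their assignment and skipped; the stream
continues.

## Descriptors

The descriptor block is RDKit's full 2D catalogue (~210 descriptors),
the open equivalent of commercial 2D descriptor sets of comparable size;
the exact names used are recorded in every selection result and model
file, and no attempt is made to reproduce any other toolkit's values
numerically. Computation is a pure function of (SMILES, descriptor set).

Cleaning, applied to training matrices only: constant columns and
columns with more than 20% missing values are dropped; remaining missing
values are imputed with the training-set median. The medians and
per-feature (min, max) ranges are frozen into the cleaned matrix and
re-applied to every later matrix (library, simplified candidates), so
test-time imputation and applicability checks never see test statistics.

## Hybrid feature selection

Three stages compose, all scored by mean R² over a seeded, shuffled
5-fold cross-validation of the downstream model family (RBF-SVR with
fixed mid-grid settings during selection; the final hyperparameters are
tuned afterwards):

1. **CFE** keeps descriptors with |Pearson r(descriptor, pIC50)| ≥ 0.3
   on raw (unscaled) values. The absolute value is used deliberately: a
   strongly anti-correlated descriptor is informative. Undefined
   correlations (constant columns) count as 0. If fewer than two
   descriptors survive, the two with the largest |r| are retained so the
   later stages have a working set.
2. **RFE** is iterated to convergence: each pass evaluates the working
   set with every single descriptor left out and permanently removes the
   one whose removal improves the score the most; it stops when no
   removal improves the score by more than 10⁻⁶ (a float-noise guard) or
   the working set reaches the floor of 2. A consequence worth stating:
   an exactly redundant descriptor whose removal does not *strictly*
   improve the score is kept — redundancy alone is not grounds for
   removal under an improvement-only rule.
3. **RFA** walks every removed descriptor — CFE-removed first, then
   RFE-removed, each in removal order — and permanently re-adds any whose
   addition strictly improves the score. This is where non-linear
   relationships (|r| < 0.3 but kernel-learnable) are rescued; on the
   scaffold benchmark RFA contributes most of the final feature set,
   because multi-position variation dilutes every univariate correlation.

Ties always break towards the earliest matrix column. The composition
guarantees the final CV score is never below the post-CFE score, and the
whole procedure is deterministic given (data, config, seed).

## QSAR models and validation

One model per target — the assays being emulated are single-protein —
with all dual-target logic (means, Pareto) strictly downstream. The model
is a pipeline of z-scoring (means/SDs frozen from training) and RBF-SVR.
Grid search is exhaustive over C ∈ {0.1, 1, 10, 100},
γ ∈ {10⁻³, 10⁻², 10⁻¹, 1}, ε ∈ {0.01, 0.1} (configurable), judged by mean
5-fold CV R² on seeded folds; the winner is refit on all data.

Validation panel:

* **Q² (LOO)** — 1 − PRESS/SS_tot with each prediction from a model
  trained without that sample.
* **R²(CV5), R²(CV10)** — out-of-fold predictions pooled into one vector
  and scored once (pooled, not fold-averaged — the choice is documented
  because both conventions exist). Folds are stratified by y-quantile:
  sort by y, deal each consecutive block of k samples to the k folds in
  seeded random order. With k = n this reduces *exactly* to LOO, which
  the tests assert.
* **y-randomization** — 50 repetitions by default: permute y, rescore by
  5-fold CV, report all scores and the mean. Informative models collapse
  to ≤ 0.

Applicability domain is the per-feature range rule: a prediction is
flagged as extrapolating iff any selected feature lies strictly outside
its training [min, max]; boundary values are inside (closed interval).
Flagged compounds are carried, not removed — range extrapolation shows no
activity bias on combinatorial libraries, and dropping them would discard
information; the flag travels through every downstream table.

Mean pIC50 values in report tables use decimal half-even (banker's)
rounding at two decimals. This is the convention that reproduces the
printed means of already-rounded per-target pairs — (7.81 + 7.08)/2
reports as 7.44 — where half-up would print 7.45.

## Simplification

The top set is the best N compounds by mean predicted pIC50 among those
above the activity threshold (defaults N = 4000, pIC50 > 7; a shortfall
is logged, not fatal). Frequencies are counted from assignment vectors —
provenance, not substructure matching — so they are exact. Privileged
substituents are the top-k per position (k an int or per-position map)
or, alternatively, all substituents above a fraction cutoff; hydrogen is
always excluded, since unsubstituted positions are the simplification
target, not a privileged group.

Simplified candidates carry between 1 and `max_decorations` (default 2)
privileged substituents at distinct positions, hydrogen elsewhere,
optionally constrained so every multi-substituent product occupies an
anchor position. Pairs as the default shape reflects how such campaigns
are actually synthesised — two-point decoration keeps routes short while
a single substituent rarely yields enough candidates to select from.
Products are canonicalised, de-duplicated and re-predicted with the same
frozen models and training statistics as the library.

The complexity score is an own, frozen proxy (no external tool's formula
is reproduced):

    complexity = heavy atoms + 2·rings + distinct non-carbon elements
                 + atoms with > 2 heavy-atom neighbours

It grows with size, ring count, heteroatom diversity and branching, and
is strictly monotone under adding a heavy atom at a terminal position —
enough to order bare scaffold < simplified candidate < decorated library
member, which is all the funnel asks of it.

## Pareto ranking and selection

All objectives are maximised. The Pareto value of a candidate is its
dominance count: the number of candidates it is ≥ on every objective and
> on at least one; ties on all objectives dominate neither way. Dominance
counting is vectorised but verified exactly against an O(n²) explicit
double loop in the tests (the two implementations share no code). The
dominance count was chosen as the scoring statistic because it is bounded
by n−1, gives front members the highest scores, and degrades gracefully
for near-front points; "distance to front" scalarisations were rejected
as scale-dependent.

`rank_combinatorial` = 1 + the number of full-library compounds with
strictly greater mean prediction; the library means are streamed, so
libraries of 10⁵–10⁶ rows never need to be in memory. The final slate is
a greedy walk down the ranking (Pareto value desc, mean desc, id) keeping
only candidates that contribute at least one unseen
(position, substituent) pair, until the quota (default 17) or exhaustion.

## Synthetic benchmark

The generator stands in for a curated bioactivity training extract.
Default configuration, fixed once: a 5-position bicyclic scaffold with
(8, 6, 6, 8, 4) substituents per position including hydrogen (9,216
products) drawn from a built-in pool of 43 valid small fragments; two
targets with contribution correlation ρ = 0.8; baseline pIC50 5.5;
additive per-(position, substituent) contributions ~ N(0, 0.7) with
hydrogen fixed at 0; per position, 2 substituents receive a boosted
contribution of 0.7 + |N(0, 0.7)| so that every position carries
genuinely activity-driving chemistry (without the boost, a position's
top contributors can be statistically indistinguishable from zero, and
"recovering" them is not a meaningful test); 5 sparse pairwise
interaction terms ~ N(0, 0.2) probing the additivity assumption that
frequency-based analysis relies on; assay noise SD 0.3 per target.
Ground truth records the top-2 substituents per position by mean (and
per-target) contribution. Training sets are uniform draws without
replacement with fresh noise; a 400-compound training set is the default
study condition, commensurate with the ~700–800-compound curated sets
such campaigns typically assemble, scaled to the smaller library.

What the benchmark emulates: position-wise substituent effects dominating
activity, correlated dual-target SAR, noisy single-protein assays, and a
library whose best members are heavily decorated. What it does not:
real kinase SAR, activity cliffs, scaffold-level conformational effects,
assay systematic error, or the descriptor distributions of real
bioactivity extracts. Passing tests therefore demonstrate that the
machinery recovers planted additive signal through the full funnel — not
that any particular real campaign would reach the same Q².

## Problem sizes and determinism

Default test and acceptance runs use the 9,216-molecule benchmark with
400 training compounds — large enough for stable feature selection and
LOO validation, small enough for interactive use on a laptop core. Every
stochastic step (benchmark construction, training-set draw, CV folds,
grid search, y-randomization) is seeded from the run seed; identical
configs produce byte-identical outputs, which the tests assert.

## Known limitations

* Greedy RFE/RFA explores single-feature moves only; feature sets are
  locally, not globally, optimal (the tests verify global optimality only
  on 4-feature problems where exhaustive search is feasible).
* The range-rule applicability domain ignores correlation between
  descriptors; a compound can be inside every marginal range yet far from
  the training manifold.
* Substituent frequencies assume approximate additivity; strong synergy
  between positions (large interaction terms) would mislead any
  frequency-based privileged analysis, by construction.
* Duplicate products from symmetric assignments are counted per
  assignment, so frequency denominators follow assignments, not distinct
  structures.
* The complexity proxy is ordinal, not calibrated to synthetic step
  count.
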