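# simplihit

Rational structural simplification for scaffold-based hit discovery.

Combinatorial libraries built by decorating a privileged scaffold easily
reach 10⁵–10⁶ molecules, and the best-predicted members are almost always
the most heavily decorated — structures that would take eight-plus
synthetic steps to make. `simplihit` implements a complete triage funnel
that ends in *simple* structures instead: enumerate the library, predict
per-target activity with validated QSAR models, find the substituents
over-represented among the best-predicted compounds ("privileged"
substituents), regenerate low-decoration candidates carrying only those
substituents, and rank them by Pareto dominance across two targets. It is
aimed at small medicinal-chemistry groups running dual-target campaigns
(the motivating case: pyrido[2,3-*d*]pyrimidine inhibitors of the FGFR2
and IGF1R kinases) who need a short, synthesizable, information-rich
slate of candidates rather than the raw top of a virtual screen.

## The method

**Library.** A scaffold with k substitution positions and per-position
substituent lists of sizes n₁…n_k defines a combinatorial library of
∏ nᵢ products (e.g. 30·14·12·27·5 = 680,400). Every product is assembled
by attachment-point substitution and canonicalised.

**QSAR.** Per target, an RBF-kernel support-vector regression ŷ = f(x)
maps 2D molecular descriptors x to pIC50 (−log₁₀ IC50 [M]). Descriptors
pass through a three-stage hybrid selection:

1. *CFE* — keep descriptors with |Pearson r(x, y)| ≥ 0.3;
2. *RFE* — greedily remove, one per pass, the descriptor whose removal
   most improves the 5-fold CV R², until no removal helps;
3. *RFA* — revisit every removed descriptor and re-add it iff it strictly
   improves the score (rescuing non-linear relationships the univariate
   filter missed).

Hyperparameters (C, γ, ε) come from grid search; validation reports the
standard panel

&nbsp;&nbsp;&nbsp;&nbsp;R²(self), Q² = 1 − Σ(yᵢ − ŷ₍₋ᵢ₎)²⁄Σ(yᵢ − ȳ)² (leave-one-out),
pooled R²(CV5), R²(CV10), and the mean y-randomization score
(which must collapse to ≤ 0 for an informative model).

Predictions whose descriptors fall outside the per-feature training
[min, max] ranges are flagged as extrapolations but kept — on
combinatorial libraries the flag shows no activity bias.

**Simplification.** From the top-N compounds by mean predicted pIC50
above a threshold (defaults: N = 4000, pIC50 > 7), count substituent
frequencies per position; the top-k per position are privileged (hydrogen
never is — absence of substitution is the goal). New candidates carry 1–2
privileged substituents (hydrogen elsewhere), optionally anchored at one
position.

**Ranking.** With per-target predictions as objectives (higher = better),
a candidate's *Pareto value* is its dominance count — the number of
candidates it beats on every objective, strictly on at least one; front
members collect the highest values. Candidates are also ranked within the
full library by mean prediction, and the final slate is picked greedily
down the ranking, keeping only candidates that add an unseen
(position, substituent) pair, maximising substitution diversity.

A built-in synthetic benchmark (`simplihit.benchmark`) generates a
scaffold, substituent libraries and training/test data from a planted
additive activity oracle with pairwise interactions, correlated targets
and Gaussian assay noise, so the entire funnel is testable with no
external data.

## Attachment-point grammar

* Scaffold: ordinary SMILES with numbered wildcard atoms, one per
  position — `[*:1]`, `[*:2]`, … in the order of the declared position
  names. Example (five-point pyridopyrimidinone-style core):
  `O=C1N([*:5])c2nc([*:1])nc([*:2])c2C([*:3])=C1[*:4]` with positions
  `[C2, C4, C5, C6, N8]`.
* Substituent fragment: SMILES with exactly one unnumbered wildcard
  `[*]` marking the attachment bond, e.g. `[*]c1ccc(F)cc1`.
* `[*][H]` is the explicit "unsubstituted" fragment, so bare positions
  are ordinary library members.

## Worked example

A full run on the default synthetic benchmark (9,216-molecule library,
400 training compounds, two correlated kinase-like targets):

```yaml
# run.yaml
outdir: out
seed: 1
benchmark: {}        # default synthetic benchmark
n_train: 400
top_n: 400
top_threshold: 7.0
quota: 17
```

```text
$ simplihit run-all --config run.yaml
[simplihit] benchmark inputs: library size 9216, 400 training molecules
[simplihit] enumerated 9216 of 9216 products (0 rejected)
[simplihit] training descriptors: 142 features kept, 68 constant and 0 mostly-missing dropped
[simplihit] FGFR2: 69 features selected (CFE removed 108, RFE removed 5, RFA re-added 40)
[simplihit] IGF1R: 34 features selected (CFE removed 137, RFE removed 1, RFA re-added 30)
[simplihit] FGFR2: R2(self)=0.970 Q2=0.941 CV5=0.936 CV10=0.939 y-rand=-0.203 (69 features)
[simplihit] IGF1R: R2(self)=0.870 Q2=0.830 CV5=0.815 CV10=0.819 y-rand=-0.134 (34 features)
[simplihit] predicted 9216 library molecules for targets ['FGFR2', 'IGF1R']
[simplihit] top set 400 -> privileged {'C2': 2, 'C4': 2, 'C5': 2, 'C6': 2, 'N8': 2} -> 50 simplified candidates
[simplihit] ranked 50 candidates, selected 9 (quota 17)
```

Reading the output: both models clear the Q² ≥ 0.7 bar that separates
predictive from memorising QSAR models, and label permutation collapses
the score below zero, so the structure–activity signal is real. The 9,216
products funnel down to the 400 best-predicted, to 2 privileged
substituents per position, to 50 low-decoration candidates. The final
selection (`out/selection.csv`) starts:

```text
candidate_id,FGFR2,IGF1R,Mean,ParetoValue,RankCombinatorial
C2:*c1ccc(F)cc1|C4:*Br,8.99,7.64,8.32,46,1064
C2:*c1ccc(F)cc1|C5:*c1ccccc1,9.02,7.58,8.3,45,1088
C2:*c1ccc(F)cc1|C6:*F,8.87,7.64,8.25,45,1146
```

Each row is a two-substituent candidate with its per-target predictions,
their mean, the number of simplified candidates it Pareto-dominates
(out of 49 others), and where its mean would rank inside the full
9,216-molecule library — deliberately *not* rank 1: these are simple,
synthesizable structures trading a little predicted potency for much
shorter routes.

Stage sub-commands (`simplihit enumerate|describe|select-features|train|
predict|simplify|rank --config run.yaml`) re-run any stage from the
persisted artifacts; `simplihit enumerate --count-only` reports the
combinatorial count of huge libraries without enumerating them.

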