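# Methods

## The model

`txinjury` treats molecular injury in a transplant biopsy as a position in a
low-dimensional continuous space estimated from ten standardized injury
scores: six gene-set (PBT) scores and four classifier probabilities.

**PBT scores.** A gene-set score is the mean, over the set's probe sets, of
the biopsy's log2 expression minus the per-gene mean of a designated control
group. Because the matrix stores log2 intensities this is a geometric-mean
fold change; `2**score` is the fold change on the natural scale. Scores are
translation-equivariant (adding c to a sample adds c to its score) and
invariant to member/sample order. Set members absent from the matrix are
dropped with a logged count; a set reduced below two members warns, since a
single-probe "set" is really a single-gene value. Control-identical samples
score exactly 0.

**Classifiers.** Each phenotype (eGFR ≤ 30 mL/min/1.73m²; proteinuria
positivity; ci > 1; ct > 1) defines binary labels on the biopsies where the
phenotype is recorded. Training is stratified k-fold (default 10) with the
whole pipeline — standardization, univariate F-statistic feature selection
(default top 30), L2-regularized logistic regression — fitted inside each
training fold, so out-of-fold probabilities come from models that never saw
the biopsy. The reported AUC is the Mann–Whitney statistic on out-of-fold
probabilities (ties count ½). A final model refit on all labeled data only
projects unlabeled/new biopsies; it is never substituted for the
out-of-fold probabilities.

**Correlation PCA.** The ten inputs are z-scored (n−1 denominator, stored
parameters so new biopsies are projected with training statistics) and
decomposed by SVD; eigenvalues/loadings equal the eigendecomposition of the
correlation matrix, and variance fractions are eigenvalues over their sum.
Signs are fixed deterministically: PC1 so the mean input score correlates
positively (global injury), PC2 so the chronic-minus-acute score contrast
(MCAT, IGT, ci>1_Prob, ct>1_Prob vs IRRAT30, IRITD3, IRITD5, DAMP)
correlates positively, PC3 so lowGFR_Prob loads positively. An
exactly-zero orientation statistic keeps the sign and warns. Orientation is
idempotent.

**Archetypal analysis.** Samples are modeled as convex combinations of k
archetypes that are themselves convex combinations of samples
(X ≈ α·β·X, rows of α and β on the probability simplex). The alternating
solver computes the α-step *exactly* per sample by enumerating active sets
(k is small), and updates each archetype against its partial residual,
projecting onto the convex hull of the data via penalized NNLS and
accepting the update only when the objective does not increase — so the RSS
trace is non-increasing at every iteration, which the tests assert.
Defaults: k = 5, 10 random restarts (k distinct data points each),
tolerance 1e-6 relative RSS change, 500 max iterations, sum-to-one
satisfied exactly by construction in α and by renormalization in β.

*Where the archetypes live.* By default the AA is fitted on the retained PC
scores (3 components) standardized to unit variance. Fitting directly on
the ten standardized scores is supported (`archetype_space="scores"`) but
was found inferior for recovering planted state structure: the classifier
probability columns saturate near 0/1, bending the score-space hull, and
PC1's eigenvalue (~5) outweighs PC3's (~0.3) in the least-squares
objective, so minor-but-meaningful dimensions get ignored. Whitening the
retained components makes the five planted states comparably weighted
(adjusted Rand index vs planted states ~0.63 in score space vs ~0.72–0.78
in whitened PC space at n = 4000).

**Archetype labels and groups.** With k = 5 the archetypes are named by
deterministic rules on their centroids in standardized input-score space
(computed through β when the fit was in PC space): lowest mean input score
→ *normal*; of the rest, the two highest on the acute-minus-chronic score
contrast are the acute pair, split by PC1 position (*AKI2* higher, *AKI1*
lower); of the remaining two, the higher mean acute-set score is *CKDAKI*,
the other *mildCKD*. Each biopsy's group is the argmax of its archetype
scores; exact ties (measure zero) break to the lowest archetype index.

**Factor map.** A variable's coordinate on PCj is its Pearson correlation
with the PCj scores. For an input column this equals loading × √eigenvalue
(the correlation-PCA identity, asserted to 1e-8); supplementary variables
(archetype scores, the 12 failed-repair set means, single genes) are
projected without influencing the fit. Top PC-correlated genes are ranked
by Spearman ρ with deterministic probe-id tie-breaks. A 2-D UMAP embedding
(seeded) is provided for visualization only.

## Survival design

Time 0 is the biopsy; the event is death-censored graft failure within 3
years (1095 days); death with a functioning graft is non-informative
censoring; administrative censoring applies at 3 years; one biopsy per
kidney is chosen uniformly at random under a seed, and biopsies without
positive follow-up are excluded with a logged count.

- **Kaplan–Meier** curves per injury group via lifelines (product-limit),
  with at-risk tables; verified against hand product-limit computations.
- **Cox with time-varying effects**: partial-likelihood fit (lifelines)
  with PC main effects and PC × g(TxBx) interactions, g = natural log of
  days by default (linear days selectable — the transform is a genuinely
  open choice; log is used because biopsy times span 3 days to 15 years).
  β(t) = main + interaction·g(t), with delta-method pointwise bands from
  the coefficient covariance. Fewer than 10 events per parameter warns.
- **Random survival forests** (scikit-survival): default ntree = 5000
  mirroring field practice, configurable downward since tree count is a
  runtime rather than statistical choice (tests and the acceptance script
  use 500). OOB error = 1 − concordance on out-of-bag predictions.
  Permutation importance is computed by this package: predictors are
  processed in name-sorted order with per-predictor seeded permutations and
  scored by the drop in Harrell's C of the forest's risk predictions, so
  the result is invariant to the caller's column order. The reference
  forest implementation's `nsplit` random-splitting parameter has no
  scikit-survival equivalent; the behavioural contract (permutation
  importance, 1−C error) is unchanged. Missing predictors are
  median-imputed.
- **Harrell's C** is computed over comparable pairs (the earlier time is an
  event; risk ties count ½), cross-checked against brute-force pair
  enumeration and scikit-survival's estimator.
- **Restricted cubic splines**: 3 knots at the 0.10/0.50/0.90 quantiles
  (Harrell's standard placements for 4 and 5 knots are also built in),
  truncated-power basis restricted to linearity beyond the boundary knots,
  least-squares coefficients.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes — it
is the study condition, not a tuning knob.

- **Latent states.** Each biopsy draws one of five planted states
  (normal 35%, AKI1 10%, AKI2 15%, mildCKD 20%, CKDAKI 20%) placed at
  vertices in (z1 acute, z2 chronic, z3 remodeling) space — normal at the
  origin, AKI states early-time with AKI2 more acute and AKI1 more
  remodeling, CKD states late with CKDAKI carrying acute + remodeling
  change — plus independent within-state Gaussian scatter (sd 0.4 per
  axis). A strict reading of "independent latent axes" conflicts with
  planting five vertex states (a mixture induces latent dependence); the
  vertex mixture was kept because archetype/state recovery is the point of
  the design.
- **Expression.** Per-gene baseline N(7, 1.2²) log2 units; every member of
  a gene set adds that set's configured (z1, z2, z3) loading times the
  biopsy's latents; i.i.d. N(0, 0.5²) measurement noise. Acute sets load on
  z1 (with small opposite-sign z3 contrasts, so remodeling varies *within*
  acute injury), chronic sets on z2 (opposite-sign z3 contrasts), New1 sets
  −0.6 z1 + 0.4 z3, New2/New3 0.5 z1 + 0.35 z3, New4 0.9 z1 + 0.6 z3, all
  New sets except New1 with −0.3 z2; one MKI67 probe at (0.4, −0.4, 0.1).
  Controls are baseline + noise with latents at zero (default 4 samples).
- **Clinical couplings.** TxBx is log-uniform on [3 days, 15 years]
  marginally, rank-coupled to z2 at 0.85; donor age N(45, 13²) coupled to
  z3 at 0.2; eGFR = 50 − 6 z1 + 2 z2 − 4 z3 + N(0, 9²), floored at 5 (the
  default noise keeps the low-GFR classifier's out-of-fold AUC near the
  mid-0.8s, a realistic ceiling for a molecular classifier of a clinical
  label); proteinuria and ci/ct through logistic/cutpoint links on the
  latents; %cortex uniform 5–95 so the >10% filter has work to do; ~15% of
  biopsies are repeat biopsies sharing a kidney id.
- **Survival.** Exponential failure times with
  log-hazard = log(8e-5) + (0.5 + 0.15·(log TxBx − log 365))·z1 + 0.35·z3:
  the acute-axis effect is ≈0 for first-weeks biopsies and grows with log
  time, the remodeling-axis effect is constant — the time-varying structure
  the Cox analysis is designed to detect. Death with function is an
  independent exponential (rate 1.5e-5/day); 30% of kidneys draw a uniform
  administrative censor before the 10-year horizon. Repeat biopsies of one
  kidney draw independent outcomes; only one enters any survival analysis,
  so the single-row-per-kidney analyses are unaffected.

Everything above is a `CohortConfig` field; the config round-trips through
JSON and the generator is byte-deterministic per seed.

**What the generator does not emulate:** probe-level microarray artifacts
(batch/scanner effects), realistic probe annotation, rejection-driven
expression, center-specific proteinuria definitions (a single logistic link
stands in for heterogeneous standard-of-care methods), and correlated
outcomes across repeat biopsies. Passing tests therefore demonstrate that
the estimators recover the structure they assume, not that real cohorts
satisfy those assumptions.

## Numerical choices and scale

- Standardization sd uses the n−1 denominator (documented for reproducible
  projection of new biopsies).
- Simplex constraints: α exact (active-set enumeration); β renormalized
  NNLS with penalty weight 1e4; both within 1e-8 in tests.
- Argmax ties break to the lowest archetype index.
- PCA keeps all components; three are interpreted and oriented.
- Problem sizes in the tests and acceptance script — 400–4000 biopsies,
  100–2000 probe sets, 500-tree forests, 10–20 replicate batteries — were
  chosen as the smallest scales at which the Monte-Carlo checks have
  comfortable margins.

## Known limitations

- The archetype count k = 5 is a modeling choice (configurable); the
  labeling rules are defined only for k = 5.
- The generator fixes three latent axes; real cohorts may have more
  injury-related dimensions.
- Classifier probabilities enter standardization like any other column;
  whether to standardize before or after probability computation is an
  open convention and the package picks the simpler one.
- Cox time-interaction fits use one transform for all PCs at a time;
  per-PC transforms require separate calls.
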