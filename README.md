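# txinjury

Molecular injury modelling for kidney transplant biopsies.

Kidney transplants experience parenchymal injury from donation, rejection,
drug toxicity and other stresses. In bulk transcriptomes of indication
biopsies, injury does not separate into discrete AKI/CKD diseases; it forms
continuous gradients. `txinjury` implements a complete injury-phenotyping
pipeline for such cohorts — and, because the real microarray cohorts it is
designed for cannot be shipped, a fully parameterised synthetic-cohort
generator with ground-truth latent structure so that every stage of the
pipeline is testable against known truth.

The pipeline:

1. **Gene-set (PBT) scores.** For a gene set *S* and biopsy *s*, the score is
   the mean log2 fold-change over the control-kidney baseline,
   `score_s = mean_{g in S} (x_gs − mean_c x_gc)`, with the control group
   (e.g. nephrectomy samples) designated in the expression matrix. Six
   transplant-derived input sets are scored (four acute-injury-related:
   IRRAT30, IRITD3, IRITD5, DAMP; two chronic: MCAT, IGT), plus twelve
   failed-repair epithelial-state signatures (New1 oxidative stress, New2
   hypoxia, New3 interferon response, New4 EMT, for three nephron segments
   each) used as supplementary variables only.
2. **Molecular classifiers.** Four cross-validated binary classifiers
   (low eGFR ≤ 30, proteinuria, ci > 1 fibrosis, ct > 1 atrophy) trained on
   expression with in-fold univariate feature selection and a regularized
   logistic model; labeled biopsies receive out-of-fold probabilities,
   unlabeled biopsies full-data-model projections.
3. **The injury space.** The 10 standardized inputs (6 PBT scores + 4
   classifier probabilities) enter a correlation PCA with deterministic PC
   orientation (PC1 = global injury, PC2 = chronicity/time contrast, PC3 =
   low-function/epithelial-remodeling pole) and an archetypal analysis
   (alternating simplex-constrained least squares, Cutler–Breiman
   formulation) with k = 5 archetypes labeled normal, AKI1, AKI2, mildCKD
   and CKDAKI; each biopsy gets 5 simplex archetype scores and an argmax
   group. Supplementary variables (the New gene-set means, archetype scores)
   are projected onto the PC factor map as correlations.
4. **Outcomes.** Biopsy-anchored death-censored 3-year graft survival, one
   random biopsy per kidney: Kaplan–Meier curves per injury group, Cox
   models with PC × log(TxBx) time-varying effects, random-survival-forest
   permutation importance (OOB error = 1 − Harrell's C), restricted cubic
   splines (3 knots) for score-vs-time/eGFR curves, and Spearman
   associations with donor age and single genes (e.g. the MKI67 probe set).

## Worked example

```python
import txinjury as tx

cfg = tx.CohortConfig(n_biopsies=400, n_probesets=500, seed=7)
expr, meta, sets, truth = tx.generate_cohort(cfg)

probs, _ = tx.classifiers.classifier_probabilities(expr, meta, n_folds=5, seed=1)
table = tx.score_table(expr, sets, probs)

results = tx.InjuryModel(table).fit(seed=3)
print(results.summary())

frame = tx.survival.build_survival_frame(meta, results.biopsy_frame(), seed=1)
curves = tx.survival.km_curve(frame, results.groups)
for g in ["normal", "AKI1", "AKI2", "mildCKD", "CKDAKI"]:
    s = tx.survival.survival_at(curves[g], 3 * 365)
    print(f"3-year death-censored survival, {g:8s}: {100*s:5.1f}%")
```

prints

```
Injury space model
==================================================
biopsies: 400   inputs: 10

PC   eigenvalue   % variance   orientation
PC1       5.492       54.9%   mean input score correlates positively
PC2       3.705       37.0%   CKD-minus-AKI contrast correlates positively
PC3       0.324        3.2%   lowGFR_Prob loads positively
PC4       0.217        2.2%   -
PC5       0.106        1.1%   -

archetypes: k=5, RSS=39.76, converged=True
group sizes: normal=171, mildCKD=97, AKI2=52, CKDAKI=42, AKI1=38

3-year death-censored survival, normal  :  89.3%
3-year death-censored survival, AKI1    :  82.1%
3-year death-censored survival, AKI2    :  87.6%
3-year death-censored survival, mildCKD :  73.7%
3-year death-censored survival, CKDAKI  :  23.9%
```

PC1 captures most of the score variance and is oriented toward globally
increased injury; PC2 separates chronic from acute scores; PC3 is small but
carries the remodeling/low-function contrast. The five archetype groups
order survival the way the injury biology predicts: biopsies in the
combined chronic+acute state (CKDAKI) fare far worse than molecularly
normal ones. Ground truth for this cohort is in `truth`
(`z1/z2/z3` latents, planted state labels, hazard multipliers), so recovery
can be checked directly — e.g. `results.pc_scores["PC1"].corr(truth.df.z1)`.

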