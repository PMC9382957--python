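# emovocab

Analysis pipeline for studying how children's **emotion vocabulary**
develops toward adult usage, built around free-labeling data: children
(four age groups, 4–11 years) and adults label 20 illustrated emotion
vignettes — six basic emotions (joy, fear, sadness, anger, disgust,
surprise) plus 14 subordinate "complex" emotions — and the pipeline asks
how many emotion words each group produces, which ones, how similar the
children's usage pattern is to the adults', what semantic dimensions
organise the labeling, and which word properties predict ease of learning.

It is written for developmental psycholinguists who want the full analysis
chain as tested, reusable code: a synthetic-data generator emulating the
study design makes every stage runnable and testable without access to raw
recordings.

## The analysis chain

1. **Coding.** Free answers are coded against a curated lexicon: surface
   forms collapse onto canonical stems ("ärgerlich" → "Ärger"),
   valence-only answers ("gut", "schlecht") become the two *unspecific*
   pseudo-words, negations of specific emotions ("nicht traurig") map to
   the unspecific category of the opposite valence, and physiological /
   cognitive / behavioral descriptors ("müde") are not emotion words.
   A word list keeps the words used by ≥ 5 distinct participants.
2. **Vocabulary size.** Per-participant distinct-word counts, compared
   across age groups with a one-way ANOVA (effect size
   η² = SS_between / SS_total) and Bonferroni-corrected pairwise post hocs.
3. **Convergence.** Each group's *production matrix* (20 vignettes × all
   words produced; cell = number of participants producing that word for
   that vignette) is correlated with the adult matrix over all flattened
   cells (Spearman ρ, average ranks). Adjacent age groups are compared
   with Fisher's r-to-z test for independent correlations,
   `z = (atanh r₁ − atanh r₂) / √(1/(n₁−3) + 1/(n₂−3))`.
4. **Semantic dimensions.** A vignette × vignette *co-naming* matrix
   (participants giving both vignettes the same word) is turned into
   dissimilarities and embedded in two dimensions by nonmetric MDS —
   SMACOF majorization with isotonic disparities, implemented from first
   principles, reporting Kruskal stress-1 (< 0.01 near-perfect, < 0.05
   excellent, < 0.1 good). Solutions are rotation-normalised so axis 1
   separates positive from negative vignettes.
5. **Ease of learning.** Word-level predictors — child-directed-speech
   *input frequency* and *specificity*
   `H(w) = −Σ_v p(v) log₁₀ p(v)` (entropy of the word's adult usage
   distribution over the 20 vignettes) — are regressed on production
   frequency and on per-word convergence with standardized OLS.

## Worked example

```bash
emovocab simulate --out responses.csv --seed 1      # synthetic study, 150 participants
emovocab analyze --responses responses.csv --out results --seed 1
emovocab report results
```

prints

```
mean number of different emotion words per group:
     4-5: 5.2 (SD 1.1)
     6-7: 6.4 (SD 1.6)
     8-9: 7.8 (SD 1.4)
   10-11: 10.3 (SD 1.9)
   adult: 15.2 (SD 1.6)
ANOVA: F(4, 145) = 185.9, p = 5.1e-56, eta^2 = 0.84
similarity to adult usage (Spearman rho over all cells):
     4-5: rho = 0.369 (n = 520)
     6-7: rho = 0.576 (n = 520)
     8-9: rho = 0.617 (n = 520)
   10-11: rho = 0.662 (n = 520)
MDS stress-1 per group:
     4-5: 0.0000
     6-7: 0.0000
     8-9: 0.0000
   10-11: 0.0258
   adult: 0.0002
```

Reading the output: vocabulary grows steadily with age and is still well
below the adult level at 10–11; the usage *pattern* converges toward the
adult pattern with age (ρ rising monotonically); and two dimensions
suffice to represent each group's co-naming structure (stress-1 at or
near the "excellent" benchmark), with dimension 1 separating positive
from negative vignettes in every group. `results/` additionally holds
`report.json`, per-group production matrices, and the word-measures
table; `--plots` adds per-group MDS scatters.

The same analyses are available as library functions
(`emovocab.simulate_responses`, `code_dataset`, `production_matrix`,
`matrix_convergence`, `smacof`, `fit_models`, …) for scripting.

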