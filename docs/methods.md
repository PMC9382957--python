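# Methods

This note documents the statistical procedures, the generative model
behind the synthetic data, and the numerical and design choices made where
the methodology left room.

## Coding model

Coding is lookup-table based, not algorithmic: a curated lexicon maps
surface forms to 36 canonical German emotion stems, mirroring how human
coders in free-labeling studies work from an established word list.
Decision order for one answer: no-answer markers → negation prefixes →
valence-only forms → stem/synonym lookup → non-emotion descriptors →
unknown (coded as not-an-emotion-word, with a warning; a real study
resolves these by hand). Negating a specific emotion ("nicht traurig")
carries valence information but no specific category, so it is coded as
the unspecific pseudo-word of the *opposite* valence; negating an
unspecific form flips it. The two unspecific pseudo-words behave as
ordinary words everywhere downstream (word list, matrices, similarity
matching, word-level measures) because valence-only labeling is itself a
developmental stage worth measuring, not noise.

The word list keeps codes used by at least `min_participants = 5`
distinct participants of the pooled sample — a participant-count, not a
token-count, threshold — ordered by descending token frequency with
alphabetical tie-break for determinism. Production matrices use the
*threshold-free* universe of all words produced anywhere in the sample,
so rare words still occupy cells; the thresholded list is reserved for
the word-level measures, where per-word statistics need enough users to
be meaningful.

## Vocabulary statistics

The distinct-word count per participant is compared across groups with a
one-way ANOVA computed from explicit sums of squares, which makes
η² = SS_between / SS_total available directly; p comes from the F
distribution. If SS_total = 0 (all counts identical) the statistic is
undefined and flagged as degenerate rather than forced to 0. Post hocs
are pooled-variance two-sample t tests with p multiplied by the number of
pairs (10 for five groups), capped at 1 — the plain Bonferroni rule.

## Convergence

A group's production matrix is flattened row-major and Spearman-correlated
with the adult matrix, *including* zero cells: the zeros form one large
tie group under average ranks, and this is the only reading under which
the full 20 × W cell count (1,320 for a 66-word universe) is the n of the
correlation. Per-word convergence correlates one word's 20-vignette count
vector between child and adult matrices; a vector without variance
(typically a word one side never produced) has no defined correlation and
is kept as missing internally — tabular output may render it 0.00, but
the distinction is preserved.

Fisher's r-to-z test compares two independent correlations:
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)). The one-tailed p
(normal tail beyond |z|) is reported as primary — the natural direction
when testing for an *increase* in similarity with age — with the
two-tailed p alongside.

## Multidimensional scaling

All scaling machinery is implemented in-package.

* **Dissimilarity transform.** Co-naming counts are normalised per
  vignette pair: d_ij = 1 − s_ij / n_pairs_ij, the share of participants
  answering both vignettes who did *not* give them the same word.
  Normalising by answering participants (not by the maximal cell) keeps
  groups of different sizes comparable; the max-count variant is
  available behind an option.
* **Initialisation.** Classical (Torgerson) scaling of the
  double-centered squared dissimilarities, negative eigenvalues clipped
  at zero, column signs fixed deterministically — so the whole procedure
  is deterministic with no random restarts.
* **SMACOF.** Iterative majorization (Guttman transforms). In the default
  nonmetric mode each iteration re-fits disparities by monotone
  regression (pool-adjacent-violators) of the configuration distances on
  the dissimilarities, using Kruskal's primary approach to ties: within a
  block of tied dissimilarities, pairs are ordered by their current
  distances and left free to receive unequal disparities. Disparities are
  rescaled to the distance norm each iteration to prevent configuration
  collapse. Convergence when the stress decrease falls below
  `tol = 1e-9`, `max_iter = 1000`. Fit is Kruskal stress-1,
  √(Σ(d̂−dist)²/Σdist²), whose per-iteration sequence is non-increasing
  (asserted in tests). Coincident points (zero distances) are handled by
  zeroing their ratio terms in the Guttman transform — the degenerate
  all-tied case arises naturally when a group co-names whole clusters of
  vignettes perfectly.
* **Orientation.** Stress is invariant under rotation, reflection,
  translation and uniform scaling, so solutions are normalised: rotate to
  principal axes, flip axis 1 so the positive-valence centroid is on the
  right, fix remaining signs by largest-magnitude entry. Only axis 1 is
  interpreted (valence); the second dimension is reported but not
  interpreted.

## Word-level predictors and regressions

Specificity is the entropy of a word's usage distribution over the 20
vignettes in the adult reference group, in **log₁₀ units**:
H(w) = −Σ p(v) log₁₀ p(v), giving a ceiling of log₁₀ 20 ≈ 1.301. The
log-10 base matches the scale of the published word table, whose maximum
printed specificity (1.10) is consistent with that ceiling and not with
natural log. Words the adults never produced have no distribution and get
a *missing* value, never 0.

Input frequency is consumed as a precomputed (surface form, count) table;
counts are attributed to stems via the synonym map or, failing that, by
substring containment (longest stem wins), emulating stem-based corpus
queries. Absent stems get 0 with a warning.

Regressions are OLS on z-scored DV and predictors, so single-predictor β
equals the Pearson correlation. Rows with missing specificity are scored
0 by default — maximally specific. This choice is deliberate: the
published regression degrees of freedom, (1, 36) with 38 words, show that
the reference analysis retained all rows including the three without an
entropy value, and zero-imputation reproduces its reported fit
(R² = .64 computed here vs .63 published for the 10–11y production-
frequency model) where row exclusion does not (R² = .74, df (1, 33)).
`exclude` and `max` (impute log₁₀ 20) remain available as options.
Missing per-word convergence values are scored 0 in regressions, matching
how such cells are tabulated.

## The synthetic-data generator

The generator emulates one study: 20 vignettes (6 basic + 14 complex,
7 positive / 13 negative), child groups of 30/31/32/30 and 27 adults, one
answer per participant × vignette in presentation order, per-participant
random streams derived from (seed, participant index) so runs are
reproducible and participants independent.

A child's answer follows the developmental progression of labeling
strategies:

1. with probability `dont_know_rate[group]` — no answer; five consecutive
   non-answers discontinue the child's session (the remaining responses
   are blank);
2. with `valence_error_rate` (default 0.02) the scene's valence is
   misread and the child gives a valence-only label of the flipped
   valence;
3. with `unspecific_rate[group]` — a valence-only label ("gut",
   "schlecht", "nicht gut", …), the early strategy;
4. otherwise the child produces the target word if it is in their active
   vocabulary — probability `vocab_curve[group]` for subordinate targets,
   min(1, ease × vocab) for basic targets, where the per-category ease
   (sadness/joy 20, fear/anger 2, disgust/surprise 1) encodes that the
   valence-anchor words are acquired first and disgust/surprise words
   last;
5. an unknown target is overgeneralized (probability
   `overgeneralize_basic = 0.95`) to the vignette's basic-category word
   if available, else to the valence-anchor basic word (sad/happy);
   otherwise the answer falls back to a valence-only label.

Basic words produced by children are swapped for child-register variants
(fröhlich/froh for joy, sauer for anger, Grusel for fear) with a
probability that decays as the vocabulary curve matures — children grow
out of the register. These variants are the synthetic counterpart of
words that children use but adults never do, so the word table contains
rows with missing specificity, exercising the imputation policy. A small
synonym-surface probability (0.15) makes the generator emit inflected
forms, giving the coding step real work.

Adults always answer from a per-vignette profile: target stem 0.55,
synonym surface 0.12, basic-category word 0.33. The basic-word mass makes
adult usage of basic words broad (high entropy) and of subordinate words
concentrated (low entropy), and brings adult distinct-word counts down to
a realistic level — real adults do not use 20 different words for 20
vignettes.

Defaults were calibrated once, by simulation, against the reference
study's published group-level conditions — mean distinct-word counts
rising roughly 4.4 → 9.7 across child groups with adults near 15,
valence-only token shares falling from roughly 40% to 5%, and
similarity-to-adult correlations increasing with age with a spread of
about 0.2–0.3 — and then frozen: `vocab_curve` 0.04/0.08/0.15/0.27 (1.0
for adults), `unspecific_rate` 0.25/0.08/0.05/0.03 (0 for adults),
`dont_know_rate` 0.18/0.08/0.04/0.02 (0 for adults).

**What the generator does not emulate:** free German text (answers are
coded-level tokens plus a thin synonym layer), inter-coder disagreement,
vignette-order and fatigue effects, per-vignette difficulty differences
within a category, cross-sectional cohort differences, and the true
adult per-vignette label distributions, which are unpublished — the adult
profile is a design choice. Consequently, passing parameter-recovery
tests shows the pipeline detects age-graded structure *of the kind the
model plants*; it does not validate the pipeline against transcription
noise or coder ambiguity in real recordings.

## Problem sizes

The default synthetic study (150 participants × 20 vignettes) runs the
full five-analysis pipeline in about a second; property suites use 10–20
seeded replicates and 20-point scaling problems. These sizes give stable
group-level statistics (group means, rank correlations over ≥ 500 cells)
while keeping every run interactive.

## Known limitations

* The similarity-to-adult ρ of synthetic runs is higher in absolute terms
  than values typical of real free-labeling data, because the synthetic
  word universe is smaller (≈ 26 words vs 66) and the zero-cell tie mass
  correspondingly heavier; the *ordering* across age groups, not the
  absolute level, is the validated quantity.
* Whether co-naming should count two valence-only answers as "the same
  word" is a genuine ambiguity of the similarity definition; the default
  counts them (they are pseudo-words throughout), and
  `match_unspecific=False` provides the sensitivity analysis.
* Nonmetric MDS on strongly clustered co-naming data legitimately reaches
  stress ≈ 0 with degenerate (coincident-point) configurations; this is a
  property of the data, not a solver failure, and the metric mode is
  available for comparison.
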