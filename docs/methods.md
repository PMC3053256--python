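# Methods

## Model and procedure

The package treats interactor extraction as a ranking problem over the
identifiers an upstream gene-normalization stage has attached to a
block-structured full-text article. Three stages are chained:

1. **Initial ranking.** Either a frequency baseline — article mention count,
   ties broken by Results-section mention count, then earliest mention — or
   any scoring model over the per-identifier feature vector (frequency,
   Results-ratio, location flags for title/abstract/first/Results/last/
   appendix/other sections, section headings and figure/table captions,
   keyword/full-name/abbreviation field matches, sentence co-occurrence with
   keywords, defined abbreviations and figure references, and indicator
   phrases such as "we conclude"). A max-margin linear model
   (`LinearSvmModel`) is the reference trained configuration; the shipped
   end-to-end path uses the frequency baseline so that the algorithmic core
   is exercised without any external training corpus.

2. **Re-ranking.** Sentence-level association drives candidate-list
   generation, placement scoring and a dynamic program, as summarized in the
   README. The per-rank accuracies (`svmAccuracy`) are estimated on a
   training corpus as the fraction of articles whose rank-i identifier is in
   the gold set, among articles that have a rank-i identifier.

3. **Pair ranking.** Sentence co-occurrence defines the candidate pair set;
   `IPTScore = MI · score · score` orders it.

### Assumptions

- Association is estimated per article; probabilities are sentence
  frequencies over the article's own sentences (N = sentences containing at
  least one identifier). Counting is over distinct sentences: repeating an
  identifier inside one sentence adds nothing.
- The initial ranking's top ranks are more reliable than its lower ranks;
  the accuracy profile encodes this and the re-ranking score exploits it
  twice (at the target rank and at the supporting list's rank).
- A mention's sentence is the one containing its span start; mentions
  outside any sentence (possible only with hand-built documents) are ignored
  by the statistics with a debug log.

## Fidelity and deliberate interpretation choices

Several details of the published description are underdetermined; the
choices below are part of this package's definition:

- **Own-list counting (`include_own`).** The literal rankN_Ratio formula
  sums over lists owned by *y ≠ x*, which gives isolated identifiers an
  undefined 0/0 ratio even though candidate generation clearly uses each
  identifier's own list. Default `include_own=True` counts the own list in
  both sums; the literal mode is available by flag and returns 0 on a zero
  denominator.
- **Accuracy at the target rank.** The score formula is read with
  `svmAccuracy(i)` and `deciderRank(x, i, L)` (its worked-example form);
  the recurrence's boundary is read as i ≥ 2.
- **Duplicate checking in the DP.** A candidate may extend a predecessor
  tuple only if it is absent from that tuple's traced from-chain. This is
  exactly the published table-filling procedure, and it is a *heuristic*:
  one chain per tuple cannot represent every duplicate-free prefix, so the
  DP can score below the exhaustive optimum. Correctness here is defined as
  fidelity to that procedure; optimality is measured, not asserted. On 500
  random instances with 2–6 identifiers the DP output never exceeds the
  exhaustive optimum (a feasibility/bound invariant in the test suite) and
  matches it on roughly nine in ten instances.
- **Degenerate instances.** If every final-rank tuple has overall score 0
  (possible through chain blocking), the input ranking is returned unchanged
  with a warning — re-ranking never destroys an ordering it cannot improve.
- **Leftover identifiers.** Identifiers absent from the traced path are
  appended in original-rank order so the output always ranks every
  normalized identifier; evaluation requires a full list. In pair scoring,
  such appended-tail identifiers take `floor_epsilon` instead of a hard 0 so
  association can still order their pairs.
- **Tie-breaks.** Everywhere deterministic: candidate-list filling breaks
  association ties by better original rank then identifier; the DP breaks
  predecessor ties by higher overall score, higher tuple score, better
  original rank, then identifier.
- **Ranks in IPTScore.** i and j are positions in the *re-ranked* list by
  default; original-ranking positions are available via `rank_mode="svm"`.

## Evaluation metric

AUC iP/R walks the ranked list; at the j-th correct hit it records recall
j/|gold| and precision j/position, interpolates precision as the maximum at
any equal-or-higher recall, and sums interpolated precision × recall
increment. The recall denominator is the gold-set size, so gold items never
returned cap the score below 1 — the reading under which missing curatable
identifiers must hurt. Duplicates count at first occurrence only. The
two-sample t statistic uses the unpooled standard error and is reported
raw; the significance helper compares against the one-sided 95% critical
value 1.67 (df 89) used for system comparison.

## Corpus dialect

The block file format is two lines per block — `TYPE<TAB>text`, then the
heading path joined by `" | "` (possibly empty) — with six block types
(TITLE, ABSTRACT, BODY, FIGURE, KEYWORD, TABLE). This canonical dialect is
this package's own definition: the upstream corpus format is described
structurally in the literature but its exact byte layout is not public.
A lossless JSON form is provided, annotations are TSV standoff records with
0-based half-open per-block character offsets, and ranks are 1-based
throughout. Sentence segmentation is rule-based with a fixed abbreviation
list ("Fig.", "et al.", "e.g.", "i.e.", "vs.", …) — reproducibility over
sophistication. Abbreviation definitions are detected with a simple
`Full Name (ABBR)` parenthetical matcher requiring initial-letter agreement.
Greek letters are transliterated to their spelled-out names; collapsed
ranges such as `SOCS1-SOCS7` expand to their components, with a cap of 20
members to avoid pathological expansions.

## Synthetic data

The generator plants the structure the method exploits: per article,
`n_interactors` gold interactors (default 4 of 9 identifiers) whose gold
pairs (default 3) co-occur in sentences at `pair_mention_rate ×
cooccurrence_boost` (default 0.4 × 5), against non-gold interactor pairs at
the base rate and sparse background co-mentions (rate 0.1). Mention
frequencies separate three classes: strongly mentioned interactors (Poisson
rate 8), weakly mentioned interactors (rate 1, the later half — the case
re-ranking is designed to rescue), and background genes (rate 5, one
"focus" gene at 5 discussed throughout without interacting). Interactor
mentions are placed with a section bias favouring Results (0.55), and the
articles carry keywords, a figure caption naming the most co-mentioned
pair, figure references in Results sentences, and an indicator-phrase
conclusion, so every ranking feature has signal. Rates were chosen so that
frequency ranking is good but imperfect — its mistakes (weak interactors
buried below backgrounds) are exactly the ones sentence co-occurrence can
correct, which mirrors the motivating scenario of a rarely mentioned
interactor always appearing beside the top-ranked one.

Sentences are templates, not natural language: the pipeline consumes
standoff annotations, so linguistic variation would test a tagger this
package deliberately does not contain. Passing recovery tests therefore
demonstrates that the algorithms exploit planted co-occurrence and section
structure; they say nothing about mention tagging, normalization quality,
species ambiguity, or real journal prose. Per-article seeds are derived by
hashing (corpus seed, article index), so corpora are reproducible and
articles independent; identical configs give byte-identical output.

Test problem sizes — 40 training articles for the accuracy profile, 50 test
articles for recovery means, 500 random instances for the DP and metric
oracles, 200 seeds for the boost/no-boost contrast — keep the full suite in
the tens of seconds while leaving the statistical checks comfortably
powered.

## Known limitations

- The DP is faithful to its published description, hence only heuristically
  optimal under the no-duplicate constraint (gap quantified above).
- The headline corpus results of the original evaluation are not
  reproducible here: they require the external challenge corpus, a trained
  ranking model and an era-specific normalization system. This package
  reproduces the worked examples, closed-form statistics and directional
  claims instead.
- Rank 1 can never change: only the rank-1 identifier's own candidate list
  fills slot 1. This is inherent to the candidate-generation scheme.
- Keyword and abbreviation matching is exact (case-insensitive) string
  matching; no fuzzy or synonym matching.
- The accuracy-profile cross-validation fold count is configuration, not
  dogma; profiles can equally be supplied as TSV from any external source.
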