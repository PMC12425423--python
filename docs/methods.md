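# Methods

This note documents the models and procedures implemented in `ademiner`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## Task and data model

A corpus is a set of clinical notes; each note is a token sequence
partitioned into sentences and annotated with:

* **entities** — contiguous, non-overlapping token spans from five classes:
  Finding, Drug, Disorder, Body Structure, ADE Cue.  Class names serialize
  with underscores (`Body_Structure`, `ADE_Cue`) because the column formats
  cannot carry internal spaces.
* **relations** — directed typed links between two entities of the same
  note: Indication (Finding/Disorder → Drug), ADE (Drug → Finding/Disorder),
  ADE Outcome (ADE Cue → Finding/Disorder), ADE Cause (Drug → ADE Cue),
  plus the No-relation class for permissible-but-unannotated pairs.

On disk a note is a `.txt` / `.conll` / `.ann` triple: two-column CoNLL-BIO
(token, tag; blank line = sentence boundary) carries tokens and entities,
brat standoff (T-/R-lines) carries entities with character offsets and the
relations.  Character spans are mapped to the minimal covering token span,
which is robust to whitespace drift.  When only CoNLL is available, token
offsets are synthesized by single-space joining — deterministic and exactly
reversible, so write→parse round trips are bit-exact.

Corpus splitting is done once, 70/10/20, by seeded permutation; the test
size is `round(0.20·N)`, validation `round(0.10·N)` (half-up), training the
remainder (395 notes → 276/40/79).

## NER stage

Token classification over the 11-label BIO scheme.  Notes are segmented
into overlapping 128-token windows with stride 96 so long texts fit the
encoder.  Two points the windowed setup leaves open are resolved as
follows:

* **Overlap merging.**  A token covered by several windows takes its
  prediction from the window in which its minimum distance to a window
  boundary is largest (ties → earlier window).  Rationale: boundary tokens
  lack one-sided context.
* **Validity repair.**  Raw argmax output may violate the BIO grammar; a
  stray `I-X` with no same-class predecessor becomes `B-X`, everything else
  is untouched.  The repair is idempotent and leaves valid sequences
  unchanged, so `bio_to_entities` always accepts the pipeline's output.

The default `NerTrainConfig` is the full-scale fine-tuning schedule
(batch 128, gradient accumulation 3, Adam at 5·10⁻⁵, dropout 0.1, weight
decay 0.01, gradient clipping 1.0, early stopping with a patience of 1600
optimizer steps).

## RE stage

Notes are segmented into passages of three sentences with stride one —
annotated relations rarely span more than three sentences, so every
relation the generator emits joins entities at most two sentences apart and
is capturable.  A **candidate** is an unordered entity pair that (a) has a
permissible type pair under the closed schema and (b) co-occurs inside at
least one passage.  Open points resolved:

* **Canonical passage.**  A pair co-occurring in several overlapping
  passages is attached only to the passage in which its outermost tokens
  are most centered (ties → earliest), so training and evaluation never see
  duplicated pairs.
* **Direction.**  Candidates are presented in document order; the 5-class
  classifier itself distinguishes Indication from ADE, and the semantic
  direction of a predicted relation is implied by its label (e.g. the Drug
  is always arg1 of an ADE).
* **Pair marking.**  The classifier input is the passage token sequence
  with `[E1]…[/E1]` and `[E2]…[/E2]` marker tokens around the two
  entities; inputs longer than `max_input_tokens` (512) are truncated
  symmetrically around the marked pair.
* **Schema-constrained decoding.**  At prediction time the argmax is taken
  within the candidate's permissible label slot (a Drug–ADE Cue pair can
  only be ADE Cause or No relation).  This mirrors the predefined
  permissibility rules of the integrated task and keeps argument
  orientation well-defined; the unconstrained argmax remains available.
* **Class imbalance** is not addressed by default: No-relation dominates
  the candidate distribution (~90 %), as in the emulated corpus.

The default `ReTrainConfig` is the full-scale schedule (batch 32, up to 50
epochs, patience 3 epochs on validation loss, Adam at 2.575·10⁻⁵,
cross-entropy, weight decay 10⁻⁴).

## Encoder backend

Both stages share a pluggable encoder contract: map a token sequence to
per-token states and support gradient fitting.  The bundled backend is a
small bidirectional encoder in pure numpy:

    embeddings + learned positions
    → local-context layer (concatenation of a ±2-token window, ReLU)
    → one single-head softmax self-attention block (residual)
    → position-wise feed-forward block (residual)

with a per-token softmax head for tagging and an entity-marker head for
relation classification (concatenation of the hidden states at the four
marker positions — the standard entity-marker pooling for RE).  Training
uses Adam with decoupled weight decay on weight matrices, global-norm
gradient clipping, optional gradient accumulation, inverted dropout, and
early stopping on validation loss with best-parameter restoration.  All
backward passes are hand-derived and verified against numerical
differentiation to ~10⁻⁹ relative error in the test suite.  Computation is
float64 and single-threaded-deterministic: identical seeds give identical
training curves.

**Desk-scale schedules.**  The full-scale defaults above assume a large
pretrained encoder.  For the tiny randomly initialized backend the package
provides `NerTrainConfig.desk_scale()` / `ReTrainConfig.desk_scale()`
(batch 32, learning rate 3·10⁻³, ≤ 40/30 epochs, patience 80 steps / 3
epochs): a from-scratch d=32 model needs a larger step size and converges
within a few dozen epochs on the separable benchmark.  The test suite and
`scripts/acceptance.py` use a 500-note corpus with these schedules; at that
size the full pipeline (two trainings plus evaluation) takes on the order
of two minutes on one CPU.

## Synthetic corpus generator

The generator emulates the *statistical* structure a Swedish clinical ADE
corpus exhibits, with no attempt at clinical or morphological realism —
the text is pseudo-Swedish syllable filler.  Configured conditions
(defaults in parentheses):

| Parameter | Default | Meaning |
| --- | --- | --- |
| `entity_class_weights` | .35/.29/.20/.12/.04 | Finding/Drug/Disorder/Body Structure/ADE Cue proportions |
| `compound_entity_rate` | 0.23 | probability an entity mention has ≥ 2 tokens |
| `ade_note_fraction` | 0.62 | probability a note contains ≥ 1 ADE-flavored relation |
| `mean_sentences_per_note` | 14 | Poisson mean (minimum 3) |
| `relation_attach_prob` | 0.10 | probability a sentence unit is realized as a related pair |
| `lexical_overlap_rate` | 0.0 | fraction of ADE-cue terms shared into Disorder/Finding vocabularies |

Primary relations are realized as same-sentence `entity trigger entity`
triples, where the trigger word comes from a per-relation-class vocabulary.
This guarantees the ≤ 2-sentence co-occurrence the passage window needs,
and gives each relation class a learnable lexical signal.  No-relation
instances are never generated explicitly; they arise downstream as
untriggered permissible pairs sharing a passage, which reproduces the
No-relation majority (~90 % of candidates at the defaults).  The
`relation_attach_prob` default was chosen so that primary relations make up
roughly the 8 % share the emulated corpus reports; notes drawn as non-ADE
realize only Indication triples, and notes drawn as ADE-containing are
guaranteed at least one ADE-flavored triple (appended in a final sentence
if none arose).  Because triple entities are drawn from the permissible
pairs rather than the marginal class distribution, the lone-entity class
weights are analytically corrected so the overall entity-class marginal
still matches the configured proportions in expectation (the correction
ignores the small forced-triple contribution, a ≤ 1–2 % effect well inside
the ±0.05 acceptance band).

**What passing on this benchmark shows — and what it does not.**  In
separable mode every entity class and every relation class has a disjoint
vocabulary, so near-perfect scores demonstrate that the machinery is
correct (windowing, merging, candidate generation, training loop, stacked
inference, scoring), not that the tiny encoder would approach the reported
performance of a pretrained clinical transformer on real notes.  Real
clinical text has lexical overlap between ADE Cue, Disorder and Finding,
compound words, negation/speculation, and annotation inconsistency, none of
which the default generator produces; `lexical_overlap_rate > 0` restores
the first of these qualitatively and makes the ADE Cue class confusable by
construction.

## Evaluation

* **NER** is scored token-level over merged B/I categories (five entity
  classes; `O` = Other excluded from macro, micro pooled over non-Other
  tokens), matching an evaluation that converts predictions back to BIO
  tags.  An entity-level report under strict/relaxed matching is emitted as
  well, since the granularity of per-class scores is otherwise ambiguous.
* **Matching.**  Strict = same class and identical span; relaxed = same
  class and ≥ 1 shared token.  One-to-one resolution is greedy by largest
  overlap, then earliest position; every exact-span pair is provably kept
  in both modes, which makes strict true positives a subset of relaxed ones
  and hence strict F1 ≤ relaxed F1 per class, a property the suite checks
  over randomized perturbations.
* **Relations.**  A predicted relation is a true positive iff its label
  matches a gold relation whose arguments are matched (under the chosen
  mode) to the prediction's arguments; argument pairs are compared
  unordered because direction is label-implied.  Macro averages are
  reported both over the four primary classes and including No-relation,
  since the averaging scope is a genuine degree of freedom under a 92 %
  majority class.
* **Note level.**  Binary ContainingADE/NoADE report with macro average;
  the decision rule is monotone (adding relations can never unflag a note).
  Whether "an ADE relation" means the ADE class alone or all three
  ADE-flavored classes is configurable (`AdeRuleConfig`); the default uses
  all three, as ADE Cause/Outcome indicate an event even when incomplete.
* **Error analysis** reports the 6×6 token-category confusion matrix and,
  per off-diagonal cell, the most frequent case-folded surface terms.

All reports are cross-checked in the test suite against independent naive
counting oracles (plain loops, exhaustive or Hungarian assignment), and
F-beta against its closed form.

## Grid search

Hyperparameter search trains one model per grid point and selects the
maximum validation macro-F1 (token-level over entity classes for NER,
primary-class macro for RE), ties toward the earlier grid point; the full
score table is returned for logging.  The selection metric is a package
choice — only the strategy, not the metric, is fixed by the emulated
protocol.

## Numerical and degenerate-input conventions

* F-beta is 0 when precision = recall = 0.
* Empty training sets, single-label candidate sets, empty grids, dangling
  relation arguments, overlapping entities and invalid BIO sequences raise
  errors rather than being silently repaired (BIO repair is explicit and
  only applied to model output).
* Entities spanning more sentences than the passage window are skipped
  with a logged warning, as are gold relations no passage can capture.
* Validation-loss improvements are compared with a 10⁻⁹ margin; best
  parameters are deep-copied and restored at the end of training.
* Seeds propagate to every stochastic component (lexicon, corpus, split,
  initialization, shuffling, dropout); derived seeds stay below 2³¹.

## Known limitations

* The bundled encoder is word-level: there is no subword tokenization, so
  the full-scale configs' subword-alignment concern (supervise only each
  word's first piece) does not arise until a real transformer backend is
  plugged in.
* Discontinuous and overlapping entities, brat events/attributes, n-ary
  and cross-note relations are out of scope.
* The generator emulates marginal distributions (class proportions,
  ADE-note fraction, No-relation share), not the unknown joint distribution
  of relations within notes.
* Cross-passage relations (> 3 sentences apart) are not candidates; the
  pipeline cannot recover them by construction.
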