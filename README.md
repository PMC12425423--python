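# ademiner

Detecting **adverse drug events (ADEs)** in clinical free text with an
integrated NER → RE pipeline.

Structured EHR fields under-report medication harms: even notes carrying an
ADE-related ICD-10 code often describe the event only in free text, and a
substantial fraction of coded notes contain no explicit description at all.
`ademiner` implements the text-mining pipeline a pharmacovigilance group
needs to surface those descriptions:

1. **Named-entity recognition** — token classification over the 11-label BIO
   scheme (`O` plus `B-`/`I-` for *Finding*, *Drug*, *Disorder*,
   *Body Structure*, *ADE Cue*), with long notes segmented into overlapping
   128-token windows (stride 96) and window predictions merged and repaired
   into valid BIO sequences.
2. **Relation extraction** — a 5-class classifier over entity pairs marked
   inside 3-sentence passages (stride one sentence).  The schema is closed:
   only five unordered type pairs can carry a relation, each with a fixed
   label slot — {Drug, Finding/Disorder} → *Indication* | *ADE* |
   *No relation*; {ADE Cue, Finding/Disorder} → *ADE Outcome* |
   *No relation*; {Drug, ADE Cue} → *ADE Cause* | *No relation*.
   *No relation* instances are permissible pairs that co-occur in a passage
   without an annotated relation; they dominate (~92 % of candidates).
3. **Stacked end-to-end inference** — predicted entities feed candidate
   generation and relation classification, so NER errors propagate exactly
   as in deployment: a missed or mistyped entity silently removes its pairs.
4. **Note-level ADE detection** — the rule "a note contains an ADE iff at
   least one ADE-flavored relation (*ADE*, *ADE Cause*, *ADE Outcome*) was
   extracted".
5. **Evaluation** — per-class and micro/macro precision, recall, F1
   (F1 = 2PR/(P+R)) and F2 (Fβ = (1+β²)PR/(β²P+R)), under **strict**
   (exact span, same class) and **relaxed** (≥ 1 shared token, same class)
   matching, plus confusion matrices and term-level error analysis.

Because real annotated clinical corpora of this kind are sensitive and not
distributable, the package ships a **synthetic corpus generator** that
reproduces the statistical structure such a corpus exhibits — entity-class
proportions 0.35/0.29/0.20/0.12/0.04, ~23 % multiword ("compound")
entities, ~62 % of notes containing an explicit ADE relation, a mean of 14
sentences per note, and the dominant No-relation class — in a pseudo-Swedish
template language.  In its default *separable mode* the class vocabularies
are disjoint, so a tiny CPU-trainable encoder can learn the tasks; an
*overlap mode* shares ADE-cue terms into the Disorder/Finding vocabularies
to reproduce the class confusions seen in real clinical text.

The encoder behind both stages is pluggable: the default is a small
randomly initialized bidirectional encoder (embeddings → local-context
layer → one self-attention block → feed-forward, trained with Adam and
early stopping) implemented in numpy so everything runs on one CPU; a
full-scale pretrained clinical transformer drops in behind the same
estimator surface.

## Worked example

```python
from ademiner import (
    GeneratorConfig, generate_corpus, split_corpus,
    NerTrainConfig, ReTrainConfig, train_ner, train_re,
    generate_candidates, AdeExtractor,
    score_entities, score_relation_labels, score_notes,
)
from ademiner.pipeline import note_ade_flags

config = GeneratorConfig(n_notes=200, seed=42)
notes = generate_corpus(config)
by_id = {n.id: n for n in notes}
split = split_corpus([n.id for n in notes], seed=42)   # 70/10/20
train = [by_id[i] for i in split.train]
val = [by_id[i] for i in split.validation]
test = [by_id[i] for i in split.test]

tagger = train_ner(train, val_notes=val, config=NerTrainConfig.desk_scale(seed=42))
candidates = lambda ns: [c for n in ns for c in generate_candidates(n)]
re_model = train_re(candidates(train), candidates(val),
                    config=ReTrainConfig.desk_scale(seed=42))

ner_report = score_entities([n.entities for n in test],
                            tagger.predict_entities(test), "strict")
print(ner_report.to_text())

test_c = candidates(test)
re_report = score_relation_labels([c.gold_label for c in test_c],
                                  re_model.predict(test_c))
print(f"RE macro-F1 (primary classes): {re_report.macro['f1']:.3f}")

extractor = AdeExtractor(tagger, re_model)
preds = extractor.predict(test)
note_report = score_notes(note_ade_flags(test),
                          {p.note_id: p.note_ade_flag for p in preds})
print(f"note-level ADE macro-F1:       {note_report.macro['f1']:.3f}")
```

Output (a couple of minutes on one CPU):

```
               Finding  P=0.976  R=1.000  F1=0.988  F2=0.995  n=242
                  Drug  P=0.968  R=1.000  F1=0.984  F2=0.993  n=241
              Disorder  P=0.993  R=0.993  F1=0.993  F2=0.993  n=134
        Body_Structure  P=0.938  R=0.884  F1=0.910  F2=0.894  n=69
               ADE_Cue  P=0.815  R=0.733  F1=0.772  F2=0.748  n=30
                 micro  P=0.967  R=0.976  F1=0.972
                 macro  P=0.938  R=0.922  F1=0.929
RE macro-F1 (primary classes): 0.894
note-level ADE macro-F1:       0.919
```

Each row is strict entity-level precision/recall/F1/F2 with its test-set
support.  Even on synthetic data the familiar pattern appears: the minority
*ADE Cue* class (n=30 here) is hardest, and note-level detection remains
strong because one correctly extracted ADE relation suffices to flag a
note.  At 500 notes (the scale the test suite uses) every entity class
reaches F1 ≥ 0.95 and the relation macro-F1 exceeds 0.90.

There is also a CLI mirroring the stages:

```bash
ademiner generate corpus/ --n-notes 200 --seed 42
ademiner train-ner corpus/ runs/ner --seed 42
ademiner train-re  corpus/ runs/re  --seed 42
ademiner predict  corpus/ runs/ner runs/re --out predictions.json
ademiner evaluate corpus/ runs/ner runs/re --mode relaxed
```

## Layout

| Module                 | Contents |
| ---------------------- | -------- |
| `ademiner.types`       | `Note`, `Entity`, `RelationInstance`, BIO tag set, enums |
| `ademiner.corpus_io`   | CoNLL-BIO and brat standoff read/write, BIO ↔ spans, 70/10/20 splitting |
| `ademiner.synthetic`   | `GeneratorConfig`, lexicon builder, corpus generator |
| `ademiner.ner`         | `BioTagger` estimator, windowing, BIO repair |
| `ademiner.relations`   | relation schema, passages, candidate generation, `RelationClassifier` |
| `ademiner.pipeline`    | `AdeExtractor`, note-level ADE rule, grid search |
| `ademiner.evaluation`  | F-beta, strict/relaxed matching, all reports, error analysis |
| `ademiner._nn`         | the numpy encoder backend (verified against numerical gradients) |

See `docs/methods.md` for the modelling choices, parameter meanings and
limitations.
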