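import numpy as np
import pytest

from ademiner.relations import (
    MARKER_TOKENS,
    RELATION_SCHEMA,
    CandidatePair,
    RelationClassifier,
    ReTrainConfig,
    classify_pairs,
    generate_candidates,
    make_passages,
    permissible_labels,
    render_pair_input,
    render_pair_tokens,
    train_re,
)
from ademiner.types import EntityClass, RelationClass

from conftest import make_note
from oracles import naive_candidate_pairs


class TestSchema:
    def test_closed_pair_sets(self):
        assert permissible_labels(EntityClass.DRUG, EntityClass.FINDING) == {
            RelationClass.INDICATION,
            RelationClass.ADE,
            RelationClass.NO_RELATION,
        }
        assert permissible_labels(EntityClass.DRUG, EntityClass.ADE_CUE) == {
            RelationClass.ADE_CAUSE,
            RelationClass.NO_RELATION,
        }
        assert permissible_labels(EntityClass.DRUG, EntityClass.BODY_STRUCTURE) is None
        assert permissible_labels(EntityClass.FINDING, EntityClass.DISORDER) is None
        assert len(RELATION_SCHEMA) == 5


class TestPassages:
    def test_five_sentences_give_three_passages(self, small_corpus):
        note = next(n for n in small_corpus if len(n.sentences) >= 5)
        passages = make_passages(note)
        assert len(passages) == len(note.sentences) - 2
        assert [p.sent_start for p in passages] == list(range(len(passages)))
        assert all(p.sent_end - p.sent_start == 3 for p in passages)

    def test_short_note_gives_single_clipped_passage(self):
        note = make_note(
            """
            en O

            tva O
            """
        )
        passages = make_passages(note)
        assert len(passages) == 1
        assert (passages[0].sent_start, passages[0].sent_end) == (0, 2)
        assert (passages[0].token_start, passages[0].token_end) == (0, 2)

    def test_every_entity_contained_in_some_passage(self, small_corpus):
        for note in small_corpus:
            passages = make_passages(note)
            for ent in note.entities:
                assert any(p.contains(ent) for p in passages)


class TestCandidates:
    def test_schema_excludes_body_structure_pairs(self):
        note = make_note(
            """
            Waran B-Drug
            ger O
            yrsel B-Finding
            i O
            armen B-Body_Structure
            """
        )
        cands = generate_candidates(note)
        assert len(cands) == 1
        assert {cands[0].e1.cls, cands[0].e2.cls} == {
            EntityClass.DRUG,
            EntityClass.FINDING,
        }
        assert cands[0].gold_label is RelationClass.NO_RELATION

    def test_label_slots_for_triple_cooccurrence(self):
        note = make_note(
            """
            Waran B-Drug
            biverkan B-ADE_Cue
            yrsel B-Finding
            """
        )
        cands = generate_candidates(note)
        slots = {
            frozenset({c.e1.cls, c.e2.cls}): c.label_set for c in cands
        }
        assert len(cands) == 3
        assert slots[frozenset({EntityClass.DRUG, EntityClass.ADE_CUE})] == {
            RelationClass.ADE_CAUSE,
            RelationClass.NO_RELATION,
        }
        assert slots[frozenset({EntityClass.ADE_CUE, EntityClass.FINDING})] == {
            RelationClass.ADE_OUTCOME,
            RelationClass.NO_RELATION,
        }
        assert slots[frozenset({EntityClass.DRUG, EntityClass.FINDING})] == {
            RelationClass.INDICATION,
            RelationClass.ADE,
            RelationClass.NO_RELATION,
        }

    def test_matches_naive_enumeration_oracle(self, small_corpus):
        for note in small_corpus[:50]:
            got = {
                (c.e1.id, c.e2.id, c.gold_label.value)
                for c in generate_candidates(note)
            }
            assert got == naive_candidate_pairs(note)

    def test_one_candidate_per_pair(self, small_corpus):
        for note in small_corpus:
            cands = generate_candidates(note)
            pairs = [frozenset({c.e1.id, c.e2.id}) for c in cands]
            assert len(pairs) == len(set(pairs))

    def test_gold_labels_respect_schema(self, small_corpus):
        for note in small_corpus:
            for cand in generate_candidates(note):
                assert cand.gold_label in cand.label_set


class TestRendering:
    def test_direct_insertion(self):
        note = make_note(
            """
            Waran B-Drug
            gav O
            blödning B-Finding
            """
        )
        [cand] = generate_candidates(note)
        assert cand.rendered_text == "[E1] Waran [/E1] gav [E2] blödning [/E2]"

    def test_markers_appear_exactly_once(self, small_corpus):
        for note in small_corpus[:20]:
            for cand in generate_candidates(note):
                for marker in MARKER_TOKENS:
                    assert cand.tokens.count(marker) == 1

    def test_stripping_markers_recovers_passage(self, small_corpus):
        for note in small_corpus[:20]:
            for cand in generate_candidates(note):
                stripped = [t for t in cand.tokens if t not in MARKER_TOKENS]
                passage_tokens = note.token_texts()[
                    cand.passage.token_start : cand.passage.token_end
                ]
                assert stripped == passage_tokens

    def test_truncation_preserves_markers(self, small_corpus):
        cands = [c for n in small_corpus[:10] for c in generate_candidates(n)]
        cand = max(cands, key=lambda c: len(c.tokens))
        first = cand.tokens.index("[E1]")
        last = len(cand.tokens) - 1 - cand.tokens[::-1].index("[/E2]")
        limit = max(last - first + 1, len(cand.tokens) - 5)
        note = next(n for n in small_corpus if n.id == cand.note_id)
        out = render_pair_tokens(
            cand.passage, cand.e1, cand.e2, note.token_texts(), limit
        )
        assert len(out) <= limit < len(cand.tokens)
        for marker in MARKER_TOKENS:
            assert out.count(marker) == 1

    def test_entities_outside_passage_rejected(self):
        note = make_note(
            """
            Waran B-Drug

            a O

            b O

            yrsel B-Finding
            """
        )
        passages = make_passages(note)
        drug, finding = note.entities
        assert passages[0].contains(drug) and not passages[0].contains(finding)
        with pytest.raises(ValueError):
            render_pair_tokens(passages[0], drug, finding, note.token_texts())


def _candidates(notes):
    return [c for n in notes for c in generate_candidates(n)]


class TestRelationClassifier:
    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            RelationClassifier().fit([])

    def test_single_label_rejected(self, small_corpus):
        cands = [
            c
            for c in _candidates(small_corpus[:10])
            if c.gold_label is RelationClass.NO_RELATION
        ]
        with pytest.raises(ValueError, match="2 distinct labels"):
            RelationClassifier().fit(cands)

    def test_overfits_small_candidate_set(self, small_corpus):
        cands = _candidates(small_corpus[:6])[:40]
        assert len({c.gold_label for c in cands}) >= 2
        model = train_re(cands, config=ReTrainConfig.desk_scale(seed=0))
        assert model.predict(cands) == [c.gold_label for c in cands]

    def test_validation_loss_improves(self, small_corpus):
        cands = _candidates(small_corpus[:20])
        model = train_re(
            cands,
            config=ReTrainConfig(
                learning_rate=3e-3, epochs=5, early_stopping_patience=5, seed=1
            ),
        )
        losses = [h["val_loss"] for h in model.history_]
        assert min(losses) < losses[0] or losses[-1] < 0.1

    def test_scores_normalized_and_deterministic(self, small_corpus):
        cands = _candidates(small_corpus[:6])[:30]
        model = train_re(cands, config=ReTrainConfig(learning_rate=3e-3, epochs=2, early_stopping_patience=2, seed=2))
        scored = classify_pairs(model, cands)
        probs = np.array([s for _, s in scored])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        again = classify_pairs(model, cands)
        np.testing.assert_array_equal(probs, np.array([s for _, s in again]))
        for cand, (label, vec) in zip(cands, scored):
            allowed = cand.label_set
            best = max(
                (i for i, c in enumerate(model.classes_) if c in allowed),
                key=lambda i: vec[i],
            )
            assert label is model.classes_[best]
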