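import numpy as np
import pytest

from ademiner.corpus_io import entities_to_bio
from ademiner.evaluation import (
    MatchMode,
    error_analysis,
    fbeta,
    match_entities,
    score_entities,
    score_ner,
    score_notes,
    score_relation_labels,
    score_relations,
)
from ademiner.types import Entity, EntityClass, RelationClass, RelationInstance

from oracles import (
    jitter_tags as _jitter_tags,
    naive_fbeta,
    naive_note_counts,
    naive_relation_counts,
    naive_token_counts,
    perturbed_relation_corpus as _perturbed_relation_corpus,
)


def _ent(id, cls, start, end):
    return Entity(id=id, cls=cls, token_start=start, token_end=end)


class TestFbeta:
    @pytest.mark.parametrize("beta", [0.5, 1.0, 2.0])
    def test_perfect(self, beta):
        assert fbeta(1.0, 1.0, beta) == 1.0

    def test_degenerate_zero(self):
        assert fbeta(0.0, 0.0, 1.0) == 0.0

    def test_f2_example(self):
        assert fbeta(1.0, 0.5, 2.0) == pytest.approx(0.5556, abs=1e-4)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fbeta(-0.1, 0.5, 1.0)

    def test_recall_weighting_direction(self):
        # F2 leans toward recall; F1 sits between precision and recall
        for p in np.linspace(0.05, 1.0, 8):
            for r in np.linspace(0.05, 1.0, 8):
                f1, f2 = fbeta(p, r, 1.0), fbeta(p, r, 2.0)
                assert f1 == pytest.approx(naive_fbeta(p, r, 1.0))
                assert f2 == pytest.approx(naive_fbeta(p, r, 2.0))
                if r > p:
                    assert f2 >= f1
                elif r < p:
                    assert f2 <= f1


class TestMatchEntities:
    def test_strict_vs_relaxed_on_truncated_span(self):
        gold = [_ent("g1", EntityClass.DISORDER, 5, 7)]
        pred = [_ent("p1", EntityClass.DISORDER, 6, 7)]
        strict, ug, up = match_entities(gold, pred, MatchMode.STRICT)
        assert (strict, ug, up) == ([], [0], [0])
        relaxed, ug, up = match_entities(gold, pred, MatchMode.RELAXED)
        assert (relaxed, ug, up) == ([(0, 0)], [], [])

    def test_class_must_agree(self):
        gold = [_ent("g1", EntityClass.DISORDER, 5, 7)]
        pred = [_ent("p1", EntityClass.FINDING, 5, 7)]
        for mode in MatchMode:
            matches, _, _ = match_entities(gold, pred, mode)
            assert matches == []

    def test_one_to_one(self):
        gold = [_ent("g1", EntityClass.DRUG, 0, 3)]
        pred = [
            _ent("p1", EntityClass.DRUG, 0, 1),
            _ent("p2", EntityClass.DRUG, 1, 3),
        ]
        matches, _, up = match_entities(gold, pred, MatchMode.RELAXED)
        assert len(matches) == 1
        assert matches[0] == (0, 1)  # larger overlap wins
        assert up == [0]

    def test_matches_exhaustive_assignment_on_small_perturbations(self):
        rng = np.random.default_rng(3)
        from oracles import _best_entity_assignment

        for _ in range(60):
            gold, pred = _perturbed_instance(rng, n=int(rng.integers(1, 6)))
            for mode in ("strict", "relaxed"):
                greedy, _, _ = match_entities(gold, pred, mode)
                optimal = _best_entity_assignment(gold, pred, mode)
                assert len(greedy) == len(optimal)
                assert sorted(greedy) == sorted(optimal)


def _perturbed_instance(rng, n=4, gap=4, span=3):
    """Gold entities on a lattice; predictions derived by within-span
    truncation, drops, class flips and spurious additions."""
    classes = list(EntityClass)
    gold, pred = [], []
    cursor = 0
    for i in range(n):
        cls = classes[int(rng.integers(len(classes)))]
        start = cursor + int(rng.integers(1, 3))
        end = start + int(rng.integers(1, span + 1))
        cursor = end + gap
        gold.append(_ent(f"g{i}", cls, start, end))
        action = rng.random()
        if action < 0.15:
            continue  # dropped
        p_cls = cls if action < 0.85 else classes[int(rng.integers(len(classes)))]
        if end - start > 1 and rng.random() < 0.5:
            p_start = start + int(rng.integers(0, end - start))
            p_end = p_start + 1
        else:
            p_start, p_end = start, end
        pred.append(_ent(f"p{i}", p_cls, p_start, p_end))
    if rng.random() < 0.4:  # spurious prediction in empty space
        cls = classes[int(rng.integers(len(classes)))]
        pred.append(_ent("px", cls, cursor + 1, cursor + 2))
    return gold, pred


class TestScoreNer:
    def test_perfect_predictions(self, small_corpus):
        tags = [entities_to_bio(n.entities, len(n.tokens)) for n in small_corpus[:5]]
        report = score_ner(tags, tags)
        for metrics in report.per_class.values():
            if metrics["support"]:
                assert metrics["f1"] == 1.0
        assert report.micro["f1"] == 1.0

    def test_all_other_predictions_have_zero_recall(self, small_corpus):
        gold = [entities_to_bio(n.entities, len(n.tokens)) for n in small_corpus[:5]]
        pred = [["O"] * len(g) for g in gold]
        report = score_ner(gold, pred)
        for metrics in report.per_class.values():
            assert metrics["recall"] == 0.0

    def test_matches_counting_oracle(self, small_corpus):
        notes = small_corpus[:20]
        gold = [entities_to_bio(n.entities, len(n.tokens)) for n in notes]
        rng = np.random.default_rng(0)
        pred = [_jitter_tags(g, rng) for g in gold]
        report = score_ner(gold, pred)
        counts = naive_token_counts(gold, pred)
        for cls, (tp, fp, fn) in counts.items():
            m = report.per_class[cls]
            p = tp / (tp + fp) if tp + fp else 0.0
            r = tp / (tp + fn) if tp + fn else 0.0
            assert m["precision"] == pytest.approx(p, abs=1e-12)
            assert m["recall"] == pytest.approx(r, abs=1e-12)
            assert m["f1"] == pytest.approx(naive_fbeta(p, r, 1), abs=1e-12)
            assert m["f2"] == pytest.approx(naive_fbeta(p, r, 2), abs=1e-12)
        tp = sum(v[0] for v in counts.values())
        fp = sum(v[1] for v in counts.values())
        fn = sum(v[2] for v in counts.values())
        assert report.micro["precision"] == pytest.approx(tp / (tp + fp), abs=1e-12)
        assert report.micro["recall"] == pytest.approx(tp / (tp + fn), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_ner([["O", "O"]], [["O"]])


class TestScoreRelations:
    def _note_sides(self, entities, relations):
        return [(entities, relations)]

    def test_identical_sides_are_perfect(self):
        ents = [
            _ent("T1", EntityClass.DRUG, 0, 1),
            _ent("T2", EntityClass.FINDING, 2, 4),
        ]
        rels = [RelationInstance(label=RelationClass.ADE, arg1_id="T1", arg2_id="T2")]
        for mode in MatchMode:
            report = score_relations(
                self._note_sides(ents, rels), self._note_sides(ents, rels), mode
            )
            assert report.per_class["ADE"]["f1"] == 1.0
            assert report.macro["f1"] == pytest.approx(
                np.mean([1.0, 0.0, 0.0, 0.0])
            )  # other primary classes have no support

    def test_truncated_argument_span_strict_vs_relaxed(self):
        gold_ents = [
            _ent("T1", EntityClass.DRUG, 0, 2),
            _ent("T2", EntityClass.FINDING, 3, 5),
        ]
        pred_ents = [
            _ent("P1", EntityClass.DRUG, 0, 1),  # truncated by one token
            _ent("P2", EntityClass.FINDING, 3, 5),
        ]
        rel_g = [RelationInstance(label=RelationClass.ADE, arg1_id="T1", arg2_id="T2")]
        rel_p = [RelationInstance(label=RelationClass.ADE, arg1_id="P1", arg2_id="P2")]
        strict = score_relations(
            self._note_sides(gold_ents, rel_g), self._note_sides(pred_ents, rel_p), "strict"
        )
        relaxed = score_relations(
            self._note_sides(gold_ents, rel_g), self._note_sides(pred_ents, rel_p), "relaxed"
        )
        assert strict.per_class["ADE"]["precision"] == 0.0  # FP + FN
        assert strict.per_class["ADE"]["recall"] == 0.0
        assert relaxed.per_class["ADE"]["f1"] == 1.0  # TP

    def test_dangling_argument_rejected(self):
        ents = [
            _ent("T1", EntityClass.DRUG, 0, 1),
            _ent("T2", EntityClass.FINDING, 2, 3),
        ]
        rels = [RelationInstance(label=RelationClass.ADE, arg1_id="T1", arg2_id="T9")]
        with pytest.raises(ValueError):
            score_relations([(ents, rels)], [(ents, [])], "strict")

    def test_matches_counting_oracle_on_corpus(self, small_corpus):
        gold, pred = _perturbed_relation_corpus(small_corpus[:20], seed=1)
        for mode in ("strict", "relaxed"):
            report = score_relations(gold, pred, mode)
            counts = naive_relation_counts(gold, pred, mode)
            for cls, (tp, fp, fn) in counts.items():
                m = report.per_class[cls]
                p = tp / (tp + fp) if tp + fp else 0.0
                r = tp / (tp + fn) if tp + fn else 0.0
                assert m["precision"] == pytest.approx(p, abs=1e-12), (mode, cls)
                assert m["recall"] == pytest.approx(r, abs=1e-12), (mode, cls)

    def test_strict_never_beats_relaxed(self, small_corpus):
        for seed in range(10):
            gold, pred = _perturbed_relation_corpus(small_corpus[:10], seed=seed)
            strict = score_relations(gold, pred, "strict")
            relaxed = score_relations(gold, pred, "relaxed")
            for cls in strict.per_class:
                assert strict.per_class[cls]["f1"] <= relaxed.per_class[cls]["f1"] + 1e-12


class TestScoreRelationLabels:
    def test_macro_over_primary_classes(self):
        gold = [RelationClass.ADE, RelationClass.INDICATION, RelationClass.NO_RELATION]
        pred = [RelationClass.ADE, RelationClass.NO_RELATION, RelationClass.NO_RELATION]
        report = score_relation_labels(gold, pred)
        assert report.per_class["ADE"]["f1"] == 1.0
        assert report.per_class["Indication"]["recall"] == 0.0
        assert "macro_including_no_relation" in report.extras


class TestScoreNotes:
    def test_perfect_flags(self):
        flags = {"a": True, "b": False, "c": True}
        report = score_notes(flags, flags)
        assert report.macro["f1"] == 1.0

    def test_all_positive_predictions(self):
        gold = {f"n{i}": i < 5 for i in range(10)}
        pred = {k: True for k in gold}
        report = score_notes(gold, pred)
        m = report.per_class["ContainingADE"]
        assert m["precision"] == 0.5
        assert m["recall"] == 1.0

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(2)
        gold = {f"n{i}": bool(rng.random() < 0.6) for i in range(50)}
        pred = {k: bool(rng.random() < 0.5) for k in gold}
        report = score_notes(gold, pred)
        for cls, (tp, fp, fn) in naive_note_counts(gold, pred).items():
            m = report.per_class[cls]
            assert m["precision"] == pytest.approx(
                tp / (tp + fp) if tp + fp else 0.0, abs=1e-12
            )
            assert m["recall"] == pytest.approx(
                tp / (tp + fn) if tp + fn else 0.0, abs=1e-12
            )

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_notes({"a": True}, {"b": True})


class TestErrorAnalysis:
    def test_perfect_predictions_have_empty_off_diagonal(self, small_corpus):
        notes = small_corpus[:5]
        tags = [entities_to_bio(n.entities, len(n.tokens)) for n in notes]
        tokens = [n.token_texts() for n in notes]
        conf, terms = error_analysis(tags, tags, tokens)
        off = conf.values.sum() - np.trace(conf.values)
        assert off == 0
        assert terms == {}

    def test_single_confused_token_reported(self):
        gold = [["B-Finding", "O"]]
        pred = [["O", "O"]]
        tokens = [["Illamående", "idag"]]
        conf, terms = error_analysis(gold, pred, tokens, k=3)
        assert conf.loc["Finding", "Other"] == 1
        assert terms[("Finding", "Other")] == [("illamående", 1)]

    def test_cell_counts_sum_to_token_count(self, small_corpus):
        notes = small_corpus[:10]
        gold = [entities_to_bio(n.entities, len(n.tokens)) for n in notes]
        rng = np.random.default_rng(1)
        pred = [_jitter_tags(g, rng) for g in gold]
        tokens = [n.token_texts() for n in notes]
        conf, _ = error_analysis(gold, pred, tokens)
        assert conf.values.sum() == sum(len(t) for t in tokens)
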