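"""End-to-end extraction: stacked NER → RE inference, the note-level ADE
decision rule, and grid search over training configurations.

The stacked pipeline propagates errors by construction: entities the tagger
misses (or assigns a class outside the relation schema) never reach the
relation classifier, so end-to-end relation recall is bounded by the recall
of the relation classifier run on gold entities.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

from sklearn.base import clone

from .evaluation import score_ner, score_relation_labels
from .ner import BioTagger
from .relations import RelationClassifier, generate_candidates
from .types import (
    ADE_FLAVORED_RELATIONS,
    Entity,
    EntityClass,
    Note,
    RelationClass,
    RelationInstance,
)

__all__ = [
    "AdeRuleConfig",
    "PipelinePrediction",
    "AdeExtractor",
    "run_end_to_end",
    "detect_note_ade",
    "grid_search",
]


@dataclass(frozen=True)
class AdeRuleConfig:
    """Which relation labels mark a note as containing an ADE.

    The default counts all three ADE-flavored classes (ADE, ADE Cause, ADE
    Outcome): the latter two carry incomplete information about the event
    but still indicate its presence.  Restricting to the ADE class alone is
    supported via the field.
    """

    ade_indicating_labels: frozenset[RelationClass] = field(
        default_factory=lambda: frozenset(ADE_FLAVORED_RELATIONS)
    )

    def __post_init__(self) -> None:
        if not self.ade_indicating_labels:
            raise ValueError("ade_indicating_labels must be non-empty")
        if RelationClass.NO_RELATION in self.ade_indicating_labels:
            raise ValueError("No-relation cannot indicate an ADE")


def detect_note_ade(
    relations: Sequence[RelationInstance], rule: AdeRuleConfig | None = None
) -> bool:
    """True iff at least one relation carries an ADE-indicating label."""
    rule = rule or AdeRuleConfig()
    return any(rel.label in rule.ade_indicating_labels for rel in relations)


@dataclass
class PipelinePrediction:
    """End-to-end output for one note: predicted entities, predicted primary
    relations (No-relation discarded), and the note-level ADE flag."""

    note_id: str
    entities: list[Entity]
    relations: list[RelationInstance]
    note_ade_flag: bool


#: Semantic arg1 class per relation label (arg2 is the other entity).
_ARG1_CLASS: dict[RelationClass, frozenset[EntityClass]] = {
    RelationClass.INDICATION: frozenset({EntityClass.FINDING, EntityClass.DISORDER}),
    RelationClass.ADE: frozenset({EntityClass.DRUG}),
    RelationClass.ADE_OUTCOME: frozenset({EntityClass.ADE_CUE}),
    RelationClass.ADE_CAUSE: frozenset({EntityClass.DRUG}),
}


def _orient(label: RelationClass, e1: Entity, e2: Entity) -> tuple[str, str]:
    """Order a document-order pair into semantic (arg1, arg2) for a label."""
    if e1.cls in _ARG1_CLASS[label]:
        return e1.id, e2.id
    return e2.id, e1.id


class AdeExtractor:
    """Stacked NER + RE extractor with the note-level ADE rule.

    Composes a fitted :class:`~ademiner.ner.BioTagger` and a fitted
    :class:`~ademiner.relations.RelationClassifier`; ``predict`` runs the
    full chain on raw (unannotated) notes.
    """

    def __init__(
        self,
        tagger: BioTagger,
        relation_model: RelationClassifier,
        rule: AdeRuleConfig | None = None,
    ):
        self.tagger = tagger
        self.relation_model = relation_model
        self.rule = rule or AdeRuleConfig()

    def predict_note(
        self, note: Note, entities: Sequence[Entity] | None = None
    ) -> PipelinePrediction:
        """Run the pipeline on one note.

        ``entities`` substitutes gold (or externally supplied) entities for
        the tagger's output, which isolates the relation stage from NER
        error propagation.
        """
        if entities is None:
            entities = self.tagger.predict_entities([note])[0]
        stripped = note.with_annotations(entities, relations=[])
        candidates = generate_candidates(
            stripped, max_input_tokens=self.relation_model.max_input_tokens
        )
        relations: list[RelationInstance] = []
        if candidates:
            labels = self.relation_model.predict(candidates)
            for cand, label in zip(candidates, labels):
                if label is RelationClass.NO_RELATION:
                    continue
                arg1, arg2 = _orient(label, cand.e1, cand.e2)
                relations.append(
                    RelationInstance(
                        label=label, arg1_id=arg1, arg2_id=arg2, note_id=note.id
                    )
                )
        return PipelinePrediction(
            note_id=note.id,
            entities=list(entities),
            relations=relations,
            note_ade_flag=detect_note_ade(relations, self.rule),
        )

    def predict(self, notes: Sequence[Note]) -> list[PipelinePrediction]:
        return [self.predict_note(n) for n in notes]


def run_end_to_end(
    ner_model: BioTagger,
    re_model: RelationClassifier,
    note: Note,
    rule: AdeRuleConfig | None = None,
) -> PipelinePrediction:
    """Functional wrapper over :class:`AdeExtractor` for one note."""
    return AdeExtractor(ner_model, re_model, rule).predict_note(note)


def _validation_score(model, task: str, val_notes: Sequence[Note]) -> float:
    """Validation macro-F1 used for grid-search model selection.

    NER: token-level macro-F1 over the five entity classes (O excluded).
    RE: macro-F1 over the four primary relation classes on gold candidates.
    """
    from .corpus_io import entities_to_bio

    if task == "ner":
        gold = [entities_to_bio(n.entities, len(n.tokens)) for n in val_notes]
        pred = model.predict(val_notes)
        return score_ner(gold, pred).macro["f1"]
    if task == "re":
        candidates = [c for n in val_notes for c in generate_candidates(n)]
        if not candidates:
            return 0.0
        pred = model.predict(candidates)
        gold = [c.gold_label for c in candidates]
        return score_relation_labels(gold, pred).macro["f1"]
    raise ValueError(f"unknown task {task!r}")


def grid_search(
    config_grid: Mapping[str, Sequence] | Sequence[Mapping[str, object]],
    train_notes: Sequence[Note],
    val_notes: Sequence[Note],
    task: str,
    base_estimator: BioTagger | RelationClassifier | None = None,
) -> tuple[dict, list[dict]]:
    """Train one model per grid point and select the best by validation
    macro-F1 (ties resolved toward the earlier grid point).

    ``config_grid`` is either a mapping ``param -> list of values`` (the
    cross product is explored, in order) or an explicit sequence of
    parameter dicts.  Returns ``(best_params, score_table)`` where the score
    table has one record per grid point.
    """
    if isinstance(config_grid, Mapping):
        keys = list(config_grid)
        points: list[dict] = [
            dict(zip(keys, values)) for values in product(*(config_grid[k] for k in keys))
        ]
    else:
        points = [dict(p) for p in config_grid]
    if not points:
        raise ValueError("empty configuration grid")

    if base_estimator is None:
        base_estimator = BioTagger() if task == "ner" else RelationClassifier()

    table: list[dict] = []
    best_index = -1
    best_score = -1.0
    for i, params in enumerate(points):
        model = clone(base_estimator)
        model.set_params(**params)
        if task == "ner":
            model.fit(train_notes, validation=val_notes)
            score = _validation_score(model, task, val_notes)
        else:
            train_cands = [c for n in train_notes for c in generate_candidates(n)]
            val_cands = [c for n in val_notes for c in generate_candidates(n)]
            model.fit(train_cands, validation=val_cands)
            score = _validation_score(model, task, val_notes)
        table.append({"params": params, "val_macro_f1": score})
        if score > best_score:
            best_score = score
            best_index = i
    return points[best_index], table


def note_ade_flags(notes: Iterable[Note], rule: AdeRuleConfig | None = None) -> dict[str, bool]:
    """Gold note-level ADE flags derived from annotated relations."""
    return {n.id: detect_note_ade(n.relations, rule) for n in notes}
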