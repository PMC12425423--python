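"""Relation extraction: schema-constrained candidate generation and a
5-class entity-pair classifier.

The relation schema is closed: only five unordered entity-type pairs can
carry a relation at all, and each pair type has a fixed set of labels it can
take (always including No-relation).  Candidates are generated from entity
pairs that co-occur inside a 3-sentence passage (stride one sentence); pairs
that never share a passage are not candidates, mirroring the observation
that annotated relations rarely span more than three sentences.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import _nn
from .types import (
    Entity,
    EntityClass,
    Note,
    PRIMARY_RELATIONS,
    RelationClass,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RELATION_SCHEMA",
    "permissible_labels",
    "Passage",
    "CandidatePair",
    "ReTrainConfig",
    "make_passages",
    "generate_candidates",
    "render_pair_tokens",
    "render_pair_input",
    "RelationClassifier",
    "train_re",
    "classify_pairs",
    "E1_OPEN",
    "E1_CLOSE",
    "E2_OPEN",
    "E2_CLOSE",
    "MARKER_TOKENS",
]

E1_OPEN, E1_CLOSE, E2_OPEN, E2_CLOSE = "[E1]", "[/E1]", "[E2]", "[/E2]"
MARKER_TOKENS = (E1_OPEN, E1_CLOSE, E2_OPEN, E2_CLOSE)

_F, _DR, _DI, _B, _A = (
    EntityClass.FINDING,
    EntityClass.DRUG,
    EntityClass.DISORDER,
    EntityClass.BODY_STRUCTURE,
    EntityClass.ADE_CUE,
)

#: Permissible unordered type pairs and the label sets they can carry.
RELATION_SCHEMA: dict[frozenset[EntityClass], frozenset[RelationClass]] = {
    frozenset({_DR, _F}): frozenset(
        {RelationClass.INDICATION, RelationClass.ADE, RelationClass.NO_RELATION}
    ),
    frozenset({_DR, _DI}): frozenset(
        {RelationClass.INDICATION, RelationClass.ADE, RelationClass.NO_RELATION}
    ),
    frozenset({_A, _F}): frozenset(
        {RelationClass.ADE_OUTCOME, RelationClass.NO_RELATION}
    ),
    frozenset({_A, _DI}): frozenset(
        {RelationClass.ADE_OUTCOME, RelationClass.NO_RELATION}
    ),
    frozenset({_DR, _A}): frozenset(
        {RelationClass.ADE_CAUSE, RelationClass.NO_RELATION}
    ),
}

#: All relation classes in the fixed classifier output order.
RELATION_CLASSES: tuple[RelationClass, ...] = PRIMARY_RELATIONS + (
    RelationClass.NO_RELATION,
)


def permissible_labels(
    c1: EntityClass, c2: EntityClass
) -> frozenset[RelationClass] | None:
    """Label set for an unordered type pair, or None if not a candidate pair."""
    return RELATION_SCHEMA.get(frozenset({c1, c2}))


@dataclass(frozen=True)
class Passage:
    """A sliding window of up to three sentences used as RE context."""

    note_id: str
    sent_start: int
    sent_end: int  # half-open
    token_start: int
    token_end: int  # half-open
    entity_ids: tuple[str, ...] = ()

    def contains(self, entity: Entity) -> bool:
        return self.token_start <= entity.token_start and entity.token_end <= self.token_end


def make_passages(note: Note, window: int = 3) -> list[Passage]:
    """3-sentence passages with stride one; a single clipped passage when the
    note has fewer than ``window`` sentences."""
    sentences = note.sentences or [(0, len(note.tokens))]
    n_sent = len(sentences)
    starts = range(max(n_sent - window + 1, 1))
    passages: list[Passage] = []
    for s in starts:
        e = min(s + window, n_sent)
        token_start = sentences[s][0]
        token_end = sentences[e - 1][1]
        contained = tuple(
            ent.id
            for ent in note.entities
            if token_start <= ent.token_start and ent.token_end <= token_end
        )
        passages.append(
            Passage(
                note_id=note.id,
                sent_start=s,
                sent_end=e,
                token_start=token_start,
                token_end=token_end,
                entity_ids=contained,
            )
        )
    return passages


@dataclass(frozen=True)
class CandidatePair:
    """An entity pair in its canonical passage — the RE classification unit.

    ``e1`` precedes ``e2`` in document order; the semantic direction of a
    relation is implied by the predicted label, not by the pair order.
    ``tokens`` is the passage token sequence with the pair marked by
    ``[E1]…[/E1]`` and ``[E2]…[/E2]``.
    """

    note_id: str
    passage: Passage
    e1: Entity
    e2: Entity
    gold_label: RelationClass = RelationClass.NO_RELATION
    tokens: tuple[str, ...] = ()

    @property
    def label_set(self) -> frozenset[RelationClass]:
        labels = permissible_labels(self.e1.cls, self.e2.cls)
        assert labels is not None
        return labels

    @property
    def rendered_text(self) -> str:
        return " ".join(self.tokens)


def render_pair_tokens(
    passage: Passage,
    e1: Entity,
    e2: Entity,
    note_tokens: Sequence[str],
    max_input_tokens: int = 512,
) -> tuple[str, ...]:
    """Passage tokens with the two entities wrapped in marker tokens.

    If the marked passage exceeds ``max_input_tokens`` it is truncated
    symmetrically around the marked pair so both entities survive.
    """
    if not (passage.contains(e1) and passage.contains(e2)):
        raise ValueError("entities must lie fully inside the passage")
    out: list[str] = []
    for i in range(passage.token_start, passage.token_end):
        if i == e1.token_start:
            out.append(E1_OPEN)
        if i == e2.token_start:
            out.append(E2_OPEN)
        out.append(note_tokens[i])
        if i == e1.token_end - 1:
            out.append(E1_CLOSE)
        if i == e2.token_end - 1:
            out.append(E2_CLOSE)
    return _truncate_around_markers(out, max_input_tokens)


def _truncate_around_markers(tokens: Sequence[str], max_len: int) -> tuple[str, ...]:
    """Clip a marked token sequence to ``max_len`` symmetrically around the
    marked pair so all four markers survive."""
    out = list(tokens)
    if len(out) <= max_len:
        return tuple(out)
    first = out.index(E1_OPEN)
    last = len(out) - 1 - out[::-1].index(E2_CLOSE)
    pair_len = last - first + 1
    budget = max_len - pair_len
    if budget < 0:
        raise ValueError(f"marked pair spans {pair_len} tokens > limit {max_len}")
    left = min(first, budget // 2)
    right = budget - left
    if last + 1 + right > len(out):
        right = len(out) - last - 1
        left = min(first, budget - right)
    return tuple(out[first - left : last + 1 + right])


def render_pair_input(
    passage: Passage,
    e1: Entity,
    e2: Entity,
    note_tokens: Sequence[str],
    max_input_tokens: int = 512,
) -> str:
    return " ".join(render_pair_tokens(passage, e1, e2, note_tokens, max_input_tokens))


def _pair_centering(passage: Passage, e1: Entity, e2: Entity) -> int:
    """How centered the pair's outermost tokens are within the passage."""
    span_start = min(e1.token_start, e2.token_start)
    span_end = max(e1.token_end, e2.token_end)
    return min(span_start - passage.token_start, passage.token_end - span_end)


def generate_candidates(
    note: Note,
    schema: dict[frozenset[EntityClass], frozenset[RelationClass]] | None = None,
    max_input_tokens: int = 512,
) -> list[CandidatePair]:
    """One candidate per permissible entity pair co-occurring in a passage.

    The candidate is attached to its *canonical* passage — the one in which
    the pair is most centered (ties broken toward the earliest passage) — so
    overlapping passages never duplicate a pair.  The gold label is the
    annotated relation joining the pair, if any, else No-relation; the same
    code path serves gold and predicted entities (it never reads labels to
    decide candidacy).
    """
    schema = RELATION_SCHEMA if schema is None else schema
    passages = make_passages(note)
    note_tokens = note.token_texts()
    containing: dict[str, list[Passage]] = {e.id: [] for e in note.entities}
    for passage in passages:
        for eid in passage.entity_ids:
            containing[eid].append(passage)
    for ent in note.entities:
        if not containing[ent.id]:
            logger.warning(
                "note %s: entity %s spans more sentences than the passage "
                "window; its pairs are skipped", note.id, ent.id,
            )

    gold: dict[frozenset[str], RelationClass] = {}
    for rel in note.relations:
        gold.setdefault(rel.arg_ids, rel.label)
        pair_shared = any(
            rel.arg1_id in p.entity_ids and rel.arg2_id in p.entity_ids
            for p in passages
        )
        if not pair_shared:
            logger.warning(
                "note %s: gold relation %s(%s, %s) spans more than the "
                "passage window and yields no candidate",
                note.id, rel.label.value, rel.arg1_id, rel.arg2_id,
            )

    ordered = sorted(note.entities, key=lambda e: (e.token_start, e.token_end))
    candidates: list[CandidatePair] = []
    for e1, e2 in combinations(ordered, 2):
        labels = schema.get(frozenset({e1.cls, e2.cls}))
        if labels is None:
            continue
        shared = [
            p for p in containing[e1.id] if e2.id in p.entity_ids
        ]
        if not shared:
            continue
        canonical = max(
            shared, key=lambda p: (_pair_centering(p, e1, e2), -p.sent_start)
        )
        gold_label = gold.get(frozenset({e1.id, e2.id}), RelationClass.NO_RELATION)
        if gold_label not in labels:  # defensive: schema closure
            raise ValueError(
                f"note {note.id}: gold label {gold_label} not permissible for "
                f"pair ({e1.cls}, {e2.cls})"
            )
        candidates.append(
            CandidatePair(
                note_id=note.id,
                passage=canonical,
                e1=e1,
                e2=e2,
                gold_label=gold_label,
                tokens=render_pair_tokens(
                    canonical, e1, e2, note_tokens, max_input_tokens
                ),
            )
        )
    return candidates


@dataclass(frozen=True)
class ReTrainConfig:
    """Training schedule for the relation classifier.

    Defaults are the selected full-scale fine-tuning values; ``desk_scale``
    returns the schedule used with the tiny from-scratch encoder (higher
    learning rate, bounded epochs), appropriate when no pretrained weights
    are involved.
    """

    batch_size: int = 32
    epochs: int = 50
    early_stopping_patience: int = 3  # epochs without val improvement
    optimizer: str = "adam"
    loss: str = "cross-entropy"
    learning_rate: float = 2.575e-5
    weight_decay: float = 1e-4
    max_input_tokens: int = 512
    dropout: float = 0.1
    grad_clip: float = 1.0
    d_model: int = 32
    d_ff: int = 64
    radius: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("rates and sizes must be positive")
        if self.early_stopping_patience > self.epochs:
            raise ValueError("patience must not exceed epochs")

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "ReTrainConfig":
        return cls(learning_rate=3e-3, epochs=30, seed=seed)


class RelationClassifier(BaseEstimator):
    """5-class entity-pair classifier over marked passages.

    Scikit-learn style estimator: ``fit`` consumes :class:`CandidatePair`
    sequences (gold labels carried by the candidates), ``predict`` returns
    one :class:`RelationClass` per candidate, ``predict_proba`` the
    normalized score vectors in ``classes_`` order.
    """

    def __init__(
        self,
        batch_size: int = 32,
        epochs: int = 50,
        early_stopping_patience: int = 3,
        learning_rate: float = 2.575e-5,
        weight_decay: float = 1e-4,
        max_input_tokens: int = 512,
        dropout: float = 0.1,
        grad_clip: float = 1.0,
        d_model: int = 32,
        d_ff: int = 64,
        radius: int = 2,
        seed: int = 0,
    ):
        self.batch_size = batch_size
        self.epochs = epochs
        self.early_stopping_patience = early_stopping_patience
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.max_input_tokens = max_input_tokens
        self.dropout = dropout
        self.grad_clip = grad_clip
        self.d_model = d_model
        self.d_ff = d_ff
        self.radius = radius
        self.seed = seed

    @classmethod
    def from_config(cls, config: ReTrainConfig) -> "RelationClassifier":
        return cls(
            batch_size=config.batch_size,
            epochs=config.epochs,
            early_stopping_patience=config.early_stopping_patience,
            learning_rate=config.learning_rate,
            weight_decay=config.weight_decay,
            max_input_tokens=config.max_input_tokens,
            dropout=config.dropout,
            grad_clip=config.grad_clip,
            d_model=config.d_model,
            d_ff=config.d_ff,
            radius=config.radius,
            seed=config.seed,
        )

    # -- featurization ---------------------------------------------------
    def _encode(self, candidates: Sequence[CandidatePair], max_len: int) -> dict:
        n = len(candidates)
        ids = np.zeros((n, max_len), dtype=np.int64)
        mask = np.zeros((n, max_len), dtype=float)
        marker_pos = np.zeros((n, 4), dtype=np.int64)
        for i, cand in enumerate(candidates):
            toks = _truncate_around_markers(cand.tokens, max_len)
            enc = self.vocab_.encode(toks)
            ids[i, : len(enc)] = enc
            mask[i, : len(enc)] = 1.0
            for j, marker in enumerate(MARKER_TOKENS):
                marker_pos[i, j] = toks.index(marker)
        return {"ids": ids, "mask": mask, "marker_pos": marker_pos}

    # -- estimator API ---------------------------------------------------
    def fit(
        self,
        candidates: Sequence[CandidatePair],
        y: None = None,
        validation: Sequence[CandidatePair] | None = None,
    ) -> "RelationClassifier":
        if not candidates:
            raise ValueError("cannot train on an empty candidate set")
        labels = {c.gold_label for c in candidates}
        if len(labels) < 2:
            raise ValueError("training data must contain at least 2 distinct labels")
        if validation is None:
            validation = candidates
        self.classes_ = list(RELATION_CLASSES)
        class_index = {c: i for i, c in enumerate(self.classes_)}
        self.vocab_ = _nn.Vocab.build(
            (c.tokens for c in candidates), extra=MARKER_TOKENS
        )
        max_len = min(
            self.max_input_tokens,
            max(len(c.tokens) for c in [*candidates, *validation]),
        )
        self.max_len_ = max_len
        train = self._encode(candidates, max_len)
        train["labels"] = np.array(
            [class_index[c.gold_label] for c in candidates], dtype=np.int64
        )
        val = self._encode(validation, max_len)
        val["labels"] = np.array(
            [class_index[c.gold_label] for c in validation], dtype=np.int64
        )
        self.net_ = _nn.PairClassifierNet(
            vocab_size=len(self.vocab_),
            n_labels=len(self.classes_),
            d_model=self.d_model,
            d_ff=self.d_ff,
            radius=self.radius,
            max_len=max_len,
            seed=self.seed,
        )
        self.history_ = _nn.fit(
            self.net_,
            train,
            val,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            grad_clip=self.grad_clip,
            dropout=self.dropout,
            max_epochs=self.epochs,
            patience_evals=self.early_stopping_patience,
            seed=self.seed,
        )
        return self

    def predict_proba(self, candidates: Sequence[CandidatePair]) -> np.ndarray:
        if not hasattr(self, "net_"):
            raise RuntimeError("RelationClassifier is not fitted")
        if not candidates:
            return np.zeros((0, len(self.classes_)))
        data = self._encode(candidates, self.max_len_)
        out = []
        for start in range(0, len(candidates), 256):
            sl = slice(start, start + 256)
            out.append(
                self.net_.predict_proba(
                    data["ids"][sl], data["mask"][sl], data["marker_pos"][sl]
                )
            )
        return np.concatenate(out, axis=0)

    def predict(
        self, candidates: Sequence[CandidatePair], constrain_schema: bool = True
    ) -> list[RelationClass]:
        """Predicted label per candidate: the highest-scoring label among the
        candidate's permissible label slot (the schema rules out the rest);
        pass ``constrain_schema=False`` for the unconstrained argmax."""
        probs = self.predict_proba(candidates)
        labels: list[RelationClass] = []
        for cand, row in zip(candidates, probs):
            if constrain_schema:
                allowed = cand.label_set
                idx = max(
                    (i for i, c in enumerate(self.classes_) if c in allowed),
                    key=lambda i: row[i],
                )
            else:
                idx = int(row.argmax())
            labels.append(self.classes_[idx])
        return labels


def train_re(
    candidates: Sequence[CandidatePair],
    val_candidates: Sequence[CandidatePair] | None = None,
    config: ReTrainConfig | None = None,
) -> RelationClassifier:
    """Fit a :class:`RelationClassifier`; thin wrapper over the estimator."""
    config = config or ReTrainConfig()
    model = RelationClassifier.from_config(config)
    return model.fit(candidates, validation=val_candidates)


def classify_pairs(
    model: RelationClassifier,
    candidates: Sequence[CandidatePair],
    constrain_schema: bool = True,
) -> list[tuple[RelationClass, np.ndarray]]:
    """Predicted label and normalized score vector per candidate."""
    probs = model.predict_proba(candidates)
    labels = model.predict(candidates, constrain_schema=constrain_schema)
    return list(zip(labels, probs))


def candidates_to_jsonl(candidates: Sequence[CandidatePair]) -> list[str]:
    """Line-delimited JSON serialization of a candidate set."""
    import json

    lines = []
    for c in candidates:
        lines.append(
            json.dumps(
                {
                    "note_id": c.note_id,
                    "e1": {
                        "id": c.e1.id,
                        "cls": c.e1.cls.value,
                        "token_start": c.e1.token_start,
                        "token_end": c.e1.token_end,
                    },
                    "e2": {
                        "id": c.e2.id,
                        "cls": c.e2.cls.value,
                        "token_start": c.e2.token_start,
                        "token_end": c.e2.token_end,
                    },
                    "gold_label": c.gold_label.value,
                    "rendered_text": c.rendered_text,
                }
            )
        )
    return lines
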