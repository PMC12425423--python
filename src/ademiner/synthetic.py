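"""Seed-reproducible synthetic annotated corpora.

The generator emulates the statistical structure of a Swedish clinical ADE
corpus — entity-class proportions, multiword ("compound") entity rate,
relation schema, the dominant No-relation class among candidate pairs, the
fraction of notes containing an explicit ADE description, and note length
in sentences — without any attempt at clinical realism.  Text is
pseudo-Swedish template filler: in *separable mode* (the default) every
entity class and every relation class draws from its own disjoint
vocabulary, so a small encoder can learn the tasks; *overlap mode* shares a
fraction of ADE-cue terms with the Disorder and Finding vocabularies to
reproduce the class confusions seen in real data.

Primary relations are realized as same-sentence ``entity trigger entity``
triples, where the trigger word is drawn from a per-relation-class
vocabulary.  This guarantees that related entities co-occur inside a
3-sentence passage and gives each relation class a learnable lexical
signal; unrelated permissible pairs that co-occur in a passage become
No-relation candidates downstream, which is never generated explicitly.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus_io import _tokens_from_texts, write_note_files
from .types import (
    ADE_FLAVORED_RELATIONS,
    Entity,
    EntityClass,
    Note,
    RelationClass,
    RelationInstance,
)

__all__ = ["GeneratorConfig", "Lexicon", "build_lexicon", "CorpusGenerator", "generate_corpus"]

_F, _DR, _DI, _B, _A = (
    EntityClass.FINDING,
    EntityClass.DRUG,
    EntityClass.DISORDER,
    EntityClass.BODY_STRUCTURE,
    EntityClass.ADE_CUE,
)

#: Entity-class proportions of the emulated corpus (after anonymization).
DEFAULT_CLASS_WEIGHTS: dict[EntityClass, float] = {
    _F: 0.35,
    _DR: 0.29,
    _DI: 0.20,
    _B: 0.12,
    _A: 0.04,
}

#: Unordered type pairs that triples may realize, with the relation label
#: they carry in an ADE note vs. a non-ADE note (None = pair not allowed).
_PAIR_KINDS: list[frozenset[EntityClass]] = [
    frozenset({_DR, _F}),
    frozenset({_DR, _DI}),
    frozenset({_A, _F}),
    frozenset({_A, _DI}),
    frozenset({_DR, _A}),
]

#: Among Drug–Finding/Disorder relations, share that are ADE rather than
#: Indication (810 : 1203 in the emulated corpus).
_ADE_VS_INDICATION = 810 / (810 + 1203)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Defaults mirror the emulated corpus: 395 notes, entity-class
    proportions 0.35/0.29/0.20/0.12/0.04, 23% compound entities, 62% of
    notes with an explicit ADE relation, a mean of 14 sentences per note,
    and disjoint class vocabularies (separable mode).
    """

    n_notes: int = 395
    entity_class_weights: dict[EntityClass, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS)
    )
    compound_entity_rate: float = 0.23
    ade_note_fraction: float = 0.62
    lexical_overlap_rate: float = 0.0
    mean_sentences_per_note: float = 14.0
    relation_attach_prob: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_notes < 1:
            raise ValueError("n_notes must be >= 1")
        total = sum(self.entity_class_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("entity class weights must sum to 1")
        for name in (
            "compound_entity_rate",
            "ade_note_fraction",
            "lexical_overlap_rate",
            "relation_attach_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mean_sentences_per_note <= 0:
            raise ValueError("mean_sentences_per_note must be positive")


@dataclass
class Lexicon:
    """Per-class term lists plus filler and relation-trigger vocabulary."""

    heads: dict[EntityClass, list[str]]
    continuations: dict[EntityClass, list[str]]
    filler: list[str]
    triggers: dict[RelationClass, list[str]]

    def class_vocab(self, cls: EntityClass) -> set[str]:
        return set(self.heads[cls]) | set(self.continuations[cls])


_SYLLABLES = (
    "ba be bi bo bu by da de di do du dy fa fe fi fo fu ga ge gi go gu "
    "ha he hi ho hu ja je ji jo ju ka ke ki ko ku la le li lo lu ma me "
    "mi mo mu na ne ni no nu pa pe pi po pu ra re ri ro ru sa se si so "
    "su ta te ti to tu va ve vi vo vu sten berg lund gren kvist strom"
).split()


def _word_factory(rng: np.random.Generator):
    used: set[str] = set()

    def make_word(n_syllables: int = 3) -> str:
        while True:
            k = int(rng.integers(2, n_syllables + 1))
            word = "".join(
                _SYLLABLES[int(i)] for i in rng.integers(len(_SYLLABLES), size=k)
            )
            if word not in used:
                used.add(word)
                return word

    return make_word


def build_lexicon(config: GeneratorConfig, rng: np.random.Generator | None = None) -> Lexicon:
    """Deterministic lexicon for a config; class vocabularies are pairwise
    disjoint unless ``lexical_overlap_rate`` > 0, in which case that
    fraction of ADE-cue head terms is shared into the Disorder and Finding
    lists."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    make_word = _word_factory(rng)
    heads = {cls: [make_word() for _ in range(40)] for cls in EntityClass}
    continuations = {cls: [make_word() for _ in range(12)] for cls in EntityClass}
    filler = [make_word() for _ in range(80)]
    triggers = {
        rel: [make_word() for _ in range(6)]
        for rel in (
            RelationClass.INDICATION,
            RelationClass.ADE,
            RelationClass.ADE_OUTCOME,
            RelationClass.ADE_CAUSE,
        )
    }
    if config.lexical_overlap_rate > 0:
        for term in heads[_A]:
            if rng.random() < config.lexical_overlap_rate:
                heads[_DI].append(term)
                heads[_F].append(term)
    return Lexicon(heads=heads, continuations=continuations, filler=filler, triggers=triggers)


def _pair_weights(
    weights: dict[EntityClass, float], pairs: Sequence[frozenset[EntityClass]]
) -> np.ndarray:
    w = np.array([np.prod([weights[c] for c in pair]) for pair in pairs])
    return w / w.sum()


def _lone_class_weights(config: GeneratorConfig) -> tuple[list[EntityClass], np.ndarray]:
    """Lone-entity class weights, corrected so that the overall entity-class
    marginal (lone entities + relation-triple entities) matches the
    configured proportions in expectation."""
    q = config.relation_attach_prob
    alpha = 2 * q / (1 + q)  # expected fraction of entities born inside triples
    p_pair = _pair_weights(config.entity_class_weights, _PAIR_KINDS)
    m_triple = {cls: 0.0 for cls in EntityClass}
    for pair, p in zip(_PAIR_KINDS, p_pair):
        for cls in pair:
            m_triple[cls] += p / 2.0
    classes = list(config.entity_class_weights)
    corrected = np.array(
        [
            max(config.entity_class_weights[c] - alpha * m_triple[c], 0.0)
            for c in classes
        ]
    )
    total = corrected.sum()
    if total <= 0:
        raise ValueError("relation_attach_prob too large for the class weights")
    return classes, corrected / total


class CorpusGenerator:
    """Stateful generator bound to one config and its lexicon."""

    def __init__(self, config: GeneratorConfig):
        self.config = config
        self.lexicon = build_lexicon(config)
        self._lone_classes, self._lone_weights = _lone_class_weights(config)
        self._p_pair = _pair_weights(config.entity_class_weights, _PAIR_KINDS)
        # pairs a non-ADE note may realize (Indication only)
        self._indication_pairs = [frozenset({_DR, _F}), frozenset({_DR, _DI})]
        self._p_indication = _pair_weights(
            config.entity_class_weights, self._indication_pairs
        )

    # -- mention construction -------------------------------------------
    def _pick(self, rng: np.random.Generator, terms: Sequence[str]) -> str:
        return terms[int(rng.integers(len(terms)))]

    def _mention(self, rng: np.random.Generator, cls: EntityClass) -> list[str]:
        tokens = [self._pick(rng, self.lexicon.heads[cls])]
        if rng.random() < self.config.compound_entity_rate:
            extra = 1 + int(rng.random() < 0.3)
            tokens += [
                self._pick(rng, self.lexicon.continuations[cls]) for _ in range(extra)
            ]
        return tokens

    def _fillers(self, rng: np.random.Generator, low: int, high: int) -> list[str]:
        return [
            self._pick(rng, self.lexicon.filler)
            for _ in range(int(rng.integers(low, high + 1)))
        ]

    def _triple_label(
        self, rng: np.random.Generator, pair: frozenset[EntityClass], is_ade: bool
    ) -> RelationClass:
        if _A in pair:
            return RelationClass.ADE_CAUSE if _DR in pair else RelationClass.ADE_OUTCOME
        if is_ade and rng.random() < _ADE_VS_INDICATION:
            return RelationClass.ADE
        return RelationClass.INDICATION

    @staticmethod
    def _orient(
        label: RelationClass, a: tuple[EntityClass, int], b: tuple[EntityClass, int]
    ) -> tuple[int, int]:
        """Semantic (arg1, arg2) order for a realized pair, by entity index."""
        by_cls = {a[0]: a[1], b[0]: b[1]}
        if label == RelationClass.INDICATION:
            src = _F if _F in by_cls else _DI
            return by_cls[src], by_cls[_DR]
        if label == RelationClass.ADE:
            dst = _F if _F in by_cls else _DI
            return by_cls[_DR], by_cls[dst]
        if label == RelationClass.ADE_OUTCOME:
            dst = _F if _F in by_cls else _DI
            return by_cls[_A], by_cls[dst]
        return by_cls[_DR], by_cls[_A]  # ADE_CAUSE

    # -- note construction -----------------------------------------------
    def _emit_triple(
        self,
        rng: np.random.Generator,
        pair: frozenset[EntityClass],
        label: RelationClass,
        texts: list[str],
        entities: list[tuple[EntityClass, int, int]],
        relations: list[tuple[RelationClass, int, int]],
    ) -> None:
        """Append ``e1 trigger e2`` to the sentence under construction."""
        classes = sorted(pair, key=lambda c: c.value)
        if rng.random() < 0.5:
            classes = classes[::-1]
        c1, c2 = classes
        texts.extend(self._fillers(rng, 1, 3))
        m1 = self._mention(rng, c1)
        start1 = len(texts)
        texts.extend(m1)
        idx1 = len(entities)
        entities.append((c1, start1, len(texts)))
        texts.append(self._pick(rng, self.lexicon.triggers[label]))
        m2 = self._mention(rng, c2)
        start2 = len(texts)
        texts.extend(m2)
        idx2 = len(entities)
        entities.append((c2, start2, len(texts)))
        arg1, arg2 = self._orient(label, (c1, idx1), (c2, idx2))
        relations.append((label, arg1, arg2))

    def generate_note(self, rng: np.random.Generator, note_id: str) -> Note:
        cfg = self.config
        is_ade = bool(rng.random() < cfg.ade_note_fraction)
        n_sent = max(3, int(rng.poisson(cfg.mean_sentences_per_note)))

        texts: list[str] = []
        sentences: list[tuple[int, int]] = []
        entities: list[tuple[EntityClass, int, int]] = []
        relations: list[tuple[RelationClass, int, int]] = []

        def build_sentence(force_pair: frozenset[EntityClass] | None = None) -> None:
            start = len(texts)
            n_units = int(rng.choice(3, p=[0.25, 0.45, 0.30]))
            if force_pair is not None:
                # forced triples must carry an ADE-flavored label
                if _A in force_pair:
                    label = (
                        RelationClass.ADE_CAUSE
                        if _DR in force_pair
                        else RelationClass.ADE_OUTCOME
                    )
                else:
                    label = RelationClass.ADE
                self._emit_triple(rng, force_pair, label, texts, entities, relations)
            for _ in range(n_units):
                if rng.random() < cfg.relation_attach_prob:
                    if is_ade:
                        pair = _PAIR_KINDS[
                            int(rng.choice(len(_PAIR_KINDS), p=self._p_pair))
                        ]
                    else:
                        pair = self._indication_pairs[
                            int(
                                rng.choice(
                                    len(self._indication_pairs), p=self._p_indication
                                )
                            )
                        ]
                    label = self._triple_label(rng, pair, is_ade)
                    self._emit_triple(rng, pair, label, texts, entities, relations)
                else:
                    texts.extend(self._fillers(rng, 1, 3))
                    cls = self._lone_classes[
                        int(rng.choice(len(self._lone_classes), p=self._lone_weights))
                    ]
                    mention = self._mention(rng, cls)
                    ent_start = len(texts)
                    texts.extend(mention)
                    entities.append((cls, ent_start, len(texts)))
            texts.extend(self._fillers(rng, 0, 2))
            texts.append(".")
            sentences.append((start, len(texts)))

        for _ in range(n_sent):
            build_sentence()

        if is_ade and not any(lbl in ADE_FLAVORED_RELATIONS for lbl, _, _ in relations):
            pair = _PAIR_KINDS[int(rng.choice(len(_PAIR_KINDS), p=self._p_pair))]
            build_sentence(force_pair=pair)

        tokens = _tokens_from_texts(texts)
        ents = [
            Entity(id=f"T{i + 1}", cls=cls, token_start=s, token_end=e, note_id=note_id)
            for i, (cls, s, e) in enumerate(entities)
        ]
        rels = [
            RelationInstance(
                label=lbl,
                arg1_id=ents[a1].id,
                arg2_id=ents[a2].id,
                note_id=note_id,
            )
            for lbl, a1, a2 in relations
        ]
        return Note(
            id=note_id,
            text=" ".join(texts),
            tokens=tokens,
            sentences=sentences,
            entities=ents,
            relations=rels,
        )

    def generate(self) -> list[Note]:
        rng = np.random.default_rng(self.config.seed)
        width = max(4, len(str(self.config.n_notes)))
        return [
            self.generate_note(rng, f"note_{i:0{width}d}")
            for i in range(self.config.n_notes)
        ]


def generate_corpus(
    config: GeneratorConfig, out_dir: str | Path | None = None
) -> list[Note]:
    """Generate a corpus; optionally emit the per-note txt/conll/ann triples
    plus a JSON manifest of gold note-level ADE flags and the config."""
    notes = CorpusGenerator(config).generate()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for note in notes:
            write_note_files(note, out_dir)
        manifest = {
            "config": _config_to_json(config),
            "notes": {
                note.id: {
                    "ade": any(
                        r.label in ADE_FLAVORED_RELATIONS for r in note.relations
                    )
                }
                for note in notes
            },
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return notes


def _config_to_json(config: GeneratorConfig) -> dict:
    raw = asdict(config)
    raw["entity_class_weights"] = {
        cls.value: w for cls, w in config.entity_class_weights.items()
    }
    return raw
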