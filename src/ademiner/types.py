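"""Core domain types for annotated clinical notes.

A *note* is a tokenized clinical text carrying typed entity spans and typed
binary relations between them.  Entities are contiguous, non-overlapping
token ranges drawn from five classes; relations link two entities and are
drawn from four primary classes plus the catch-all ``NO_RELATION`` used for
permissible-but-unannotated pairs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "EntityClass",
    "RelationClass",
    "BIO_TAGS",
    "ENTITY_CLASSES",
    "PRIMARY_RELATIONS",
    "ADE_FLAVORED_RELATIONS",
    "Token",
    "Entity",
    "RelationInstance",
    "Note",
    "CorpusSplit",
    "tag_entity_class",
    "is_valid_bio",
]


class EntityClass(str, Enum):
    """The five entity classes of the annotation schema.

    Serialized names use underscores instead of spaces so they survive
    column-oriented file formats.
    """

    FINDING = "Finding"
    DRUG = "Drug"
    DISORDER = "Disorder"
    BODY_STRUCTURE = "Body_Structure"
    ADE_CUE = "ADE_Cue"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class RelationClass(str, Enum):
    """Four primary relation classes plus the No-relation class."""

    INDICATION = "Indication"
    ADE = "ADE"
    ADE_OUTCOME = "ADE_Outcome"
    ADE_CAUSE = "ADE_Cause"
    NO_RELATION = "No_Relation"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical entity-class ordering (corpus frequency order).
ENTITY_CLASSES: tuple[EntityClass, ...] = (
    EntityClass.FINDING,
    EntityClass.DRUG,
    EntityClass.DISORDER,
    EntityClass.BODY_STRUCTURE,
    EntityClass.ADE_CUE,
)

#: The 11-label BIO tag set: O plus B-/I- per entity class.
BIO_TAGS: tuple[str, ...] = ("O",) + tuple(
    f"{p}-{c.value}" for c in ENTITY_CLASSES for p in ("B", "I")
)

PRIMARY_RELATIONS: tuple[RelationClass, ...] = (
    RelationClass.INDICATION,
    RelationClass.ADE,
    RelationClass.ADE_OUTCOME,
    RelationClass.ADE_CAUSE,
)

#: Relation classes whose presence marks a note as describing an ADE.
ADE_FLAVORED_RELATIONS: frozenset[RelationClass] = frozenset(
    {RelationClass.ADE, RelationClass.ADE_OUTCOME, RelationClass.ADE_CAUSE}
)


def tag_entity_class(tag: str) -> EntityClass | None:
    """Entity class of a BIO tag, or None for ``O``."""
    if tag == "O":
        return None
    return EntityClass(tag[2:])


def is_valid_bio(tags: Sequence[str]) -> bool:
    """True iff no I-X appears without an immediately preceding B-X or I-X."""
    prev: str | None = None
    for t in tags:
        if t not in _TAG_SET:
            return False
        if t.startswith("I-") and (prev is None or prev[2:] != t[2:] or prev == "O"):
            return False
        prev = t
    return True


_TAG_SET = frozenset(BIO_TAGS)


@dataclass(frozen=True)
class Token:
    """A single token with half-open character offsets into the note text."""

    text: str
    index: int
    char_start: int
    char_end: int

    def __post_init__(self) -> None:
        if self.char_start >= self.char_end:
            raise ValueError(f"empty token span at index {self.index}")


@dataclass(frozen=True)
class Entity:
    """A typed, contiguous token span; ``[token_start, token_end)``."""

    id: str
    cls: EntityClass
    token_start: int
    token_end: int
    note_id: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.token_start < self.token_end:
            raise ValueError(f"bad entity span [{self.token_start}, {self.token_end})")

    @property
    def n_tokens(self) -> int:
        return self.token_end - self.token_start

    def overlaps(self, other: "Entity") -> bool:
        return self.token_start < other.token_end and other.token_start < self.token_end


@dataclass(frozen=True)
class RelationInstance:
    """A typed, directed link between two entities of the same note.

    ``arg1`` is the semantic source of the relation (e.g. the Drug in an
    ADE relation, the Finding/Disorder in an Indication).
    """

    label: RelationClass
    arg1_id: str
    arg2_id: str
    note_id: str = ""

    def __post_init__(self) -> None:
        if self.arg1_id == self.arg2_id:
            raise ValueError("relation arguments must differ")

    @property
    def arg_ids(self) -> frozenset[str]:
        return frozenset({self.arg1_id, self.arg2_id})


@dataclass
class Note:
    """A clinical note: text, tokens, sentence ranges, entities, relations."""

    id: str
    text: str
    tokens: list[Token] = field(default_factory=list)
    sentences: list[tuple[int, int]] = field(default_factory=list)
    entities: list[Entity] = field(default_factory=list)
    relations: list[RelationInstance] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n = len(self.tokens)
        covered = 0
        for s, e in self.sentences:
            if s != covered or e <= s:
                raise ValueError(f"sentence ranges must partition tokens of note {self.id}")
            covered = e
        if self.sentences and covered != n:
            raise ValueError(f"sentence ranges must cover all {n} tokens of note {self.id}")
        ids = set()
        spans: list[Entity] = []
        for ent in self.entities:
            if ent.token_end > n:
                raise ValueError(f"entity {ent.id} exceeds note length {n}")
            if ent.id in ids:
                raise ValueError(f"duplicate entity id {ent.id}")
            ids.add(ent.id)
            for other in spans:
                if ent.overlaps(other):
                    raise ValueError(f"entities {ent.id} and {other.id} overlap")
            spans.append(ent)
        for rel in self.relations:
            if rel.arg1_id not in ids or rel.arg2_id not in ids:
                raise ValueError(
                    f"relation {rel.label} references unknown entity in note {self.id}"
                )

    def entity_by_id(self, entity_id: str) -> Entity:
        for ent in self.entities:
            if ent.id == entity_id:
                return ent
        raise KeyError(entity_id)

    def token_texts(self) -> list[str]:
        return [t.text for t in self.tokens]

    def sentence_of_token(self, index: int) -> int:
        for i, (s, e) in enumerate(self.sentences):
            if s <= index < e:
                return i
        raise IndexError(index)

    def with_annotations(
        self,
        entities: Iterable[Entity],
        relations: Iterable[RelationInstance] = (),
    ) -> "Note":
        """Copy of this note carrying the given annotations instead."""
        return Note(
            id=self.id,
            text=self.text,
            tokens=list(self.tokens),
            sentences=list(self.sentences),
            entities=list(entities),
            relations=list(relations),
        )


@dataclass(frozen=True)
class CorpusSplit:
    """Disjoint train/validation/test partition of note ids."""

    train: tuple[str, ...]
    validation: tuple[str, ...]
    test: tuple[str, ...]

    def __post_init__(self) -> None:
        parts = [set(self.train), set(self.validation), set(self.test)]
        total = sum(len(p) for p in parts)
        if len(set().union(*parts)) != total:
            raise ValueError("split partitions must be pairwise disjoint")

    @property
    def all_ids(self) -> frozenset[str]:
        return frozenset(self.train) | frozenset(self.validation) | frozenset(self.test)
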