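"""Reading and writing annotated notes in CoNLL-BIO and brat standoff formats.

The CoNLL dialect used here is the minimal two-column one: each non-blank
line is ``token<TAB-or-spaces>tag``, a blank line closes a sentence.  brat
standoff carries entities as T-lines (``T1\\tDrug 0 5\\tWaran``) and binary
relations as R-lines (``R1\\tADE Arg1:T1 Arg2:T2``).  Entity classes whose
display names contain spaces serialize with underscores (``Body_Structure``,
``ADE_Cue``) because column formats cannot carry internal spaces.
"""
from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .types import (
    BIO_TAGS,
    CorpusSplit,
    Entity,
    EntityClass,
    Note,
    RelationClass,
    RelationInstance,
    Token,
)

__all__ = [
    "CorpusFormatError",
    "bio_to_entities",
    "entities_to_bio",
    "parse_conll_note",
    "write_conll_note",
    "parse_brat",
    "write_brat",
    "split_corpus",
    "write_note_files",
    "read_note_files",
    "write_split_manifest",
]

_TAG_SET = frozenset(BIO_TAGS)


class CorpusFormatError(ValueError):
    """Raised on malformed annotation input."""


def bio_to_entities(
    tags: Sequence[str], note_id: str = "", id_prefix: str = "T"
) -> list[Entity]:
    """Reconstruct entity spans from a valid BIO tag sequence.

    One entity per maximal ``B-X (I-X)*`` run, in document order, with
    half-open token ranges.  Raises :class:`CorpusFormatError` on an invalid
    sequence (an ``I-X`` without a same-class predecessor); repairing model
    output is a separate operation (:func:`ademiner.ner.repair_bio`).
    """
    entities: list[Entity] = []
    start: int | None = None
    cls: EntityClass | None = None

    def close(end: int) -> None:
        nonlocal start, cls
        if start is not None:
            assert cls is not None
            entities.append(
                Entity(
                    id=f"{id_prefix}{len(entities) + 1}",
                    cls=cls,
                    token_start=start,
                    token_end=end,
                    note_id=note_id,
                )
            )
        start, cls = None, None

    for i, tag in enumerate(tags):
        if tag not in _TAG_SET:
            raise CorpusFormatError(f"unknown BIO tag {tag!r} at position {i}")
        if tag == "O":
            close(i)
        elif tag.startswith("B-"):
            close(i)
            start, cls = i, EntityClass(tag[2:])
        else:  # I-
            if cls is None or cls.value != tag[2:]:
                raise CorpusFormatError(
                    f"invalid BIO sequence: {tag!r} at position {i} has no "
                    f"matching B-/I- predecessor"
                )
    close(len(tags))
    return entities


def entities_to_bio(entities: Sequence[Entity], n_tokens: int) -> list[str]:
    """Exact inverse of :func:`bio_to_entities` on valid input."""
    tags = ["O"] * n_tokens
    seen: list[Entity] = []
    for ent in entities:
        if ent.token_end > n_tokens:
            raise CorpusFormatError(f"entity {ent.id} exceeds {n_tokens} tokens")
        for other in seen:
            if ent.overlaps(other):
                raise CorpusFormatError(f"entities {ent.id} and {other.id} overlap")
        seen.append(ent)
        tags[ent.token_start] = f"B-{ent.cls.value}"
        for i in range(ent.token_start + 1, ent.token_end):
            tags[i] = f"I-{ent.cls.value}"
    return tags


def _tokens_from_texts(texts: Sequence[str]) -> list[Token]:
    """Synthesize character offsets by joining token texts with single spaces."""
    tokens: list[Token] = []
    pos = 0
    for i, text in enumerate(texts):
        tokens.append(Token(text=text, index=i, char_start=pos, char_end=pos + len(text)))
        pos += len(text) + 1
    return tokens


def parse_conll_note(lines: Iterable[str], note_id: str) -> Note:
    """Parse a two-column CoNLL-BIO note into a :class:`Note`.

    Blank lines delimit sentences.  Token offsets (and the note text) are
    synthesized by single-space joining, which makes the round trip through
    :func:`write_conll_note` exact.  Relations are left empty; they live in
    the brat companion file.
    """
    texts: list[str] = []
    tags: list[str] = []
    sentences: list[tuple[int, int]] = []
    sent_start = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            if len(texts) > sent_start:
                sentences.append((sent_start, len(texts)))
                sent_start = len(texts)
            continue
        parts = line.split()
        if len(parts) != 2:
            raise CorpusFormatError(
                f"{note_id}: line {lineno}: expected 'token tag', got {line!r}"
            )
        token_text, tag = parts
        if tag not in _TAG_SET:
            raise CorpusFormatError(f"{note_id}: line {lineno}: unknown tag {tag!r}")
        texts.append(token_text)
        tags.append(tag)
    if len(texts) > sent_start:
        sentences.append((sent_start, len(texts)))
    if not texts:
        raise CorpusFormatError(f"{note_id}: empty CoNLL input")

    tokens = _tokens_from_texts(texts)
    entities = bio_to_entities(tags, note_id=note_id)
    return Note(
        id=note_id,
        text=" ".join(texts),
        tokens=tokens,
        sentences=sentences,
        entities=entities,
    )


def write_conll_note(note: Note) -> list[str]:
    """Serialize a note to two-column CoNLL-BIO lines (no trailing newline)."""
    tags = entities_to_bio(note.entities, len(note.tokens))
    lines: list[str] = []
    sentences = note.sentences or [(0, len(note.tokens))]
    for si, (s, e) in enumerate(sentences):
        if si:
            lines.append("")
        for i in range(s, e):
            lines.append(f"{note.tokens[i].text}\t{tags[i]}")
    return lines


def _char_span_to_token_span(note: Note, start: int, end: int) -> tuple[int, int]:
    """Minimal token span covering the half-open character span [start, end)."""
    covering = [
        t.index for t in note.tokens if t.char_start < end and start < t.char_end
    ]
    if not covering:
        raise CorpusFormatError(
            f"{note.id}: char span [{start}, {end}) crosses no token"
        )
    return covering[0], covering[-1] + 1


def parse_brat(ann_lines: Iterable[str], note: Note) -> Note:
    """Attach brat standoff entities and relations to a tokenized note.

    Character offsets are mapped to the minimal covering token span, which is
    robust to whitespace drift between the .txt and .ann producers.
    """
    entities: list[Entity] = []
    relations: list[tuple[str, RelationClass, str, str]] = []
    for lineno, raw in enumerate(ann_lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        ann_id = fields[0]
        if ann_id.startswith("T"):
            if len(fields) < 2:
                raise CorpusFormatError(f"{note.id}.ann line {lineno}: bad T-line")
            cls_name, start_s, end_s = fields[1].split()[:3]
            try:
                cls = EntityClass(cls_name)
            except ValueError as exc:
                raise CorpusFormatError(
                    f"{note.id}.ann line {lineno}: unknown entity class {cls_name!r}"
                ) from exc
            tok_start, tok_end = _char_span_to_token_span(
                note, int(start_s), int(end_s)
            )
            entities.append(
                Entity(
                    id=ann_id,
                    cls=cls,
                    token_start=tok_start,
                    token_end=tok_end,
                    note_id=note.id,
                )
            )
        elif ann_id.startswith("R"):
            body = fields[1].split()
            label = RelationClass(body[0])
            args = dict(part.split(":", 1) for part in body[1:3])
            relations.append((ann_id, label, args["Arg1"], args["Arg2"]))
        else:
            raise CorpusFormatError(
                f"{note.id}.ann line {lineno}: unsupported annotation {ann_id!r}"
            )

    known = {e.id for e in entities}
    rels: list[RelationInstance] = []
    for ann_id, label, a1, a2 in relations:
        if a1 not in known or a2 not in known:
            raise CorpusFormatError(
                f"{note.id}.ann: relation {ann_id} references unknown entity"
            )
        rels.append(
            RelationInstance(label=label, arg1_id=a1, arg2_id=a2, note_id=note.id)
        )
    return note.with_annotations(entities, rels)


def write_brat(note: Note) -> list[str]:
    """Serialize entities (T-lines) and relations (R-lines) to brat standoff."""
    lines: list[str] = []
    for ent in note.entities:
        start = note.tokens[ent.token_start].char_start
        end = note.tokens[ent.token_end - 1].char_end
        surface = note.text[start:end]
        lines.append(f"{ent.id}\t{ent.cls.value} {start} {end}\t{surface}")
    for i, rel in enumerate(note.relations, start=1):
        lines.append(
            f"R{i}\t{rel.label.value} Arg1:{rel.arg1_id} Arg2:{rel.arg2_id}"
        )
    return lines


def _round_half_up(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def split_corpus(
    note_ids: Sequence[str],
    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> CorpusSplit:
    """Deterministic train/validation/test split of note ids.

    Sizes follow the 70/10/20 convention: the test size is
    ``round(r_test * N)``, validation ``round(r_val * N)`` (half-up), and
    training takes the remainder.
    """
    n = len(note_ids)
    if n < 3:
        raise ValueError("need at least 3 notes to form 3 partitions")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    r_train, r_val, r_test = ratios
    n_test = _round_half_up(r_test * n)
    n_val = _round_half_up(r_val * n)
    n_train = n - n_test - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"split of {n} notes leaves an empty partition")

    rng = np.random.default_rng(seed)
    order = [note_ids[i] for i in rng.permutation(n)]
    return CorpusSplit(
        train=tuple(order[:n_train]),
        validation=tuple(order[n_train : n_train + n_val]),
        test=tuple(order[n_train + n_val :]),
    )


def write_split_manifest(split: CorpusSplit, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "train": list(split.train),
                "validation": list(split.validation),
                "test": list(split.test),
            },
            indent=2,
        )
        + "\n"
    )


def write_note_files(note: Note, directory: str | Path) -> None:
    """Emit the ``<id>.txt`` / ``.conll`` / ``.ann`` triple for one note."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / f"{note.id}.txt").write_text(note.text + "\n")
    (directory / f"{note.id}.conll").write_text("\n".join(write_conll_note(note)) + "\n")
    (directory / f"{note.id}.ann").write_text(
        "\n".join(write_brat(note)) + ("\n" if note.entities or note.relations else "")
    )


def read_note_files(note_id: str, directory: str | Path) -> Note:
    """Re-assemble a note from its ``.conll`` and ``.ann`` files."""
    directory = Path(directory)
    conll = (directory / f"{note_id}.conll").read_text().splitlines()
    note = parse_conll_note(conll, note_id)
    ann_path = directory / f"{note_id}.ann"
    if ann_path.exists():
        note = parse_brat(ann_path.read_text().splitlines(), note)
    return note
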