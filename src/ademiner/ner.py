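"""Token-classification NER over the 11-label BIO scheme.

Notes are segmented into overlapping 128-token windows (stride 96) so long
texts fit the encoder; at prediction time the window outputs are merged —
for a token covered by several windows the prediction is taken from the
window in which the token sits deepest (largest minimum distance to a window
boundary), because boundary tokens lack context — and the merged tag
sequence is repaired into a valid BIO sequence.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import _nn
from .corpus_io import bio_to_entities
from .types import BIO_TAGS, Entity, Note

__all__ = [
    "NerTrainConfig",
    "chunk_tokens",
    "repair_bio",
    "BioTagger",
    "train_ner",
    "predict_note_tags",
]


def chunk_tokens(
    n_tokens: int, window: int = 128, stride: int = 96
) -> list[tuple[int, int]]:
    """Overlapping half-open token windows covering ``[0, n_tokens)``.

    Starts are ``0, stride, 2*stride, …``; generation stops at the first
    window whose end reaches the note end, which is clipped to ``n_tokens``.
    """
    if stride <= 0 or window < stride:
        raise ValueError("need 0 < stride <= window")
    if n_tokens < 1:
        raise ValueError("need at least one token")
    ranges: list[tuple[int, int]] = []
    start = 0
    while True:
        end = start + window
        if end >= n_tokens:
            ranges.append((start, n_tokens))
            return ranges
        ranges.append((start, end))
        start += stride


def repair_bio(tags: Sequence[str]) -> list[str]:
    """Minimal repair of a model-output tag sequence into a valid BIO one.

    A stray ``I-X`` with no valid predecessor (start of sequence, after
    ``O``, or after a different class) becomes ``B-X``; everything else is
    unchanged.  Idempotent; valid input passes through untouched.
    """
    out: list[str] = []
    prev = "O"
    for tag in tags:
        if tag.startswith("I-") and (prev == "O" or prev[2:] != tag[2:]):
            tag = "B-" + tag[2:]
        out.append(tag)
        prev = tag
    return out


@dataclass(frozen=True)
class NerTrainConfig:
    """Training schedule for the BIO tagger.

    Defaults are the selected full-scale fine-tuning values (batch 128 with
    3-step gradient accumulation, Adam at 5e-5, early stopping with a
    1600-step patience).  ``desk_scale`` returns the schedule used with the
    tiny from-scratch encoder.
    """

    batch_size: int = 128
    dropout: float = 0.1
    optimizer: str = "adam"
    learning_rate: float = 5e-5
    grad_accumulation: int = 3
    grad_clip: float = 1.0
    patience_steps: int = 1600
    weight_decay: float = 0.01
    window: int = 128
    stride: int = 96
    max_epochs: int = 100
    d_model: int = 32
    d_ff: int = 64
    radius: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.stride <= self.window:
            raise ValueError("need 0 < stride <= window")
        if self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("rates and sizes must be positive")

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "NerTrainConfig":
        return cls(
            batch_size=32,
            grad_accumulation=1,
            learning_rate=3e-3,
            patience_steps=80,
            max_epochs=40,
            seed=seed,
        )


class BioTagger(BaseEstimator):
    """Scikit-learn style BIO sequence tagger over whole notes.

    ``fit`` consumes :class:`~ademiner.types.Note` objects (gold entities
    carried by the notes), ``predict`` returns one repaired BIO tag sequence
    per note, ``predict_entities`` the reconstructed entity spans.
    """

    def __init__(
        self,
        window: int = 128,
        stride: int = 96,
        batch_size: int = 128,
        grad_accumulation: int = 3,
        learning_rate: float = 5e-5,
        dropout: float = 0.1,
        weight_decay: float = 0.01,
        grad_clip: float = 1.0,
        patience_steps: int = 1600,
        max_epochs: int = 100,
        d_model: int = 32,
        d_ff: int = 64,
        radius: int = 2,
        seed: int = 0,
    ):
        self.window = window
        self.stride = stride
        self.batch_size = batch_size
        self.grad_accumulation = grad_accumulation
        self.learning_rate = learning_rate
        self.dropout = dropout
        self.weight_decay = weight_decay
        self.grad_clip = grad_clip
        self.patience_steps = patience_steps
        self.max_epochs = max_epochs
        self.d_model = d_model
        self.d_ff = d_ff
        self.radius = radius
        self.seed = seed

    @classmethod
    def from_config(cls, config: NerTrainConfig) -> "BioTagger":
        return cls(
            window=config.window,
            stride=config.stride,
            batch_size=config.batch_size,
            grad_accumulation=config.grad_accumulation,
            learning_rate=config.learning_rate,
            dropout=config.dropout,
            weight_decay=config.weight_decay,
            grad_clip=config.grad_clip,
            patience_steps=config.patience_steps,
            max_epochs=config.max_epochs,
            d_model=config.d_model,
            d_ff=config.d_ff,
            radius=config.radius,
            seed=config.seed,
        )

    # -- featurization ---------------------------------------------------
    def _note_windows(self, note: Note, with_labels: bool) -> list[dict]:
        from .corpus_io import entities_to_bio

        texts = note.token_texts()
        tag_index = {t: i for i, t in enumerate(BIO_TAGS)}
        tags = (
            entities_to_bio(note.entities, len(texts)) if with_labels else None
        )
        rows = []
        for s, e in chunk_tokens(len(texts), self.window, self.stride):
            ids = np.zeros(self.window, dtype=np.int64)
            mask = np.zeros(self.window, dtype=float)
            enc = self.vocab_.encode(texts[s:e])
            ids[: e - s] = enc
            mask[: e - s] = 1.0
            row = {"ids": ids, "mask": mask, "range": (s, e)}
            if tags is not None:
                labels = np.zeros(self.window, dtype=np.int64)
                labels[: e - s] = [tag_index[t] for t in tags[s:e]]
                row["labels"] = labels
                row["label_mask"] = mask.copy()
            rows.append(row)
        return rows

    def _stack(self, rows: list[dict], with_labels: bool) -> dict:
        data = {
            "ids": np.stack([r["ids"] for r in rows]),
            "mask": np.stack([r["mask"] for r in rows]),
        }
        if with_labels:
            data["labels"] = np.stack([r["labels"] for r in rows])
            data["label_mask"] = np.stack([r["label_mask"] for r in rows])
        return data

    # -- estimator API ---------------------------------------------------
    def fit(
        self,
        notes: Sequence[Note],
        y: None = None,
        validation: Sequence[Note] | None = None,
    ) -> "BioTagger":
        if not notes:
            raise ValueError("cannot train on an empty note set")
        if validation is None:
            validation = notes
        self.classes_ = list(BIO_TAGS)
        self.vocab_ = _nn.Vocab.build(n.token_texts() for n in notes)
        train_rows = [r for n in notes for r in self._note_windows(n, True)]
        val_rows = [r for n in validation for r in self._note_windows(n, True)]
        train = self._stack(train_rows, True)
        val = self._stack(val_rows, True)
        self.net_ = _nn.TokenClassifierNet(
            vocab_size=len(self.vocab_),
            n_labels=len(self.classes_),
            d_model=self.d_model,
            d_ff=self.d_ff,
            radius=self.radius,
            max_len=self.window,
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
            grad_accumulation=self.grad_accumulation,
            dropout=self.dropout,
            max_epochs=self.max_epochs,
            patience_steps=self.patience_steps,
            seed=self.seed,
        )
        return self

    def predict_note_proba(self, note: Note) -> np.ndarray:
        """Merged per-token label probabilities for one note (n_tokens, 11)."""
        if not hasattr(self, "net_"):
            raise RuntimeError("BioTagger is not fitted")
        rows = self._note_windows(note, with_labels=False)
        data = self._stack(rows, with_labels=False)
        probs = self.net_.predict_proba(data["ids"], data["mask"])
        n = len(note.tokens)
        merged = np.zeros((n, probs.shape[-1]))
        depth = np.full(n, -1)
        for chunk_i, row in enumerate(rows):
            s, e = row["range"]
            for t in range(s, e):
                boundary_distance = min(t - s, e - 1 - t)
                if boundary_distance > depth[t]:  # ties keep the earlier chunk
                    depth[t] = boundary_distance
                    merged[t] = probs[chunk_i, t - s]
        return merged

    def predict(self, notes: Sequence[Note]) -> list[list[str]]:
        """One repaired, valid BIO tag sequence per note."""
        out = []
        for note in notes:
            proba = self.predict_note_proba(note)
            tags = [self.classes_[i] for i in proba.argmax(axis=1)]
            out.append(repair_bio(tags))
        return out

    def predict_entities(self, notes: Sequence[Note]) -> list[list[Entity]]:
        return [
            bio_to_entities(tags, note_id=note.id, id_prefix="P")
            for note, tags in zip(notes, self.predict(notes))
        ]


def train_ner(
    train_notes: Sequence[Note],
    val_notes: Sequence[Note] | None = None,
    config: NerTrainConfig | None = None,
) -> BioTagger:
    """Fit a :class:`BioTagger`; thin wrapper over the estimator."""
    config = config or NerTrainConfig()
    model = BioTagger.from_config(config)
    return model.fit(train_notes, validation=val_notes)


def predict_note_tags(model: BioTagger, note: Note) -> list[str]:
    """Merged, repaired BIO tags for one note."""
    return model.predict([note])[0]
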