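from __future__ import annotations

import pytest

from ademiner.corpus_io import parse_conll_note
from ademiner.synthetic import CorpusGenerator, GeneratorConfig
from ademiner.types import Note


def make_note(conll_text: str, note_id: str = "n1") -> Note:
    """Build a note from inline two-column CoNLL text (for readable tests)."""
    lines = [ln.strip() for ln in conll_text.strip().splitlines()]
    return parse_conll_note(lines, note_id)


@pytest.fixture(scope="session")
def small_corpus() -> list[Note]:
    """60 separable synthetic notes shared by unit tests."""
    return CorpusGenerator(GeneratorConfig(n_notes=60, seed=5)).generate()


@pytest.fixture(scope="session")
def tiny_corpus() -> list[Note]:
    """A handful of notes for fast training smoke tests."""
    return CorpusGenerator(GeneratorConfig(n_notes=8, seed=3)).generate()
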