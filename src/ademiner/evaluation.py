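"""Evaluation: per-class and micro/macro P/R/F1/F2, strict vs relaxed span
matching, relation and note-level scoring, confusion-based error analysis.

Strict matching requires class identity and an exact token span; relaxed
matching requires class identity and at least one shared token (the direct
formalization of "at least one word of a multiword entity was found").
Matching is resolved greedily by largest token overlap with positional
tie-breaks; on small instances this coincides with the optimal assignment,
which the test suite checks by brute force.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support as _sk_prfs

from .types import (
    ENTITY_CLASSES,
    Entity,
    PRIMARY_RELATIONS,
    RelationClass,
    RelationInstance,
)

__all__ = [
    "MatchMode",
    "EvalReport",
    "fbeta",
    "match_entities",
    "score_ner",
    "score_entities",
    "score_relations",
    "score_relation_labels",
    "score_notes",
    "error_analysis",
]

OTHER = "Other"


class MatchMode(str, Enum):
    STRICT = "strict"
    RELAXED = "relaxed"


def fbeta(precision: float, recall: float, beta: float = 1.0) -> float:
    """F-beta score; 0 by convention when precision = recall = 0."""
    if precision < 0 or recall < 0 or beta < 0:
        raise ValueError("fbeta inputs must be non-negative")
    if precision == 0 and recall == 0:
        return 0.0
    b2 = beta * beta
    return (1 + b2) * precision * recall / (b2 * precision + recall)


@dataclass
class EvalReport:
    """Per-class and aggregated precision/recall/F1/F2 with confusion matrix."""

    per_class: dict[str, dict[str, float]]
    micro: dict[str, float]
    macro: dict[str, float]
    extras: dict[str, dict[str, float]] = field(default_factory=dict)
    confusion: pd.DataFrame | None = None

    def to_json(self) -> dict:
        out = {
            "per_class": self.per_class,
            "micro": self.micro,
            "macro": self.macro,
            **{k: v for k, v in self.extras.items()},
        }
        if self.confusion is not None:
            out["confusion"] = self.confusion.to_dict()
        return out

    def to_text(self) -> str:
        rows = []
        for cls, m in self.per_class.items():
            rows.append(
                f"{cls:>22s}  P={m['precision']:.3f}  R={m['recall']:.3f}  "
                f"F1={m['f1']:.3f}  F2={m['f2']:.3f}  n={int(m['support'])}"
            )
        rows.append(
            f"{'micro':>22s}  P={self.micro['precision']:.3f}  "
            f"R={self.micro['recall']:.3f}  F1={self.micro['f1']:.3f}"
        )
        rows.append(
            f"{'macro':>22s}  P={self.macro['precision']:.3f}  "
            f"R={self.macro['recall']:.3f}  F1={self.macro['f1']:.3f}"
        )
        return "\n".join(rows)


def _metrics_from_counts(tp: int, fp: int, fn: int) -> dict[str, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return {
        "precision": p,
        "recall": r,
        "f1": fbeta(p, r, 1.0),
        "f2": fbeta(p, r, 2.0),
        "support": float(tp + fn),
    }


def _report_from_counts(
    counts: Mapping[str, tuple[int, int, int]],
    macro_classes: Sequence[str],
    confusion: pd.DataFrame | None = None,
) -> EvalReport:
    per_class = {c: _metrics_from_counts(*counts[c]) for c in counts}
    tp = sum(counts[c][0] for c in counts)
    fp = sum(counts[c][1] for c in counts)
    fn = sum(counts[c][2] for c in counts)
    micro = _metrics_from_counts(tp, fp, fn)
    macro = _macro_over(per_class, macro_classes)
    return EvalReport(per_class=per_class, micro=micro, macro=macro, confusion=confusion)


def _macro_over(
    per_class: Mapping[str, Mapping[str, float]], classes: Sequence[str]
) -> dict[str, float]:
    return {
        key: float(np.mean([per_class[c][key] for c in classes])) if classes else 0.0
        for key in ("precision", "recall", "f1", "f2")
    }


# ---------------------------------------------------------------------------
# entity matching


def _overlap(a: Entity, b: Entity) -> int:
    return max(0, min(a.token_end, b.token_end) - max(a.token_start, b.token_start))


def match_entities(
    gold: Sequence[Entity], pred: Sequence[Entity], mode: MatchMode | str
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Greedy one-to-one matching between gold and predicted entities.

    Returns (matched index pairs, unmatched gold indices, unmatched pred
    indices).  A pair is admissible iff classes agree and, in strict mode,
    token ranges are identical — in relaxed mode, ranges share >= 1 token.
    Admissible pairs are consumed in order of decreasing overlap, then
    earliest position.
    """
    mode = MatchMode(mode)
    admissible: list[tuple[int, int, int, int, int]] = []
    for gi, g in enumerate(gold):
        for pi, p in enumerate(pred):
            if g.cls != p.cls:
                continue
            if mode is MatchMode.STRICT:
                if (g.token_start, g.token_end) != (p.token_start, p.token_end):
                    continue
                ov = g.n_tokens
            else:
                ov = _overlap(g, p)
                if ov == 0:
                    continue
            admissible.append((-ov, g.token_start, p.token_start, gi, pi))
    admissible.sort()
    used_g: set[int] = set()
    used_p: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _, _, _, gi, pi in admissible:
        if gi in used_g or pi in used_p:
            continue
        used_g.add(gi)
        used_p.add(pi)
        matches.append((gi, pi))
    unmatched_gold = [i for i in range(len(gold)) if i not in used_g]
    unmatched_pred = [i for i in range(len(pred)) if i not in used_p]
    return matches, unmatched_gold, unmatched_pred


# ---------------------------------------------------------------------------
# NER scoring


def _merge_tag(tag: str) -> str:
    return OTHER if tag == "O" else tag[2:]


def score_ner(
    gold_tags: Sequence[Sequence[str]], pred_tags: Sequence[Sequence[str]]
) -> EvalReport:
    """Token-level report over merged B/I entity categories.

    The macro average runs over the five entity classes (the Other category
    is excluded); the micro average pools all non-Other tokens.
    """
    if len(gold_tags) != len(pred_tags):
        raise ValueError("gold and predicted corpora differ in note count")
    gold_flat: list[str] = []
    pred_flat: list[str] = []
    for i, (g, p) in enumerate(zip(gold_tags, pred_tags)):
        if len(g) != len(p):
            raise ValueError(f"note {i}: tag sequences differ in length")
        gold_flat.extend(_merge_tag(t) for t in g)
        pred_flat.extend(_merge_tag(t) for t in p)

    classes = [c.value for c in ENTITY_CLASSES]
    p1, r1, f1, support = _sk_prfs(
        gold_flat, pred_flat, labels=classes, zero_division=0, beta=1.0
    )
    _, _, f2, _ = _sk_prfs(
        gold_flat, pred_flat, labels=classes, zero_division=0, beta=2.0
    )
    per_class = {
        c: {
            "precision": float(p1[i]),
            "recall": float(r1[i]),
            "f1": float(f1[i]),
            "f2": float(f2[i]),
            "support": float(support[i]),
        }
        for i, c in enumerate(classes)
    }
    mp, mr, mf1, _ = _sk_prfs(
        gold_flat, pred_flat, labels=classes, average="micro", zero_division=0
    )
    _, _, mf2, _ = _sk_prfs(
        gold_flat, pred_flat, labels=classes, average="micro", zero_division=0, beta=2.0
    )
    micro = {
        "precision": float(mp),
        "recall": float(mr),
        "f1": float(mf1),
        "f2": float(mf2),
    }
    macro = _macro_over(per_class, classes)
    all_cats = classes + [OTHER]
    conf = pd.DataFrame(
        _sk_confusion(gold_flat, pred_flat, labels=all_cats),
        index=all_cats,
        columns=all_cats,
    )
    return EvalReport(per_class=per_class, micro=micro, macro=macro, confusion=conf)


def score_entities(
    gold: Sequence[Sequence[Entity]],
    pred: Sequence[Sequence[Entity]],
    mode: MatchMode | str = MatchMode.STRICT,
) -> EvalReport:
    """Entity-level report under strict or relaxed span matching."""
    if len(gold) != len(pred):
        raise ValueError("gold and predicted corpora differ in note count")
    classes = [c.value for c in ENTITY_CLASSES]
    counts = {c: [0, 0, 0] for c in classes}
    for g_ents, p_ents in zip(gold, pred):
        matches, unmatched_g, unmatched_p = match_entities(g_ents, p_ents, mode)
        for gi, _pi in matches:
            counts[g_ents[gi].cls.value][0] += 1
        for pi in unmatched_p:
            counts[p_ents[pi].cls.value][1] += 1
        for gi in unmatched_g:
            counts[g_ents[gi].cls.value][2] += 1
    return _report_from_counts(
        {c: tuple(v) for c, v in counts.items()}, macro_classes=classes
    )


# ---------------------------------------------------------------------------
# relation scoring


def score_relations(
    gold: Sequence[tuple[Sequence[Entity], Sequence[RelationInstance]]],
    pred: Sequence[tuple[Sequence[Entity], Sequence[RelationInstance]]],
    mode: MatchMode | str = MatchMode.STRICT,
) -> EvalReport:
    """Relation report under entity matching in the given mode.

    A predicted relation is a true positive iff a gold relation with the
    same label exists whose argument entities are matched one-to-one (per
    :func:`match_entities` under ``mode``) to the prediction's arguments.
    Relations are compared as unordered argument pairs because the pair
    order at inference is document order while the semantic direction is
    implied by the label.  The main macro average runs over the four
    primary classes; ``extras["macro_including_no_relation"]`` adds the
    No-relation class.
    """
    if len(gold) != len(pred):
        raise ValueError("gold and predicted corpora differ in note count")
    mode = MatchMode(mode)
    classes = [c.value for c in PRIMARY_RELATIONS] + [RelationClass.NO_RELATION.value]
    counts = {c: [0, 0, 0] for c in classes}
    for (g_ents, g_rels), (p_ents, p_rels) in zip(gold, pred):
        g_by_id = {e.id: i for i, e in enumerate(g_ents)}
        p_by_id = {e.id: i for i, e in enumerate(p_ents)}
        for rel in g_rels:
            if rel.arg1_id not in g_by_id or rel.arg2_id not in g_by_id:
                raise ValueError(f"gold relation references unknown entity {rel}")
        for rel in p_rels:
            if rel.arg1_id not in p_by_id or rel.arg2_id not in p_by_id:
                raise ValueError(f"predicted relation references unknown entity {rel}")
        matches, _, _ = match_entities(list(g_ents), list(p_ents), mode)
        pred_to_gold = {p_ents[pi].id: g_ents[gi].id for gi, pi in matches}
        remaining = Counter(
            (rel.label.value, frozenset({rel.arg1_id, rel.arg2_id})) for rel in g_rels
        )
        for rel in p_rels:
            mapped1 = pred_to_gold.get(rel.arg1_id)
            mapped2 = pred_to_gold.get(rel.arg2_id)
            key = (rel.label.value, frozenset({mapped1, mapped2}))
            if mapped1 and mapped2 and remaining.get(key, 0) > 0:
                remaining[key] -= 1
                counts[rel.label.value][0] += 1
            else:
                counts[rel.label.value][1] += 1
        for (label, _args), n in remaining.items():
            counts[label][2] += n

    report = _report_from_counts(
        {c: tuple(v) for c, v in counts.items()},
        macro_classes=[c.value for c in PRIMARY_RELATIONS],
    )
    report.extras["macro_including_no_relation"] = _macro_over(
        report.per_class, classes
    )
    return report


def score_relation_labels(
    gold_labels: Sequence[RelationClass], pred_labels: Sequence[RelationClass]
) -> EvalReport:
    """Multiclass report for a relation classifier run on fixed candidates
    (gold entities); macro over the four primary classes, with the
    No-relation-inclusive macro in ``extras``."""
    if len(gold_labels) != len(pred_labels):
        raise ValueError("label sequences differ in length")
    gold_v = [g.value for g in gold_labels]
    pred_v = [p.value for p in pred_labels]
    classes = [c.value for c in PRIMARY_RELATIONS] + [RelationClass.NO_RELATION.value]
    counts: dict[str, tuple[int, int, int]] = {}
    for c in classes:
        tp = sum(1 for g, p in zip(gold_v, pred_v) if g == p == c)
        fp = sum(1 for g, p in zip(gold_v, pred_v) if p == c and g != c)
        fn = sum(1 for g, p in zip(gold_v, pred_v) if g == c and p != c)
        counts[c] = (tp, fp, fn)
    conf = pd.DataFrame(
        _sk_confusion(gold_v, pred_v, labels=classes), index=classes, columns=classes
    )
    report = _report_from_counts(
        counts, macro_classes=[c.value for c in PRIMARY_RELATIONS], confusion=conf
    )
    report.extras["macro_including_no_relation"] = _macro_over(
        report.per_class, classes
    )
    return report


# ---------------------------------------------------------------------------
# note-level scoring


def score_notes(
    gold_flags: Mapping[str, bool], pred_flags: Mapping[str, bool]
) -> EvalReport:
    """Binary note-level report: ContainingADE vs NoADE, with macro average."""
    if set(gold_flags) != set(pred_flags):
        raise ValueError("gold and predicted note ids differ")
    counts: dict[str, tuple[int, int, int]] = {}
    for name, positive in (("ContainingADE", True), ("NoADE", False)):
        tp = sum(
            1 for k in gold_flags if gold_flags[k] == positive and pred_flags[k] == positive
        )
        fp = sum(
            1 for k in gold_flags if gold_flags[k] != positive and pred_flags[k] == positive
        )
        fn = sum(
            1 for k in gold_flags if gold_flags[k] == positive and pred_flags[k] != positive
        )
        counts[name] = (tp, fp, fn)
    return _report_from_counts(counts, macro_classes=["ContainingADE", "NoADE"])


# ---------------------------------------------------------------------------
# error analysis


def error_analysis(
    gold_tags: Sequence[Sequence[str]],
    pred_tags: Sequence[Sequence[str]],
    tokens: Sequence[Sequence[str]],
    k: int = 10,
) -> tuple[pd.DataFrame, dict[tuple[str, str], list[tuple[str, int]]]]:
    """Confusion matrix over the six token categories plus, per off-diagonal
    cell, the ``k`` most frequent case-folded token strings with counts."""
    cats = [c.value for c in ENTITY_CLASSES] + [OTHER]
    gold_flat: list[str] = []
    pred_flat: list[str] = []
    terms: dict[tuple[str, str], Counter] = {}
    for g_seq, p_seq, t_seq in zip(gold_tags, pred_tags, tokens):
        if not len(g_seq) == len(p_seq) == len(t_seq):
            raise ValueError("tag and token sequences must be aligned")
        for g, p, tok in zip(g_seq, p_seq, t_seq):
            gc, pc = _merge_tag(g), _merge_tag(p)
            gold_flat.append(gc)
            pred_flat.append(pc)
            if gc != pc:
                terms.setdefault((gc, pc), Counter())[tok.casefold()] += 1
    conf = pd.DataFrame(
        _sk_confusion(gold_flat, pred_flat, labels=cats), index=cats, columns=cats
    )
    top_terms = {
        cell: counter.most_common(k) for cell, counter in sorted(terms.items())
    }
    return conf, top_terms
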