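"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive — plain loops and enumerations with
no shared code with the implementation under test.
"""
from __future__ import annotations

from itertools import combinations

from ademiner.types import ENTITY_CLASSES, BIO_TAGS, RelationClass


def enumerate_valid_bio(max_len: int):
    """All valid BIO sequences over the 11-tag alphabet up to max_len."""
    results = [[]]
    frontier = [[]]
    for _ in range(max_len):
        nxt = []
        for seq in frontier:
            for tag in BIO_TAGS:
                if tag.startswith("I-"):
                    if not seq:
                        continue
                    prev = seq[-1]
                    if prev == "O" or prev[2:] != tag[2:]:
                        continue
                nxt.append(seq + [tag])
        results.extend(nxt)
        frontier = nxt
    return results


def naive_entity_spans(tags):
    """Entity spans (cls_value, start, end) via direct scanning."""
    spans = []
    i = 0
    while i < len(tags):
        if tags[i].startswith("B-"):
            cls = tags[i][2:]
            j = i + 1
            while j < len(tags) and tags[j] == f"I-{cls}":
                j += 1
            spans.append((cls, i, j))
            i = j
        else:
            i += 1
    return spans


# --- candidate generation ---------------------------------------------------

SCHEMA_PAIRS = {
    frozenset({"Drug", "Finding"}),
    frozenset({"Drug", "Disorder"}),
    frozenset({"ADE_Cue", "Finding"}),
    frozenset({"ADE_Cue", "Disorder"}),
    frozenset({"Drug", "ADE_Cue"}),
}


def naive_candidate_pairs(note):
    """All permissible entity pairs co-occurring in >= 1 three-sentence
    passage, with their gold labels; returned as a set of
    (e1_id, e2_id, gold_label_value) triples with e1 before e2 in document
    order."""
    sentences = note.sentences or [(0, len(note.tokens))]
    n_sent = len(sentences)
    windows = []
    for s in range(max(n_sent - 2, 1)):
        e = min(s + 3, n_sent)
        windows.append((sentences[s][0], sentences[e - 1][1]))
    gold = {}
    for rel in note.relations:
        gold[frozenset({rel.arg1_id, rel.arg2_id})] = rel.label.value
    out = set()
    ordered = sorted(note.entities, key=lambda x: (x.token_start, x.token_end))
    for a, b in combinations(ordered, 2):
        if frozenset({a.cls.value, b.cls.value}) not in SCHEMA_PAIRS:
            continue
        together = any(
            ws <= a.token_start and a.token_end <= we
            and ws <= b.token_start and b.token_end <= we
            for ws, we in windows
        )
        if not together:
            continue
        label = gold.get(frozenset({a.id, b.id}), "No_Relation")
        out.add((a.id, b.id, label))
    return out


# --- metric counting --------------------------------------------------------


def naive_fbeta(p, r, beta):
    if p == 0 and r == 0:
        return 0.0
    return (1 + beta**2) * p * r / (beta**2 * p + r)


def naive_token_counts(gold_tags, pred_tags):
    """Per-class (tp, fp, fn) over merged B/I token categories."""
    classes = [c.value for c in ENTITY_CLASSES]
    counts = {c: [0, 0, 0] for c in classes}
    for g_seq, p_seq in zip(gold_tags, pred_tags):
        for g, p in zip(g_seq, p_seq):
            gc = "Other" if g == "O" else g[2:]
            pc = "Other" if p == "O" else p[2:]
            for c in classes:
                if gc == c and pc == c:
                    counts[c][0] += 1
                elif pc == c and gc != c:
                    counts[c][1] += 1
                elif gc == c and pc != c:
                    counts[c][2] += 1
    return counts


def naive_relation_counts(gold_sides, pred_sides, mode):
    """Per-label (tp, fp, fn) for relation sets under entity matching.

    Entities are matched per note by a maximum assignment over admissible
    pairs (class equal; strict: identical span, relaxed: >= 1 shared token),
    preferring cardinality then total overlap, via the Hungarian algorithm.
    """
    labels = [c.value for c in RelationClass]
    counts = {c: [0, 0, 0] for c in labels}
    for (g_ents, g_rels), (p_ents, p_rels) in zip(gold_sides, pred_sides):
        mapping = _hungarian_assignment(g_ents, p_ents, mode)
        pred_to_gold = {p_ents[pi].id: g_ents[gi].id for gi, pi in mapping}
        gold_keys = [
            (r.label.value, frozenset({r.arg1_id, r.arg2_id})) for r in g_rels
        ]
        used = [False] * len(gold_keys)
        for rel in p_rels:
            m1 = pred_to_gold.get(rel.arg1_id)
            m2 = pred_to_gold.get(rel.arg2_id)
            hit = None
            if m1 and m2:
                key = (rel.label.value, frozenset({m1, m2}))
                for i, gk in enumerate(gold_keys):
                    if not used[i] and gk == key:
                        hit = i
                        break
            if hit is None:
                counts[rel.label.value][1] += 1
            else:
                used[hit] = True
                counts[rel.label.value][0] += 1
        for i, (label, _) in enumerate(gold_keys):
            if not used[i]:
                counts[label][2] += 1
    return counts


def _admissible(g, p, mode):
    if g.cls != p.cls:
        return 0
    if mode == "strict":
        return g.n_tokens if (g.token_start, g.token_end) == (p.token_start, p.token_end) else 0
    return max(0, min(g.token_end, p.token_end) - max(g.token_start, p.token_start))


def _hungarian_assignment(gold, pred, mode):
    """Maximum-cardinality (then maximum-overlap) assignment over admissible
    pairs using scipy's Hungarian solver."""
    import numpy as np
    from scipy.optimize import linear_sum_assignment

    if not gold or not pred:
        return []
    big = 10_000.0
    score = np.zeros((len(gold), len(pred)))
    for gi, g in enumerate(gold):
        for pi, p in enumerate(pred):
            ov = _admissible(g, p, mode)
            if ov > 0:
                score[gi, pi] = big + ov
    rows, cols = linear_sum_assignment(score, maximize=True)
    return [(gi, pi) for gi, pi in zip(rows, cols) if score[gi, pi] > 0]


def _best_entity_assignment(gold, pred, mode):
    """Exhaustive search for the matching with maximum cardinality, then
    maximum total overlap.  Exponential; for small notes only."""
    pairs = [
        (gi, pi, _admissible(g, p, mode))
        for gi, g in enumerate(gold)
        for pi, p in enumerate(pred)
        if _admissible(g, p, mode) > 0
    ]

    best = ([], 0, 0)

    def extend(i, chosen, used_g, used_p, total):
        nonlocal best
        if (len(chosen), total) > (len(best[0]), best[2]):
            best = (list(chosen), len(chosen), total)
        if i == len(pairs):
            return
        for j in range(i, len(pairs)):
            gi, pi, ov = pairs[j]
            if gi in used_g or pi in used_p:
                continue
            chosen.append((gi, pi))
            extend(j + 1, chosen, used_g | {gi}, used_p | {pi}, total + ov)
            chosen.pop()

    extend(0, [], set(), set(), 0)
    return best[0]


# --- perturbation utilities -------------------------------------------------


def jitter_tags(tags, rng, rate=0.15):
    """Randomly corrupt a BIO sequence, then repair it to validity."""
    from ademiner.ner import repair_bio
    from ademiner.types import BIO_TAGS

    out = [
        t if rng.random() > rate else BIO_TAGS[int(rng.integers(len(BIO_TAGS)))]
        for t in tags
    ]
    return repair_bio(out)


def perturbed_relation_corpus(notes, seed):
    """Gold (entities, relations) sides plus predictions with span
    truncations, entity drops, label flips and dropped relations."""
    import numpy as np

    from ademiner.types import Entity, RelationClass, RelationInstance

    rng = np.random.default_rng(seed)
    labels = [
        RelationClass.INDICATION,
        RelationClass.ADE,
        RelationClass.ADE_OUTCOME,
        RelationClass.ADE_CAUSE,
    ]
    gold, pred = [], []
    for note in notes:
        gold.append((list(note.entities), list(note.relations)))
        p_ents = []
        for e in note.entities:
            r = rng.random()
            if r < 0.1:
                continue
            start, end = e.token_start, e.token_end
            if end - start > 1 and r < 0.45:
                start = start + 1  # truncate
            p_ents.append(
                Entity(
                    id="P" + e.id,
                    cls=e.cls,
                    token_start=start,
                    token_end=end,
                    note_id=e.note_id,
                )
            )
        kept = {e.id[1:] for e in p_ents}
        p_rels = []
        for rel in note.relations:
            if rel.arg1_id in kept and rel.arg2_id in kept and rng.random() > 0.15:
                label = rel.label if rng.random() > 0.2 else labels[int(rng.integers(4))]
                p_rels.append(
                    RelationInstance(
                        label=label,
                        arg1_id="P" + rel.arg1_id,
                        arg2_id="P" + rel.arg2_id,
                        note_id=rel.note_id,
                    )
                )
        pred.append((p_ents, p_rels))
    return gold, pred


def naive_note_counts(gold_flags, pred_flags):
    counts = {}
    for name, positive in (("ContainingADE", True), ("NoADE", False)):
        tp = fp = fn = 0
        for k in gold_flags:
            if gold_flags[k] == positive and pred_flags[k] == positive:
                tp += 1
            elif pred_flags[k] == positive:
                fp += 1
            elif gold_flags[k] == positive:
                fn += 1
        counts[name] = [tp, fp, fn]
    return counts
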