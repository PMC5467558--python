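"""Shared fixtures: hand-built sentences, documents and parse trees.

Documents are assembled programmatically from token-level sentence specs so
character offsets, parses and mentions stay mutually consistent by
construction.
"""

from __future__ import annotations

import pytest

from cidre.corpus import (
    CHEMICAL,
    DISEASE,
    DependencyTree,
    Document,
    Mention,
    Token,
)

# one token: (form, lemma, pos, head, deprel)
Row = tuple[str, str, str, int, str]


def build_sentences(doc_id, sentence_specs):
    """Assemble (Document text pieces, trees, mentions) from token specs.

    ``sentence_specs``: list of (rows, mention_marks) where mention_marks are
    (first_token, last_token, etype, concept_ids) with 1-based inclusive
    token positions.  Sentence 0 becomes the title.
    """
    offset = 0
    texts = []
    trees = {}
    mentions = []
    for s_idx, (rows, marks) in enumerate(sentence_specs):
        tokens = []
        starts, ends = [], []
        for i, (form, lemma, pos, head, deprel) in enumerate(rows):
            start = offset
            end = start + len(form)
            tokens.append(Token(i + 1, form, lemma, pos, head, deprel, start, end))
            starts.append(start)
            ends.append(end)
            offset = end + 1
        texts.append(" ".join(r[0] for r in rows))
        trees[(doc_id, s_idx)] = DependencyTree(s_idx, tokens)
        for first, last, etype, cids in marks:
            mentions.append((starts[first - 1], ends[last - 1], etype, tuple(cids)))
    return texts, trees, mentions


def make_document(doc_id, sentence_specs, gold=()):
    texts, trees, raw_mentions = build_sentences(doc_id, sentence_specs)
    title, abstract = texts[0], " ".join(texts[1:])
    doc_text = title + " " + abstract
    mentions = [
        Mention(s, e, doc_text[s:e], etype, cids)
        for s, e, etype, cids in raw_mentions
    ]
    doc = Document(doc_id, title, abstract, mentions, set(gold))
    doc.validate()
    return doc, trees


def svo(subject, verb, obj, verb_lemma=None, obj_adj=None):
    """A subject–verb–object sentence with a root verb, nsubj and dobj."""
    rows: list[Row] = [("The", "the", "DT", 2, "det"),
                       (subject, subject, "NN", 3, "nsubj")]
    v = 3
    rows.append((verb, verb_lemma or verb, "VBD", 0, "root"))
    if obj_adj:
        rows.append((obj_adj, obj_adj, "JJ", 5, "amod"))
        rows.append((obj, obj, "NN", v, "dobj"))
        rows.append((".", ".", ".", v, "punct"))
    else:
        rows.append((obj, obj, "NN", v, "dobj"))
        rows.append((".", ".", ".", v, "punct"))
    return rows


@pytest.fixture
def fig_tree():
    """Dependency tree of "The dipyridamole induced his hyperemia."."""
    rows = [
        ("The", "the", "DT", 2, "det"),
        ("dipyridamole", "dipyridamole", "NN", 3, "nsubj"),
        ("induced", "induce", "VBD", 0, "root"),
        ("his", "his", "PRP$", 5, "poss"),
        ("hyperemia", "hyperemia", "NN", 3, "dobj"),
        (".", ".", ".", 3, "punct"),
    ]
    tokens = []
    offset = 0
    for i, (form, lemma, pos, head, deprel) in enumerate(rows):
        tokens.append(
            Token(i + 1, form, lemma, pos, head, deprel, offset, offset + len(form))
        )
        offset += len(form) + 1
    return DependencyTree(0, tokens)


@pytest.fixture
def midazolam_doc():
    """A five-sentence document mirroring the canonical worked example.

    The chemical C1 (D008874, midazolam) co-occurs with disease D1 (D006323)
    in the title (sentence 0) and sentence 3, and only across sentences with
    disease D2 (D012140, mentioned in sentence 2).
    """
    C1, D1, D2 = "D008874", "D006323", "D012140"
    specs = [
        # title (a): intramuscular midazolam caused cardiorespiratory arrest
        (
            [
                ("Intramuscular", "intramuscular", "JJ", 2, "amod"),
                ("midazolam", "midazolam", "NN", 3, "nsubj"),
                ("caused", "cause", "VBD", 0, "root"),
                ("cardiorespiratory", "cardiorespiratory", "JJ", 5, "amod"),
                ("arrest", "arrest", "NN", 3, "dobj"),
                (".", ".", ".", 3, "punct"),
            ],
            [(2, 2, CHEMICAL, [C1]), (4, 5, DISEASE, [D1])],
        ),
        # (b): no mentions
        (
            [
                ("The", "the", "DT", 2, "det"),
                ("sedative", "sedative", "NN", 4, "nsubj"),
                ("is", "be", "VBZ", 4, "cop"),
                ("common", "common", "JJ", 0, "root"),
                (".", ".", ".", 4, "punct"),
            ],
            [],
        ),
        # (c): intravenous administration causes respiratory depression (D2)
        (
            [
                ("Intravenous", "intravenous", "JJ", 2, "amod"),
                ("administration", "administration", "NN", 3, "nsubj"),
                ("causes", "cause", "VBZ", 0, "root"),
                ("respiratory", "respiratory", "JJ", 5, "amod"),
                ("depression", "depression", "NN", 3, "dobj"),
                (".", ".", ".", 3, "punct"),
            ],
            [(4, 5, DISEASE, [D2])],
        ),
        # (d): midazolam produced arrest again (C1 with D1)
        (
            [
                ("The", "the", "DT", 2, "det"),
                ("midazolam", "midazolam", "NN", 3, "nsubj"),
                ("produced", "produce", "VBD", 0, "root"),
                ("cardiorespiratory", "cardiorespiratory", "JJ", 5, "amod"),
                ("arrest", "arrest", "NN", 3, "dobj"),
                (".", ".", ".", 3, "punct"),
            ],
            [(2, 2, CHEMICAL, [C1]), (4, 5, DISEASE, [D1])],
        ),
        # (e): review sentence, no mentions
        (
            [
                ("Safe", "safe", "JJ", 2, "amod"),
                ("use", "use", "NN", 4, "nsubj"),
                ("is", "be", "VBZ", 4, "cop"),
                ("reviewed", "review", "VBN", 0, "root"),
                (".", ".", ".", 4, "punct"),
            ],
            [],
        ),
    ]
    doc, trees = make_document("2375138", specs, gold={(C1, D1)})
    return doc, trees
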