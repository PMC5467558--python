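"""Seeded synthetic CID corpora with a planted, learnable relation signal.

Documents are built from subject–verb–object sentence templates with
hand-constructed dependency trees (root verb, ``nsubj`` to the chemical,
``dobj`` to the disease), mirroring the canonical example sentence
"The dipyridamole induced his hyperemia."  A chemical–disease concept pair is
gold-positive iff a trigger verb links its mentions within a sentence, or a
two-sentence drug-anaphora template spans sentences ("The physician
administered X ." / "This drug provoked Y .").  Template geometry guarantees
every intra-sentence pair has a chemical-to-disease dependency path of at
most 9 tokens, so the default path window sees the whole path.

Generated corpora emit exactly the formats the corpus readers consume
(PubTator, 8-column parse blocks, MeSH tree TSV), so fixtures and real data
are interchangeable.  Generation is a pure function of the configuration:
the same config yields a byte-identical corpus.

Density choices emulate the real task: a handful of chemicals (3–6) and
diseases (2–5) per abstract, about two gold relations per document (every
document carries at least one — the real corpus is curated from a relation
database), rare inter-sentence positives, and a tree-numbered toy ontology in
which some mentioned chemicals are hypernyms of chemicals in gold relations.
``noise_rate`` emulates annotation disagreement: each planted positive is
dropped with that probability and negatives are flipped in at a matched
expected count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .corpus import (
    CHEMICAL,
    DISEASE,
    DependencyTree,
    Document,
    Mention,
    MeshOntology,
    Token,
)
from .features import Vocabulary

# ---------------------------------------------------------------------------
# Lexicons (deterministic order matters for reproducibility)

_CHEM_SYLL_A = ("dipy", "meto", "carbo", "fluo", "oxa", "pheno", "rito", "sulfa")
_CHEM_SYLL_B = ("zolam", "pril", "mide", "caine", "statin", "mycin", "navir", "ridine")
_DIS_SYLL_A = ("cardio", "hepato", "neuro", "nephro", "dermo", "hemo", "osteo", "arthro")
_DIS_SYLL_B = ("pathy", "itis", "osis", "emia", "algia", "trophy", "plasia", "sclerosis")

TRIGGER_VERBS = (("induced", "induce"), ("caused", "cause"),
                 ("produced", "produce"), ("triggered", "trigger"))
NONTRIGGER_VERBS = (("accompanied", "accompany"), ("preceded", "precede"),
                    ("followed", "follow"))
_ADJECTIVES = ("acute", "severe", "mild", "chronic", "transient")
_ADVERBS = ("rapidly", "subsequently", "occasionally")


@dataclass
class SynthConfig:
    """Generator settings; every corpus is a pure function of this object."""

    n_docs: int = 100
    sentences_per_doc: tuple[int, int] = (4, 10)
    chem_pool: int = 24  # concepts, including hypernym ancestors
    dis_pool: int = 24
    trigger_lexicon: tuple[tuple[str, str], ...] = TRIGGER_VERBS
    intra_positive_rate: float = 0.4  # extra intra positives ~ 1 + Bin(2, rate)
    inter_positive_rate: float = 0.25  # P(document carries one inter positive)
    hypernym_rate: float = 0.3  # P(hypernym-distractor sentence)
    hierarchy_depth: int = 3  # tree-number segments of leaf concepts
    noise_rate: float = 0.05
    vocab_size: int = 0  # 0 = unbounded; else caps the name pools
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.intra_positive_rate, self.inter_positive_rate,
                  self.hypernym_rate, self.noise_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must be in [0, 1]")
        if self.hierarchy_depth < 2:
            raise ValueError("hierarchy_depth must be >= 2")
        if self.n_docs > 0 and (self.chem_pool < 8 or self.dis_pool < 7):
            raise ValueError(
                "concept pools too small to host hierarchy plus per-document draws"
            )


@dataclass
class _Concept:
    cid: str
    name: str
    tree_numbers: tuple[str, ...]
    is_leaf: bool
    ancestor: str | None = None  # concept id of the direct hypernym (leaves)


def _make_concepts(
    pool: int, syll_a: Sequence[str], syll_b: Sequence[str],
    id_base: int, tree_root: str, depth: int, vocab_cap: int,
) -> list[_Concept]:
    names = [a + b for a in syll_a for b in syll_b]
    if vocab_cap:
        names = names[: max(pool, vocab_cap)]
    if pool > len(names):
        raise ValueError(f"concept pool {pool} exceeds the name pool {len(names)}")
    n_general = max(2, pool // 4)
    concepts: list[_Concept] = []
    for g in range(n_general):
        concepts.append(
            _Concept(
                cid=f"D{id_base + g}",
                name=names[g],
                tree_numbers=(f"{tree_root}.{100 + g}",),
                is_leaf=False,
            )
        )
    for j in range(pool - n_general):
        g = j % n_general
        extra = ".".join(str(500 + j + 7 * k) for k in range(depth - 2))
        concepts.append(
            _Concept(
                cid=f"D{id_base + n_general + j}",
                name=names[n_general + j],
                tree_numbers=(f"{tree_root}.{100 + g}.{extra}",),
                is_leaf=True,
                ancestor=f"D{id_base + g}",
            )
        )
    return concepts


def build_ontology(config: SynthConfig) -> tuple[list[_Concept], list[_Concept], MeshOntology]:
    chems = _make_concepts(
        config.chem_pool, _CHEM_SYLL_A, _CHEM_SYLL_B,
        1000, "D02", config.hierarchy_depth, config.vocab_size,
    )
    diss = _make_concepts(
        config.dis_pool, _DIS_SYLL_A, _DIS_SYLL_B,
        2000, "C14", config.hierarchy_depth, config.vocab_size,
    )
    numbers = {c.cid: set(c.tree_numbers) for c in chems + diss}
    return chems, diss, MeshOntology(numbers)


# ---------------------------------------------------------------------------
# Sentence templates: (form, lemma, pos, head, deprel) rows plus mention marks


class _SentenceDraft:
    def __init__(self, rows, mentions):
        # rows: list of (form, lemma, pos, head, deprel)
        # mentions: list of (first_tok, last_tok, etype, concept_id) 1-based inclusive
        self.rows = rows
        self.mentions = mentions

    @property
    def text(self) -> str:
        return " ".join(r[0] for r in self.rows)

    @property
    def root_form(self) -> str:
        return next(r[0] for r in self.rows if r[3] == 0)


def _intra_sentence(chem, dis, verb, adj, adv=None, compound=False) -> _SentenceDraft:
    vf, vl = verb
    if adv is None and not compound:
        rows = [
            ("The", "the", "DT", 2, "det"),
            (chem.name, chem.name, "NN", 3, "nsubj"),
            (vf, vl, "VBD", 0, "root"),
            (adj, adj, "JJ", 5, "amod"),
            (dis.name, dis.name, "NN", 3, "dobj"),
            (".", ".", ".", 3, "punct"),
        ]
        mentions = [(2, 2, CHEMICAL, chem.cid), (5, 5, DISEASE, dis.cid)]
    elif compound:
        rows = [
            ("The", "the", "DT", 2, "det"),
            (chem.name, chem.name, "NN", 3, "nsubj"),
            (vf, vl, "VBD", 0, "root"),
            (adj, adj, "JJ", 6, "amod"),
            (dis.name, dis.name, "NN", 6, "compound"),
            ("syndrome", "syndrome", "NN", 3, "dobj"),
            (".", ".", ".", 3, "punct"),
        ]
        mentions = [(2, 2, CHEMICAL, chem.cid), (5, 6, DISEASE, dis.cid)]
    else:
        rows = [
            ("The", "the", "DT", 2, "det"),
            (chem.name, chem.name, "NN", 4, "nsubj"),
            (adv, adv, "RB", 4, "advmod"),
            (vf, vl, "VBD", 0, "root"),
            (adj, adj, "JJ", 6, "amod"),
            (dis.name, dis.name, "NN", 4, "dobj"),
            (".", ".", ".", 4, "punct"),
        ]
        mentions = [(2, 2, CHEMICAL, chem.cid), (6, 6, DISEASE, dis.cid)]
    return _SentenceDraft(rows, mentions)


def _admin_sentence(chem) -> _SentenceDraft:
    rows = [
        ("The", "the", "DT", 2, "det"),
        ("physician", "physician", "NN", 3, "nsubj"),
        ("administered", "administer", "VBD", 0, "root"),
        (chem.name, chem.name, "NN", 3, "dobj"),
        ("to", "to", "IN", 7, "case"),
        ("the", "the", "DT", 7, "det"),
        ("patient", "patient", "NN", 3, "nmod"),
        (".", ".", ".", 3, "punct"),
    ]
    return _SentenceDraft(rows, [(4, 4, CHEMICAL, chem.cid)])


def _tolerate_sentence(chem) -> _SentenceDraft:
    rows = [
        ("The", "the", "DT", 2, "det"),
        ("patient", "patient", "NN", 3, "nsubj"),
        ("tolerated", "tolerate", "VBD", 0, "root"),
        (chem.name, chem.name, "NN", 3, "dobj"),
        ("well", "well", "RB", 3, "advmod"),
        (".", ".", ".", 3, "punct"),
    ]
    return _SentenceDraft(rows, [(4, 4, CHEMICAL, chem.cid)])


def _provoke_sentence(dis, adj) -> _SentenceDraft:
    rows = [
        ("This", "this", "DT", 2, "det"),
        ("drug", "drug", "NN", 3, "nsubj"),
        ("provoked", "provoke", "VBD", 0, "root"),
        (adj, adj, "JJ", 5, "amod"),
        (dis.name, dis.name, "NN", 3, "dobj"),
        (".", ".", ".", 3, "punct"),
    ]
    return _SentenceDraft(rows, [(5, 5, DISEASE, dis.cid)])


def _noted_sentence(dis, adj) -> _SentenceDraft:
    rows = [
        ("The", "the", "DT", 2, "det"),
        ("chart", "chart", "NN", 3, "nsubj"),
        ("noted", "note", "VBD", 0, "root"),
        (adj, adj, "JJ", 5, "amod"),
        (dis.name, dis.name, "NN", 3, "dobj"),
        ("previously", "previously", "RB", 3, "advmod"),
        (".", ".", ".", 3, "punct"),
    ]
    return _SentenceDraft(rows, [(5, 5, DISEASE, dis.cid)])


def _filler_sentence() -> _SentenceDraft:
    rows = [
        ("The", "the", "DT", 3, "det"),
        ("medical", "medical", "JJ", 3, "amod"),
        ("team", "team", "NN", 4, "nsubj"),
        ("reviewed", "review", "VBD", 0, "root"),
        ("the", "the", "DT", 7, "det"),
        ("complete", "complete", "JJ", 7, "amod"),
        ("record", "record", "NN", 4, "dobj"),
        (".", ".", ".", 4, "punct"),
    ]
    return _SentenceDraft(rows, [])


def _title_with_chem(chem) -> _SentenceDraft:
    rows = [
        ("Adverse", "adverse", "JJ", 2, "amod"),
        ("events", "event", "NNS", 0, "root"),
        ("of", "of", "IN", 4, "case"),
        (chem.name, chem.name, "NN", 2, "nmod"),
        ("in", "in", "IN", 7, "case"),
        ("clinical", "clinical", "JJ", 7, "amod"),
        ("practice", "practice", "NN", 2, "nmod"),
        (".", ".", ".", 2, "punct"),
    ]
    return _SentenceDraft(rows, [(4, 4, CHEMICAL, chem.cid)])


def _title_plain() -> _SentenceDraft:
    rows = [
        ("Observations", "observation", "NNS", 0, "root"),
        ("from", "from", "IN", 4, "case"),
        ("the", "the", "DT", 4, "det"),
        ("registry", "registry", "NN", 1, "nmod"),
        (".", ".", ".", 1, "punct"),
    ]
    return _SentenceDraft(rows, [])


# ---------------------------------------------------------------------------
# Corpus generation


def generate_corpus(
    config: SynthConfig,
) -> tuple[list[Document], dict[tuple[str, int], DependencyTree], MeshOntology]:
    """Generate documents, their parses and the toy ontology.

    Raises on infeasible configurations (pools too small for the requested
    rates).  Offsets, mention texts, gold relations and parses are mutually
    consistent and pass all corpus-reader invariants.
    """
    rng = np.random.default_rng(config.seed)
    # separate stream: document structure is invariant to the noise setting
    noise_rng = np.random.default_rng((config.seed, 7919))
    chems, diss, ontology = build_ontology(config)
    chem_leaves = [c for c in chems if c.is_leaf]
    dis_leaves = [d for d in diss if d.is_leaf]
    chem_by_id = {c.cid: c for c in chems}
    if (config.intra_positive_rate > 0 or config.inter_positive_rate > 0) and (
        not chem_leaves or not dis_leaves
    ):
        raise ValueError("positive rates require non-empty leaf concept pools")

    docs: list[Document] = []
    trees: dict[tuple[str, int], DependencyTree] = {}
    for d in range(config.n_docs):
        doc_id = str(9000000 + d)
        doc, doc_trees = _generate_document(
            doc_id, config, rng, noise_rng, chem_leaves, dis_leaves, chem_by_id
        )
        docs.append(doc)
        trees.update(doc_trees)
    return docs, trees, ontology


def _generate_document(doc_id, config, rng, noise_rng, chem_leaves, dis_leaves,
                       chem_by_id):
    n_chem = int(rng.integers(3, min(7, len(chem_leaves) + 1)))
    n_dis = int(rng.integers(2, min(6, len(dis_leaves) + 1)))
    chem_idx = rng.choice(len(chem_leaves), size=n_chem, replace=False)
    dis_idx = rng.choice(len(dis_leaves), size=n_dis, replace=False)
    doc_chems = [chem_leaves[i] for i in chem_idx]
    doc_diss = [dis_leaves[i] for i in dis_idx]

    want_inter = rng.random() < config.inter_positive_rate
    # the inter-positive pair uses concepts mentioned nowhere else in the doc
    inter_chem = doc_chems[-1] if want_inter else None
    inter_dis = doc_diss[-1] if want_inter else None
    free_chems = doc_chems[:-1] if want_inter else doc_chems
    free_diss = doc_diss[:-1] if want_inter else doc_diss

    pairs = [(c, e) for c in free_chems for e in free_diss]
    order = rng.permutation(len(pairs))
    pairs = [pairs[i] for i in order]

    n_intra_pos = 1 + int(rng.binomial(2, config.intra_positive_rate))
    n_intra_neg = int(rng.integers(1, 3))
    n_inter_neg = int(rng.integers(0, 2))

    blocks: list[list[_SentenceDraft]] = []
    gold: set[tuple[str, str]] = set()
    pos_chems: list = []

    def draw_pair():
        # distinct concept pairs only; constructs are skipped once exhausted
        return pairs.pop() if pairs else None

    for _ in range(n_intra_pos):
        drawn = draw_pair()
        if drawn is None:
            break
        chem, dis = drawn
        verb = config.trigger_lexicon[int(rng.integers(len(config.trigger_lexicon)))]
        draft = _intra_sentence(
            chem, dis, verb,
            _ADJECTIVES[int(rng.integers(len(_ADJECTIVES)))],
            adv=_ADVERBS[int(rng.integers(len(_ADVERBS)))]
            if rng.random() < 0.3 else None,
            compound=rng.random() < 0.25,
        )
        blocks.append([draft])
        gold.add((chem.cid, dis.cid))
        pos_chems.append(chem)

    for _ in range(n_intra_neg):
        drawn = draw_pair()
        if drawn is None:
            break
        chem, dis = drawn
        verb = NONTRIGGER_VERBS[int(rng.integers(len(NONTRIGGER_VERBS)))]
        blocks.append([
            _intra_sentence(
                chem, dis, verb,
                _ADJECTIVES[int(rng.integers(len(_ADJECTIVES)))],
                compound=rng.random() < 0.25,
            )
        ])

    if want_inter:
        blocks.append([
            _admin_sentence(inter_chem),
            _provoke_sentence(
                inter_dis, _ADJECTIVES[int(rng.integers(len(_ADJECTIVES)))]
            ),
        ])
        gold.add((inter_chem.cid, inter_dis.cid))

    for _ in range(n_inter_neg):
        drawn = draw_pair()
        if drawn is None:
            break
        chem, dis = drawn
        blocks.append([
            _tolerate_sentence(chem),
            _noted_sentence(dis, _ADJECTIVES[int(rng.integers(len(_ADJECTIVES)))]),
        ])

    if pos_chems and rng.random() < config.hypernym_rate:
        general = chem_by_id[pos_chems[0].ancestor]
        dis = free_diss[int(rng.integers(len(free_diss)))]
        verb = NONTRIGGER_VERBS[int(rng.integers(len(NONTRIGGER_VERBS)))]
        blocks.append([
            _intra_sentence(
                general, dis, verb,
                _ADJECTIVES[int(rng.integers(len(_ADJECTIVES)))],
            )
        ])

    # pad with filler sentences up to the minimum abstract length
    lo, _hi = config.sentences_per_doc
    while sum(len(b) for b in blocks) < lo:
        blocks.append([_filler_sentence()])

    block_order = rng.permutation(len(blocks))
    sentence_drafts: list[_SentenceDraft] = []
    title_chem = free_chems[0] if rng.random() < 0.7 else None
    title = _title_with_chem(title_chem) if title_chem is not None else _title_plain()
    sentence_drafts.append(title)
    for b in block_order:
        sentence_drafts.extend(blocks[b])

    # annotation noise: drop planted positives, flip in matched negatives.
    # Flip-in candidates are restricted to leaf concepts actually mentioned,
    # so noisy gold stays supported by mentions of the matching type.
    if config.noise_rate > 0:
        leaf_ids = {c.cid for c in doc_chems} | {e.cid for e in doc_diss}
        mentioned_chems: set[str] = set()
        mentioned_diss: set[str] = set()
        for draft in sentence_drafts:
            for _f, _l, etype, cid in draft.mentions:
                if cid not in leaf_ids:
                    continue
                (mentioned_chems if etype == CHEMICAL else mentioned_diss).add(cid)
        doc_pairs = {(c, e) for c in mentioned_chems for e in mentioned_diss}
        negatives = sorted(doc_pairs - gold)
        n_pos = len(gold)
        for pair in sorted(gold):
            if noise_rng.random() < config.noise_rate:
                gold.discard(pair)
        if negatives and n_pos:
            p_in = min(1.0, config.noise_rate * n_pos / len(negatives))
            for pair in negatives:
                if noise_rng.random() < p_in:
                    gold.add(pair)

    return _assemble(doc_id, sentence_drafts, gold)


def _assemble(doc_id, drafts: list[_SentenceDraft], gold):
    texts = [d.text for d in drafts]
    title = texts[0]
    abstract = " ".join(texts[1:])
    doc_text = title + " " + abstract

    mentions: list[Mention] = []
    trees: dict[tuple[str, int], DependencyTree] = {}
    offset = 0
    for s_idx, draft in enumerate(drafts):
        tokens = []
        pos_cursor = offset
        starts, ends = [], []
        for i, (form, lemma, pos, head, deprel) in enumerate(draft.rows):
            start = pos_cursor
            end = start + len(form)
            tokens.append(Token(i + 1, form, lemma, pos, head, deprel, start, end))
            starts.append(start)
            ends.append(end)
            pos_cursor = end + 1  # single space between tokens
        for first, last, etype, cid in draft.mentions:
            m_start = starts[first - 1]
            m_end = ends[last - 1]
            mentions.append(
                Mention(m_start, m_end, doc_text[m_start:m_end], etype, (cid,))
            )
        trees[(doc_id, s_idx)] = DependencyTree(s_idx, tokens)
        offset = pos_cursor  # sentences joined by a single space

    doc = Document(doc_id, title, abstract, mentions, set(gold))
    doc.mentions.sort(key=lambda m: (m.start, m.end))
    doc.validate()
    return doc, trees


# ---------------------------------------------------------------------------
# Reference labeler and embeddings


def rule_based_reference(
    doc: Document, trees: dict[tuple[str, int], DependencyTree],
    trigger_forms: Iterable[str] = tuple(f for f, _ in TRIGGER_VERBS),
) -> set[tuple[str, str]]:
    """Oracle labeler reading the planted signal directly off the templates.

    A pair is positive iff a trigger root verb links its mentions in one
    sentence, or an 'administered'/'provoked' two-sentence anaphora spans
    them.  At noise_rate=0 this recovers the gold annotation exactly.
    """
    from .corpus import split_sentences

    triggers = set(trigger_forms)
    views = split_sentences(doc, trees)
    out: set[tuple[str, str]] = set()
    for v in views:
        root = v.tree.root.form
        chems = [m for m in v.mentions if m.etype == CHEMICAL]
        diss = [m for m in v.mentions if m.etype == DISEASE]
        if root in triggers:
            for cm in chems:
                for dm in diss:
                    for cid in cm.normalized_ids:
                        for did in dm.normalized_ids:
                            out.add((cid, did))
    for i in range(len(views) - 1):
        if views[i].tree.root.form == "administered" and \
                views[i + 1].tree.root.form == "provoked":
            for cm in views[i].mentions:
                if cm.etype != CHEMICAL:
                    continue
                for dm in views[i + 1].mentions:
                    if dm.etype != DISEASE:
                        continue
                    for cid in cm.normalized_ids:
                        for did in dm.normalized_ids:
                            out.add((cid, did))
    return out


def generate_embeddings(
    vocab: Vocabulary, d0: int, seed: int
) -> np.ndarray:
    """Uniform(-0.05, 0.05) embedding table; the ``<PAD>`` column is zero."""
    rng = np.random.default_rng(seed)
    T = rng.uniform(-0.05, 0.05, size=(d0, len(vocab)))
    T[:, vocab.pad_id] = 0.0
    return T
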