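"""Corpus I/O: PubTator documents, dependency parses, MeSH tree numbers, word vectors.

The PubTator dialect handled here is the line-oriented format the BioCreative
CDR corpus ships in: per document a ``PMID|t|TITLE`` line, a ``PMID|a|ABSTRACT``
line, then tab-separated mention rows ``PMID  start  end  text  type  conceptID``
and relation rows ``PMID  CID  chemID  disID``, with a blank line between
documents.  Document text is the title, a single space, and the abstract;
mention offsets are 0-based half-open over that concatenation.

Dependency parses are consumed, never produced: each sentence is a block headed
by ``#doc_id<TAB>sentence_index`` followed by one 8-column token row
(index, form, lemma, pos, head, deprel, char_start, char_end).  Head links must
form a single rooted tree.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

import networkx as nx

logger = logging.getLogger(__name__)

CHEMICAL = "Chemical"
DISEASE = "Disease"
ENTITY_TYPES = frozenset({CHEMICAL, DISEASE})

#: concept-identifier marker for mentions the annotator could not normalize
UNNORMALIZED = "-1"


class CorpusError(ValueError):
    """Malformed corpus input (offsets, entity types, head links, ...)."""


def _warn(message: str, strict: bool) -> None:
    if strict:
        raise CorpusError(message)
    logger.warning(message)


@dataclass(frozen=True)
class Mention:
    """An entity mention: a character span of the document text.

    ``concept_ids`` is an ordered tuple because composite annotations
    (``D012140|D003643``) carry several identifiers on one span.
    """

    start: int
    end: int
    text: str
    etype: str
    concept_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.etype not in ENTITY_TYPES:
            raise CorpusError(f"unknown entity type {self.etype!r}")
        if not (0 <= self.start < self.end):
            raise CorpusError(f"bad mention span [{self.start}, {self.end})")

    @property
    def normalized_ids(self) -> tuple[str, ...]:
        """Concept IDs usable for concept-level relations (drops ``-1``)."""
        return tuple(c for c in self.concept_ids if c != UNNORMALIZED)


@dataclass
class Document:
    """A title+abstract article with mention and concept-pair annotations."""

    doc_id: str
    title: str
    abstract: str
    mentions: list[Mention] = field(default_factory=list)
    gold_relations: set[tuple[str, str]] = field(default_factory=set)

    @property
    def text(self) -> str:
        return self.title + " " + self.abstract

    def validate(self, strict: bool = False) -> None:
        text = self.text
        boundary = len(self.title)
        for m in self.mentions:
            if m.end > len(text):
                raise CorpusError(
                    f"{self.doc_id}: mention [{m.start},{m.end}) beyond text"
                )
            if text[m.start : m.end] != m.text:
                raise CorpusError(
                    f"{self.doc_id}: mention text {m.text!r} != slice "
                    f"{text[m.start:m.end]!r} at [{m.start},{m.end})"
                )
            if m.start < boundary < m.end:
                raise CorpusError(
                    f"{self.doc_id}: mention [{m.start},{m.end}) crosses the "
                    "title/abstract boundary"
                )
        ids_by_type: dict[str, set[str]] = {CHEMICAL: set(), DISEASE: set()}
        for m in self.mentions:
            ids_by_type[m.etype].update(m.normalized_ids)
        for chem, dis in self.gold_relations:
            if chem not in ids_by_type[CHEMICAL] or dis not in ids_by_type[DISEASE]:
                _warn(
                    f"{self.doc_id}: gold relation ({chem}, {dis}) has no "
                    "supporting mention of the matching type",
                    strict=False if not strict else strict,
                )

    def concept_ids(self, etype: str) -> set[str]:
        return {c for m in self.mentions if m.etype == etype for c in m.normalized_ids}


@dataclass(frozen=True)
class Token:
    index: int  # 1-based within the sentence
    form: str
    lemma: str
    pos: str
    head: int  # 0 = synthetic ROOT
    deprel: str
    char_start: int
    char_end: int

    @property
    def is_verb(self) -> bool:
        return self.pos.startswith("VB")


@dataclass
class DependencyTree:
    sentence_index: int
    tokens: list[Token]

    def __post_init__(self) -> None:
        self._check_tree()

    def _check_tree(self) -> None:
        n = len(self.tokens)
        roots = [t for t in self.tokens if t.head == 0]
        where = f"sentence {self.sentence_index}"
        if len(roots) != 1:
            raise CorpusError(f"{where}: expected exactly one root, got {len(roots)}")
        g = nx.DiGraph()
        g.add_nodes_from(range(n + 1))
        for t in self.tokens:
            if not (0 <= t.head <= n):
                raise CorpusError(f"{where}: head {t.head} out of range")
            g.add_edge(t.head, t.index)
        if not nx.is_arborescence(g):
            raise CorpusError(f"{where}: head links do not form a rooted tree")

    @property
    def root(self) -> Token:
        return next(t for t in self.tokens if t.head == 0)

    def token(self, index: int) -> Token:
        return self.tokens[index - 1]

    @property
    def char_span(self) -> tuple[int, int]:
        return (
            min(t.char_start for t in self.tokens),
            max(t.char_end for t in self.tokens),
        )


_TREE_NUMBER = re.compile(r"^[A-Za-z0-9]+(\.[A-Za-z0-9]+)*$")


@dataclass
class MeshOntology:
    """Concept ID -> set of MeSH tree numbers; total over any queried ID."""

    tree_numbers: dict[str, set[str]] = field(default_factory=dict)

    def numbers(self, concept_id: str) -> set[str]:
        return self.tree_numbers.get(concept_id, set())


@dataclass
class SentenceView:
    """A sentence of a document: its char span, parse and contained mentions."""

    index: int  # position within the document's ordered sentence list
    start: int
    end: int
    tree: DependencyTree
    mentions: list[Mention] = field(default_factory=list)

    def mention_token_indices(self, mention: Mention) -> list[int]:
        """1-based indices of tokens overlapping the mention span."""
        return [
            t.index
            for t in self.tree.tokens
            if t.char_start < mention.end and t.char_end > mention.start
        ]


# ---------------------------------------------------------------------------
# PubTator reading / writing


def read_pubtator(stream: Iterable[str], strict: bool = False) -> list[Document]:
    """Parse PubTator-format text into documents.

    Mention offsets are validated against the reconstructed document text
    (title + one space + abstract); a mismatch is an error naming the document
    and span.  Composite concept IDs are split on ``|``.
    """
    docs: list[Document] = []
    for block in _blocks(stream):
        docs.append(_parse_block(block, strict=strict))
    return docs


def _blocks(stream: Iterable[str]) -> Iterator[list[str]]:
    block: list[str] = []
    for raw in stream:
        line = raw.rstrip("\n")
        if line.strip() == "":
            if block:
                yield block
                block = []
        else:
            block.append(line)
    if block:
        yield block


def _parse_block(lines: list[str], strict: bool) -> Document:
    title = abstract = None
    doc_id = None
    mentions: list[Mention] = []
    relations: set[tuple[str, str]] = set()
    for line in lines:
        m = re.match(r"^([^|\t]+)\|t\|(.*)$", line)
        if m:
            doc_id, title = m.group(1), m.group(2)
            continue
        m = re.match(r"^([^|\t]+)\|a\|(.*)$", line)
        if m:
            abstract = m.group(2)
            continue
        fields = line.split("\t")
        if len(fields) >= 2 and fields[1] == "CID":
            if len(fields) != 4:
                raise CorpusError(f"malformed relation row: {line!r}")
            relations.add((fields[2], fields[3]))
        elif len(fields) >= 6:
            pmid, start, end, text, etype = fields[:5]
            concept = fields[5]
            if etype not in ENTITY_TYPES:
                raise CorpusError(f"{pmid}: unknown entity type {etype!r} in {line!r}")
            ids = tuple(dict.fromkeys(concept.split("|")))
            if UNNORMALIZED in ids:
                logger.info("%s: unnormalized mention %r", pmid, text)
            mentions.append(Mention(int(start), int(end), text, etype, ids))
        else:
            raise CorpusError(f"unrecognized PubTator line: {line!r}")
    if doc_id is None or title is None or abstract is None:
        raise CorpusError("document block missing title or abstract line")
    doc = Document(doc_id, title, abstract, mentions, relations)
    doc.mentions.sort(key=lambda m: (m.start, m.end))
    doc.validate(strict=strict)
    return doc


def write_pubtator(docs: Sequence[Document], stream: TextIO) -> None:
    """Inverse of :func:`read_pubtator` (field-for-field round trip)."""
    for doc in docs:
        stream.write(f"{doc.doc_id}|t|{doc.title}\n")
        stream.write(f"{doc.doc_id}|a|{doc.abstract}\n")
        for m in sorted(doc.mentions, key=lambda m: (m.start, m.end)):
            cid = "|".join(m.concept_ids)
            stream.write(
                f"{doc.doc_id}\t{m.start}\t{m.end}\t{m.text}\t{m.etype}\t{cid}\n"
            )
        for chem, dis in sorted(doc.gold_relations):
            stream.write(f"{doc.doc_id}\tCID\t{chem}\t{dis}\n")
        stream.write("\n")


# ---------------------------------------------------------------------------
# Dependency parses


def read_parses(stream: Iterable[str]) -> dict[tuple[str, int], DependencyTree]:
    """Read 8-column parse blocks into a ``(doc_id, sentence_index) -> tree`` map."""
    trees: dict[tuple[str, int], DependencyTree] = {}
    header: tuple[str, int] | None = None
    rows: list[Token] = []

    def flush() -> None:
        nonlocal rows, header
        if header is not None and rows:
            trees[header] = DependencyTree(header[1], rows)
        rows = []

    for raw in stream:
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            flush()
            fields = line[1:].split("\t")
            if len(fields) != 2:
                raise CorpusError(f"malformed parse header: {line!r}")
            header = (fields[0], int(fields[1]))
            continue
        if header is None:
            raise CorpusError("token row before any sentence header")
        f = line.split("\t")
        if len(f) != 8:
            raise CorpusError(f"expected 8 columns, got {len(f)}: {line!r}")
        rows.append(
            Token(int(f[0]), f[1], f[2], f[3], int(f[4]), f[5], int(f[6]), int(f[7]))
        )
    flush()
    return trees


def write_parses(
    trees: Mapping[tuple[str, int], DependencyTree], stream: TextIO
) -> None:
    for (doc_id, sent_idx), tree in trees.items():
        stream.write(f"#{doc_id}\t{sent_idx}\n")
        for t in tree.tokens:
            stream.write(
                f"{t.index}\t{t.form}\t{t.lemma}\t{t.pos}\t{t.head}\t{t.deprel}"
                f"\t{t.char_start}\t{t.char_end}\n"
            )
        stream.write("\n")


def split_sentences(
    doc: Document, trees: Mapping[tuple[str, int], DependencyTree]
) -> list[SentenceView]:
    """Assign each mention to the sentence containing its start offset.

    Sentence extent is defined by the parse file (min/max token offsets);
    a mention whose end crosses the sentence boundary is assigned to the
    sentence containing its start, with a warning.
    """
    doc_trees = sorted(
        (tree for (d, _), tree in trees.items() if d == doc.doc_id),
        key=lambda t: t.char_span[0],
    )
    views = []
    for i, tree in enumerate(doc_trees):
        s, e = tree.char_span
        views.append(SentenceView(index=i, start=s, end=e, tree=tree))
    for m in doc.mentions:
        # the sentence containing the mention start: last view starting at/before it
        host = None
        for v in views:
            if v.start <= m.start:
                host = v
        if host is None:
            _warn(f"{doc.doc_id}: mention {m.text!r} precedes every sentence", False)
            continue
        if m.end > host.end:
            logger.warning(
                "%s: mention %r straddles a sentence boundary; assigned to "
                "sentence %d",
                doc.doc_id,
                m.text,
                host.index,
            )
        host.mentions.append(m)
    return views


# ---------------------------------------------------------------------------
# MeSH tree numbers and word vectors


def read_mesh_tree(stream: Iterable[str]) -> MeshOntology:
    """Read TSV rows ``conceptID<TAB>treeNumber``, aggregating per concept."""
    numbers: dict[str, set[str]] = {}
    for raw in stream:
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise CorpusError(f"malformed MeSH tree row: {line!r}")
        concept, number = fields
        if not _TREE_NUMBER.match(number):
            raise CorpusError(f"malformed tree number {number!r} for {concept}")
        numbers.setdefault(concept, set()).add(number)
    return MeshOntology(numbers)


def write_mesh_tree(ontology: MeshOntology, stream: TextIO) -> None:
    for concept in sorted(ontology.tree_numbers):
        for number in sorted(ontology.tree_numbers[concept]):
            stream.write(f"{concept}\t{number}\n")


def read_word_vectors(
    stream: Iterable[str], vocab_filter: set[str] | None = None
) -> dict[str, list[float]]:
    """Read whitespace-format word vectors, keeping only ``vocab_filter`` tokens.

    All vectors must share one dimension; a deviating line is an error.
    """
    vectors: dict[str, list[float]] = {}
    dim: int | None = None
    for raw in stream:
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split(" ")
        token, values = parts[0], [float(x) for x in parts[1:]]
        if dim is None:
            dim = len(values)
        elif len(values) != dim:
            raise CorpusError(
                f"inconsistent vector dimension for {token!r}: "
                f"{len(values)} != {dim}"
            )
        if vocab_filter is None or token in vocab_filter:
            vectors[token] = values
    return vectors
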