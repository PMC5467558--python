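"""Relation-instance construction and MeSH hypernymy filtering.

A relation instance is one (chemical mention, disease mention) pair together
with one concept identifier from each mention.  Pairs co-occurring in a
sentence form *intra*-sentence instances; concept pairs that never co-occur in
any sentence of the document form *inter*-sentence instances, one per
cross-sentence mention pair within a sentence-distance window (nearest pair as
fallback).  Labels are assigned distantly from the document-level gold
concept-pair annotations.

Hypernymy between concepts is decided on MeSH tree numbers: ``a`` is a
hypernym of ``b`` iff some tree number of ``a`` is a proper, segment-aligned
prefix of some tree number of ``b``.  During training, negative instances
whose chemical (disease) is a hypernym of a chemical (disease) already in a
positive relation of the same document are removed; at test time the same rule
prunes predicted document-level pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product
from typing import Iterable, Sequence, TextIO

from .corpus import (
    CHEMICAL,
    DISEASE,
    Document,
    Mention,
    MeshOntology,
    SentenceView,
)

INTRA = "intra"
INTER = "inter"

POSITIVE = 1
NEGATIVE = 0


@dataclass(frozen=True)
class RelationInstance:
    doc_id: str
    chem_mention: Mention
    dis_mention: Mention
    chem_id: str
    dis_id: str
    level: str  # INTRA or INTER
    sentence_index: int | None = None  # intra
    sentence_index_pair: tuple[int, int] | None = None  # inter (chem, dis)
    label: int | None = None

    @property
    def pair(self) -> tuple[str, str]:
        return (self.chem_id, self.dis_id)

    @property
    def sentence_distance(self) -> int:
        if self.level == INTRA:
            return 0
        si, sj = self.sentence_index_pair
        return abs(si - sj)


def build_instances(
    doc: Document,
    sentences: Sequence[SentenceView],
    inter_window: int = 3,
    inter_all_pairs: bool = False,
) -> tuple[list[RelationInstance], list[RelationInstance]]:
    """Construct intra- and inter-sentence instances for one document.

    Intra: one instance per (chemical mention, disease mention, chem_id,
    dis_id) co-occurring in a sentence.  Inter: only for concept pairs with no
    intra co-occurrence anywhere in the document; one instance per
    cross-sentence mention pair with sentence distance <= ``inter_window``
    (all cross-sentence pairs when ``inter_all_pairs``), or the single nearest
    pair if none falls within the window.  Mentions with only the
    unnormalized ``-1`` identifier never produce instances.
    """
    intra: list[RelationInstance] = []
    intra_pairs: set[tuple[str, str]] = set()
    for view in sentences:
        chems = [m for m in view.mentions if m.etype == CHEMICAL]
        diss = [m for m in view.mentions if m.etype == DISEASE]
        for cm, dm in product(chems, diss):
            for cid, did in product(cm.normalized_ids, dm.normalized_ids):
                intra.append(
                    RelationInstance(
                        doc.doc_id, cm, dm, cid, did, INTRA,
                        sentence_index=view.index,
                    )
                )
                intra_pairs.add((cid, did))

    # mention -> hosting sentence index
    sent_of: dict[tuple[int, int], int] = {}
    for view in sentences:
        for m in view.mentions:
            sent_of[(m.start, m.end)] = view.index

    chem_mentions = [m for m in doc.mentions if m.etype == CHEMICAL]
    dis_mentions = [m for m in doc.mentions if m.etype == DISEASE]
    by_pair: dict[tuple[str, str], list[RelationInstance]] = {}
    for cm, dm in product(chem_mentions, dis_mentions):
        ci = sent_of.get((cm.start, cm.end))
        di = sent_of.get((dm.start, dm.end))
        if ci is None or di is None or ci == di:
            continue
        for cid, did in product(cm.normalized_ids, dm.normalized_ids):
            if (cid, did) in intra_pairs:
                continue
            by_pair.setdefault((cid, did), []).append(
                RelationInstance(
                    doc.doc_id, cm, dm, cid, did, INTER,
                    sentence_index_pair=(ci, di),
                )
            )

    inter: list[RelationInstance] = []
    for pair, candidates in by_pair.items():
        if inter_all_pairs:
            inter.extend(candidates)
            continue
        within = [c for c in candidates if c.sentence_distance <= inter_window]
        if within:
            inter.extend(within)
        else:
            inter.append(
                min(
                    candidates,
                    key=lambda c: (
                        c.sentence_distance,
                        c.chem_mention.start,
                        c.dis_mention.start,
                    ),
                )
            )
    return intra, inter


def label_instances(
    instances: Iterable[RelationInstance],
    gold_relations: set[tuple[str, str]],
) -> list[RelationInstance]:
    """Distant labeling: positive iff the instance's concept pair is gold."""
    return [
        replace(inst, label=POSITIVE if inst.pair in gold_relations else NEGATIVE)
        for inst in instances
    ]


def is_hypernym(ontology: MeshOntology, a: str, b: str) -> bool:
    """True iff some tree number of ``a`` is a proper segment-prefix of one of ``b``.

    Equal tree numbers do not count: a concept is not its own hypernym.
    Unknown concept IDs have no tree numbers and are never hypernyms.
    """
    nums_a = ontology.numbers(a)
    nums_b = ontology.numbers(b)
    for ta in nums_a:
        seg_a = ta.split(".")
        for tb in nums_b:
            seg_b = tb.split(".")
            if len(seg_a) < len(seg_b) and seg_b[: len(seg_a)] == seg_a:
                return True
    return False


def hypernym_filter_train(
    instances: Sequence[RelationInstance],
    gold_relations: set[tuple[str, str]],
    ontology: MeshOntology,
) -> list[RelationInstance]:
    """Drop negative instances generalizing a concept in a positive relation.

    A negative instance is removed iff its chemical is a hypernym of some
    chemical occurring in any gold relation of the document, or its disease is
    a hypernym of some disease there.  Positive instances are never removed.
    """
    pos_chems = {c for c, _ in gold_relations}
    pos_diss = {d for _, d in gold_relations}
    kept = []
    for inst in instances:
        if inst.label != NEGATIVE:
            kept.append(inst)
            continue
        if any(is_hypernym(ontology, inst.chem_id, c) for c in pos_chems):
            continue
        if any(is_hypernym(ontology, inst.dis_id, d) for d in pos_diss):
            continue
        kept.append(inst)
    return kept


def hypernym_filter_predict(
    relations: set[tuple[str, str]], ontology: MeshOntology
) -> set[tuple[str, str]]:
    """Keep only the most specific predicted concept pairs of a document.

    A pair is removed iff its chemical is a hypernym of another predicted
    pair's chemical, or its disease is a hypernym of another predicted pair's
    disease.
    """
    chems = {c for c, _ in relations}
    diss = {d for _, d in relations}
    kept = set()
    for chem, dis in relations:
        if any(is_hypernym(ontology, chem, other) for other in chems - {chem}):
            continue
        if any(is_hypernym(ontology, dis, other) for other in diss - {dis}):
            continue
        kept.add((chem, dis))
    return kept


def dump_instances(instances: Iterable[RelationInstance], stream: TextIO) -> None:
    """Stable TSV debug dump of instances (one row per instance)."""
    stream.write(
        "doc_id\tlevel\tchem_id\tdis_id\tchem_span\tdis_span\tsentences\tlabel\n"
    )
    for i in instances:
        sents = (
            str(i.sentence_index)
            if i.level == INTRA
            else f"{i.sentence_index_pair[0]},{i.sentence_index_pair[1]}"
        )
        stream.write(
            f"{i.doc_id}\t{i.level}\t{i.chem_id}\t{i.dis_id}"
            f"\t{i.chem_mention.start}-{i.chem_mention.end}"
            f"\t{i.dis_mention.start}-{i.dis_mention.end}"
            f"\t{sents}\t{'' if i.label is None else i.label}\n"
        )
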