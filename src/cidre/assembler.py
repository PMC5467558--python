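"""Merging mention-level predictions into document-level relations.

A concept pair holds at document level iff at least one of its mention-pair
instances — at either sentence level — is predicted positive.  Documents where
nothing was extracted fall back to heuristics: (a) every chemical mentioned in
the title is paired with every disease in the document; (b) if the title has
no chemical, the most frequently mentioned chemical is used instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .corpus import CHEMICAL, DISEASE, Document
from .instances import POSITIVE, RelationInstance

PROV_INTRA = "intra"
PROV_INTER = "inter"
PROV_RULE_A = "pp_rule_a"
PROV_RULE_B = "pp_rule_b"


@dataclass
class DocumentPrediction:
    doc_id: str
    relations: set[tuple[str, str]] = field(default_factory=set)
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)
    confidence: dict[tuple[str, str], float] = field(default_factory=dict)


def merge_mention_predictions(
    doc: Document,
    intra: Sequence[tuple[RelationInstance, int, float]],
    inter: Sequence[tuple[RelationInstance, int, float]],
) -> DocumentPrediction:
    """Any positively-predicted mention pair asserts its concept pair.

    Confidence is the maximum over supporting (positive) instances; the
    provenance records the level of the best supporter.
    """
    pred = DocumentPrediction(doc.doc_id)
    for level, results in ((PROV_INTRA, intra), (PROV_INTER, inter)):
        for inst, label, conf in results:
            if label != POSITIVE:
                continue
            pair = inst.pair
            if pair not in pred.relations or conf > pred.confidence[pair]:
                pred.confidence[pair] = conf
                pred.provenance[pair] = level
            pred.relations.add(pair)
    return pred


def _title_chemicals(doc: Document) -> list[str]:
    boundary = len(doc.title)
    seen: dict[str, None] = {}
    for m in doc.mentions:
        if m.etype == CHEMICAL and m.end <= boundary:
            for cid in m.normalized_ids:
                seen.setdefault(cid, None)
    return list(seen)


def _most_frequent_chemical(doc: Document) -> str | None:
    counts: dict[str, int] = {}
    first: dict[str, int] = {}
    for m in doc.mentions:
        if m.etype != CHEMICAL:
            continue
        for cid in m.normalized_ids:
            counts[cid] = counts.get(cid, 0) + 1
            first.setdefault(cid, m.start)
    if not counts:
        return None
    # highest count; ties broken by earliest first occurrence
    return min(counts, key=lambda c: (-counts[c], first[c]))


def post_process(doc: Document, prediction: DocumentPrediction) -> DocumentPrediction:
    """Heuristic fallback for documents with no extracted relation.

    Fires only when the incoming relation set is empty, hence idempotent.
    Rule (a): all title chemicals x all diseases of the document.  Rule (b),
    when the title has no chemical: the most frequently mentioned chemical x
    all diseases.  A document lacking chemicals or diseases stays empty.
    """
    if prediction.relations:
        return prediction
    diseases = sorted(doc.concept_ids(DISEASE))
    if not diseases:
        return prediction
    title_chems = _title_chemicals(doc)
    if title_chems:
        chems, provenance = title_chems, PROV_RULE_A
    else:
        chem = _most_frequent_chemical(doc)
        if chem is None:
            return prediction
        chems, provenance = [chem], PROV_RULE_B
    for cid in chems:
        for did in diseases:
            pair = (cid, did)
            prediction.relations.add(pair)
            prediction.provenance[pair] = provenance
            prediction.confidence[pair] = 0.5
    return prediction


def write_predictions_tsv(predictions: Sequence[DocumentPrediction], stream) -> None:
    stream.write("doc_id\tchem_id\tdis_id\tconfidence\tprovenance\n")
    for pred in predictions:
        for chem, dis in sorted(pred.relations):
            stream.write(
                f"{pred.doc_id}\t{chem}\t{dis}"
                f"\t{pred.confidence.get((chem, dis), ''):.6f}"
                f"\t{pred.provenance.get((chem, dis), '')}\n"
            )
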