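"""End-to-end orchestration: instances -> classifiers -> document relations.

Training: per document, mention-pair instances are constructed, distantly
labeled from the document-level gold pairs, and hypernym-filtered; the
intra-sentence instances train the CNN, the inter-sentence instances train
the maximum-entropy classifier.

Prediction: instance construction -> per-level classification -> document
merging -> test-time hypernym filtering -> heuristic post-processing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .assembler import DocumentPrediction, merge_mention_predictions, post_process
from .cnn import CnnHyperparameters, CnnModel, train_cnn
from .corpus import DependencyTree, Document, MeshOntology, split_sentences
from .features import Vocabulary, encode_intra
from .instances import (
    NEGATIVE,
    RelationInstance,
    build_instances,
    hypernym_filter_predict,
    hypernym_filter_train,
    label_instances,
)
from .maxent import MaxEntModel, extract_inter_features, train_maxent

logger = logging.getLogger(__name__)


@dataclass
class PipelineOptions:
    inter_window: int = 3
    inter_all_pairs: bool = False
    use_hypernym_filter: bool = True
    use_post_processing: bool = True
    maxent_l2: float = 1.0


@dataclass
class PipelineModel:
    cnn: CnnModel
    maxent: MaxEntModel
    options: PipelineOptions = field(default_factory=PipelineOptions)


def _doc_instances(doc, trees, options):
    views = split_sentences(doc, trees)
    intra, inter = build_instances(
        doc, views,
        inter_window=options.inter_window,
        inter_all_pairs=options.inter_all_pairs,
    )
    return views, intra, inter


def train_pipeline(
    docs: list[Document],
    trees: dict[tuple[str, int], DependencyTree],
    ontology: MeshOntology,
    hyper: CnnHyperparameters,
    options: PipelineOptions | None = None,
    init_vectors=None,
    seed: int | None = None,
) -> PipelineModel:
    options = options or PipelineOptions()
    vocab = Vocabulary.from_corpus(trees)

    intra_encoded = []
    inter_feats, inter_labels = [], []
    counts = {"intra": 0, "inter": 0, "filtered": 0}
    for doc in docs:
        views, intra, inter = _doc_instances(doc, trees, options)
        intra = label_instances(intra, doc.gold_relations)
        inter = label_instances(inter, doc.gold_relations)
        counts["intra"] += len(intra)
        counts["inter"] += len(inter)
        if options.use_hypernym_filter:
            before = len(intra) + len(inter)
            intra = hypernym_filter_train(intra, doc.gold_relations, ontology)
            inter = hypernym_filter_train(inter, doc.gold_relations, ontology)
            counts["filtered"] += before - len(intra) - len(inter)
        view_by_index = {v.index: v for v in views}
        for inst in intra:
            intra_encoded.append(
                encode_intra(
                    inst, view_by_index[inst.sentence_index], vocab,
                    hyper.w, hyper.v_max, hyper.l_max,
                )
            )
        for inst in inter:
            inter_feats.append(extract_inter_features(inst, doc, views))
            inter_labels.append(inst.label)
    logger.info(
        "training instances: %d intra, %d inter (%d removed by hypernym filter)",
        counts["intra"], counts["inter"], counts["filtered"],
    )

    cnn = train_cnn(intra_encoded, hyper, vocab, init_vectors=init_vectors,
                    seed=seed)

    if len(set(inter_labels)) < 2:
        # degenerate corpus: fall back to a prior-only model
        logger.warning("inter-sentence training data has a single class; "
                       "using a prior-only model")
        prior = float(np.mean(inter_labels)) if inter_labels else 0.0
        prior = min(max(prior, 1e-6), 1 - 1e-6)
        maxent = MaxEntModel(
            feature_index={}, weights=np.zeros(0),
            bias=float(np.log(prior / (1 - prior))), l2=options.maxent_l2,
        )
    else:
        maxent = train_maxent(inter_feats, inter_labels, l2=options.maxent_l2)
    return PipelineModel(cnn=cnn, maxent=maxent, options=options)


def predict_pipeline(
    docs: list[Document],
    trees: dict[tuple[str, int], DependencyTree],
    ontology: MeshOntology,
    model: PipelineModel,
    majority_baseline: bool = False,
) -> dict[str, DocumentPrediction]:
    """Document-level relation prediction for a corpus.

    ``majority_baseline`` replaces the CNN's intra-sentence decisions with the
    majority class (negative), leaving everything else in place — a control
    quantifying how much of the end-to-end score the learned classifier
    contributes.
    """
    options = model.options
    hyper = model.cnn.hyper
    out: dict[str, DocumentPrediction] = {}
    for doc in docs:
        views, intra, inter = _doc_instances(doc, trees, options)
        view_by_index = {v.index: v for v in views}
        if majority_baseline:
            intra_results = [(inst, NEGATIVE, 1.0) for inst in intra]
        else:
            encoded = [
                encode_intra(
                    inst, view_by_index[inst.sentence_index], model.cnn.vocab,
                    hyper.w, hyper.v_max, hyper.l_max,
                )
                for inst in intra
            ]
            intra_results = [
                (inst, label, conf)
                for inst, (label, conf) in zip(intra, model.cnn.predict(encoded))
            ]
        inter_results = [
            (inst, *model.maxent.predict(extract_inter_features(inst, doc, views)))
            for inst in inter
        ]
        pred = merge_mention_predictions(doc, intra_results, inter_results)
        if options.use_hypernym_filter:
            kept = hypernym_filter_predict(pred.relations, ontology)
            for pair in pred.relations - kept:
                pred.provenance.pop(pair, None)
                pred.confidence.pop(pair, None)
            pred.relations = kept
        if options.use_post_processing:
            pred = post_process(doc, pred)
        out[doc.doc_id] = pred
    return out


def gold_map(docs: list[Document]) -> dict[str, set[tuple[str, str]]]:
    return {doc.doc_id: set(doc.gold_relations) for doc in docs}


def prediction_map(
    predictions: dict[str, DocumentPrediction]
) -> dict[str, set[tuple[str, str]]]:
    return {doc_id: set(p.relations) for doc_id, p in predictions.items()}
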