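"""Mention-pair construction, distant labeling and hypernymy filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cidre.corpus import CHEMICAL, DISEASE, MeshOntology, split_sentences
from cidre.instances import (
    INTER,
    INTRA,
    NEGATIVE,
    POSITIVE,
    build_instances,
    hypernym_filter_predict,
    hypernym_filter_train,
    is_hypernym,
    label_instances,
)
from tests.conftest import make_document, svo


def test_worked_example_intra_and_inter_levels(midazolam_doc):
    doc, trees = midazolam_doc
    views = split_sentences(doc, trees)
    intra, inter = build_instances(doc, views)
    # (C1, D1) co-occurs in sentences 0 and 3 -> two intra instances
    c1d1 = [i for i in intra if i.pair == ("D008874", "D006323")]
    assert sorted(i.sentence_index for i in c1d1) == [0, 3]
    # (C1, D2) never shares a sentence -> inter only
    assert all(i.pair != ("D008874", "D012140") for i in intra)
    c1d2 = [i for i in inter if i.pair == ("D008874", "D012140")]
    assert c1d2 and all(i.level == INTER for i in c1d2)


def test_document_without_both_types_yields_nothing():
    specs = [(svo("aspirin", "helped", "patient"), [(2, 2, CHEMICAL, ["D1"])])]
    doc, trees = make_document("1", specs)
    intra, inter = build_instances(doc, split_sentences(doc, trees))
    assert intra == [] and inter == []


def test_intra_cooccurrence_suppresses_inter_for_the_pair():
    specs = [
        (svo("drugx", "caused", "rash"),
         [(2, 2, CHEMICAL, ["C"]), (4, 4, DISEASE, ["D"])]),
        (svo("clinic", "monitored", "patient"), []),
        (svo("nurse", "observed", "rash"), [(4, 4, DISEASE, ["D"])]),
    ]
    doc, trees = make_document("1", specs)
    intra, inter = build_instances(doc, split_sentences(doc, trees))
    assert len([i for i in intra if i.pair == ("C", "D")]) == 1
    assert inter == []


def test_inter_window_and_nearest_fallback():
    chem = (svo("drugx", "relieved", "pain"), [(2, 2, CHEMICAL, ["C"])])
    filler = (svo("team", "reviewed", "chart"), [])
    dis = (svo("chart", "showed", "anemia"), [(4, 4, DISEASE, ["D"])])
    # distance 5 > window: only the single nearest pair is kept
    specs = [chem, filler, filler, filler, filler, dis]
    doc, trees = make_document("1", specs)
    _, inter = build_instances(doc, split_sentences(doc, trees), inter_window=3)
    assert len(inter) == 1 and inter[0].sentence_distance == 5
    # inside the window every cross-sentence pair appears
    specs = [chem, filler, dis]
    doc, trees = make_document("2", specs)
    _, inter = build_instances(doc, split_sentences(doc, trees), inter_window=3)
    assert len(inter) == 1 and inter[0].sentence_distance == 2


def test_unnormalized_mentions_build_no_instances():
    specs = [
        (svo("mystery", "caused", "rash"),
         [(2, 2, CHEMICAL, ["-1"]), (4, 4, DISEASE, ["D"])]),
    ]
    doc, trees = make_document("1", specs)
    intra, inter = build_instances(doc, split_sentences(doc, trees))
    assert intra == [] and inter == []


def test_intra_completeness_invariant():
    """|intra| = sum over sentences of #chem-IDs x #dis-IDs in the sentence."""
    from cidre.synthetic import SynthConfig, generate_corpus

    docs, trees, _ = generate_corpus(SynthConfig(n_docs=15, seed=3))
    for doc in docs:
        views = split_sentences(doc, trees)
        intra, inter = build_instances(doc, views)
        expected = 0
        for v in views:
            n_chem = sum(
                len(m.normalized_ids) for m in v.mentions if m.etype == CHEMICAL
            )
            n_dis = sum(
                len(m.normalized_ids) for m in v.mentions if m.etype == DISEASE
            )
            expected += n_chem * n_dis
        assert len(intra) == expected
        # exclusivity: no concept pair at both levels
        assert {i.pair for i in intra}.isdisjoint({i.pair for i in inter})


def test_distant_labeling(midazolam_doc):
    doc, trees = midazolam_doc
    intra, inter = build_instances(doc, split_sentences(doc, trees))
    labeled = label_instances(intra + inter, doc.gold_relations)
    for inst in labeled:
        assert inst.label == (POSITIVE if inst.pair in doc.gold_relations else NEGATIVE)
    assert any(i.label == POSITIVE for i in labeled)
    # empty gold set -> everything negative
    assert all(
        i.label == NEGATIVE for i in label_instances(intra + inter, set())
    )
    # labeling is a pure function of the concept pair
    by_pair = {}
    for inst in labeled:
        by_pair.setdefault(inst.pair, set()).add(inst.label)
    assert all(len(v) == 1 for v in by_pair.values())


# ---------------------------------------------------------------------------
# hypernymy


def test_is_hypernym_prefix_and_segment_boundary():
    ont = MeshOntology({
        "A": {"C01.252"},
        "B": {"C01.252.400"},
        "C": {"C01.25"},
    })
    assert is_hypernym(ont, "A", "B")
    assert not is_hypernym(ont, "B", "A")
    assert not is_hypernym(ont, "C", "B")  # substring but not segment prefix
    assert not is_hypernym(ont, "A", "A")  # a concept is not its own hypernym
    assert not is_hypernym(ont, "Z", "B")  # unknown concept


def _brute_force_hypernym(ont, a, b):
    for ta in ont.numbers(a):
        for tb in ont.numbers(b):
            if tb != ta and tb.startswith(ta + "."):
                return True
    return False


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.data())
def test_is_hypernym_agrees_with_bruteforce_enumeration(data):
    segment = st.sampled_from(["C01", "C14", "252", "400", "067", "9"])
    number = st.builds(
        ".".join, st.lists(segment, min_size=1, max_size=4)
    )
    concepts = {
        f"D{i}": data.draw(st.sets(number, min_size=0, max_size=3))
        for i in range(20)
    }
    ont = MeshOntology(concepts)
    for a in concepts:
        for b in concepts:
            assert is_hypernym(ont, a, b) == _brute_force_hypernym(ont, a, b)


def _toy_ontology():
    return MeshOntology({
        "C_gen": {"D02.100"},
        "C_spec": {"D02.100.200"},
        "C_other": {"D02.300"},
        "D_gen": {"C14.100"},
        "D_spec": {"C14.100.500"},
    })


def test_train_filter_removes_generalizing_negatives():
    ont = _toy_ontology()
    specs = [
        (svo("specdrug", "caused", "rash"),
         [(2, 2, CHEMICAL, ["C_spec"]), (4, 4, DISEASE, ["D_spec"])]),
        (svo("gendrug", "accompanied", "rash"),
         [(2, 2, CHEMICAL, ["C_gen"]), (4, 4, DISEASE, ["D_spec"])]),
        (svo("otherdrug", "accompanied", "rash"),
         [(2, 2, CHEMICAL, ["C_other"]), (4, 4, DISEASE, ["D_spec"])]),
    ]
    gold = {("C_spec", "D_spec")}
    doc, trees = make_document("1", specs, gold=gold)
    intra, _ = build_instances(doc, split_sentences(doc, trees))
    labeled = label_instances(intra, gold)
    kept = hypernym_filter_train(labeled, gold, ont)
    kept_pairs = {i.pair for i in kept}
    assert ("C_gen", "D_spec") not in kept_pairs  # generalizes a positive chem
    assert ("C_other", "D_spec") in kept_pairs
    assert ("C_spec", "D_spec") in kept_pairs  # positives never removed
    # no positives in the document -> nothing removed
    unlabeled = label_instances(intra, set())
    assert hypernym_filter_train(unlabeled, set(), ont) == unlabeled


def test_predict_filter_keeps_most_specific_pairs():
    ont = _toy_ontology()
    preds = {("C_gen", "D_spec"), ("C_spec", "D_spec")}
    assert hypernym_filter_predict(preds, ont) == {("C_spec", "D_spec")}
    single = {("C_gen", "D_spec")}
    assert hypernym_filter_predict(single, ont) == single


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.data())
def test_predict_filter_matches_bruteforce_pairwise_filter(data):
    ont = _toy_ontology()
    ids_c = ["C_gen", "C_spec", "C_other"]
    ids_d = ["D_gen", "D_spec"]
    preds = data.draw(
        st.sets(st.tuples(st.sampled_from(ids_c), st.sampled_from(ids_d)))
    )
    expected = set()
    for chem, dis in preds:
        dominated = False
        for chem2, dis2 in preds:
            if chem2 != chem and is_hypernym(ont, chem, chem2):
                dominated = True
            if dis2 != dis and is_hypernym(ont, dis, dis2):
                dominated = True
        if not dominated:
            expected.add((chem, dis))
    got = hypernym_filter_predict(preds, ont)
    assert got == expected
    assert got <= preds  # always a subset
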