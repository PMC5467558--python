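"""The CNN classifier: lookup, convolution/pooling, forward, gradients, training."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cidre.cnn import (
    CnnHyperparameters,
    CnnModel,
    conv_pool,
    forward,
    init_parameters,
    load_checkpoint,
    lookup,
    loss_and_gradients,
    mention_embedding,
    save_checkpoint,
    softmax,
    train_cnn,
)
from cidre.features import PAD, EncodedInstance, Vocabulary

TINY = CnnHyperparameters(
    d0=4, w=3, v=3, n1=3, n2=5, n3=2, v_max=2, l_max=6, p_drop=0.3, seed=0
)


def tiny_vocab():
    return Vocabulary([f"t{i}" for i in range(8)] + ["nsubj", "dobj"])


def random_instance(vocab, hyper, rng, label=None):
    n_slots = 2 + 2 * (hyper.w - 1) + hyper.v_max
    slots = []
    for s in range(n_slots):
        k = int(rng.integers(1, 3))
        slots.append([int(rng.integers(2, len(vocab))) for _ in range(k)])
    paths = np.full((3, hyper.l_max), vocab.pad_id, dtype=np.int32)
    for p in range(3):
        n = int(rng.integers(1, hyper.l_max + 1))
        paths[p, :n] = rng.integers(2, len(vocab), size=n)
    return EncodedInstance(
        slots, paths, label if label is not None else int(rng.integers(2))
    )


# ---------------------------------------------------------------------------
# embedding lookup


def test_lookup_matches_one_hot_matrix_product():
    vocab = tiny_vocab()
    rng = np.random.default_rng(0)
    T = rng.normal(size=(4, len(vocab)))
    T[:, vocab.pad_id] = 0.0
    ids = [3, 7, 3, 5, 2]
    got = lookup(T, ids)
    # brute-force e_i = T u_{t_i} with explicit one-hot vectors
    for col, tid in enumerate(ids):
        u = np.zeros(len(vocab))
        u[tid] = 1.0
        assert np.allclose(got[:, col], T @ u)
    # repeated token -> identical columns; PAD -> zero column
    assert np.array_equal(got[:, 0], got[:, 2])
    assert np.array_equal(lookup(T, [vocab.pad_id])[:, 0], np.zeros(4))


def test_mention_embedding_is_token_mean():
    vocab = tiny_vocab()
    T = np.random.default_rng(1).normal(size=(4, len(vocab)))
    assert np.allclose(mention_embedding(T, [5]), T[:, 5])
    T[:, 6] = -T[:, 5]
    assert np.allclose(mention_embedding(T, [5, 6]), np.zeros(4))
    assert np.allclose(
        mention_embedding(T, [2, 3, 4]), (T[:, 2] + T[:, 3] + T[:, 4]) / 3
    )


# ---------------------------------------------------------------------------
# convolution and pooling


def naive_conv_pool(X0, W1, b1, mask):
    """Loop-based reference for Z = W1 X0 + b1, masked row max, tanh."""
    n1, ncol = W1.shape[0], X0.shape[1]
    Z = np.empty((n1, ncol))
    for i in range(n1):
        for j in range(ncol):
            acc = b1[i]
            for k in range(W1.shape[1]):
                acc += W1[i, k] * X0[k, j]
            Z[i, j] = acc
    cols = [j for j in range(ncol) if mask[j]] or list(range(ncol))
    m = np.array([max(Z[i, j] for j in cols) for i in range(n1)])
    return np.tanh(m)


def test_conv_pool_matches_naive_oracle():
    rng = np.random.default_rng(42)
    for _ in range(200):
        n1, vd0, ncol = 2, 3, 4
        X0 = rng.normal(size=(vd0, ncol))
        W1 = rng.normal(size=(n1, vd0))
        b1 = rng.normal(size=n1)
        mask = rng.random(ncol) < 0.7
        d, _, _ = conv_pool(X0, W1, b1, mask)
        assert np.max(np.abs(d - naive_conv_pool(X0, W1, b1, mask))) < 1e-10


def test_conv_pool_zero_input_gives_zero_features():
    d, _, _ = conv_pool(np.zeros((3, 5)), np.zeros((2, 3)), np.zeros(2))
    assert np.array_equal(d, np.zeros(2))


def test_pooling_invariant_to_column_permutation_and_padding():
    rng = np.random.default_rng(7)
    X0 = rng.normal(size=(6, 10))
    W1 = rng.normal(size=(4, 6))
    b1 = rng.normal(size=4)
    mask = np.array([True] * 7 + [False] * 3)
    d0_, _, _ = conv_pool(X0, W1, b1, mask)
    # permute the unmasked columns
    perm = np.concatenate([rng.permutation(7), np.arange(7, 10)])
    d1_, _, _ = conv_pool(X0[:, perm], W1, b1, mask)
    assert np.allclose(d0_, d1_)
    # append fully-padded (masked) columns
    X2 = np.hstack([X0, rng.normal(size=(6, 3))])
    mask2 = np.concatenate([mask, [False] * 3])
    d2_, _, _ = conv_pool(X2, W1, b1, mask2)
    assert np.allclose(d0_, d2_)


def test_all_masked_falls_back_to_unmasked_max(caplog):
    X0 = np.arange(6.0).reshape(2, 3)
    with caplog.at_level("WARNING"):
        d, m, _ = conv_pool(X0, np.eye(2), np.zeros(2), np.zeros(3, dtype=bool))
    assert np.allclose(m, [2.0, 5.0])
    assert "masked" in caplog.text


# ---------------------------------------------------------------------------
# forward pass


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(-50, 50), min_size=2, max_size=6))
def test_softmax_normalizes(scores):
    p = softmax(np.array(scores))
    assert abs(p.sum() - 1.0) < 1e-9
    assert (p >= 0).all()


def test_zero_parameters_give_uniform_probabilities():
    vocab = tiny_vocab()
    hyper = TINY
    params = init_parameters(vocab, hyper, np.random.default_rng(0))
    for name in params.names():
        getattr(params, name)[...] = 0.0
    enc = random_instance(vocab, hyper, np.random.default_rng(3))
    cache = forward(enc, params, hyper, vocab.pad_id)
    assert np.allclose(cache.probs, [0.5, 0.5])


def test_dropout_off_makes_train_equal_test():
    vocab = tiny_vocab()
    hyper = CnnHyperparameters(
        d0=4, w=3, v=3, n1=3, n2=5, n3=2, v_max=2, l_max=6, p_drop=0.0
    )
    params = init_parameters(vocab, hyper, np.random.default_rng(0))
    enc = random_instance(vocab, hyper, np.random.default_rng(4))
    test_cache = forward(enc, params, hyper, vocab.pad_id, train=False)
    train_cache = forward(
        enc, params, hyper, vocab.pad_id, train=True,
        rng=np.random.default_rng(0),
    )
    assert np.allclose(test_cache.probs, train_cache.probs)


def test_forward_matches_loop_oracle():
    """Independent elementwise recomputation of the stacked transformations."""
    vocab = tiny_vocab()
    hyper = CnnHyperparameters(
        d0=2, w=3, v=3, n1=2, n2=3, n3=2, v_max=1, l_max=4, p_drop=0.0
    )
    rng = np.random.default_rng(11)
    params = init_parameters(vocab, hyper, rng)
    enc = random_instance(vocab, hyper, rng)
    cache = forward(enc, params, hyper, vocab.pad_id)

    T = params.T
    # context: mean embedding per slot
    c = []
    for slot in enc.context_slots:
        c.extend(sum(T[:, t] for t in slot) / len(slot))
    # paths: pad windows, stack embeddings, convolve column by column
    half = (hyper.v - 1) // 2
    cols, centers = [], []
    for row in enc.path_ids:
        padded = [vocab.pad_id] * half + list(row) + [vocab.pad_id] * half
        for j in range(len(row)):
            window = padded[j : j + hyper.v]
            cols.append(np.concatenate([T[:, t] for t in window]))
            centers.append(row[j])
    scores = [params.W1 @ col + params.b1 for col in cols]
    live = [j for j, cen in enumerate(centers) if cen != vocab.pad_id]
    m = [max(s[i] for j, s in enumerate(scores) if j in live)
         for i in range(hyper.n1)]
    d = np.tanh(m)
    k = np.concatenate([c, d])
    r = np.tanh(params.W2 @ k + params.b2)
    o = params.W3 @ r + params.b3
    probs = np.exp(o - o.max())
    probs /= probs.sum()
    assert np.allclose(cache.probs, probs, atol=1e-12)


def test_dropout_zero_fraction_statistics():
    """Over 1e5 coordinate draws the zeroed fraction is within 3 SE of p."""
    vocab = tiny_vocab()
    hyper = CnnHyperparameters(
        d0=4, w=3, v=3, n1=3, n2=1000, n3=2, v_max=2, l_max=6, p_drop=0.3
    )
    params = init_parameters(vocab, hyper, np.random.default_rng(0))
    rng = np.random.default_rng(123)
    enc = random_instance(vocab, hyper, np.random.default_rng(5))
    zeros = total = 0
    for _ in range(100):
        cache = forward(enc, params, hyper, vocab.pad_id, train=True, rng=rng)
        zeros += int((cache.drop_mask == 0).sum())
        total += hyper.n2
    frac = zeros / total
    se = math.sqrt(0.3 * 0.7 / total)
    assert abs(frac - 0.3) <= 3 * se


# ---------------------------------------------------------------------------
# loss and gradients


def test_loss_at_zero_parameters_is_log2():
    vocab = tiny_vocab()
    hyper = TINY
    params = init_parameters(vocab, hyper, np.random.default_rng(0))
    for name in params.names():
        getattr(params, name)[...] = 0.0
    enc = random_instance(vocab, hyper, np.random.default_rng(6), label=1)
    J, _ = loss_and_gradients(
        [enc], params, hyper, vocab.pad_id, train=False
    )
    assert abs(J - math.log(2)) < 1e-12


def test_duplicated_instance_leaves_mean_loss_unchanged():
    vocab = tiny_vocab()
    hyper = CnnHyperparameters(
        d0=4, w=3, v=3, n1=3, n2=5, n3=2, v_max=2, l_max=6, p_drop=0.0, lam=0.0
    )
    params = init_parameters(vocab, hyper, np.random.default_rng(2))
    enc = random_instance(vocab, hyper, np.random.default_rng(7), label=0)
    J1, _ = loss_and_gradients([enc], params, hyper, vocab.pad_id, train=False)
    J2, _ = loss_and_gradients(
        [enc, enc], params, hyper, vocab.pad_id, train=False
    )
    assert abs(J1 - J2) < 1e-12


def finite_difference_check(batch, params, hyper, pad_id, masks, step=1e-5,
                            sample=None, rng=None):
    """Max relative error between analytic and central-difference gradients."""
    _, grads = loss_and_gradients(
        batch, params, hyper, pad_id, train=True, drop_masks=masks
    )
    worst = 0.0
    for name in params.names():
        p = getattr(params, name)
        coords = list(np.ndindex(p.shape))
        if name == "T":
            coords = [c for c in coords if c[1] != pad_id]
        if sample is not None and len(coords) > sample:
            pick = rng.choice(len(coords), size=sample, replace=False)
            coords = [coords[i] for i in pick]
        for idx in coords:
            orig = p[idx]
            p[idx] = orig + step
            j1, _ = loss_and_gradients(
                batch, params, hyper, pad_id, train=True, drop_masks=masks
            )
            p[idx] = orig - step
            j2, _ = loss_and_gradients(
                batch, params, hyper, pad_id, train=True, drop_masks=masks
            )
            p[idx] = orig
            numeric = (j1 - j2) / (2 * step)
            analytic = grads[name][idx]
            rel = abs(numeric - analytic) / max(abs(numeric), abs(analytic), 1e-8)
            worst = max(worst, rel)
    return worst


def test_gradients_match_finite_differences_sampled():
    vocab = tiny_vocab()
    hyper = TINY
    rng = np.random.default_rng(0)
    params = init_parameters(vocab, hyper, rng)
    batch = [random_instance(vocab, hyper, rng, label=i % 2) for i in range(3)]
    masks = [
        (np.random.default_rng(100 + i).random(hyper.n2) >= hyper.p_drop)
        .astype(float)
        for i in range(3)
    ]
    worst = finite_difference_check(
        batch, params, hyper, vocab.pad_id, masks, sample=40,
        rng=np.random.default_rng(9),
    )
    assert worst < 1e-4


# ---------------------------------------------------------------------------
# training


def corpus_encoded(n_docs, seed, hyper, noise=0.0, vocab=None):
    from cidre.corpus import split_sentences
    from cidre.features import encode_intra
    from cidre.instances import build_instances, label_instances
    from cidre.synthetic import SynthConfig, generate_corpus

    docs, trees, _ = generate_corpus(
        SynthConfig(n_docs=n_docs, noise_rate=noise, seed=seed)
    )
    if vocab is None:
        vocab = Vocabulary.from_corpus(trees)
    encoded = []
    for doc in docs:
        views = split_sentences(doc, trees)
        intra, _ = build_instances(doc, views)
        by_index = {v.index: v for v in views}
        for inst in label_instances(intra, doc.gold_relations):
            encoded.append(
                encode_intra(inst, by_index[inst.sentence_index], vocab,
                             hyper.w, hyper.v_max, hyper.l_max)
            )
    return encoded, vocab


SMALL_TRAIN = CnnHyperparameters(
    d0=24, n1=16, n2=32, epochs=6, l_max=16, seed=0
)


@pytest.fixture(scope="module")
def trained_small():
    encoded, vocab = corpus_encoded(100, seed=21, hyper=SMALL_TRAIN)
    model = train_cnn(encoded, SMALL_TRAIN, vocab, seed=5)
    return model, encoded, vocab


def test_training_is_deterministic(trained_small):
    model, encoded, vocab = trained_small
    again = train_cnn(encoded, SMALL_TRAIN, vocab, seed=5)
    for name in model.params.names():
        assert np.array_equal(getattr(model.params, name),
                              getattr(again.params, name))


def test_zero_epochs_returns_initialization():
    vocab = tiny_vocab()
    hyper = CnnHyperparameters(
        d0=4, w=3, v=3, n1=3, n2=5, n3=2, v_max=2, l_max=6, epochs=0, seed=3
    )
    enc = [random_instance(vocab, hyper, np.random.default_rng(1), label=i % 2)
           for i in range(4)]
    model = train_cnn(enc, hyper, vocab, seed=3)
    expected = init_parameters(vocab, hyper, np.random.default_rng(3))
    for name in expected.names():
        assert np.array_equal(getattr(model.params, name),
                              getattr(expected, name))


def test_planted_rule_is_learned(trained_small):
    """On a noise-free trigger-verb corpus the CNN recovers the rule."""
    model, encoded, _ = trained_small
    preds = model.predict(encoded)
    acc = np.mean([p[0] == e.label for p, e in zip(preds, encoded)])
    assert acc >= 0.98
    # held-out mention-level F on a fresh corpus, encoded with the model vocab
    test_enc, _ = corpus_encoded(
        30, seed=22, hyper=SMALL_TRAIN, vocab=model.vocab
    )
    test_preds = model.predict(test_enc)
    tp = sum(1 for p, e in zip(test_preds, test_enc) if p[0] == 1 and e.label == 1)
    fp = sum(1 for p, e in zip(test_preds, test_enc) if p[0] == 1 and e.label == 0)
    fn = sum(1 for p, e in zip(test_preds, test_enc) if p[0] == 0 and e.label == 1)
    f1 = 2 * tp / max(2 * tp + fp + fn, 1)
    assert f1 >= 0.95


def test_epoch_loss_non_increasing_early(trained_small):
    model, _, _ = trained_small
    trace = model.loss_trace[:5]
    assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))


def test_prediction_is_deterministic_and_tie_goes_negative(trained_small):
    model, encoded, vocab = trained_small
    one = encoded[0]
    assert model.predict([one, one])[0] == model.predict([one, one])[1]
    # zero parameters: 0.5/0.5 tie resolves to the negative label
    zero = model.params.copy()
    for name in zero.names():
        getattr(zero, name)[...] = 0.0
    tie_model = CnnModel(hyper=model.hyper, vocab=vocab, params=zero)
    label, conf = tie_model.predict([one])[0]
    assert label == 0 and abs(conf - 0.5) < 1e-12


def test_checkpoint_round_trip_bit_exact(trained_small, tmp_path):
    model, _, _ = trained_small
    path = tmp_path / "cnn.npz"
    save_checkpoint(model, path)
    loaded = load_checkpoint(path)
    assert loaded.hyper == model.hyper
    assert loaded.vocab.to_dict() == model.vocab.to_dict()
    for name in model.params.names():
        assert np.array_equal(getattr(loaded.params, name),
                              getattr(model.params, name))
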