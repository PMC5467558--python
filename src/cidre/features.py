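"""Intra-sentence feature assembly for the CNN classifier.

Two feature families are produced per mention-pair instance:

* **Contextual features** — word embeddings of the chemical and disease
  mentions (token-mean for multi-token mentions), of the (w-1)/2 tokens to the
  left and right of each mention, and of up to ``V_max`` verbs strictly
  between the mentions, padded with ``<PAD>`` slots.

* **Dependency features** — three token sequences through the sentence's
  dependency tree: root-to-chemical (R2C), root-to-disease (R2D) and
  chemical-to-disease (C2D).  Paths interleave surface forms, dependency
  labels and traversal-direction arrows ("↓" head-to-dependent, "↑"
  dependent-to-head), e.g. ``ROOT ↓ root ↓ induced ↓ nsubj ↓ dipyridamole``.
  Each path is padded to a fixed length and sliced into v-token windows
  centered at every position; the stacked window embeddings form the
  convolution input matrix X0.

This module works at the token/index level; the embedding arithmetic lives in
:mod:`cidre.cnn`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .corpus import DependencyTree, Mention, SentenceView
from .instances import RelationInstance

PAD = "<PAD>"
UNK = "<UNK>"
ROOT = "ROOT"
UP = "↑"  # ↑ dependent-to-head step
DOWN = "↓"  # ↓ head-to-dependent step

SPECIALS = (PAD, UNK, ROOT, UP, DOWN)


def mention_head_token(tree: DependencyTree, token_indices: Sequence[int]) -> int:
    """The mention token governed from outside the mention; ties/none -> last.

    For a multi-token mention the head is the unique token whose governor lies
    outside the mention's token set; if zero or several tokens qualify, the
    last mention token is used.
    """
    if not token_indices:
        raise ValueError("mention aligned to no tokens")
    inside = set(token_indices)
    external = [i for i in token_indices if tree.token(i).head not in inside]
    if len(external) == 1:
        return external[0]
    return token_indices[-1]


def _ancestors(tree: DependencyTree, index: int) -> list[int]:
    """Path of token indices from the root down to ``index`` (inclusive)."""
    chain = [index]
    seen = {index}
    while True:
        head = tree.token(chain[-1]).head
        if head == 0:
            break
        if head in seen:  # cannot happen for a validated tree
            raise ValueError("cycle in head links")
        chain.append(head)
        seen.add(head)
    return chain[::-1]


def extract_dependency_paths(
    tree: DependencyTree, chem_head: int, dis_head: int
) -> tuple[list[str], list[str], list[str]]:
    """The R2C, R2D and C2D token sequences for a mention pair.

    R2C/R2D start at the synthetic ROOT and walk head-to-dependent:
    ``[ROOT, ↓, deprel, ↓, form, ...]``.  C2D walks the unique tree path from
    the chemical head to the disease head through their lowest common
    ancestor, emitting ``↑`` for dependent-to-head steps and ``↓`` for
    head-to-dependent steps, with the dependency label between the arrows.
    """

    def root_path(target: int) -> list[str]:
        seq = [ROOT]
        for idx in _ancestors(tree, target):
            tok = tree.token(idx)
            seq += [DOWN, tok.deprel, DOWN, tok.form]
        return seq

    chem_chain = _ancestors(tree, chem_head)
    dis_chain = _ancestors(tree, dis_head)
    lca_depth = 0
    for a, b in zip(chem_chain, dis_chain):
        if a != b:
            break
        lca_depth += 1
    up_part = chem_chain[lca_depth - 1 :][::-1]  # chem head ... lca
    down_part = dis_chain[lca_depth:]  # below lca ... dis head

    c2d = [tree.token(up_part[0]).form]
    for idx in up_part[:-1]:
        tok = tree.token(idx)
        parent = tree.token(tok.head)
        c2d += [UP, tok.deprel, UP, parent.form]
    for idx in down_part:
        tok = tree.token(idx)
        c2d += [DOWN, tok.deprel, DOWN, tok.form]

    return root_path(chem_head), root_path(dis_head), c2d


def pad_path(path: Sequence[str], length: int, keep_tail: bool = False) -> list[str]:
    """Right-pad with ``<PAD>`` to ``length``; truncate keeping head or tail."""
    if len(path) > length:
        path = list(path[-length:]) if keep_tail else list(path[:length])
    return list(path) + [PAD] * (length - len(path))


def path_windows(path: Sequence[str], v: int) -> list[list[str]]:
    """All v-token windows centered at each path position (out-of-range -> PAD)."""
    half = (v - 1) // 2
    n = len(path)
    windows = []
    for center in range(n):
        win = [
            path[j] if 0 <= j < n else PAD
            for j in range(center - half, center + half + 1)
        ]
        windows.append(win)
    return windows


@dataclass
class ContextSpec:
    """Contextual feature slots as token lists; each slot embeds to its mean."""

    slots: list[list[str]]


def contextual_slots(
    instance: RelationInstance,
    sentence: SentenceView,
    w: int,
    v_max: int,
) -> ContextSpec:
    """Assemble the contextual feature slots in fixed order.

    Order: chemical mention, disease mention, left then right context of the
    chemical, left then right context of the disease, then ``v_max`` slots of
    verbs strictly between the mentions (textual order, padded/truncated).
    Out-of-sentence context positions are ``<PAD>`` slots.
    """
    tree = sentence.tree
    forms = [t.form for t in tree.tokens]
    chem_idx = sentence.mention_token_indices(instance.chem_mention)
    dis_idx = sentence.mention_token_indices(instance.dis_mention)
    if not chem_idx or not dis_idx:
        raise ValueError(
            f"{instance.doc_id}: mention not aligned to sentence "
            f"{sentence.index} tokens"
        )
    half = (w - 1) // 2

    def context(indices: Sequence[int]) -> list[list[str]]:
        lo, hi = indices[0] - 1, indices[-1] - 1  # 0-based first/last token
        left = [
            [forms[lo - k]] if lo - k >= 0 else [PAD] for k in range(half, 0, -1)
        ]
        right = [
            [forms[hi + k]] if hi + k < len(forms) else [PAD]
            for k in range(1, half + 1)
        ]
        return left + right

    slots: list[list[str]] = [
        [forms[i - 1] for i in chem_idx],
        [forms[i - 1] for i in dis_idx],
    ]
    slots += context(chem_idx)
    slots += context(dis_idx)

    lo = min(instance.chem_mention.end, instance.dis_mention.end)
    hi = max(instance.chem_mention.start, instance.dis_mention.start)
    verbs = [
        t.form
        for t in tree.tokens
        if t.is_verb and t.char_start >= lo and t.char_end <= hi
    ]
    verb_slots = [[f] for f in verbs[:v_max]]
    verb_slots += [[PAD]] * (v_max - len(verb_slots))
    slots += verb_slots
    return ContextSpec(slots)


def n_context_slots(w: int, v_max: int) -> int:
    return 2 + 2 * (w - 1) + v_max


# ---------------------------------------------------------------------------
# Vocabulary and instance encoding


class Vocabulary:
    """Token -> index map with reserved ``<PAD>`` (0) and ``<UNK>`` (1)."""

    def __init__(self, tokens: Sequence[str] = ()):  # deterministic order kept
        self._index: dict[str, int] = {}
        for tok in SPECIALS:
            self._index[tok] = len(self._index)
        for tok in tokens:
            if tok not in self._index:
                self._index[tok] = len(self._index)

    @classmethod
    def from_corpus(
        cls,
        trees: Mapping[tuple[str, int], DependencyTree],
        extra: Sequence[str] = (),
    ) -> "Vocabulary":
        """Collect all surface forms and dependency labels, sorted."""
        tokens: set[str] = set()
        for tree in trees.values():
            for t in tree.tokens:
                tokens.add(t.form)
                tokens.add(t.deprel)
        tokens.update(extra)
        return cls(sorted(tokens))

    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def __getitem__(self, token: str) -> int:
        return self._index.get(token, self._index[UNK])

    @property
    def pad_id(self) -> int:
        return self._index[PAD]

    def tokens(self) -> list[str]:
        return list(self._index)

    def to_dict(self) -> dict[str, int]:
        return dict(self._index)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, int]) -> "Vocabulary":
        vocab = cls.__new__(cls)
        vocab._index = dict(sorted(mapping.items(), key=lambda kv: kv[1]))
        return vocab


@dataclass
class EncodedInstance:
    """Vocabulary-indexed features of one intra-sentence instance."""

    context_slots: list[list[int]]  # each slot embeds to the mean of its ids
    path_ids: np.ndarray  # (3, L_max) int32, PAD-padded R2C/R2D/C2D
    label: int | None = None


def encode_intra(
    instance: RelationInstance,
    sentence: SentenceView,
    vocab: Vocabulary,
    w: int,
    v_max: int,
    l_max: int,
) -> EncodedInstance:
    """Turn an intra instance into context slot ids and padded path ids."""
    spec = contextual_slots(instance, sentence, w, v_max)
    slot_ids = [[vocab[t] for t in slot] for slot in spec.slots]

    tree = sentence.tree
    chem_head = mention_head_token(
        tree, sentence.mention_token_indices(instance.chem_mention)
    )
    dis_head = mention_head_token(
        tree, sentence.mention_token_indices(instance.dis_mention)
    )
    r2c, r2d, c2d = extract_dependency_paths(tree, chem_head, dis_head)
    rows = [
        [vocab[t] for t in pad_path(r2c, l_max, keep_tail=True)],
        [vocab[t] for t in pad_path(r2d, l_max, keep_tail=True)],
        [vocab[t] for t in pad_path(c2d, l_max, keep_tail=False)],
    ]
    return EncodedInstance(
        context_slots=slot_ids,
        path_ids=np.asarray(rows, dtype=np.int32),
        label=instance.label,
    )
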