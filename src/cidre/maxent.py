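"""Maximum-entropy (L2 logistic regression) classifier for inter-sentence pairs.

Cross-sentence chemical–disease mention pairs get sparse indicator features:
mention surfaces and lemmas, side-prefixed bags of sentence lemmas, the
sentence-distance bucket, title flags, per-concept mention-count buckets and
verb-lemma features (plain and interacted with the distance bucket).  The
weights maximize the L2-penalized log-likelihood; the problem is convex, so
the optimum is unique and the fit is deterministic given the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.optimize
import scipy.sparse as sp

from .corpus import CHEMICAL, DISEASE, Document, SentenceView
from .instances import NEGATIVE, POSITIVE, RelationInstance


def _bucket(n: int) -> str:
    return str(n) if n < 3 else "3+"


def extract_inter_features(
    instance: RelationInstance,
    doc: Document,
    sentences: Sequence[SentenceView],
) -> dict[str, float]:
    """Deterministic sparse feature expansion of one inter-sentence instance."""
    ci, di = instance.sentence_index_pair
    cs, ds = sentences[ci], sentences[di]
    feats: dict[str, float] = {}

    def put(name: str) -> None:
        feats[name] = 1.0

    put(f"chem_surf={instance.chem_mention.text.lower()}")
    put(f"dis_surf={instance.dis_mention.text.lower()}")
    for idx in cs.mention_token_indices(instance.chem_mention):
        put(f"chem_lemma={cs.tree.token(idx).lemma}")
    for idx in ds.mention_token_indices(instance.dis_mention):
        put(f"dis_lemma={ds.tree.token(idx).lemma}")

    dist = _bucket(instance.sentence_distance)
    put(f"dist={dist}")

    for side, view in (("cs", cs), ("ds", ds)):
        for tok in view.tree.tokens:
            put(f"{side}_lemma={tok.lemma}")
            if tok.is_verb:
                put(f"{side}_verb={tok.lemma}")
                put(f"{side}_verb+dist={tok.lemma}_{dist}")

    title_end = len(doc.title)
    if instance.chem_mention.end <= title_end:
        put("chem_in_title")
    if instance.dis_mention.end <= title_end:
        put("dis_in_title")
    if ci == 0 or di == 0:
        put("pair_touches_title")

    chem_count = sum(
        1 for m in doc.mentions
        if m.etype == CHEMICAL and instance.chem_id in m.concept_ids
    )
    dis_count = sum(
        1 for m in doc.mentions
        if m.etype == DISEASE and instance.dis_id in m.concept_ids
    )
    put(f"chem_count={_bucket(chem_count)}")
    put(f"dis_count={_bucket(dis_count)}")
    return feats


@dataclass
class MaxEntModel:
    """Logistic-regression weights over a frozen feature dictionary."""

    feature_index: dict[str, int]
    weights: np.ndarray  # (n_features,)
    bias: float
    l2: float
    meta: dict = field(default_factory=dict)

    def score(self, features: Mapping[str, float]) -> float:
        """Linear score; unseen features are dropped, never grown."""
        s = self.bias
        for name, value in features.items():
            idx = self.feature_index.get(name)
            if idx is not None:
                s += self.weights[idx] * value
        return s

    def predict(self, features: Mapping[str, float]) -> tuple[int, float]:
        """(label, probability of positive); ties at 0.5 go negative."""
        p = 1.0 / (1.0 + np.exp(-self.score(features)))
        p = min(max(p, 1e-12), 1.0 - 1e-12)
        return (POSITIVE if p > 0.5 else NEGATIVE, float(p))


def _design_matrix(
    featsets: Sequence[Mapping[str, float]], index: Mapping[str, int]
) -> sp.csr_matrix:
    rows, cols, vals = [], [], []
    for i, feats in enumerate(featsets):
        for name, value in feats.items():
            j = index.get(name)
            if j is not None:
                rows.append(i)
                cols.append(j)
                vals.append(value)
    return sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(featsets), len(index))
    )


def train_maxent(
    featsets: Sequence[Mapping[str, float]],
    labels: Sequence[int],
    l2: float = 1.0,
    x0: np.ndarray | None = None,
    gtol: float = 1e-7,
) -> MaxEntModel:
    """Fit weights by minimizing NLL + l2*||w||² (bias unpenalized).

    The objective is strictly convex for ``l2 > 0``; L-BFGS-B is run to a
    small projected-gradient tolerance, so restarts agree to ~1e-4.
    Degenerate single-class input is an error.
    """
    y = np.asarray(labels, dtype=float)
    if len(set(labels)) < 2:
        raise ValueError("training data must contain both classes")
    index: dict[str, int] = {}
    for feats in featsets:
        for name in feats:
            if name not in index:
                index[name] = len(index)
    X = _design_matrix(featsets, index)
    n, k = X.shape

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        w, b = theta[:k], theta[k]
        z = X @ w + b
        # log(1 + exp(z)) - y*z, stably
        nll = float(np.sum(np.logaddexp(0.0, z) - y * z))
        p = 1.0 / (1.0 + np.exp(-z))
        resid = p - y
        gw = X.T @ resid + 2.0 * l2 * w
        gb = float(resid.sum())
        return nll + l2 * float(w @ w), np.concatenate([gw, [gb]])

    theta0 = np.zeros(k + 1) if x0 is None else np.asarray(x0, dtype=float)
    result = scipy.optimize.minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 5000, "gtol": gtol, "ftol": 1e-14},
    )
    theta = result.x
    return MaxEntModel(
        feature_index=index,
        weights=theta[:k],
        bias=float(theta[k]),
        l2=l2,
        meta={"grad_norm": float(np.max(np.abs(objective(theta)[1]))),
              "converged": bool(result.success)},
    )


def predict_maxent(
    model: MaxEntModel, features: Mapping[str, float]
) -> tuple[int, float]:
    return model.predict(features)


def save_maxent(model: MaxEntModel, path) -> None:
    import json

    meta = {
        "format": "cidre-maxent-1",
        "features": model.feature_index,
        "bias": model.bias,
        "l2": model.l2,
        "meta": model.meta,
    }
    with open(path, "wb") as fh:
        np.savez(
            fh,
            _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            weights=model.weights,
        )


def load_maxent(path) -> MaxEntModel:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        if meta.get("format") != "cidre-maxent-1":
            raise ValueError(f"unrecognized checkpoint format: {meta.get('format')}")
        return MaxEntModel(
            feature_index=meta["features"],
            weights=data["weights"].copy(),
            bias=meta["bias"],
            l2=meta["l2"],
            meta=meta["meta"],
        )
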