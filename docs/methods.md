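# Methods

This note documents the model, the choices made where the design was open,
the synthetic data the package is validated on, and what those validations
do and do not show.

## Task and decomposition

A CID relation holds between a chemical and a disease *concept* (MeSH
identifier) at document level; the same concept may surface as several
mentions across sentences. The pipeline therefore (1) builds mention-pair
instances, (2) classifies them per sentence level, (3) merges instance
decisions back to concept pairs.

**Instance construction.** Every (chemical mention, disease mention) pair
sharing a sentence yields one intra-sentence instance per concept-ID
combination (composite annotations like `A|B` are split; mentions normalized
to `-1` are excluded — they cannot participate in concept-level relations).
A concept pair with *no* intra co-occurrence anywhere in the document is
represented at inter-sentence level instead: one instance per cross-sentence
mention pair within a 3-sentence window, or the single nearest pair if none
is that close (both the window and an all-pairs mode are configurable).
Building inter instances only for never-co-occurring pairs keeps the two
levels disjoint, which makes the merge step interpretable and prevents
double counting. Labels are assigned distantly: an instance is positive iff
its concept pair is annotated for the document. This is the standard noise
source of the task — a gold pair's unsupportive mention pairs are still
labeled positive.

**Hypernymy.** Concept `a` is a hypernym of `b` iff some MeSH tree number of
`a` is a *proper, segment-aligned* prefix of some tree number of `b`
(`C01.252` ⊑ `C01.252.400`, but `C01.25` is not a prefix of `C01.252`, and a
concept is never its own hypernym). During training, negative instances
whose chemical (disease) generalizes a chemical (disease) in any gold
relation of the same document are removed. At test time the same relation
prunes the predicted document-level pairs. The test-time filter runs after
merging and before post-processing: it is defined on document-level pairs,
and post-processed pairs exist precisely because the document came out
empty, so re-filtering them would be circular.

## The intra-sentence CNN

Shapes: T ∈ ℝ^(d₀×|V|); W₁ ∈ ℝ^(n₁×v·d₀); W₂ ∈ ℝ^(n₂×n_f) with
n_f = n₁ + d₀·(2 + 2(w−1) + V_max); W₃ ∈ ℝ^(n₃×n₂), n₃ = 2 (the task is
binary: positive/negative).

Decisions where the architecture description leaves room:

* **Padding and pooling.** Paths are right-padded with `<PAD>` to a fixed
  length (default L_max = 40 tokens; longer paths are truncated keeping the
  mention end for root paths and the chemical end for the chemical-disease
  path). The `<PAD>` embedding column is structurally zero: it is excluded
  from the L2 penalty, receives no gradient, and is reset after every
  update. Max-pooling by default ignores columns whose *center* token is
  `<PAD>` — pooling over padding would let a zero column win whenever all
  real activations of a filter are negative; the literal variant is
  available behind `pool_include_pad` for comparison. Pooling spans all
  three path blocks jointly (the pooled matrix covers all 3l columns);
  `pool_per_path` pools each path separately and triples the dependency
  feature size.
* **Dropout.** Inverted scaling (`h = r∘m/(1−p)` at training) so the test
  network is exactly the undropped forward pass — no test-time rescaling.
* **Verbs.** "Verbs between the mentions" is operationalized as tokens with
  POS prefix `VB` whose character span lies strictly between the mention
  spans, in textual order, truncated to V_max = 5 slots.
* **Mention heads for paths.** The path endpoint of a multi-token mention is
  the unique mention token whose governor lies outside the mention; if zero
  or several qualify, the last token.
* **Regularization.** λ‖θ‖² covers every parameter including biases and the
  full embedding table (minus the `<PAD>` column). The penalty is applied
  densely each batch; at this package's vocabulary sizes (10²–10⁴ tokens)
  that costs little and keeps the analytic gradient exactly equal to the
  objective's.
* **Optimization.** AdaGrad with per-coordinate accumulators,
  update = lr·g/√(G+ε), ε = 10⁻⁸, default 15 epochs of shuffled mini-batches.
  All randomness (initialization, shuffling, dropout) derives from one seed;
  identical seeds give bit-identical parameters. Embeddings without a
  supplied pretrained vector are initialized uniform(−0.05, 0.05), as are
  all weight matrices. Non-finite losses abort training.

Gradient correctness is not assumed: the test suite checks every parameter
in θ against central finite differences (relative error < 10⁻⁴ at step
10⁻⁵, with frozen dropout masks), and the convolution/pooling stage against
a naive loop implementation (agreement to 10⁻¹⁰).

## The inter-sentence maximum-entropy classifier

Binary L2 logistic regression over sparse indicator features: mention
surface and lemmas, side-prefixed lemma bags of the two host sentences,
sentence-distance bucket (1/2/3+), chemical/disease-in-title flags, whether
either host sentence is the title, per-concept mention-count buckets, and
verb lemmas per side — both alone and interacted with the distance bucket
(cross-sentence relations are typically signalled by a verb *at a
particular discourse distance*, which a purely additive verb feature cannot
express). The feature dictionary grows only during training; unseen test
features are dropped. The penalized likelihood is strictly convex, so the
optimizer (L-BFGS on the analytic gradient) is run to a small
projected-gradient tolerance and restarts agree to ~10⁻⁴; an independent
logistic-regression implementation is used as a cross-check in the tests.
Ties at probability exactly 0.5 resolve to negative, favoring precision.

## Document assembly

A concept pair is asserted iff at least one of its instances is predicted
positive; the reported confidence is the maximum over positive supporters
and the provenance records the supporting level. Post-processing fires only
for documents with an empty prediction set: (a) every chemical mentioned
within the title span is paired with every disease concept of the document;
(b) if the title has no chemical, the most frequently mentioned chemical is
used, ties broken by earliest first mention. A document lacking either
entity type stays empty. The rules are idempotent by construction.

## Synthetic corpora

The generator emulates the statistical shape of the real corpus rather than
its language: 3–6 chemicals and 2–5 diseases per abstract, about two gold
relations per document with at least one guaranteed (the real corpus is
curated from a relation database, at roughly 2 relations per article), and
rare inter-sentence positives (inter-sentence recall is known to be the
weak point of this task). Sentences come from subject–verb–object templates
with hand-built dependency trees; a pair is positive iff a trigger verb
("induced", "caused", …) links its mentions in one sentence, or a
two-sentence drug-anaphora template ("The physician administered X." /
"This drug provoked Y.") spans them. Non-trigger verbs ("accompanied", …)
produce co-occurring negatives. Template geometry keeps every
chemical-to-disease path at ≤ 9 tokens, so the default path window covers
whole paths. A tree-numbered toy ontology provides hypernym ancestors, and
a configurable fraction of documents mention a drug-class ancestor of a
positive chemical in a negative sentence, exercising both filter stages.

`noise_rate` models annotation disagreement (the real corpus's
inter-annotator agreement is limited): each planted positive is dropped
with that probability, and negatives among mentioned concept pairs are
flipped in at a matched expected count, so the noise is symmetric in
expectation. Noise draws use a separate random stream, so the same seed
yields the same document structure at any noise level. Generation is a pure
function of the configuration; equal configurations give byte-identical
corpora.

**What passing tests show — and don't.** The planted signal is linearly
recoverable by construction (a rule-based reference labeler scores F = 1.0
at zero noise), so recovery failures localize bugs in the pipeline rather
than in the data. The end-to-end check (400 training / 100 test documents,
5% noise, scaled network d₀=50, n₁=40, n₂=80 — sizes chosen so the full run
takes well under a minute on one CPU) requires the pipeline to reach F ≥
0.90 while the majority-class control stays ≤ 0.30. This demonstrates
correct mechanics and a learnable signal path; it does *not* predict scores
on real abstracts, whose lexical variety, parse errors, co-reference and
discourse structure the templates deliberately do not model.

## Known limitations

* No co-reference or discourse inference: an inter-sentence relation whose
  evidence is anaphoric beyond the feature templates will be missed.
* The post-processing heuristics trade precision for recall aggressively;
  on corpora where many documents truly contain no relation they should be
  disabled (`--no-post-processing`).
* Sentence segmentation is taken from the parse file; the package never
  re-tokenizes or re-parses text.
* The CNN is CPU-only and single-width; position embeddings, attention and
  multiple filter sizes are out of scope.
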