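# Methods

`ontolord` implements a three-phase strategy for training text encoders that
represent ontology concepts well without sacrificing general sentence
semantics, together with a cross-lingual distillation step and the evaluation
harness used to measure all of it. This note records the model, the
parameters that matter, what the synthetic study fixture does and does not
emulate, and the design decisions taken where the design was genuinely open.

## The training strategy

**Phase 1 — contrastive learning of names against definitions.** The training
corpus pairs each concept name (anchor) with that concept's definitions —
human-written and machine-generated definitions play the same role — and with
short template verbalizations of the knowledge-graph relations the concept
participates in ("{subject} is a concept that may treat {object}"). Batches
contain B pairs over B *distinct* concepts; the loss is the InfoNCE softmax
cross-entropy over the B×B cosine matrix divided by a temperature τ, with the
diagonal as the true class, symmetrized over the name→definition and
definition→name directions. Distinctness is enforced by the batch sampler so
that no in-batch negative is a false negative. A light semantic-textual-
similarity (STS) adaptation — one full-batch gradient step per epoch on
MSE(cos(e₁,e₂), gold/5) — runs before and again after the contrastive epochs,
anchoring the encoder to sentence-level human judgment.

**Phase 2 — self-distillation.** The phase-1 model (the teacher) embeds each
concept's preferred name and one definition (generated preferred, falling
back to human; name-only concepts reuse the name embedding); the two vectors
are averaged per concept, and the averaged bank is reduced by principal
component analysis. A fresh student — initialized from the *STS-adapted base*,
not from the teacher — is trained so that a randomly initialized linear
projection head maps its embedding of *every* textual variant of a concept
(all names, noisy name copies, all definitions) to that concept's reduced
target, under plain MSE. The head is discarded at export; the deliverable is
the student's own full-dimension embedding. The mechanism that makes this
gentle: gradients reach the student only through the head's d×D matrix, so
updates to the embedding geometry are confined to a d-dimensional subspace
and the complement — where much of the general-language geometry lives — is
untouched.

**Phase 3 — weight averaging.** Different head seeds give slightly different
students; their parameters are averaged elementwise (a uniform "model soup";
no greedy member selection). The mean is computed as
`first + mean(member − first)`, which is exact when members coincide.
Projection heads are seed-specific and never enter the soup.

**Cross-lingual distillation.** A multilingual student (initialized as a copy
of the souped teacher) is trained on a parallel corpus so that both sides of
each pair land on the frozen teacher's embedding of the source text:
`MSE(s(src), t(src)) + MSE(s(tgt), t(src))`. Parallel pairs can also be mined
from per-language name lists by mutual-best cosine alignment under a
pluggable scorer with a score threshold (default 0.8).

## The reference encoder

All phases are encoder-agnostic behind a small contract (`encode`,
`parameters`). The trainable reference implementation hashes character
n-grams (murmur3) into a fixed number of buckets, L2-normalizes the count
vector, applies a trainable linear map `W` (D × buckets), and L2-normalizes
the output. Similarity is cosine everywhere, hence a dot product on the
normalized vectors. Gradients are analytic; optimization is plain SGD with a
fixed learning rate, with updates scattered only onto the hash columns active
in the batch.

Defaults (also the fixture's study conditions):

| parameter | default | why |
|---|---|---|
| dimension D | 64 | small enough for seconds-scale training; large enough that cross-concept cosine noise (≈1/√D) does not swamp a 50-concept geometry |
| hash buckets | 16384 | comfortably above the (2,3)-gram space of the fixture's alphabet, so distinct n-grams rarely share a column — a requirement for the cross-lingual column mapping to be learnable |
| n-gram range | (2,3) | bigrams give robustness to character noise; trigrams give discrimination; 4-grams were excluded because they inflate the feature space past what a desk-scale parallel corpus can pin down |
| init scale | 0.05 | cosine structure is scale-invariant, but a small initialization keeps never-trained columns (hit only by novel n-grams in noisy mentions) from drowning the trained signal |
| τ (temperature) | 0.2 | with unit-norm embeddings the InfoNCE gradient vanishes once the positive-negative gap is a few τ wide; 0.2 keeps synonyms contracting long enough to cluster tightly. Exposed in config |
| batch size B | 8 | 7 in-batch negatives suffice at 50 concepts |
| contrastive epochs / lr | 120 / 1.0 | past the loss plateau; chosen for the fixture's scale |
| STS adaptation epochs / lr | 50 / 2.0 | full-batch steps on the small STS train split |
| PCA target dim d | 64 at the library level; 48 in the fixture pipeline | 64 follows the reduction the method prescribes at full scale. A 50-concept bank has centered rank 49, so the fixture reduces its D=64 space to d=48 — a real projection that still keeps the teacher geometry representable |
| distill epochs / lr / head decay | 200 / 0.5 / 0.01 | decay on the *head only* forces the student embedding, not the head, to carry the target geometry, leaving the complement subspace intact |
| soup members | 3 | config-exposed |
| cross-lingual epochs / lr | 200 / 0.5 | the column-level translation mapping converges slowly; 200 epochs over the full parallel corpus reach the residual floor |

Pretrained transformer sentence encoders can be plugged in behind the same
contract via `FunctionEncoder` (inference only); nothing in the test suite
depends on them.

## The synthetic study fixture

The generator (`ontolord.synth`) produces, from one seed, everything the
pipeline consumes: an ontology, STS/BCR/NEL benchmarks, and parallel corpora.

* **Topics and concepts.** Concepts are grouped into latent topics (default
  5 × 10). Definitions mix three topic-level tokens (shared within the
  topic), two concept-specific tokens, and a filler-vocabulary token, the way
  real definitions mix domain vocabulary with term-specific content.
* **Synonyms are lexically unrelated.** A concept's names (default 4) are
  independent surface forms, as brand and generic drug names are. Linking
  them is only possible through the shared definitions — the regime
  definition-grounded contrastive learning targets. A generator whose
  synonyms shared a visible token core would let any string-overlap baseline
  link mentions, and the before/after contrast would be meaningless.
* **Tokens are consonant-vowel syllables** from a 14×5 inventory, so the
  character-n-gram space is compact and coverable.
* **Mentions** are character-perturbed (swap/delete/duplicate at rate 0.1 per
  character) held-out synonyms — names seen in training but absent from the
  retrieval dictionary, and never string-equal to any dictionary entry. This
  forces generalization, not lookup, and mimics informal spelling variation.
* **Gold labels** derive from the latent structure — same concept 5.0, same
  topic 2.5, unrelated 0.0 on the STS scale — with uniform ±0.5 jitter
  clipped to [0,5], so perfect correlations are unattainable by construction.
* **General-language STS.** A separate benchmark of filler-vocabulary
  sentence pairs (graded by token overlap) that no training phase ever sees.
  It plays the role of general-domain similarity benchmarks: the in-domain
  STS split used for adaptation cannot restore it, so it isolates what
  concept training does to the rest of the embedding space.
* **Languages are bijective character ciphers** (alphabet permutations,
  space fixed) — deterministic, invertible stand-ins for translations that
  preserve pair structure with no external resource. The parallel corpus
  contains the names and definitions of 80% of concepts plus 6000 short
  "prose" lines of fresh syllable tokens; the held-out 20% of concepts'
  names evaluate generalization. The prose matters: learning the cipher at
  the hash-column level is a linear dictionary-translation problem, and it
  is identifiable only when the number of parallel texts exceeds the number
  of active feature columns.

**What passing tests do and do not show.** The fixture shows that each phase
does the job its design claims — synonym linking emerges from definitions,
distillation transfers geometry while preserving an untouched general task,
averaging and cipher distillation behave as specified — under a linear
bag-of-n-grams encoder on a 50-concept world. It does not show anything
about real clinical language: no polysemy, no compositional syntax, no
distribution shift between formal and informal registers beyond character
noise, and the paper-scale headline numbers (which require licensed
terminologies, pretrained transformers, and GPU fine-tuning) are out of
reach by design.

## Numerical choices and degenerate inputs

* Embedding norms are floored at 1e-12 before division; a text shorter than
  the smallest n-gram contributes itself as a single feature, so no input
  has an empty feature set.
* InfoNCE validates that inputs are unit-norm (tolerance 1e-3) and returns
  exactly 0 for a single-pair batch (single-logit softmax).
* PCA components are sign-fixed (largest-magnitude coordinate positive) so
  transforms are reproducible across runs and backends.
* NEL scores a concept by its best-scoring name; ties break by first
  dictionary occurrence — dictionary row order is the documented tie-break.
* Correlations raise an explicit error when a score series has zero
  variance rather than returning NaN.
* All randomness flows through named integer seeds via NumPy Generators;
  reruns of any phase with the same seed are bit-identical.

## Geometry-recovery measurement

Teacher-student agreement after self-distillation is measured as the
Spearman correlation between the two models' pairwise concept cosine
matrices, where a concept's embedding is its name/definition average (the
same construct the distillation targets are built from) and each bank is
mean-centered before computing cosines. Centering follows the standard
practice for comparing representational geometries across models; here it is
also the faithful choice, because the common-mean (anisotropy) component is
exactly what the distillation phase is designed *not* to transfer — its
targets are PCA-centered by construction.

## Known limitations

* The reference encoder is linear over hashed n-gram counts: it cannot model
  word order or long-range composition, and hash collisions softly couple
  unrelated features (mitigated by the bucket count).
* Cross-lingual transfer requires n-gram-level coverage by the parallel
  corpus; a morphologically creative "language" (not expressible as a
  character bijection) would need a far larger corpus or a subword encoder.
* The soup averages every parameter, including any normalization statistics
  a pluggable encoder might carry; members must come from the same
  architecture and comparable training trajectories.
* Desk-scale problem sizes throughout (50 concepts, ~100 mentions, ~6800
  parallel pairs) were chosen so the full pipeline trains in minutes on one
  CPU; users with real ontologies should expect to re-tune epochs, τ, and
  the PCA dimension.
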