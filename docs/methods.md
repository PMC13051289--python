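# Methods

`subtypebench` implements the machinery of a benchmark that contrasts two
ways of classifying short social-media posts into six depression-related
content categories — five subtype classes (postpartum, major, bipolar,
psychotic, atypical) and a no-depression class: few-shot multiple-choice
prompting of instruction-tuned causal language models, and supervised
fine-tuning of transformer encoders with low-rank adapters. The package
reimplements the protocols, the training objective and the evaluation layer
as tested, reusable code, and exercises them end to end on synthetic
corpora so that no dataset download, pretrained checkpoint or GPU is needed.

Labels here are content annotations of individual posts, not diagnoses; the
package treats them purely as a six-way single-label classification target.

## Task and data model

Each example is a pair (x_i, y_i): a short text and exactly one label from
the six classes, fixed in letter order A=postpartum, B=major, C=bipolar,
D=psychotic, E=no-depression, F=atypical. That order is also the option
order of the multiple-choice prompt and the axis order of every confusion
matrix. Text normalisation is deliberately minimal — Unicode NFC, collapsed
whitespace, stripped ends — with no negation or sarcasm handling, so both
protocol tracks see the same surface form.

Splitting is stratified per class: within each class, a seeded shuffle
followed by contiguous slicing, with slice sizes set by largest-remainder
rounding so per-class counts land within ±1 of expectation. Exact-duplicate
texts (after normalisation) are collapsed to their first occurrence before
splitting, so no text appears in two partitions. The default 0.8/0.1/0.1
ratio is a convention, configurable everywhere; nothing downstream depends
on it.

## Synthetic corpora

The generator emulates the structural properties the pipeline depends on,
not tweet semantics:

- **Class proportions.** Defaults are the benchmark corpus's empirical mix
  (postpartum 24.9%, major 16.8%, bipolar 16.3%, psychotic 15.4%, atypical
  13.2%, no-depression 13.2%). The printed percentages sum to 99.8%, so they
  are renormalised rather than padded — this preserves the relative
  composition. Integer counts come from largest-remainder apportionment
  (ties by class order), which is exact, deterministic and independent of
  the PRNG.
- **Confusability.** The clinically confusable triple {major, atypical,
  bipolar} can share a vocabulary pool at a controllable rate (`overlap`),
  reproducing at desk scale the error structure real models show: as
  overlap grows, a keyword-count oracle's errors concentrate inside the
  triple while off-block errors stay near zero.
- **Noise.** A class-neutral token pool (`noise_rate`, default 0.1) and
  occasional URL/@mention tokens (`url_mention_rate`, default 0.1) give the
  exemplar-selection filters something to filter.
- **Vocabulary.** All tokens are seeded CV-syllable pseudo-words, never real
  clinical language: the tests exercise separability, confusability and
  imbalance, not semantics. Text lengths are uniform over 5–40 tokens, a
  free choice (no length distribution is published for the corpus).
  Colliding texts get a disambiguating `dupN` token so uniqueness is exact.

Because the generator plants the decision structure explicitly, passing
recovery tests show the *protocols* are implemented correctly — they say
nothing about absolute performance on real language, which needs the real
corpus and real backbones (explicitly out of scope here).

## Few-shot prompting protocol

A target is classified by a fixed prompt: one instruction line, the six
options in letter order, six labelled exemplars (one per class, drawn once
from the training split with a fixed seed, preferring short, clean texts —
no URL/@mention substrings, ≤120 characters, falling back with a flag to
the shortest example when a class has no clean candidate), the target, and
an `Answer:` cue. Each option letter is scored by its log-probability under
a pluggable next-token scorer; both the bare and space-prefixed letter
surface forms are scored and max-pooled, since tokenizers differ on leading
spaces. Scores are renormalised over the six letters (argmax-preserving, so
voting is unaffected).

Self-consistency uses k=5 prompt realizations. With a deterministic scorer
the only available stochastic degree of freedom is the exemplar order, so a
realization permutes the six exemplar lines (seeded by realization index)
and nothing else; this is one admissible operationalisation of "independent
realizations" and is documented as such. The final label is the majority
letter; ties break by the tied letters' summed log-probability across
realizations, then by letter order, with a flag recording that a tie-break
fired. The protocol performs no parameter updates.

The shipped scorer is a mock: it scores letters by lexicon-hit counts of
the target text (sharpness-scaled) plus a small seeded perturbation. It
exists to exercise the protocol; any real causal-LM backend that can return
log-probabilities for candidate continuations satisfies the same contract.

## Training objective

For logits z ∈ R^6, true class y, and training-split class counts n_c:

- **Class-balanced weights** w_c ∝ (1−β)/(1−β^{n_c}), β=0.999, normalised
  by the across-class mean so mean(w)=1. β^{n_c} is computed as
  exp(n_c log β) to avoid underflow at corpus-scale counts.
- **Margins** m_c = C₀ n_c^{−1/4}, C₀=0.5, subtracted from the true-class
  logit only. This is the printed form, used exactly as printed; the
  original label-distribution-aware margin formulation additionally
  normalises by the largest margin, a variant deliberately not implemented.
- **Focal term** w_y (1−p̃_y)^γ (−log p̃_y), γ=2, with p̃ the softmax of the
  margin-shifted logits via a stable log-sum-exp.
- **R-Drop** ½[KL(p⁽¹⁾‖p⁽²⁾) + KL(p⁽²⁾‖p⁽¹⁾)] between the softmax outputs
  of two dropout-perturbed forward passes, weight λ_rd=0.5. Probabilities
  are clipped below at 1e-12 before logs, since near-one-hot softmax
  outputs are routine late in training.
- **Pairwise hinge** on bipolar-labelled examples only: max(0, δ−(z_bip −
  z_no)) + max(0, δ−(z_bip − z_aty)), δ=0.15, weight λ_pair=0.15, pushing
  the bipolar logit clear of its two most confusable competitors. The
  published objective does not state which stochastic pass this is computed
  on; it is averaged over both, for symmetry with the focal term.
- **Total** L = ½(focal⁽¹⁾+focal⁽²⁾) + λ_rd·RDrop + λ_pair·Pair, reduced by
  the batch mean (per-example losses are what is published; the mean makes
  the learning rate batch-size invariant).

Class counts always come from the training split only — no frequency
information leaks from validation or test. Imbalance is handled entirely at
the loss level; there is no over- or under-sampling anywhere.

Analytic gradients of the total with respect to both logit vectors are
implemented alongside the values (the softmax Jacobian is 6×6, so this is
cheap) and verified against central finite differences to 1e-4 relative
error in the tests.

## Fine-tuning recipe

The recipe is expressed against a trainable-encoder contract: tokenise and
head-truncate to 160 tokens (including specials), run two stochastic
forward passes per batch with distinct dropout masks, expose named
projection modules for adapter injection with base weights frozen, and
support AdamW (decoupled weight decay 0.03), gradient-norm clipping at 1.0,
and a linear-warmup (ratio 0.06) cosine-decay-to-zero schedule at peak rate
2e-4 shared by the classifier head and adapter parameters. Adapter defaults
are rank 8, α=16, dropout 0.05. DeBERTa-style encoders attach adapters to
`query_proj/key_proj/value_proj/dense`; other supported encoder families to
`query/key/value` and the feed-forward projections. Training runs up to 10
epochs with early stopping on validation macro-F1 (patience 2, improvement
threshold 5e-4; an epoch improves only if it beats the best by at least the
threshold), and the best epoch's weights are restored at the end — the
restoration is standard practice, chosen here since the published recipe is silent on it.
Decoding is argmax over logits from a single deterministic pass, or over
the mean of several dropout-active passes when MC-dropout averaging is
requested.

The shipped implementation of the contract is a deterministic numpy
fixture: hashed bag-of-tokens features (512-dim), frozen random projections
named `query/key/value` (averaged) with a residual `ffn_in→ffn_out` block
(64-dim), dropout on the pooled representation, and a zero-initialised
linear head. LoRA adapters (A small random, B zero, scaled α/r) make
injection a no-op at initialisation, and the trainable count is exactly
r·(fan_in+fan_out) per module plus the head — two orders of magnitude below
the frozen base. Desk-scale runs use learning rate 0.01 rather than the
2e-4 default: AdamW's update magnitude is ~lr per step regardless of
gradient scale, and a freshly initialised linear model on a few hundred
examples (~600 steps) needs a step size suited to its own scale, whereas
2e-4 is sized for nudging a pretrained transformer. The 2e-4 default is
kept as the config default; the fixture runs pass their rate explicitly.

Problem sizes for the shipped analyses and tests: corpora of 120–1,200
examples, 10-epoch budgets, 1,000-pass MC-dropout checks. On a separable
(overlap 0) corpus the recipe reaches validation macro-F1 ≥ 0.99 within the
budget, matching a convex logistic-regression oracle fitted on the same
features.

## Evaluation

Macro-F1 — the unweighted mean of per-class F1 — is the primary metric;
accuracy, macro precision and macro recall are secondary. Confusion
matrices are tallied in canonical label order. Zero-denominator classes
(empty row or column) get precision/recall/F1 = 0 with an explicit flag and
still count in macro means; the convention is conservative and matches the
common library default. When values are compared against printed
percentages, fractions are rounded half-up to one decimal on the percentage
scale.

The published benchmark's tables (14 models × validation/test × four
metrics) and the in-text confusion counts for the two best models are
transcribed as fixtures. The published confusion matrices are only
partially printed, so the fixtures store known cells, row totals and column
totals sparsely and never impute missing entries; the table's
precision/recall columns are treated as macro-averaged, consistent with the
macro framing of the evaluation (an interpretation — the published tables
do not say). Best-vs-best comparison selects each track's best model by the
primary metric (macro-F1), ties to the first listed model, and reports the
delta on the requested metric in percentage points; this reproduces both
the +19.2 pp macro-F1 and the +20.4 pp accuracy gaps, the latter being the
gap between the two macro-F1-best models rather than the column-wise
maximum.

## Limitations

- Absolute scores of the published models are not reproducible here by
  design: they require the real 15k-tweet corpus, pretrained 100M–900M
  parameter backbones, and GPU fine-tuning. The package verifies protocol
  correctness, metric arithmetic and recovery of planted structure.
- The mock scorer reads the generating lexicon, so on synthetic data the
  few-shot track is a ceiling rather than the weaker baseline it is with
  real language models; only the error *structure* (confusable-block
  concentration) transfers.
- The prompt template wording and the realization mechanism are fixed,
  versioned choices; the published prompt text is not available.
- Whether validation macro-F1 during training used MC-dropout averaging is
  unstated in the published setup; the default here is a single deterministic pass.
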