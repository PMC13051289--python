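"""Seeded generator of tweet-like six-class corpora for desk-scale testing.

The generator emulates the structural features of the real annotated tweet
corpus that the pipeline stages depend on: six mutually exclusive classes at
the published benchmark's empirical proportions (postpartum 24.9%, major 16.8%, bipolar
16.3%, psychotic 15.4%, atypical 13.2%, no-depression 13.2%), short noisy
token sequences, class-specific vocabulary with a controllable amount of
vocabulary shared between the clinically confusable triple
{major, atypical, bipolar}, and occasional URL/@mention tokens so that
exemplar-selection filters have something to filter.

Vocabularies are seeded pseudo-words, not real clinical language: the
pipeline's tests exercise structure (separability, confusability, imbalance),
not semantics.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .corpus import (
    LABEL_ORDER,
    N_CLASSES,
    Corpus,
    CorpusError,
    LabeledExample,
    SubtypeLabel,
)

__all__ = [
    "BENCHMARK_PROPORTIONS",
    "CONFUSABLE_TRIPLE",
    "GeneratorConfig",
    "Lexicon",
    "allocate_counts",
    "build_lexicon",
    "generate_corpus",
    "keyword_classifier",
    "MockLetterScorer",
    "make_mock_scorer",
]

#: Empirical class proportions of the benchmark corpus, in canonical label order
#: (postpartum, major, bipolar, psychotic, no_depression, atypical).  The
#: printed percentages sum to 99.8%; they are renormalised wherever used.
BENCHMARK_PROPORTIONS: tuple[float, ...] = (0.249, 0.168, 0.163, 0.154, 0.132, 0.132)

#: The clinically confusable triple that shares vocabulary under overlap > 0.
CONFUSABLE_TRIPLE: frozenset[SubtypeLabel] = frozenset(
    {SubtypeLabel.MAJOR, SubtypeLabel.ATYPICAL, SubtypeLabel.BIPOLAR}
)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic corpus generator.

    overlap controls the rate at which the confusable triple draws from a
    shared vocabulary pool; noise_rate the rate of class-neutral filler
    tokens; url_mention_rate the fraction of texts receiving a URL or
    @mention token.
    """

    n_total: int = 600
    proportions: Sequence[float] = BENCHMARK_PROPORTIONS
    overlap: float = 0.0
    noise_rate: float = 0.1
    url_mention_rate: float = 0.1
    length_range: tuple[int, int] = (5, 40)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_total < N_CLASSES:
            raise ValueError(f"n_total must be >= {N_CLASSES}, got {self.n_total}")
        if len(self.proportions) != N_CLASSES or any(p <= 0 for p in self.proportions):
            raise ValueError("proportions must be six positive fractions")
        for name in ("overlap", "noise_rate", "url_mention_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.length_range[0] < 3 or self.length_range[1] < self.length_range[0]:
            raise ValueError(f"invalid length_range {self.length_range}")


def allocate_counts(n_total: int, proportions: Sequence[float]) -> np.ndarray:
    """Apportion n_total into six class counts by largest-remainder rounding.

    Proportions are renormalised to sum to 1 first; exact quotas are floored
    and the remainder distributed by largest fractional part, ties broken by
    canonical class order.  Counts always sum exactly to n_total.
    """
    if n_total < N_CLASSES:
        raise ValueError(f"n_total must be >= {N_CLASSES}, got {n_total}")
    p = np.asarray(proportions, dtype=float)
    if p.shape != (N_CLASSES,) or np.any(p <= 0):
        raise ValueError("proportions must be six positive fractions")
    p = p / p.sum()
    quotas = p * n_total
    counts = np.floor(quotas).astype(int)
    order = np.argsort(-(quotas - counts), kind="stable")
    for c in order[: n_total - int(counts.sum())]:
        counts[c] += 1
    return counts


_CONSONANTS = "bcdfghjklmnpqrstvwz"
_VOWELS = "aeiou"


def _pseudo_words(rng: np.random.Generator, n: int, taken: set[str]) -> list[str]:
    """n distinct CV-syllable pseudo-words not colliding with `taken`."""
    words: list[str] = []
    while len(words) < n:
        syllables = rng.integers(2, 4)
        word = "".join(
            _CONSONANTS[rng.integers(len(_CONSONANTS))]
            + _VOWELS[rng.integers(len(_VOWELS))]
            for _ in range(syllables)
        )
        if word not in taken:
            taken.add(word)
            words.append(word)
    return words


@dataclass
class Lexicon:
    """Per-class, shared-confusable and neutral token pools.

    With overlap = 0 the six per-class lists are pairwise disjoint; the
    shared pool is only ever sampled by the confusable triple, at a rate
    equal to the generator's overlap parameter.
    """

    class_tokens: dict[SubtypeLabel, list[str]] = field(default_factory=dict)
    shared_tokens: list[str] = field(default_factory=list)
    neutral_tokens: list[str] = field(default_factory=list)

    def effective_vocabulary(self, label: SubtypeLabel) -> frozenset[str]:
        """Tokens diagnostic of `label`: its own list plus the shared pool
        when the label belongs to the confusable triple."""
        tokens = set(self.class_tokens[label])
        if label in CONFUSABLE_TRIPLE:
            tokens.update(self.shared_tokens)
        return frozenset(tokens)


def build_lexicon(
    seed: int, tokens_per_class: int = 40, shared_size: int = 30, neutral_size: int = 40
) -> Lexicon:
    """Build a seeded pseudo-word lexicon with disjoint pools."""
    rng = np.random.default_rng(seed)
    taken: set[str] = set()
    lex = Lexicon(
        class_tokens={
            label: _pseudo_words(rng, tokens_per_class, taken) for label in LABEL_ORDER
        },
        shared_tokens=_pseudo_words(rng, shared_size, taken),
        neutral_tokens=_pseudo_words(rng, neutral_size, taken),
    )
    return lex


def generate_corpus(
    config: GeneratorConfig, lexicon: Lexicon | None = None
) -> tuple[Corpus, Lexicon]:
    """Generate a corpus with exactly the allocated per-class counts.

    Deterministic given config.seed.  Each text is a space-joined token
    sequence drawn from the class's own pool, the shared confusable pool
    (triple classes only, at rate `overlap`) and the neutral pool (at rate
    `noise_rate`); `url_mention_rate` of texts receive a synthetic URL or
    @mention token.  Texts are globally unique: a colliding draw gets a
    disambiguating ``dupN`` token appended.
    """
    rng = np.random.default_rng(config.seed)
    lex = lexicon if lexicon is not None else build_lexicon(config.seed)
    counts = allocate_counts(config.n_total, config.proportions)

    lo, hi = config.length_range
    examples: list[LabeledExample] = []
    seen_texts: set[str] = set()
    dup_counter = 0
    for label, n_class in zip(LABEL_ORDER, counts):
        own = lex.class_tokens[label]
        in_triple = label in CONFUSABLE_TRIPLE
        for _ in range(n_class):
            n_tokens = int(rng.integers(lo, hi + 1))
            tokens: list[str] = []
            for _ in range(n_tokens):
                u = rng.random()
                if u < config.noise_rate:
                    pool = lex.neutral_tokens
                elif in_triple and u < config.noise_rate + (
                    1 - config.noise_rate
                ) * config.overlap:
                    pool = lex.shared_tokens
                else:
                    pool = own
                tokens.append(pool[int(rng.integers(len(pool)))])
            if rng.random() < config.url_mention_rate:
                extra = (
                    f"http://t.co/{int(rng.integers(10 ** 6)):06d}"
                    if rng.random() < 0.5
                    else f"@user{int(rng.integers(10 ** 4))}"
                )
                tokens.insert(int(rng.integers(len(tokens) + 1)), extra)
            text = " ".join(tokens)
            while text in seen_texts:
                dup_counter += 1
                text = " ".join(tokens + [f"dup{dup_counter}"])
            seen_texts.add(text)
            examples.append(
                LabeledExample(id=f"synth-{len(examples):06d}", text=text, label=label)
            )
    # seeded interleave so labels are not block-ordered downstream
    perm = rng.permutation(len(examples))
    return Corpus([examples[i] for i in perm]), lex


def keyword_classifier(lexicon: Lexicon) -> Callable[[str], SubtypeLabel]:
    """A trivial oracle classifier: argmax of per-class lexicon-hit counts.

    Shared-pool tokens count as hits for all three confusable classes; ties
    are broken by canonical class order.  On an overlap=0, noise-free corpus
    this oracle is perfect by construction; as overlap grows its errors
    concentrate inside the confusable block.
    """
    vocab = {label: lexicon.effective_vocabulary(label) for label in LABEL_ORDER}

    def classify(text: str) -> SubtypeLabel:
        tokens = text.split()
        hits = [sum(tok in vocab[label] for tok in tokens) for label in LABEL_ORDER]
        return LABEL_ORDER[int(np.argmax(hits))]

    return classify


class MockLetterScorer:
    """Deterministic desk-scale stand-in for an LLM's next-token letter scoring.

    Conforms to the scorer contract used by the prompting module: given a
    rendered prompt and candidate continuation strings, returns one finite
    log-probability per candidate.  The target tweet is parsed from the
    prompt's ``Tweet:`` line; each option letter is scored by
    sharpness x (lexicon-hit count for that letter's class), plus a small
    perturbation derived deterministically from the seed and the full prompt
    text, then log-normalised over the six letters.
    """

    def __init__(self, lexicon: Lexicon, sharpness: float = 2.0, seed: int = 0) -> None:
        if sharpness < 0:
            raise ValueError(f"sharpness must be non-negative, got {sharpness}")
        self.lexicon = lexicon
        self.sharpness = sharpness
        self.seed = seed
        self._vocab = {
            label: lexicon.effective_vocabulary(label) for label in LABEL_ORDER
        }

    def _letter_log_probs(self, prompt_text: str) -> dict[str, float]:
        target = None
        for line in prompt_text.splitlines():
            if line.startswith("Tweet: "):
                target = line[len("Tweet: ") :]
        if target is None:
            raise ValueError("prompt has no parseable 'Tweet: ' target line")
        tokens = target.split()
        # perturbation is a pure function of (seed, prompt text): realizations
        # differ only through the prompt they render
        rng = np.random.default_rng(
            (self.seed, zlib.crc32(prompt_text.encode("utf-8")))
        )
        raw = np.array(
            [
                self.sharpness * sum(tok in self._vocab[label] for tok in tokens)
                for label in LABEL_ORDER
            ],
            dtype=float,
        )
        raw += 0.01 * rng.standard_normal(N_CLASSES)
        log_probs = raw - _logsumexp(raw)
        return {label.letter: float(lp) for label, lp in zip(LABEL_ORDER, log_probs)}

    def score(self, prompt_text: str, candidates: Sequence[str]) -> list[float]:
        """Log-probability for each candidate continuation string."""
        by_letter = self._letter_log_probs(prompt_text)
        scores = []
        for cand in candidates:
            letter = cand.strip()
            if letter in by_letter:
                # the space-prefixed variant is marginally less likely, as a
                # tokenizer splitting off the leading space would make it
                penalty = 0.0 if cand == letter else 1e-3
                scores.append(by_letter[letter] - penalty)
            else:
                scores.append(-30.0)
        return scores


def _logsumexp(x: np.ndarray) -> float:
    m = float(np.max(x))
    return m + float(np.log(np.sum(np.exp(x - m))))


def make_mock_scorer(
    lexicon: Lexicon, sharpness: float = 2.0, seed: int = 0
) -> MockLetterScorer:
    """Factory matching the scorer-contract plugin interface."""
    return MockLetterScorer(lexicon, sharpness=sharpness, seed=seed)
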