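"""Few-shot multiple-choice prompting with self-consistency voting.

A target text is classified by rendering a fixed multiple-choice prompt —
instruction, six options A-F in fixed letter order, one exemplar per class,
and the target — scoring each option letter by its log-probability under a
pluggable next-token scorer, and majority-voting over k independent prompt
realizations.  A realization varies only the order in which the six exemplar
lines appear; instruction, option order and target are never touched.  The
protocol performs no parameter updates anywhere.

The scorer is a contract, not a model: anything with a
``score(prompt_text, candidates) -> list[float]`` method (one finite
log-probability per candidate continuation string) plugs in, from the
desk-scale lexicon mock to a real causal-LM backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

from .corpus import (
    LABEL_ORDER,
    LETTERS,
    N_CLASSES,
    Corpus,
    CorpusError,
    LabeledExample,
    SubtypeLabel,
)

__all__ = [
    "Scorer",
    "ExemplarSet",
    "RenderedPrompt",
    "VoteRecord",
    "select_exemplars",
    "render_prompt",
    "score_options",
    "predict_with_self_consistency",
    "evaluate_prompting",
    "INSTRUCTION",
]

INSTRUCTION = "Classify the tweet into exactly one category. Answer with a single letter."

#: Surface variants scored per letter; tokenizers differ on leading spaces,
#: so the letter's score is the max over its variants.
_LETTER_VARIANTS: dict[str, tuple[str, str]] = {L: (L, " " + L) for L in LETTERS}


class Scorer(Protocol):
    """Next-token scorer contract shared by mock and real LLM backends."""

    def score(self, prompt_text: str, candidates: Sequence[str]) -> Sequence[float]:
        """Return one finite log-probability per candidate continuation."""
        ...


def _is_clean(text: str) -> bool:
    lowered = text.lower()
    return "http" not in lowered and "www." not in lowered and "@" not in text


@dataclass
class ExemplarSet:
    """One few-shot exemplar per class, drawn once from the training split."""

    exemplars: dict[SubtypeLabel, LabeledExample]
    selection_seed: int
    fallback_used: dict[SubtypeLabel, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.exemplars) != set(LABEL_ORDER):
            missing = [l.label_name for l in LABEL_ORDER if l not in self.exemplars]
            raise CorpusError(f"exemplar set missing classes: {missing}")


@dataclass(frozen=True)
class RenderedPrompt:
    """A fully rendered prompt: instruction, options, exemplars, target."""

    text: str
    option_letters: tuple[str, ...]
    target_id: str


@dataclass
class VoteRecord:
    """Per-realization letter scores and the majority-vote decision."""

    letter_log_probs: np.ndarray  # (k, 6)
    realization_letters: list[str]
    final_letter: str
    final_label: SubtypeLabel
    tie_broken: bool

    @property
    def k(self) -> int:
        return len(self.realization_letters)


def select_exemplars(
    train: Corpus, seed: int, max_chars: int = 120
) -> ExemplarSet:
    """Pick one short, clean exemplar per class from the training split.

    Candidates are examples with no URL (``http``/``www.``) or ``@`` token
    and at most `max_chars` characters; the shortest wins, ties resolved by
    a seeded shuffle.  A class with no clean candidate falls back to its
    shortest example overall and is flagged.
    """
    rng = np.random.default_rng(seed)
    exemplars: dict[SubtypeLabel, LabeledExample] = {}
    fallback: dict[SubtypeLabel, bool] = {}
    for label in LABEL_ORDER:
        members = [ex for ex in train if ex.label is label]
        if not members:
            raise CorpusError(f"training split has no examples of {label.label_name!r}")
        # seeded shuffle first, then stable sort by length: ties fall in
        # shuffle order, deterministically per seed
        perm = rng.permutation(len(members))
        shuffled = [members[i] for i in perm]
        clean = [ex for ex in shuffled if _is_clean(ex.text) and len(ex.text) <= max_chars]
        pool, fell_back = (clean, False) if clean else (shuffled, True)
        exemplars[label] = min(pool, key=lambda ex: len(ex.text))
        fallback[label] = fell_back
    return ExemplarSet(exemplars=exemplars, selection_seed=seed, fallback_used=fallback)


def render_prompt(
    target: LabeledExample | str,
    exemplars: ExemplarSet,
    realization_index: int = 0,
) -> RenderedPrompt:
    """Assemble the fixed prompt template deterministically.

    The realization index seeds a permutation of the six exemplar lines and
    nothing else, operationalising "independent prompt realizations" for a
    deterministic scorer.
    """
    if realization_index < 0:
        raise ValueError(f"realization_index must be >= 0, got {realization_index}")
    target_text = target.text if isinstance(target, LabeledExample) else str(target)
    target_id = target.id if isinstance(target, LabeledExample) else ""

    lines = [INSTRUCTION]
    lines += [f"{label.letter}. {label.label_name}" for label in LABEL_ORDER]
    lines.append("Examples:")
    order = np.random.default_rng(
        (exemplars.selection_seed, realization_index)
    ).permutation(N_CLASSES)
    for idx in order:
        label = LABEL_ORDER[idx]
        ex = exemplars.exemplars[label]
        lines.append(f"{label.letter}. {ex.text} -> {label.letter}")
    lines.append(f"Tweet: {target_text}")
    lines.append("Answer:")
    return RenderedPrompt(text="\n".join(lines), option_letters=LETTERS, target_id=target_id)


def score_options(scorer: Scorer, prompt: RenderedPrompt) -> np.ndarray:
    """Score the six option letters, max-pooling over surface variants and
    renormalising to a proper log-distribution (argmax-preserving)."""
    candidates: list[str] = []
    for letter in prompt.option_letters:
        candidates.extend(_LETTER_VARIANTS[letter])
    raw = np.asarray(scorer.score(prompt.text, candidates), dtype=float)
    pooled = raw.reshape(N_CLASSES, 2).max(axis=1)
    bad = ~np.isfinite(pooled)
    if np.any(bad):
        letters = [prompt.option_letters[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"scorer returned non-finite log-probability for {letters}")
    m = pooled.max()
    return pooled - (m + np.log(np.exp(pooled - m).sum()))


def predict_with_self_consistency(
    scorer: Scorer,
    target: LabeledExample | str,
    exemplars: ExemplarSet,
    k: int = 5,
) -> VoteRecord:
    """Majority vote over k prompt realizations.

    Ties on vote count are broken by the tied letters' summed log-probability
    across realizations, then by letter order; a tie-break of any kind sets
    the record's flag.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    scores = np.empty((k, N_CLASSES))
    letters: list[str] = []
    for r in range(k):
        prompt = render_prompt(target, exemplars, realization_index=r)
        scores[r] = score_options(scorer, prompt)
        letters.append(LETTERS[int(np.argmax(scores[r]))])

    counts = {L: letters.count(L) for L in LETTERS}
    top = max(counts.values())
    tied = [L for L in LETTERS if counts[L] == top]
    if len(tied) == 1:
        final = tied[0]
        tie_broken = False
    else:
        sums = {L: float(scores[:, LETTERS.index(L)].sum()) for L in tied}
        best = max(sums.values())
        final = next(L for L in tied if sums[L] == best)  # letter order on exact tie
        tie_broken = True
    return VoteRecord(
        letter_log_probs=scores,
        realization_letters=letters,
        final_letter=final,
        final_label=SubtypeLabel.from_letter(final),
        tie_broken=tie_broken,
    )


def evaluate_prompting(
    scorer: Scorer,
    corpus: Corpus,
    exemplars: ExemplarSet,
    k: int = 5,
) -> tuple[list[SubtypeLabel], list[VoteRecord]]:
    """Classify every example of a corpus; returns predictions and records."""
    records = [
        predict_with_self_consistency(scorer, ex, exemplars, k=k) for ex in corpus
    ]
    return [rec.final_label for rec in records], records
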