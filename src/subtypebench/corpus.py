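"""Label space, corpus data model, I/O, deduplication and stratified splitting.

The task is six-way single-label classification of short social-media posts
into five depression subtypes (postpartum, major, bipolar, psychotic,
atypical) plus a no-depression class.  Every downstream stage — the
synthetic generator, the prompting protocol, the fine-tuning recipe and the
evaluation layer — shares the :class:`Corpus` container defined here.

Texts are normalised minimally: Unicode NFC, runs of whitespace collapsed to
a single space, leading/trailing whitespace stripped.  No negation or
sarcasm handling is applied; both model families see the same surface form.
"""

from __future__ import annotations

import csv
import json
import re
import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "SubtypeLabel",
    "LabeledExample",
    "Corpus",
    "SplitBundle",
    "CorpusError",
    "normalize_text",
    "read_corpus",
    "write_corpus",
    "deduplicate",
    "stratified_split",
    "class_counts",
]


class CorpusError(ValueError):
    """Raised for malformed corpora: unknown labels, empty texts, bad splits."""


class SubtypeLabel(Enum):
    """The six mutually exclusive content labels, in fixed letter order A-F.

    The letter order is the option order of the multiple-choice prompt and
    the canonical axis order of every confusion matrix in the package.
    """

    POSTPARTUM = ("postpartum", "A")
    MAJOR = ("major", "B")
    BIPOLAR = ("bipolar", "C")
    PSYCHOTIC = ("psychotic", "D")
    NO_DEPRESSION = ("no_depression", "E")
    ATYPICAL = ("atypical", "F")

    def __init__(self, label_name: str, letter: str) -> None:
        self.label_name = label_name
        self.letter = letter

    @classmethod
    def from_name(cls, raw: str) -> "SubtypeLabel":
        """Resolve a label string case-insensitively, unifying space/hyphen/underscore."""
        key = re.sub(r"[\s_\-]+", "_", raw.strip().lower())
        for member in cls:
            if member.label_name == key:
                return member
        raise CorpusError(
            f"unknown label {raw!r}: expected one of "
            f"{[m.label_name for m in cls]}"
        )

    @classmethod
    def from_letter(cls, letter: str) -> "SubtypeLabel":
        for member in cls:
            if member.letter == letter:
                return member
        raise CorpusError(f"unknown option letter {letter!r}: expected A-F")

    @property
    def index(self) -> int:
        """Position in canonical (letter) order, 0-5."""
        return list(type(self)).index(self)


#: Canonical label order (A-F); the row/column order of confusion matrices.
LABEL_ORDER: tuple[SubtypeLabel, ...] = tuple(SubtypeLabel)
LETTERS: tuple[str, ...] = tuple(m.letter for m in LABEL_ORDER)
N_CLASSES: int = len(LABEL_ORDER)

_WS = re.compile(r"\s+")


def normalize_text(text: str) -> str:
    """NFC-normalise and collapse internal whitespace; strip the ends."""
    return _WS.sub(" ", unicodedata.normalize("NFC", text)).strip()


@dataclass(frozen=True)
class LabeledExample:
    """One short text carrying exactly one subtype label."""

    id: str
    text: str
    label: SubtypeLabel

    def __post_init__(self) -> None:
        if not normalize_text(self.text):
            raise CorpusError(f"example {self.id!r}: text empty after normalization")


@dataclass
class Corpus:
    """An ordered collection of labelled examples with unique ids."""

    examples: list[LabeledExample] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [ex.id for ex in self.examples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CorpusError(f"duplicate ids in corpus: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.examples)

    def __iter__(self) -> Iterator[LabeledExample]:
        return iter(self.examples)

    def __getitem__(self, i: int) -> LabeledExample:
        return self.examples[i]

    @property
    def n(self) -> int:
        return len(self.examples)

    def texts(self) -> list[str]:
        return [ex.text for ex in self.examples]

    def labels(self) -> list[SubtypeLabel]:
        return [ex.label for ex in self.examples]


@dataclass
class SplitBundle:
    """Train/validation/test partitions, disjoint by id and by normalised text."""

    train: Corpus
    validation: Corpus
    test: Corpus

    def __iter__(self) -> Iterator[Corpus]:
        return iter((self.train, self.validation, self.test))

    def validate(self) -> None:
        """Check the partition invariants; raise :class:`CorpusError` on violation."""
        parts = [self.train, self.validation, self.test]
        seen_ids: set[str] = set()
        seen_texts: set[str] = set()
        for part in parts:
            for ex in part:
                if ex.id in seen_ids:
                    raise CorpusError(f"id {ex.id!r} appears in more than one partition")
                seen_ids.add(ex.id)
                t = normalize_text(ex.text)
                if t in seen_texts:
                    raise CorpusError(
                        f"text of example {ex.id!r} duplicated across partitions"
                    )
                seen_texts.add(t)


def _example_from_record(record: dict, lineno: int, auto_id: int) -> LabeledExample:
    text = record.get("text")
    if text is None or not normalize_text(str(text)):
        raise CorpusError(f"record {lineno}: empty or missing text")
    raw_label = record.get("label")
    if raw_label is None:
        raise CorpusError(f"record {lineno}: missing label")
    try:
        label = SubtypeLabel.from_name(str(raw_label))
    except CorpusError as err:
        raise CorpusError(f"record {lineno}: {err}") from None
    ex_id = record.get("id")
    if ex_id is None or str(ex_id) == "":
        ex_id = str(auto_id)
    return LabeledExample(id=str(ex_id), text=normalize_text(str(text)), label=label)


def read_corpus(path: str | Path, format: str | None = None) -> Corpus:
    """Read a corpus from JSONL (one object per line) or CSV (header id,text,label).

    The format is inferred from the suffix when not given.  Label strings are
    matched case-insensitively with spaces/hyphens/underscores unified;
    missing ids are assigned sequentially; texts are normalised on read.
    """
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    examples: list[LabeledExample] = []
    if fmt == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                record = json.loads(line)
                examples.append(_example_from_record(record, lineno, len(examples)))
    elif fmt == "csv":
        with path.open(encoding="utf-8", newline="") as fh:
            for lineno, record in enumerate(csv.DictReader(fh), start=1):
                examples.append(_example_from_record(record, lineno, len(examples)))
    else:
        raise CorpusError(f"unknown corpus format {fmt!r}: expected jsonl or csv")
    return Corpus(examples)


def write_corpus(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    """Write a corpus as JSONL or CSV; inverse of :func:`read_corpus`."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for ex in corpus:
                fh.write(
                    json.dumps(
                        {"id": ex.id, "text": ex.text, "label": ex.label.label_name},
                        ensure_ascii=False,
                    )
                    + "\n"
                )
    elif fmt == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "text", "label"])
            for ex in corpus:
                writer.writerow([ex.id, ex.text, ex.label.label_name])
    else:
        raise CorpusError(f"unknown corpus format {fmt!r}: expected jsonl or csv")


def deduplicate(corpus: Corpus) -> Corpus:
    """Drop exact duplicates by normalised text, keeping the first occurrence."""
    seen: set[str] = set()
    survivors = []
    for ex in corpus:
        key = normalize_text(ex.text)
        if key not in seen:
            seen.add(key)
            survivors.append(ex)
    return Corpus(survivors)


def class_counts(corpus: Corpus | Iterable[LabeledExample]) -> np.ndarray:
    """Per-class example counts n_c in canonical label order; sums to N."""
    counts = np.zeros(N_CLASSES, dtype=int)
    for ex in corpus:
        counts[ex.label.index] += 1
    return counts


def _largest_remainder_sizes(n: int, ratios: Sequence[float]) -> list[int]:
    """Apportion n into len(ratios) integer slots by largest-remainder rounding."""
    quotas = np.asarray(ratios, dtype=float) * n
    sizes = np.floor(quotas).astype(int)
    remainder = n - int(sizes.sum())
    # ties in fractional part broken by slot order (stable argsort)
    order = np.argsort(-(quotas - sizes), kind="stable")
    for slot in order[:remainder]:
        sizes[slot] += 1
    return sizes.tolist()


def stratified_split(
    corpus: Corpus,
    ratios: Sequence[float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitBundle:
    """Deterministic per-class stratified split into train/validation/test.

    The corpus is deduplicated first (exact-duplicate texts collapse to the
    first occurrence) so no text is shared across partitions.  Within each
    class, examples are shuffled by a seeded PRNG and sliced contiguously,
    with slice sizes apportioned by largest-remainder rounding — per-class
    counts land within +/-1 of the stratified expectation.
    """
    ratios = [float(r) for r in ratios]
    if len(ratios) != 3 or any(r <= 0 for r in ratios):
        raise CorpusError(f"ratios must be three positive fractions, got {ratios}")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise CorpusError(f"ratios must sum to 1, got sum={sum(ratios)}")

    deduped = deduplicate(corpus)
    rng = np.random.default_rng(seed)
    parts: list[list[LabeledExample]] = [[], [], []]
    for label in LABEL_ORDER:
        members = [ex for ex in deduped if ex.label is label]
        if 0 < len(members) < 3:
            raise CorpusError(
                f"class {label.label_name!r} has {len(members)} example(s); "
                "need at least one per partition"
            )
        perm = rng.permutation(len(members))
        shuffled = [members[i] for i in perm]
        sizes = _largest_remainder_sizes(len(members), ratios)
        offset = 0
        for slot, size in enumerate(sizes):
            parts[slot].extend(shuffled[offset : offset + size])
            offset += size
    bundle = SplitBundle(Corpus(parts[0]), Corpus(parts[1]), Corpus(parts[2]))
    bundle.validate()
    return bundle
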