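"""Keyword lexicon, text normalization, and feature extraction.

A report is reduced to integer counts of lexicon phrases plus their
negated variants ("no infiltrate"-style expansions). Matching is
phrase-level on the normalized token stream: left-to-right,
non-overlapping, longest match wins, so a negated occurrence never also
counts as a bare occurrence of the inner phrase.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "DEFAULT_NEGATION_CUES",
    "KeywordEntry",
    "Lexicon",
    "TokenSequence",
    "FeatureVector",
    "normalize_text",
    "tokenize",
    "expand_negations",
    "extract_features",
    "label_by_rules",
    "default_lexicon",
    "features_to_matrix",
]

#: Minimal high-precision cue list; prepended verbatim to expandable phrases.
DEFAULT_NEGATION_CUES: tuple[str, ...] = ("no", "without", "no evidence of", "negative for")

POLARITIES = ("indicates_pneumonia", "indicates_no_pneumonia", "hedged")

_NON_TOKEN = re.compile(r"[^a-z0-9\-\s]+")
_DANGLING_HYPHEN = re.compile(r"(?<![a-z0-9])-|-(?![a-z0-9])")
_WS = re.compile(r"\s+")


def normalize_text(raw: str) -> str:
    """Lowercase, strip punctuation to spaces (keeping intra-word hyphens),
    and collapse whitespace. Deterministic; empty in, empty out."""
    text = raw.lower()
    text = _NON_TOKEN.sub(" ", text)
    text = _DANGLING_HYPHEN.sub(" ", text)
    return _WS.sub(" ", text).strip()


@dataclass(frozen=True)
class TokenSequence:
    """Ordered lowercase tokens plus the id of the report they came from."""

    tokens: tuple[str, ...]
    source_report_id: str = ""

    def __post_init__(self) -> None:
        if any(t == "" for t in self.tokens):
            raise ValueError("token sequence must not contain empty tokens")

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)


def tokenize(text: str, source_report_id: str = "") -> TokenSequence:
    """Split normalized text on whitespace. ``""`` yields the empty sequence."""
    return TokenSequence(tokens=tuple(text.split()), source_report_id=source_report_id)


@dataclass(frozen=True)
class KeywordEntry:
    phrase: str
    polarity: str
    expandable: bool

    def __post_init__(self) -> None:
        if not self.phrase:
            raise ValueError("keyword phrase must be non-empty")
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}, got {self.polarity!r}")


def expand_negations(entry: KeywordEntry, cues: Sequence[str] = DEFAULT_NEGATION_CUES) -> list[str]:
    """Negated variants of an expandable phrase, one per cue, in cue order.

    The bare phrase is not included. Calling this on a non-expandable
    entry (e.g., one that already carries a negation cue) is a contract
    error.
    """
    if not entry.expandable:
        raise ValueError(f"entry {entry.phrase!r} is not eligible for negation expansion")
    if not cues:
        raise ValueError("cue list must be non-empty")
    return [f"{cue} {entry.phrase}" for cue in cues]


@dataclass(frozen=True)
class Lexicon:
    """Ordered keyword list; entry order fixes feature indices."""

    entries: tuple[KeywordEntry, ...]
    version: str = "table1-defaults"

    def __post_init__(self) -> None:
        phrases = [normalize_text(e.phrase) for e in self.entries]
        if len(set(phrases)) != len(phrases):
            dupes = sorted({p for p in phrases if phrases.count(p) > 1})
            raise ValueError(f"duplicate phrases after normalization: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def feature_names(self, cues: Sequence[str] = DEFAULT_NEGATION_CUES) -> list[str]:
        """Bare phrase per entry, immediately followed by its ``|negated``
        twin for expandable entries."""
        names: list[str] = []
        for entry in self.entries:
            names.append(entry.phrase)
            if entry.expandable:
                names.append(f"{entry.phrase}|negated")
        return names

    @classmethod
    def from_csv(cls, path, version: Optional[str] = None) -> "Lexicon":
        entries = []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            required = {"phrase", "polarity", "expandable"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise ValueError(f"lexicon CSV must have columns {sorted(required)}")
            for row in reader:
                entries.append(
                    KeywordEntry(
                        phrase=normalize_text(row["phrase"]),
                        polarity=row["polarity"].strip(),
                        expandable=row["expandable"].strip() in ("1", "true", "True"),
                    )
                )
        return cls(entries=tuple(entries), version=version or str(path))

    def to_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["phrase", "polarity", "expandable"])
            for e in self.entries:
                writer.writerow([e.phrase, e.polarity, int(e.expandable)])


def default_lexicon() -> Lexicon:
    """The packaged keyword list (chest-radiograph pneumonia phrases)."""
    ref = resources.files("cxrnlp").joinpath("data/lexicon.csv")
    with resources.as_file(ref) as path:
        return Lexicon.from_csv(path, version="table1-defaults")


@dataclass(frozen=True)
class FeatureVector:
    """Aligned per-feature occurrence counts for one report."""

    values: tuple[int, ...]
    feature_names: tuple[str, ...]
    report_id: str = ""

    def __post_init__(self) -> None:
        if len(self.values) != len(self.feature_names):
            raise ValueError("values and feature_names must align")
        if any(v < 0 for v in self.values):
            raise ValueError("feature counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=np.int64)


def _matcher_table(lexicon: Lexicon, cues: Sequence[str]) -> tuple[dict[tuple[str, ...], int], list[str]]:
    """Candidate token-tuple -> feature index, plus the feature name list.

    A negated expansion that collides with an existing bare entry (e.g.
    the expansion "no pleural effusion" when that exact phrase is itself
    a lexicon entry) is dropped: the explicit entry takes precedence.
    """
    names = lexicon.feature_names(cues)
    index = {name: i for i, name in enumerate(names)}
    table: dict[tuple[str, ...], int] = {}
    for entry in lexicon.entries:
        table[tuple(entry.phrase.split())] = index[entry.phrase]
    for entry in lexicon.entries:
        if not entry.expandable:
            continue
        for variant in expand_negations(entry, cues):
            key = tuple(variant.split())
            if key in table:
                continue  # explicit lexicon entry wins
            table[key] = index[f"{entry.phrase}|negated"]
    return table, names


def extract_features(
    text_or_report,
    lexicon: Lexicon,
    cues: Sequence[str] = DEFAULT_NEGATION_CUES,
) -> FeatureVector:
    """Count non-overlapping phrase occurrences in a report.

    Accepts a raw string or any object with ``text`` and ``report_id``
    attributes. Scanning is left-to-right with longest-match-wins, so the
    cue-prefixed variant shadows its bare suffix at the same site.
    """
    if not len(lexicon):
        raise ValueError("lexicon must be non-empty")
    if isinstance(text_or_report, str):
        text, report_id = text_or_report, ""
    else:
        text, report_id = text_or_report.text, text_or_report.report_id
    tokens = tokenize(normalize_text(text)).tokens

    table, names = _matcher_table(lexicon, cues)
    lengths = sorted({len(k) for k in table}, reverse=True)
    counts = [0] * len(names)
    i, n = 0, len(tokens)
    while i < n:
        matched = False
        for L in lengths:
            if i + L > n:
                continue
            idx = table.get(tokens[i : i + L])
            if idx is not None:
                counts[idx] += 1
                i += L
                matched = True
                break
        if not matched:
            i += 1
    return FeatureVector(values=tuple(counts), feature_names=tuple(names), report_id=report_id)


def label_by_rules(
    features: FeatureVector,
    lexicon: Lexicon,
    cues: Sequence[str] = DEFAULT_NEGATION_CUES,
    hedged_positive: bool = True,
) -> int:
    """Rule-based reference label: 1 iff any positive-polarity evidence.

    Bare counts on pneumonia-indicating phrases count as positive
    evidence; their negated twins do not (the negated match already
    consumed the site, cancelling that phrase only). Hedged phrases count
    as positive under the default sensitivity-oriented policy.
    """
    expected = tuple(lexicon.feature_names(cues))
    if features.feature_names != expected:
        raise ValueError("feature vector is not aligned to this lexicon")
    by_name = dict(zip(features.feature_names, features.values))
    evidence = 0
    for entry in lexicon.entries:
        if entry.polarity == "indicates_pneumonia":
            evidence += by_name[entry.phrase]
        elif entry.polarity == "hedged" and hedged_positive:
            evidence += by_name[entry.phrase]
    return int(evidence > 0)


def features_to_matrix(vectors: Iterable[FeatureVector]) -> tuple[np.ndarray, list[str], list[str]]:
    """Stack per-report vectors into (matrix, feature_names, report_ids)."""
    vectors = list(vectors)
    if not vectors:
        raise ValueError("no feature vectors supplied")
    names = vectors[0].feature_names
    for v in vectors:
        if v.feature_names != names:
            raise ValueError("feature vectors have mismatched feature names")
    X = np.vstack([v.as_array() for v in vectors])
    return X, list(names), [v.report_id for v in vectors]
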