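"""Abbreviation–expansion dictionaries and their companion tables.

The sense inventory at the center of the toolkit is a many-to-many mapping
between short forms ("af") and long forms ("atrial fibrillation",
"afebrile").  This module loads and validates the dictionary, the table of
clinically equivalent expansion sets, and the list of abbreviations that
double as ordinary English words; it also computes the summary statistics
that motivate the aligner's scoring rules (how often expansions share the
abbreviation's first character, and how often all senses of an abbreviation
have the same token count).

File formats are plain text: two-column TSV for the dictionary (optional
``#`` comments), abbreviation + N expansions per TSV row for the equivalence
table, one abbreviation per line for the English-word list.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Iterator, TextIO

from .text import normalize, tokenize


class DictionaryError(ValueError):
    """Malformed or inconsistent dictionary input."""


class DictionaryParseError(DictionaryError):
    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


# Low-quality indicator names
CONTAINS_OWN_ABBREVIATION = "contains-own-abbreviation"
CONTAINS_OTHER_ABBREVIATION = "contains-other-abbreviation"
CONTAINS_PARENTHESES = "contains-parentheses"
NOT_FOUND_IN_CORPUS = "not-found-in-corpus"


@dataclass(frozen=True)
class DictStats:
    """Summary statistics over a sense inventory."""

    n_abbrevs: int
    n_pairs: int
    n_ambiguous: int
    frac_same_first_char: float
    frac_uniform_expansion_token_count: float


class AbbrevDictionary:
    """A deduplicated set of (abbreviation, expansion) pairs.

    Both sides are normalized (lowercase, collapsed whitespace).  An
    abbreviation may map to many expansions and an expansion to many
    abbreviations; a reverse index supports the latter direction.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        expansions: dict[str, set[str]] = {}
        reverse: dict[str, set[str]] = {}
        for abbrev, expansion in pairs:
            abbrev = normalize(abbrev)
            expansion = normalize(expansion)
            if not abbrev or not expansion:
                raise DictionaryError(
                    "abbreviation and expansion must be non-empty after normalization"
                )
            expansions.setdefault(abbrev, set()).add(expansion)
            reverse.setdefault(expansion, set()).add(abbrev)
        if not expansions:
            raise DictionaryError("dictionary has no entries")
        self._expansions = expansions
        self._reverse = reverse

    # -- queries ---------------------------------------------------------

    @property
    def abbreviations(self) -> frozenset[str]:
        return frozenset(self._expansions)

    def expansions_of(self, abbreviation: str) -> frozenset[str]:
        try:
            return frozenset(self._expansions[abbreviation])
        except KeyError:
            raise KeyError(f"unknown abbreviation: {abbreviation!r}") from None

    def abbreviations_of(self, expansion: str) -> frozenset[str]:
        return frozenset(self._reverse.get(normalize(expansion), ()))

    def __contains__(self, abbreviation: str) -> bool:
        return abbreviation in self._expansions

    def has_pair(self, abbreviation: str, expansion: str) -> bool:
        return normalize(expansion) in self._expansions.get(normalize(abbreviation), ())

    def pairs(self) -> Iterator[tuple[str, str]]:
        for abbrev in sorted(self._expansions):
            for expansion in sorted(self._expansions[abbrev]):
                yield abbrev, expansion

    @property
    def n_abbrevs(self) -> int:
        return len(self._expansions)

    @property
    def n_pairs(self) -> int:
        return sum(len(v) for v in self._expansions.values())

    def is_ambiguous(self, abbreviation: str) -> bool:
        """True iff the abbreviation has more than one valid expansion."""
        return len(self.expansions_of(abbreviation)) > 1

    @property
    def all_expansions(self) -> frozenset[str]:
        return frozenset(self._reverse)

    # -- IO --------------------------------------------------------------

    @classmethod
    def load(cls, source: str | Path | TextIO) -> "AbbrevDictionary":
        """Load a two-column tab-separated dictionary.

        Raises :class:`DictionaryParseError` (with a line number) on a record
        that does not have exactly two fields, and :class:`DictionaryError`
        on empty fields.
        """
        close = False
        if isinstance(source, (str, Path)):
            stream: TextIO = open(source, encoding="utf-8")
            close = True
        else:
            stream = source
        pairs: list[tuple[str, str]] = []
        try:
            for lineno, raw in enumerate(stream, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise DictionaryParseError(
                        f"expected 2 tab-separated fields, got {len(fields)}", lineno
                    )
                abbrev, expansion = fields
                if not abbrev.strip() or not expansion.strip():
                    raise DictionaryParseError("empty field", lineno)
                pairs.append((abbrev, expansion))
        finally:
            if close:
                stream.close()
        return cls(pairs)

    def dump(self, destination: str | Path | TextIO) -> None:
        close = False
        if isinstance(destination, (str, Path)):
            stream: TextIO = open(destination, "w", encoding="utf-8")
            close = True
        else:
            stream = destination
        try:
            for abbrev, expansion in self.pairs():
                stream.write(f"{abbrev}\t{expansion}\n")
        finally:
            if close:
                stream.close()


class EquivalenceTable:
    """Sets of clinically equivalent expansions, keyed by abbreviation.

    One abbreviation may carry several independent sets; sets are never
    merged.  Every set has at least two members.
    """

    def __init__(self, sets: Iterable[tuple[str, Iterable[str]]] = ()):
        self._sets: dict[str, list[frozenset[str]]] = {}
        for abbrev, members in sets:
            self.add(abbrev, members)

    def add(self, abbreviation: str, members: Iterable[str]) -> None:
        abbrev = normalize(abbreviation)
        group = frozenset(normalize(m) for m in members)
        if len(group) < 2:
            raise DictionaryError(
                f"equivalence set for {abbrev!r} must have >=2 distinct members"
            )
        self._sets.setdefault(abbrev, []).append(group)

    def sets_for(self, abbreviation: str) -> list[frozenset[str]]:
        return list(self._sets.get(normalize(abbreviation), ()))

    def are_equivalent(self, abbreviation: str, a: str, b: str) -> bool:
        a, b = normalize(a), normalize(b)
        return any(a in s and b in s for s in self.sets_for(abbreviation))

    def __len__(self) -> int:
        return sum(len(v) for v in self._sets.values())

    @classmethod
    def load(cls, source: str | Path | TextIO) -> "EquivalenceTable":
        close = False
        if isinstance(source, (str, Path)):
            stream: TextIO = open(source, encoding="utf-8")
            close = True
        else:
            stream = source
        table = cls()
        try:
            for lineno, raw in enumerate(stream, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                fields = [f for f in line.split("\t") if f.strip()]
                if len(fields) < 3:
                    raise DictionaryParseError(
                        "equivalence record needs an abbreviation and >=2 expansions",
                        lineno,
                    )
                table.add(fields[0], fields[1:])
        finally:
            if close:
                stream.close()
        return table

    def dump(self, destination: str | Path | TextIO) -> None:
        close = False
        if isinstance(destination, (str, Path)):
            stream: TextIO = open(destination, "w", encoding="utf-8")
            close = True
        else:
            stream = destination
        try:
            for abbrev in sorted(self._sets):
                for group in self._sets[abbrev]:
                    stream.write(abbrev + "\t" + "\t".join(sorted(group)) + "\n")
        finally:
            if close:
                stream.close()


def load_english_word_list(
    source: str | Path | TextIO, dictionary: AbbrevDictionary
) -> frozenset[str]:
    """Load the list of abbreviations that double as English words.

    Every member must be a dictionary abbreviation.
    """
    close = False
    if isinstance(source, (str, Path)):
        stream: TextIO = open(source, encoding="utf-8")
        close = True
    else:
        stream = source
    words: set[str] = set()
    try:
        for lineno, raw in enumerate(stream, start=1):
            word = normalize(raw)
            if not word or word.startswith("#"):
                continue
            if word not in dictionary:
                raise DictionaryParseError(
                    f"{word!r} is not a dictionary abbreviation", lineno
                )
            words.add(word)
    finally:
        if close:
            stream.close()
    return frozenset(words)


def flag_low_quality(
    abbreviation: str,
    expansion: str,
    dictionary: AbbrevDictionary,
    english_words: frozenset[str] | None = None,
    corpus_counts: dict[str, int] | None = None,
) -> set[str]:
    """Assign low-quality indicators to one dictionary entry.

    Indicators (a subset is returned):

    * ``contains-own-abbreviation`` — the expansion contains its own
      abbreviation as a whole token (``ekg`` -> "ekg monitoring").
    * ``contains-other-abbreviation`` — the expansion contains a different
      dictionary abbreviation as a whole token.  Abbreviations that double as
      English words (``english_words``) are exempt, since otherwise nearly
      every expansion containing a common word would be flagged.
    * ``contains-parentheses`` — literal parentheses in the expansion.
    * ``not-found-in-corpus`` — only when ``corpus_counts`` is supplied and
      the expansion has zero occurrences.

    Pure classification; never raises for well-formed entries.
    """
    abbrev = normalize(abbreviation)
    exp = normalize(expansion)
    flags: set[str] = set()
    if "(" in exp or ")" in exp:
        flags.add(CONTAINS_PARENTHESES)
    tokens = set(tokenize(exp).tokens)
    if abbrev in tokens:
        flags.add(CONTAINS_OWN_ABBREVIATION)
    exempt = english_words or frozenset()
    for token in tokens:
        if token != abbrev and token in dictionary and token not in exempt:
            flags.add(CONTAINS_OTHER_ABBREVIATION)
            break
    if corpus_counts is not None and corpus_counts.get(exp, 0) == 0:
        flags.add(NOT_FOUND_IN_CORPUS)
    return flags


def dictionary_stats(
    dictionary: AbbrevDictionary,
    tokenizer: Callable[[str], int] | None = None,
    first_char_quantifier: str = "all",
) -> DictStats:
    """Summary statistics of the sense inventory.

    ``frac_same_first_char`` is the fraction of abbreviations whose
    expansions share the abbreviation's first character.  The quantifier over
    expansions is configurable: ``"all"`` (default — every expansion must
    share the first character) or ``"any"`` (at least one does), exposed for
    sensitivity checks because the natural-language description of this
    statistic is ambiguous.

    ``frac_uniform_expansion_token_count`` is the fraction of abbreviations
    whose expansions all have the same token count (this is what lets a
    run-length-matched insertion gap stand in for "the expected expansion").
    """
    if first_char_quantifier not in ("all", "any"):
        raise ValueError("first_char_quantifier must be 'all' or 'any'")
    count_tokens = tokenizer or (lambda s: len(tokenize(s)))
    quantifier = all if first_char_quantifier == "all" else any
    n_ambiguous = 0
    n_same_first = 0
    n_uniform = 0
    for abbrev in dictionary.abbreviations:
        expansions = dictionary.expansions_of(abbrev)
        if len(expansions) > 1:
            n_ambiguous += 1
        if quantifier(e[0] == abbrev[0] for e in expansions):
            n_same_first += 1
        if len({count_tokens(e) for e in expansions}) == 1:
            n_uniform += 1
    n = dictionary.n_abbrevs
    return DictStats(
        n_abbrevs=n,
        n_pairs=dictionary.n_pairs,
        n_ambiguous=n_ambiguous,
        frac_same_first_char=n_same_first / n,
        frac_uniform_expansion_token_count=n_uniform / n,
    )
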