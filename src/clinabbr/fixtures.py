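"""Synthetic corpora, dictionaries, and gold-labeled snippets.

Every other module in this package is exercised against data built here, so
no download is ever required.  The generators emulate the statistical
structure that matters for the machinery — not clinical semantics:

* a sense inventory whose abbreviations are acronyms of their expansions
  (so most expansions share the abbreviation's first character, the
  property the SFC alignment rule relies on), with controlled ambiguity and
  a designated set of abbreviations that double as common English words;
* a "web" corpus with a power-law skew over expansion frequencies (common
  long forms occur orders of magnitude more often than rare ones) and a
  configurable fraction of sentences contaminated with native, unexpanded
  abbreviations;
* gold-labeled snippets with exact character spans and intended expansions,
  including homograph instances labeled as word-usage (must not be
  expanded) or abbreviation-usage.

Sentences are template-based (slot-filled noun phrases between fixed
context words); that is adequate because no consumer of these fixtures
looks at meaning, only at token structure.  All generators are
deterministic under a fixed seed, and the corpus generator emits *exact*
planned occurrence counts rather than sampling them, so verification by
recounting is exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np

from .dictionary import AbbrevDictionary, EquivalenceTable
from .evaluation import GoldLabel

# Per-initial vocabulary used to spell acronym expansions.
_MED_WORDS: dict[str, tuple[str, ...]] = {
    "a": ("arterial", "aortic", "atrial", "acute"),
    "b": ("biliary", "bronchial", "bilateral", "benign"),
    "c": ("cardiac", "chronic", "coronary", "cystic"),
    "d": ("diastolic", "dilated", "distal", "ductal"),
    "e": ("embolic", "esophageal", "eczematous"),
    "f": ("femoral", "fibrotic", "focal", "frontal"),
    "g": ("gastric", "glomerular", "granular"),
    "h": ("hepatic", "hilar", "humeral"),
    "i": ("ischemic", "inguinal", "intracranial"),
    "k": ("keratotic", "kinetic"),
    "l": ("lumbar", "lateral", "lingual"),
    "m": ("mitral", "metabolic", "mucosal"),
    "n": ("nodular", "necrotic", "nasal"),
    "o": ("occipital", "ovarian", "orbital"),
    "p": ("pulmonary", "pancreatic", "parietal"),
    "r": ("renal", "radial", "retinal"),
    "s": ("systolic", "septal", "sacral"),
    "t": ("thoracic", "tibial", "temporal"),
    "u": ("ulnar", "urinary", "uterine"),
    "v": ("venous", "ventricular", "vascular"),
    "w": ("wedge", "woven"),
}

# Optional trailing head-noun; breaks token-count uniformity across senses.
_TAIL_WORDS = ("syndrome", "disease", "injury")

# Common-word homograph pool; every word can be spelled from _MED_WORDS.
_HOMOGRAPH_POOL = ("us", "it", "am", "pm", "all", "or", "as", "be", "no", "ms")

# Context vocabulary, disjoint from everything above and from any
# generated abbreviation (checked at generation time).
_CONTEXT_WORDS = (
    "reviewed",
    "noted",
    "stable",
    "improving",
    "unchanged",
    "extensive",
    "recurrent",
    "resolving",
)
_RESERVED = set(_CONTEXT_WORDS) | set(_TAIL_WORDS) | {
    "the",
    "patient",
    "was",
    "seen",
    "for",
    "with",
    "and",
    "today",
    "showed",
    "findings",
    "on",
    "exam",
}


def _spell_expansion(
    abbrev: str, rng: np.random.Generator, with_tail_prob: float = 0.25
) -> tuple[str, ...]:
    words = tuple(
        _MED_WORDS[ch][int(rng.integers(len(_MED_WORDS[ch])))] for ch in abbrev
    )
    if rng.random() < with_tail_prob:
        words = words + (_TAIL_WORDS[int(rng.integers(len(_TAIL_WORDS)))],)
    return words


def _nested(a: tuple[str, ...], b: tuple[str, ...]) -> bool:
    """True when one token tuple is a contiguous subsequence of the other."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    return any(
        long_[i : i + len(short)] == short for i in range(len(long_) - len(short) + 1)
    )


def generate_fixture_dictionary(
    n_abbrevs: int,
    ambiguity_rate: float = 0.3,
    homograph_rate: float = 0.1,
    rng: np.random.Generator | None = None,
) -> tuple[AbbrevDictionary, frozenset[str], EquivalenceTable]:
    """Generate a synthetic sense inventory.

    Returns (dictionary, English-word abbreviation set, equivalence table).
    Abbreviations are 2–3 letter acronyms; ``ambiguity_rate`` of them get
    2–3 expansions, ``homograph_rate`` of them are drawn from a small
    common-English-word pool.  At least one clinical-equivalence set is
    emitted (two same-length variants of one sense).
    """
    if n_abbrevs < 1:
        raise ValueError("n_abbrevs must be >= 1")
    if not (0 <= ambiguity_rate <= 1 and 0 <= homograph_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng()

    letters = sorted(_MED_WORDS)
    entries: dict[str, list[tuple[str, ...]]] = {}
    all_expansions: list[tuple[str, ...]] = []

    n_homographs = min(round(n_abbrevs * homograph_rate), len(_HOMOGRAPH_POOL))
    homographs = [
        _HOMOGRAPH_POOL[i]
        for i in rng.choice(len(_HOMOGRAPH_POOL), size=n_homographs, replace=False)
    ]

    def admissible(expansion: tuple[str, ...]) -> bool:
        return not any(_nested(expansion, other) for other in all_expansions)

    def add_abbrev(abbrev: str) -> bool:
        n_senses = 2 + int(rng.integers(2)) if rng.random() < ambiguity_rate else 1
        senses: list[tuple[str, ...]] = []
        for _ in range(40):
            if len(senses) == n_senses:
                break
            cand = _spell_expansion(abbrev, rng)
            if cand in senses or not admissible(cand):
                continue
            senses.append(cand)
        if not senses:
            return False
        entries[abbrev] = senses
        all_expansions.extend(senses)
        return True

    for word in sorted(homographs):
        add_abbrev(word)
    attempts = 0
    while len(entries) < n_abbrevs and attempts < n_abbrevs * 200:
        attempts += 1
        k = 2 + int(rng.random() < 0.4)
        abbrev = "".join(letters[int(rng.integers(len(letters)))] for _ in range(k))
        if abbrev in entries or abbrev in _RESERVED or abbrev in _HOMOGRAPH_POOL:
            continue
        add_abbrev(abbrev)
    if len(entries) < n_abbrevs:
        raise ValueError("vocabulary too small for the requested dictionary size")

    # Equivalence sets are same-length variants of an existing sense; the
    # variant becomes an extra dictionary expansion, so none are created
    # when the caller asked for a fully unambiguous inventory.
    equivalence = EquivalenceTable()
    n_equiv = max(1, n_abbrevs // 8) if ambiguity_rate > 0 else 0
    made = 0
    for abbrev in sorted(entries):
        if made >= n_equiv:
            break
        base = entries[abbrev][0]
        pos = len(base) - 1
        ch = base[pos][0]
        bucket = _MED_WORDS.get(ch, ())
        variants = [w for w in bucket if w != base[pos]]
        if not variants:
            continue
        variant = list(base)
        variant[pos] = variants[int(rng.integers(len(variants)))]
        variant_t = tuple(variant)
        if not admissible(variant_t):
            continue
        entries[abbrev].append(variant_t)
        all_expansions.append(variant_t)
        equivalence.add(abbrev, [" ".join(base), " ".join(variant_t)])
        made += 1

    pairs = [
        (abbrev, " ".join(sense))
        for abbrev in entries
        for sense in entries[abbrev]
    ]
    dictionary = AbbrevDictionary(pairs)
    return dictionary, frozenset(homographs), equivalence


# ---------------------------------------------------------------------------
# Web corpus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorpusSpec:
    """Shape of the synthetic web corpus.

    ``base_count`` / ``zipf_exponent`` define the planned per-expansion
    occurrence counts max(1, round(base_count / rank ** exponent)) over a
    random rank permutation; ``expansion_counts`` overrides the law with
    explicit exact counts.  ``native_abbrev_fraction`` of sentences carry a
    raw, unexpanded abbreviation alongside their long form.
    """

    n_documents: int = 100
    base_count: int = 50
    zipf_exponent: float = 1.2
    native_abbrev_fraction: float = 0.5
    expansion_counts: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.native_abbrev_fraction <= 1:
            raise ValueError("native_abbrev_fraction must lie in [0, 1]")
        if self.n_documents < 1 or self.base_count < 1:
            raise ValueError("n_documents and base_count must be >= 1")


def generate_web_corpus(
    spec: CorpusSpec,
    dictionary: AbbrevDictionary,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Emit (doc_id, text) documents plus the exact per-expansion counts.

    Each planned occurrence becomes one template sentence embedding the long
    form exactly once; sentences are shuffled and chunked into
    ``n_documents`` documents.  Native contamination appends " with
    <abbreviation>" to the chosen fraction of sentences.
    """
    rng = rng if rng is not None else np.random.default_rng()
    expansions = sorted(dictionary.all_expansions)
    if spec.expansion_counts is not None:
        counts = {e: int(c) for e, c in spec.expansion_counts.items()}
    else:
        ranks = rng.permutation(len(expansions))
        counts = {
            e: max(1, round(spec.base_count / (int(r) + 1) ** spec.zipf_exponent))
            for e, r in zip(expansions, ranks)
        }

    abbrevs = sorted(dictionary.abbreviations)
    sentences: list[str] = []
    for expansion in sorted(counts):
        for _ in range(counts[expansion]):
            ctx = _CONTEXT_WORDS[int(rng.integers(len(_CONTEXT_WORDS)))]
            sentence = f"the {expansion} findings were {ctx} on exam"
            if rng.random() < spec.native_abbrev_fraction:
                native = abbrevs[int(rng.integers(len(abbrevs)))]
                sentence += f" with {native}"
            sentences.append(sentence + ".")

    order = rng.permutation(len(sentences))
    shuffled = [sentences[int(i)] for i in order]
    documents: list[tuple[str, str]] = []
    n_docs = min(spec.n_documents, len(shuffled)) or 1
    bounds = np.linspace(0, len(shuffled), n_docs + 1).astype(int)
    for d in range(n_docs):
        chunk = shuffled[bounds[d] : bounds[d + 1]]
        if chunk:
            documents.append((f"doc{d:05d}", " ".join(chunk)))
    return documents, counts


def write_corpus(documents: Iterable[tuple[str, str]], destination: str | Path | TextIO) -> None:
    close = False
    if isinstance(destination, (str, Path)):
        stream: TextIO = open(destination, "w", encoding="utf-8")
        close = True
    else:
        stream = destination
    try:
        for doc_id, text in documents:
            stream.write(json.dumps({"doc_id": doc_id, "text": text}) + "\n")
    finally:
        if close:
            stream.close()


def read_corpus(source: str | Path | TextIO) -> list[tuple[str, str]]:
    close = False
    if isinstance(source, (str, Path)):
        stream: TextIO = open(source, encoding="utf-8")
        close = True
    else:
        stream = source
    try:
        docs = []
        for line in stream:
            if line.strip():
                rec = json.loads(line)
                docs.append((rec["doc_id"], rec["text"]))
        return docs
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# Gold-labeled snippets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GoldSnippetSpec:
    n_snippets: int = 50
    min_abbrevs: int = 1
    max_abbrevs: int = 4
    ambiguous_fraction: float = 0.5
    homograph_fraction: float = 0.2  # fraction of slots filled by homographs
    homograph_word_usage: float = 0.5  # of those, fraction used as plain words
    # Fraction of consecutive slots with no context words in between.  The
    # default keeps an anchor between slots: with immediately adjacent
    # abbreviations, the alignment cost scheme can legitimately attribute a
    # neighbor's expansion token to the wrong abbreviation when their sense
    # token counts collide, so adjacency is a stress setting, not a default.
    adjacent_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_snippets < 1 or self.min_abbrevs < 1:
            raise ValueError("n_snippets and min_abbrevs must be >= 1")
        if self.max_abbrevs < self.min_abbrevs:
            raise ValueError("max_abbrevs must be >= min_abbrevs")


@dataclass(frozen=True)
class GoldSnippet:
    """An abbreviated snippet, its labels, and the fully expanded reference."""

    snippet_id: str
    text: str
    labels: tuple[GoldLabel, ...]
    expanded_text: str


def generate_gold_snippets(
    spec: GoldSnippetSpec,
    dictionary: AbbrevDictionary,
    rng: np.random.Generator | None = None,
    english_words: frozenset[str] | None = None,
) -> list[GoldSnippet]:
    """Generate labeled snippets with exact spans and intended expansions.

    Homograph slots are labeled as word-usage (``expansion=None``) or
    abbreviation-usage per the spec fractions.  Substituting every gold
    expansion back into the text yields ``expanded_text`` exactly.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if english_words is None:
        english_words = frozenset(
            a for a in dictionary.abbreviations if a in _HOMOGRAPH_POOL
        )
    ambiguous = sorted(
        a
        for a in dictionary.abbreviations
        if dictionary.is_ambiguous(a) and a not in english_words
    )
    unambiguous = sorted(
        a
        for a in dictionary.abbreviations
        if not dictionary.is_ambiguous(a) and a not in english_words
    )
    homographs = sorted(english_words)
    if not (ambiguous or unambiguous):
        raise ValueError("dictionary too small for the requested snippet spec")

    def pick(pool: list[str]) -> str:
        return pool[int(rng.integers(len(pool)))]

    snippets: list[GoldSnippet] = []
    for i in range(spec.n_snippets):
        k = int(rng.integers(spec.min_abbrevs, spec.max_abbrevs + 1))
        abbr_parts: list[str] = ["the", "patient", "was", "seen", "for"]
        exp_parts: list[str] = list(abbr_parts)
        labels: list[GoldLabel] = []
        cursor = sum(len(p) + 1 for p in abbr_parts)  # next char position
        for slot in range(k):
            if slot > 0 and rng.random() >= spec.adjacent_fraction:
                connector = _CONTEXT_WORDS[int(rng.integers(len(_CONTEXT_WORDS)))]
                for parts in (abbr_parts, exp_parts):
                    parts.append("and")
                    parts.append(connector)
                cursor += len("and") + 1 + len(connector) + 1
            use_homograph = homographs and rng.random() < spec.homograph_fraction
            if use_homograph:
                token = pick(homographs)
                as_word = rng.random() < spec.homograph_word_usage
                if as_word:
                    abbr_parts.append(token)
                    exp_parts.append(token)
                    labels.append(
                        GoldLabel(f"s{i:04d}", token, cursor, cursor + len(token), None)
                    )
                    cursor += len(token) + 1
                    continue
                abbrev = token
            else:
                pool = (
                    ambiguous
                    if ambiguous and (not unambiguous or rng.random() < spec.ambiguous_fraction)
                    else unambiguous
                )
                abbrev = pick(pool)
            senses = sorted(dictionary.expansions_of(abbrev))
            gold = senses[int(rng.integers(len(senses)))]
            abbr_parts.append(abbrev)
            exp_parts.append(gold)
            labels.append(
                GoldLabel(f"s{i:04d}", abbrev, cursor, cursor + len(abbrev), gold)
            )
            cursor += len(abbrev) + 1
        abbr_parts.append("today")
        exp_parts.append("today")
        snippets.append(
            GoldSnippet(
                snippet_id=f"s{i:04d}",
                text=" ".join(abbr_parts),
                labels=tuple(labels),
                expanded_text=" ".join(exp_parts),
            )
        )
    return snippets


def oracle_expand(snippet: GoldSnippet) -> str:
    """Replace every labeled abbreviation with its gold expansion."""
    text = snippet.text
    for label in sorted(snippet.labels, key=lambda l: -l.start):
        if label.expansion is None:
            continue
        text = text[: label.start] + label.expansion + text[label.end :]
    return text


def write_gold_snippets(
    snippets: Iterable[GoldSnippet], destination: str | Path | TextIO
) -> None:
    close = False
    if isinstance(destination, (str, Path)):
        stream: TextIO = open(destination, "w", encoding="utf-8")
        close = True
    else:
        stream = destination
    try:
        for s in snippets:
            stream.write(
                json.dumps(
                    {
                        "snippet_id": s.snippet_id,
                        "text": s.text,
                        "labels": [
                            {
                                "abbrev": l.abbreviation,
                                "start": l.start,
                                "end": l.end,
                                "expansion": l.expansion,
                            }
                            for l in s.labels
                        ],
                        "expanded_text": s.expanded_text,
                    }
                )
                + "\n"
            )
    finally:
        if close:
            stream.close()


def read_gold_snippets(source: str | Path | TextIO) -> list[GoldSnippet]:
    close = False
    if isinstance(source, (str, Path)):
        stream: TextIO = open(source, encoding="utf-8")
        close = True
    else:
        stream = source
    try:
        snippets = []
        for line in stream:
            if not line.strip():
                continue
            rec = json.loads(line)
            snippets.append(
                GoldSnippet(
                    snippet_id=rec["snippet_id"],
                    text=rec["text"],
                    labels=tuple(
                        GoldLabel(
                            rec["snippet_id"],
                            l["abbrev"],
                            l["start"],
                            l["end"],
                            l["expansion"],
                        )
                        for l in rec["labels"]
                    ),
                    expanded_text=rec.get("expanded_text", rec["text"]),
                )
            )
        return snippets
    finally:
        if close:
            stream.close()
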