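"""Reverse-substitution corpus generation.

Reverse substitution (RS) manufactures (abbreviated input, expanded label)
training pairs from ordinary text by replacing dictionary long forms with
their abbreviations: "patients with atrial fibrillation can have chest
pain" becomes "pts with af can have cp", and the original sentence is the
label.  On web-scale corpora a naive find-and-replace is hopeless — common
long forms ("patient") occur orders of magnitude more often than rare ones
("posterior tibialis") — so web-scale reverse substitution (WSRS) balances
the stream with frequency-dependent keep probabilities:

    p_keep = 1 / (n + 1) ** alpha

where ``n`` counts prior events in the shard.  A snippet containing long
forms is kept with the *maximum* keep probability over its long forms
(``n`` = times that long form has already been substituted, exponent
``alpha_rs`` = 1.0); kept snippets substitute each long-form occurrence with
probability 0.95.  Snippets with no substitutions are retained as negative
examples with probability 1/(n_no_rs + 1) ** 1.5.  After all shards
complete, examples are grouped by their rarest substitution and each group
is capped at N = 1000.

The module also provides plain rate-based RS (expected ``target``
substitutions per expansion, used for clinical-note test sets), balanced
test-set sampling (keep a snippet only while one of its abbreviations has
been seen fewer than twice), and the snippet filters applied to an
anonymized clinical dataset with single-abbreviation labels (dictionary
membership, modified-form screening, 100-token cap).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

import numpy as np

from .dictionary import AbbrevDictionary
from .text import split_sentences, tokenize

NO_SUBSTITUTION = "no-substitution"


@dataclass(frozen=True)
class Snippet:
    """One to three consecutive sentences from a document."""

    text: str
    doc_id: str = ""
    sentence_span: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("snippet text must be non-empty")


@dataclass(frozen=True)
class WsrsConfig:
    """WSRS hyperparameters (defaults are the study's operating point)."""

    alpha_rs: float = 1.0
    alpha_no_rs: float = 1.5
    p_substitute: float = 0.95
    max_chars: int = 1024
    min_tokens: int = 3
    cap_n: int = 1000
    counter_scope: str = "document"  # or "worker"

    def __post_init__(self) -> None:
        if self.alpha_rs <= 0 or self.alpha_no_rs <= 0:
            raise ValueError("alpha exponents must be positive")
        if not 0.0 <= self.p_substitute <= 1.0:
            raise ValueError("p_substitute must be a probability")
        if self.cap_n < 1:
            raise ValueError("cap_n must be >= 1")
        if self.counter_scope not in ("worker", "document"):
            raise ValueError("counter_scope must be 'worker' or 'document'")


@dataclass
class ShardCounters:
    """Per-shard substitution tallies driving the keep probabilities."""

    n_rs: dict[str, int] = field(default_factory=dict)
    n_no_rs: int = 0

    def reset(self) -> None:
        self.n_rs.clear()
        self.n_no_rs = 0


@dataclass(frozen=True)
class Substitution:
    expansion: str
    abbreviation: str
    input_span: tuple[int, int]
    label_span: tuple[int, int]


@dataclass(frozen=True)
class TrainingExample:
    """(abbreviated input, original label) pair with provenance."""

    input_text: str
    label_text: str
    substitutions: tuple[Substitution, ...] = ()
    rarest_key: str = NO_SUBSTITUTION
    doc_id: str = ""

    @property
    def abbreviations(self) -> tuple[str, ...]:
        return tuple(s.abbreviation for s in self.substitutions)

    def reconstruct_input(self) -> str:
        """Replay the stored substitutions on the label text."""
        text = self.label_text
        for sub in sorted(self.substitutions, key=lambda s: -s.label_span[0]):
            s, e = sub.label_span
            text = text[:s] + sub.abbreviation + text[e:]
        return text


# ---------------------------------------------------------------------------
# Snippet extraction
# ---------------------------------------------------------------------------

def extract_snippets(
    document: str,
    rng: np.random.Generator,
    doc_id: str = "",
) -> list[Snippet]:
    """Cut a document into consecutive 1–3 sentence windows.

    Window lengths are drawn uniformly from {1, 2, 3}; windows are
    non-overlapping and cover all detected sentences in order.  A document
    with no detected sentence yields an empty list.
    """
    sentences = split_sentences(document)
    snippets: list[Snippet] = []
    i = 0
    while i < len(sentences):
        k = int(rng.integers(1, 4))
        window = sentences[i : i + k]
        snippets.append(
            Snippet(" ".join(window), doc_id=doc_id, sentence_span=(i, i + len(window)))
        )
        i += k
    return snippets


# ---------------------------------------------------------------------------
# Long-form detection
# ---------------------------------------------------------------------------

def find_long_forms(
    text: str, dictionary: AbbrevDictionary
) -> list[tuple[str, tuple[int, int]]]:
    """Locate dictionary long forms in text, longest-match-first.

    Matching is token-based (word boundaries are respected); overlapping
    candidates are resolved longest-match-first scanning left to right.
    Returns (expansion, character span) pairs in left-to-right order.
    """
    seq = tokenize(text)
    by_first: dict[str, list[tuple[str, ...]]] = {}
    for expansion in dictionary.all_expansions:
        toks = tuple(expansion.split())
        by_first.setdefault(toks[0], []).append(toks)
    for cands in by_first.values():
        cands.sort(key=len, reverse=True)

    matches: list[tuple[str, tuple[int, int]]] = []
    i = 0
    while i < len(seq.tokens):
        chosen = None
        for cand in by_first.get(seq.tokens[i], ()):
            if tuple(seq.tokens[i : i + len(cand)]) == cand:
                chosen = cand
                break
        if chosen is None:
            i += 1
            continue
        start = seq.offsets[i][0]
        end = seq.offsets[i + len(chosen) - 1][1]
        matches.append((" ".join(chosen), (start, end)))
        i += len(chosen)
    return matches


# ---------------------------------------------------------------------------
# WSRS sampling
# ---------------------------------------------------------------------------

def keep_probability(n: int, alpha: float) -> float:
    """1 / (n + 1) ** alpha — the frequency-balancing keep probability."""
    if n < 0:
        raise ValueError("count must be non-negative")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return 1.0 / (n + 1) ** alpha


def _sentence_index(text: str, position: int) -> int:
    offset = 0
    for idx, sentence in enumerate(split_sentences(text)):
        found = text.find(sentence, offset)
        if found >= 0 and found <= position < found + len(sentence):
            return idx
        offset = found + len(sentence) if found >= 0 else offset
    return 0


def _substitute(
    snippet: Snippet,
    long_forms: Sequence[tuple[str, tuple[int, int]]],
    dictionary: AbbrevDictionary,
    p_substitute: float,
    rng: np.random.Generator,
) -> TrainingExample:
    """Substitute each long-form occurrence independently with probability
    ``p_substitute``; when an expansion has several abbreviations, one is
    drawn per (sentence, expansion) so repeated mentions within a sentence
    abbreviate consistently."""
    label = snippet.text
    chosen: list[tuple[str, str, tuple[int, int]]] = []
    per_sentence: dict[tuple[int, str], str] = {}
    for expansion, span in long_forms:
        if rng.random() >= p_substitute:
            continue
        abbrevs = sorted(dictionary.abbreviations_of(expansion))
        key = (_sentence_index(label, span[0]), expansion)
        if key not in per_sentence:
            per_sentence[key] = (
                abbrevs[0]
                if len(abbrevs) == 1
                else abbrevs[int(rng.integers(len(abbrevs)))]
            )
        chosen.append((expansion, per_sentence[key], span))

    # build the abbreviated text right-to-left, then recompute input spans
    input_text = label
    for expansion, abbrev, (s, e) in sorted(chosen, key=lambda c: -c[2][0]):
        input_text = input_text[:s] + abbrev + input_text[e:]
    substitutions = []
    shift = 0
    for expansion, abbrev, (s, e) in sorted(chosen, key=lambda c: c[2][0]):
        input_span = (s + shift, s + shift + len(abbrev))
        substitutions.append(Substitution(expansion, abbrev, input_span, (s, e)))
        shift += len(abbrev) - (e - s)
    return TrainingExample(
        input_text=input_text,
        label_text=label,
        substitutions=tuple(substitutions),
        doc_id=snippet.doc_id,
    )


def _rarest_key(
    substitutions: Sequence[Substitution], freq: dict[str, int]
) -> str:
    if not substitutions:
        return NO_SUBSTITUTION
    return min(
        (s.expansion for s in substitutions),
        key=lambda e: (freq.get(e, 0), e),
    )


def wsrs_sample_shard(
    snippets: Iterable[Snippet],
    dictionary: AbbrevDictionary,
    config: WsrsConfig,
    counters: ShardCounters,
    rng: np.random.Generator,
    global_freq: dict[str, int] | None = None,
) -> list[TrainingExample]:
    """Run WSRS over one shard of snippets.

    For each snippet (after the >max_chars filter) the keep decision uses
    the maximum of the per-long-form keep probabilities, read from the
    counters *before* any increments for this snippet.  Counters increment
    per actual substitution (``n_rs``) and per retained negative example
    (``n_no_rs``).  With ``counter_scope="document"`` the counters reset at
    every document boundary, emulating the per-document implementation; with
    ``"worker"`` they persist for the whole shard.  ``rarest_key`` is
    assigned from ``global_freq`` when given, otherwise from the shard
    counters at emission time (ties broken lexicographically).
    """
    if dictionary.n_pairs == 0:  # defensive; the constructor forbids this
        raise ValueError("dictionary is empty")
    examples: list[TrainingExample] = []
    current_doc: str | None = None
    for snippet in snippets:
        if config.counter_scope == "document" and snippet.doc_id != current_doc:
            if current_doc is not None:
                counters.reset()
            current_doc = snippet.doc_id
        if len(snippet.text) > config.max_chars:
            continue
        long_forms = find_long_forms(snippet.text, dictionary)

        example: TrainingExample | None = None
        if long_forms:
            p_keep = max(
                keep_probability(counters.n_rs.get(exp, 0), config.alpha_rs)
                for exp, _ in long_forms
            )
            if rng.random() < p_keep:
                example = _substitute(
                    snippet, long_forms, dictionary, config.p_substitute, rng
                )
                if not example.substitutions:
                    example = None  # fell through: candidate with no substitutions

        if example is not None:
            if len(tokenize(example.input_text)) < config.min_tokens:
                continue
            for sub in example.substitutions:
                counters.n_rs[sub.expansion] = counters.n_rs.get(sub.expansion, 0) + 1
            freq = global_freq if global_freq is not None else counters.n_rs
            examples.append(
                replace(example, rarest_key=_rarest_key(example.substitutions, freq))
            )
        else:
            if len(tokenize(snippet.text)) < config.min_tokens:
                continue
            p_no = keep_probability(counters.n_no_rs, config.alpha_no_rs)
            if rng.random() < p_no:
                counters.n_no_rs += 1
                examples.append(
                    TrainingExample(
                        input_text=snippet.text,
                        label_text=snippet.text,
                        doc_id=snippet.doc_id,
                    )
                )
    return examples


def cap_by_rarest(
    examples: Sequence[TrainingExample],
    cap_n: int,
    rng: np.random.Generator,
) -> list[TrainingExample]:
    """Cap every rarest-substitution group at ``cap_n`` examples.

    Groups larger than the cap are downsampled uniformly without
    replacement; relative input order is preserved.
    """
    groups: dict[str, list[int]] = {}
    for idx, ex in enumerate(examples):
        groups.setdefault(ex.rarest_key, []).append(idx)
    keep: set[int] = set()
    for key in sorted(groups):
        indices = groups[key]
        if len(indices) <= cap_n:
            keep.update(indices)
        else:
            picked = rng.choice(len(indices), size=cap_n, replace=False)
            keep.update(indices[i] for i in picked)
    return [ex for idx, ex in enumerate(examples) if idx in keep]


# ---------------------------------------------------------------------------
# Rate-based reverse substitution (clinical test sets)
# ---------------------------------------------------------------------------

def count_expansions(
    snippets: Iterable[Snippet], dictionary: AbbrevDictionary
) -> dict[str, int]:
    """Total long-form occurrence counts over a snippet pool
    (longest-match-first, same matcher as substitution)."""
    counts: dict[str, int] = {}
    for snippet in snippets:
        for expansion, _ in find_long_forms(snippet.text, dictionary):
            counts[expansion] = counts.get(expansion, 0) + 1
    return counts


def rate_based_reverse_substitution(
    snippets: Sequence[Snippet],
    dictionary: AbbrevDictionary,
    target: int,
    expansion_counts: dict[str, int],
    rng: np.random.Generator,
) -> list[TrainingExample]:
    """Replace each expansion occurrence with probability
    min(1, target / total count), for an expected ``target`` substitutions
    per expansion.  Expansions rarer than the target are always replaced.
    Returns one example per snippet that received >=1 substitution.
    """
    if target <= 0:
        raise ValueError("target must be positive")
    examples: list[TrainingExample] = []
    for snippet in snippets:
        long_forms = find_long_forms(snippet.text, dictionary)
        if not long_forms:
            continue
        selected = []
        for expansion, span in long_forms:
            rate = min(1.0, target / expansion_counts.get(expansion, target))
            if rate >= 1.0 or rng.random() < rate:
                selected.append((expansion, span))
        if not selected:
            continue
        example = _substitute(snippet, selected, dictionary, 1.0, rng)
        examples.append(
            replace(
                example,
                rarest_key=_rarest_key(example.substitutions, expansion_counts),
            )
        )
    return examples


def balanced_testset_sample(
    examples: Sequence[TrainingExample], min_count: int = 2
) -> list[TrainingExample]:
    """Single-pass balanced sampling: keep an example iff at least one of
    its abbreviations has been kept fewer than ``min_count`` times so far."""
    tallies: dict[str, int] = {}
    kept: list[TrainingExample] = []
    for example in examples:
        abbrevs = example.abbreviations
        if any(tallies.get(a, 0) < min_count for a in abbrevs):
            kept.append(example)
            for a in abbrevs:
                tallies[a] = tallies.get(a, 0) + 1
    return kept


# ---------------------------------------------------------------------------
# Training-example formatting and IO
# ---------------------------------------------------------------------------

PROMPT_PREFIX = "expand abbreviations: "


def format_training_example(example: TrainingExample) -> tuple[str, str]:
    """(prompt, target) in the fine-tuning format."""
    return PROMPT_PREFIX + example.input_text, example.label_text


def write_examples(examples: Iterable[TrainingExample], destination: str | Path | TextIO) -> None:
    close = False
    if isinstance(destination, (str, Path)):
        stream: TextIO = open(destination, "w", encoding="utf-8")
        close = True
    else:
        stream = destination
    try:
        for ex in examples:
            record = {
                "input": ex.input_text,
                "label": ex.label_text,
                "substitutions": [
                    {
                        "expansion": s.expansion,
                        "abbreviation": s.abbreviation,
                        "input_span": list(s.input_span),
                        "label_span": list(s.label_span),
                    }
                    for s in ex.substitutions
                ],
                "rarest_key": ex.rarest_key,
                "doc_id": ex.doc_id,
            }
            stream.write(json.dumps(record) + "\n")
    finally:
        if close:
            stream.close()


def read_examples(source: str | Path | TextIO) -> Iterator[TrainingExample]:
    close = False
    if isinstance(source, (str, Path)):
        stream: TextIO = open(source, encoding="utf-8")
        close = True
    else:
        stream = source
    try:
        for line in stream:
            if not line.strip():
                continue
            rec = json.loads(line)
            yield TrainingExample(
                input_text=rec["input"],
                label_text=rec["label"],
                substitutions=tuple(
                    Substitution(
                        s["expansion"],
                        s["abbreviation"],
                        tuple(s["input_span"]),
                        tuple(s["label_span"]),
                    )
                    for s in rec.get("substitutions", ())
                ),
                rarest_key=rec.get("rarest_key", NO_SUBSTITUTION),
                doc_id=rec.get("doc_id", ""),
            )
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# Single-abbreviation snippet dataset filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabeledSnippet:
    """A snippet with exactly one target abbreviation and its labeled sense."""

    text: str
    abbreviation: str
    expansion: str
    span: tuple[int, int] | None = None


def _modified_form_only(text: str, abbreviation: str) -> bool:
    """True when the abbreviation appears only with interior punctuation or
    case changes (e.g. "pm" present solely as "p.m."), never verbatim."""
    exact = False
    modified = False
    for token in tokenize(text).tokens:
        if token == abbreviation:
            exact = True
        elif token.replace(".", "").replace("-", "") == abbreviation:
            modified = True
    return modified and not exact


def casi_filter_pipeline(
    records: Sequence[LabeledSnippet],
    dictionary: AbbrevDictionary,
    max_tokens: int = 100,
) -> tuple[list[LabeledSnippet], dict[str, int]]:
    """Three-stage filter for single-abbreviation labeled snippets.

    1. keep records whose (abbreviation, expansion) pair is in the
       dictionary;
    2. drop records where the target abbreviation appears only in a
       modified form (interior punctuation / case variants);
    3. drop snippets longer than ``max_tokens`` tokens.

    Returns the surviving records and the per-stage surviving counts.
    """
    counts = {"input": len(records)}
    stage1 = [r for r in records if dictionary.has_pair(r.abbreviation, r.expansion)]
    counts["in_dictionary"] = len(stage1)
    stage2 = [r for r in stage1 if not _modified_form_only(r.text, r.abbreviation)]
    counts["unmodified_form"] = len(stage2)
    stage3 = [r for r in stage2 if len(tokenize(r.text)) <= max_tokens]
    counts["within_token_limit"] = len(stage3)
    return stage3, counts
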