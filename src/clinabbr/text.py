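"""Shared text utilities: normalization, tokenization, sentence splitting.

Every module that compares or counts tokens (dictionary statistics, snippet
filters, the aligner) goes through this tokenizer so that "token" means the
same thing everywhere: lowercase, whitespace-delimited, with leading and
trailing punctuation stripped.  Interior punctuation is preserved, so
"p.m." tokenizes to "p.m" (trailing dot stripped) rather than "pm" — the
distinction matters when screening for abbreviations that appear only in a
modified form.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field

_WS = re.compile(r"\s+")
_SENT_SPLIT = re.compile(r"(?<=[.?!])\s+")
_STRIP_CHARS = string.punctuation


def normalize(text: str) -> str:
    """Lowercase, trim, and collapse internal whitespace."""
    return _WS.sub(" ", text.strip()).lower()


@dataclass(frozen=True)
class TokenSequence:
    """An ordered list of normalized tokens with character offsets.

    ``offsets[i]`` is the half-open character span of ``tokens[i]`` in the
    source text, after punctuation stripping (offsets point at the stripped
    core, not the raw whitespace-delimited chunk).
    """

    tokens: tuple[str, ...]
    offsets: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.offsets and len(self.offsets) != len(self.tokens):
            raise ValueError("offsets and tokens must have equal length")

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)


def tokenize(text: str) -> TokenSequence:
    """Split on whitespace, strip edge punctuation, lowercase.

    Tokens that are pure punctuation disappear.  Deterministic; empty input
    yields an empty sequence.
    """
    tokens: list[str] = []
    offsets: list[tuple[int, int]] = []
    for match in re.finditer(r"\S+", text):
        chunk = match.group(0)
        start, end = match.start(), match.end()
        lead = len(chunk) - len(chunk.lstrip(_STRIP_CHARS))
        trail = len(chunk) - len(chunk.rstrip(_STRIP_CHARS))
        core = chunk[lead : len(chunk) - trail]
        if not core:
            continue
        tokens.append(core.lower())
        offsets.append((start + lead, end - trail))
    return TokenSequence(tuple(tokens), tuple(offsets))


def token_count(text: str) -> int:
    return len(tokenize(text))


def split_sentences(text: str) -> list[str]:
    """Rule-based sentence split on a terminator followed by whitespace.

    Intentionally simple: clinical note pipelines in this package split on
    ". " (and "? ", "! ") without an abbreviation-dot guard, matching how the
    discharge-note snippets are produced.
    """
    parts = [p for p in _SENT_SPLIT.split(text) if p.strip()]
    return parts
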