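"""Token-level global alignment between abbreviated and expanded snippets.

When a text-to-text model rewrites "pts with af" as "patients with atrial
fibrillation", evaluation has to attribute each output phrase back to the
input token it expands.  This module does that with a token-level variant of
Needleman–Wunsch global alignment using edit-distance base costs
(match/mismatch/indel = 0/1/1) plus two domain-specific rules:

* **SFC (same first character)** — a reduced mismatch cost (default 0.5)
  when two aligned, unequal tokens share their first character.  Most
  abbreviations start with the same letter as their expansion, so this
  anchors an abbreviation to the head of its expansion.

* **EG (expansion gap)** — a reduced cost (default 0.6) for a run of
  consecutive output insertions that directly follows an aligned input
  abbreviation and whose length equals (token count of some dictionary
  expansion of that abbreviation) − 1.  This lets a multi-token expansion
  tuck in behind its abbreviation instead of being chopped short, even when
  several expansions run together with no anchoring context.

By default the EG cost prices the entire qualifying run (replacing
(len−1) × indel); a per-token variant is available via
``ScoringConfig(eg_per_token=True)``.  The gap is licensed by any aligned
abbreviation (SFC or plain mismatch) and by any dictionary sense with a
matching token count.

After alignment, :func:`extract_pairs` walks the operations and emits one
(abbreviation → predicted expansion) pair per input abbreviation token that
was not left verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dictionary import AbbrevDictionary
from .text import TokenSequence, tokenize

__all__ = [
    "ScoringConfig",
    "AlignOp",
    "AlignmentResult",
    "ExtractedExpansion",
    "align",
    "extract_pairs",
    "tokenize",
]

# Operation labels
MATCH = "match"
MISMATCH = "mismatch"
SFC = "sfc"
INSERT = "insert"
DELETE = "delete"
EG_GAP = "eg-gap"

_EPS = 1e-9


@dataclass(frozen=True)
class ScoringConfig:
    """Alignment costs.  Defaults: match/mismatch/indel/SFC/EG = 0/1/1/0.5/0.6."""

    match: float = 0.0
    mismatch: float = 1.0
    indel: float = 1.0
    sfc: float = 0.5
    eg: float = 0.6
    enable_sfc: bool = True
    enable_eg: bool = True
    eg_per_token: bool = False

    def __post_init__(self) -> None:
        for name in ("match", "mismatch", "indel", "sfc", "eg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} cost must be non-negative")
        if not (self.match <= self.sfc <= self.mismatch):
            raise ValueError("expected match <= sfc <= mismatch")

    def pair_cost(self, a: str, b: str) -> tuple[float, str]:
        if a == b:
            return self.match, MATCH
        if self.enable_sfc and a[:1] == b[:1]:
            return self.sfc, SFC
        return self.mismatch, MISMATCH

    def eg_run_cost(self, run_length: int) -> float:
        return self.eg * run_length if self.eg_per_token else self.eg


@dataclass(frozen=True)
class AlignOp:
    """One aligned element pair; ``None`` marks a gap on that side."""

    input_index: int | None
    output_index: int | None
    op: str


@dataclass(frozen=True)
class AlignmentResult:
    ops: tuple[AlignOp, ...]
    total_cost: float


@dataclass(frozen=True)
class ExtractedExpansion:
    """An abbreviation and the contiguous output span predicted for it."""

    abbreviation: str
    predicted_expansion: str
    input_token_index: int
    output_token_span: tuple[int, int]  # half-open token indices; empty if deleted
    input_char_span: tuple[int, int] = (0, 0)


def _eg_run_lengths(
    token: str, dictionary: AbbrevDictionary | None
) -> tuple[int, ...]:
    """Insertion-run lengths licensed by the token's dictionary senses."""
    if dictionary is None or token not in dictionary:
        return ()
    lengths = {
        len(expansion.split()) - 1
        for expansion in dictionary.expansions_of(token)
        if len(expansion.split()) >= 2
    }
    return tuple(sorted(lengths))


def align(
    input_seq: TokenSequence | list[str],
    output_seq: TokenSequence | list[str],
    scoring: ScoringConfig | None = None,
    dictionary: AbbrevDictionary | None = None,
) -> AlignmentResult:
    """Minimum-cost global alignment of two token sequences.

    Ties in the dynamic program are broken deterministically with the
    preference match > sfc > mismatch > eg-gap > insert > delete, which
    favors anchored extraction.
    """
    scoring = scoring or ScoringConfig()
    a = tuple(input_seq.tokens if isinstance(input_seq, TokenSequence) else input_seq)
    b = tuple(output_seq.tokens if isinstance(output_seq, TokenSequence) else output_seq)
    n, m = len(a), len(b)

    eg_lengths: list[tuple[int, ...]] = [
        _eg_run_lengths(tok, dictionary) if scoring.enable_eg else () for tok in a
    ]

    # dp[i][j]: cost of aligning a[:i] with b[:j]; move[i][j] records the
    # chosen transition for a deterministic traceback.
    inf = float("inf")
    dp = [[inf] * (m + 1) for _ in range(n + 1)]
    move: list[list[tuple | None]] = [[None] * (m + 1) for _ in range(n + 1)]
    dp[0][0] = 0.0
    for i in range(1, n + 1):
        dp[i][0] = i * scoring.indel
        move[i][0] = (DELETE, 0)
    for j in range(1, m + 1):
        dp[0][j] = j * scoring.indel
        move[0][j] = (INSERT, 0)

    for i in range(1, n + 1):
        row, prev = dp[i], dp[i - 1]
        for j in range(1, m + 1):
            # candidates in tie-break preference order
            diag_cost, diag_op = scoring.pair_cost(a[i - 1], b[j - 1])
            candidates: list[tuple[float, tuple]] = [
                (prev[j - 1] + diag_cost, (diag_op, 0))
            ]
            for run in eg_lengths[i - 1]:
                if j - 1 - run >= 0:
                    anchor_cost, anchor_op = scoring.pair_cost(a[i - 1], b[j - 1 - run])
                    candidates.append(
                        (
                            dp[i - 1][j - 1 - run]
                            + anchor_cost
                            + scoring.eg_run_cost(run),
                            (EG_GAP, run, anchor_op),
                        )
                    )
            candidates.append((row[j - 1] + scoring.indel, (INSERT, 0)))
            candidates.append((prev[j] + scoring.indel, (DELETE, 0)))

            best = min(c for c, _ in candidates)
            for cost, mv in candidates:
                if cost <= best + _EPS:
                    row[j], move[i][j] = best, mv
                    break

    # traceback
    ops: list[AlignOp] = []
    i, j = n, m
    while i > 0 or j > 0:
        mv = move[i][j]
        assert mv is not None
        kind = mv[0]
        if kind in (MATCH, SFC, MISMATCH):
            ops.append(AlignOp(i - 1, j - 1, kind))
            i, j = i - 1, j - 1
        elif kind == EG_GAP:
            run, anchor_op = mv[1], mv[2]
            for k in range(run):
                ops.append(AlignOp(None, j - 1 - k, EG_GAP))
            ops.append(AlignOp(i - 1, j - 1 - run, anchor_op))
            i, j = i - 1, j - 1 - run
        elif kind == INSERT:
            ops.append(AlignOp(None, j - 1, INSERT))
            j -= 1
        else:  # DELETE
            ops.append(AlignOp(i - 1, None, DELETE))
            i -= 1
    ops.reverse()
    return AlignmentResult(tuple(ops), round(dp[n][m], 9))


def extract_pairs(
    alignment: AlignmentResult,
    input_seq: TokenSequence,
    output_seq: TokenSequence,
    dictionary: AbbrevDictionary,
) -> list[ExtractedExpansion]:
    """Extract (abbreviation -> predicted expansion) pairs from an alignment.

    For each input token that is a dictionary abbreviation and is *not*
    aligned match-to-itself, the predicted expansion is its aligned output
    token plus any immediately following inserted tokens (plain insertions or
    expansion-gap insertions), stopping at the next aligned or deleted
    token.  An abbreviation token that was deleted outright yields an
    extraction with an empty predicted expansion — the text was modified, so
    the system "attempted" the token, but produced nothing for it.
    Output spans of distinct extractions never overlap.
    """
    in_tokens = input_seq.tokens
    out_tokens = output_seq.tokens
    for op in alignment.ops:
        if op.input_index is not None and op.input_index >= len(in_tokens):
            raise ValueError("alignment is inconsistent with the input sequence")
        if op.output_index is not None and op.output_index >= len(out_tokens):
            raise ValueError("alignment is inconsistent with the output sequence")

    extractions: list[ExtractedExpansion] = []
    ops = alignment.ops
    for idx, op in enumerate(ops):
        if op.input_index is None:
            continue
        token = in_tokens[op.input_index]
        if token not in dictionary or op.op == MATCH:
            continue
        char_span = (
            input_seq.offsets[op.input_index] if input_seq.offsets else (0, 0)
        )
        if op.op == DELETE:
            extractions.append(
                ExtractedExpansion(token, "", op.input_index, (0, 0), char_span)
            )
            continue
        # aligned (sfc or mismatch): take aligned token + following insertions
        start = op.output_index
        end = start + 1
        for follow in ops[idx + 1 :]:
            if follow.op in (INSERT, EG_GAP):
                end = follow.output_index + 1
            else:
                break
        extractions.append(
            ExtractedExpansion(
                token,
                " ".join(out_tokens[start:end]),
                op.input_index,
                (start, end),
                char_span,
            )
        )
    return extractions
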