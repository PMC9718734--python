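"""Standard, iterative, and elicitive inference drivers.

A fine-tuned text-to-text expander tends to under-detect abbreviations on
out-of-domain clinical text: a single pass expands some abbreviations and
leaves others.  Chaining rounds of inference recovers the rest:

* **standard** — one pass; serve the top beam.
* **iterative** — feed the top beam back as input until the model returns
  its input unchanged (a fixed point).
* **elicitive** — iterative, plus: at a fixed point, if the second-highest
  beam differs from the input and its likelihood is at or above a fixed
  threshold, promote that beam to the new input and resume iterating.
  Terminate when the top beam is unchanged *and* the second beam falls
  below the threshold.

The threshold is stated on the probability scale (e.g. 10**-1.5); beams
carry log-likelihoods, and promotion requires the second beam's likelihood
to be strictly above the threshold (``exp(score) > threshold``), so a
threshold of 1.0 disables promotion entirely and the driver reduces to
iterative inference.  Beam size
is 2 by default.  All drivers guard against cycles (a previously seen input
recurring) and cap the number of rounds; both stops are recorded on the
trace rather than raised.

Models plug in through a minimal contract — ``generate(text, beam_size)``
returning a ranked list of ``(output, log_likelihood)`` — and a
deterministic table-backed mock is provided for testing and experiments.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

PROMPT_PREFIX = "expand abbreviations: "

ADVANCE_TOP = "advance-top"
ADVANCE_SECOND = "advance-second"
TERMINATE = "terminate"


class ModelError(RuntimeError):
    pass


class Seq2SeqModel(Protocol):
    """Contract: ranked beams, scores <= 0, deterministic per input."""

    def generate(self, text: str, beam_size: int) -> list[tuple[str, float]]:
        ...


@dataclass(frozen=True)
class InferenceConfig:
    beam_size: int = 2
    threshold: float = 10 ** -1.5  # probability scale
    max_rounds: int = 32
    prefix: str = PROMPT_PREFIX

    def __post_init__(self) -> None:
        if self.beam_size < 1:
            raise ValueError("beam_size must be >= 1")
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must lie in (0, 1]")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")


@dataclass(frozen=True)
class Round:
    input_text: str
    beams: tuple[tuple[str, float], ...]
    decision: str


@dataclass(frozen=True)
class InferenceTrace:
    rounds: tuple[Round, ...]
    final_output: str
    cycle_detected: bool = False
    max_rounds_hit: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "rounds": [
                    {
                        "input": r.input_text,
                        "beams": [list(b) for b in r.beams],
                        "decision": r.decision,
                    }
                    for r in self.rounds
                ],
                "final_output": self.final_output,
                "cycle_detected": self.cycle_detected,
                "max_rounds_hit": self.max_rounds_hit,
            },
            indent=2,
        )


class MockModel:
    """Deterministic table-backed model for tests and dry runs.

    Unknown inputs map to themselves with log-likelihood 0 (identity
    fallback).  The driver prepends the prompt prefix each round; the mock
    strips it before lookup so tables are written in plain text.
    """

    def __init__(
        self,
        table: dict[str, Sequence[tuple[str, float]]],
        prefix: str = PROMPT_PREFIX,
    ):
        for key, beams in table.items():
            scores = [score for _, score in beams]
            if any(score > 0 for score in scores):
                raise ValueError(f"log-likelihoods must be <= 0 for input {key!r}")
            if scores != sorted(scores, reverse=True):
                raise ValueError(f"beams for input {key!r} are not sorted descending")
        self._table = {k: list(v) for k, v in table.items()}
        self._prefix = prefix

    @classmethod
    def from_json(cls, path: str | Path, prefix: str = PROMPT_PREFIX) -> "MockModel":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        return cls(
            {k: [(o, float(s)) for o, s in v] for k, v in raw.items()}, prefix=prefix
        )

    def generate(self, text: str, beam_size: int) -> list[tuple[str, float]]:
        if text.startswith(self._prefix):
            text = text[len(self._prefix) :]
        beams = self._table.get(text)
        if beams is None:
            return [(text, 0.0)]
        return list(beams[:beam_size])


def make_mock_model(
    table: dict[str, Sequence[tuple[str, float]]], prefix: str = PROMPT_PREFIX
) -> MockModel:
    return MockModel(table, prefix=prefix)


def _generate(model: Seq2SeqModel, text: str, config: InferenceConfig) -> list[tuple[str, float]]:
    beams = model.generate(config.prefix + text, config.beam_size)
    if not beams:
        raise ModelError("model returned no beams")
    return beams


def standard_inference(
    model: Seq2SeqModel, text: str, config: InferenceConfig | None = None
) -> str:
    """Single pass: serve the top beam for the prefixed input."""
    config = config or InferenceConfig()
    return _generate(model, text, config)[0][0]


def _chained(
    model: Seq2SeqModel,
    text: str,
    config: InferenceConfig,
    elicit: bool,
) -> tuple[str, InferenceTrace]:
    rounds: list[Round] = []
    visited: set[str] = set()
    current = text
    cycle = False
    max_hit = False
    while True:
        if len(rounds) >= config.max_rounds:
            max_hit = True
            break
        visited.add(current)
        beams = tuple(_generate(model, current, config))
        top = beams[0][0]
        if top != current:
            if top in visited:
                rounds.append(Round(current, beams, TERMINATE))
                cycle = True
                break
            rounds.append(Round(current, beams, ADVANCE_TOP))
            current = top
            continue
        # fixed point of the top beam
        if elicit and len(beams) >= 2:
            second_text, second_score = beams[1]
            if (
                second_text != current
                and math.exp(second_score) > config.threshold
            ):
                if second_text in visited:
                    rounds.append(Round(current, beams, TERMINATE))
                    cycle = True
                    break
                rounds.append(Round(current, beams, ADVANCE_SECOND))
                current = second_text
                continue
        rounds.append(Round(current, beams, TERMINATE))
        break
    return current, InferenceTrace(tuple(rounds), current, cycle, max_hit)


def iterative_inference(
    model: Seq2SeqModel, text: str, config: InferenceConfig | None = None
) -> tuple[str, InferenceTrace]:
    """Feed the top beam back as input until it reaches a fixed point."""
    config = config or InferenceConfig()
    return _chained(model, text, config, elicit=False)


def elicitive_inference(
    model: Seq2SeqModel, text: str, config: InferenceConfig | None = None
) -> tuple[str, InferenceTrace]:
    """Iterative inference with second-beam promotion above the threshold."""
    config = config or InferenceConfig()
    if config.beam_size < 2:
        raise ValueError("elicitive inference requires beam_size >= 2")
    return _chained(model, text, config, elicit=True)


def replay_trace(model: Seq2SeqModel, trace: InferenceTrace, config: InferenceConfig) -> str:
    """Re-run the recorded decisions against the model; returns the final
    output (equal to ``trace.final_output`` for a faithful model)."""
    current = trace.rounds[0].input_text if trace.rounds else trace.final_output
    for r in trace.rounds:
        beams = _generate(model, current, config)
        if r.decision == ADVANCE_TOP:
            current = beams[0][0]
        elif r.decision == ADVANCE_SECOND:
            current = beams[1][0]
        else:
            break
    return current
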