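"""Detection/expansion metrics with bootstrap confidence intervals.

Extracted (abbreviation -> predicted expansion) pairs are scored against
gold labels per snippet:

* **TPD** — the system attempted to expand a gold abbreviation (its input
  token was not left verbatim); split into **CE** (predicted expansion
  exactly matches the gold sense, or is clinically equivalent to it) and
  **IE** (anything else).
* **FND** — a gold abbreviation the system left untouched.
* **FPD** — an attempted expansion whose input span overlaps no gold
  abbreviation.  Only meaningful on exhaustively labeled snippets; on
  datasets where just one abbreviation per snippet (or only the injected
  ones) carry labels the metric is not computed.

From the tallies:

    DR = TPD / (TPD + FND)     detection recall
    DP = TPD / (TPD + FPD)     detection precision
    EA = CE / TPD              expansion accuracy
    TA = CE / (TPD + FND)      total accuracy  (= DR * EA)

Zero denominators yield ``None`` (undefined), never 0.  Confidence
intervals resample *snippets* with replacement (default 400 resamples) and
report the empirical 2.5/97.5 percentiles around the point estimate
computed on the original sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .alignment import ExtractedExpansion, ScoringConfig, align, extract_pairs
from .dictionary import AbbrevDictionary, EquivalenceTable
from .text import normalize, tokenize

# outcome kinds
TPD_CE = "ce"
TPD_IE = "ie"
FND = "fnd"
FPD = "fpd"


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class GoldLabel:
    """One labeled abbreviation occurrence.

    ``expansion`` is the intended sense; ``None`` marks a homograph used as
    an ordinary English word, i.e. a token that must *not* be expanded (an
    attempted expansion over it counts as a false positive, leaving it
    untouched counts as nothing at all).
    """

    snippet_id: str
    abbreviation: str
    start: int
    end: int
    expansion: str | None


@dataclass(frozen=True)
class MetricCounts:
    tpd: int = 0
    fnd: int = 0
    fpd: int = 0
    ce: int = 0
    ie: int = 0

    def __post_init__(self) -> None:
        if min(self.tpd, self.fnd, self.fpd, self.ce, self.ie) < 0:
            raise EvaluationError("counts must be non-negative")
        if self.ce + self.ie != self.tpd:
            raise EvaluationError("ce + ie must equal tpd")

    def __add__(self, other: "MetricCounts") -> "MetricCounts":
        return MetricCounts(
            self.tpd + other.tpd,
            self.fnd + other.fnd,
            self.fpd + other.fpd,
            self.ce + other.ce,
            self.ie + other.ie,
        )


@dataclass(frozen=True)
class Outcome:
    snippet_id: str
    kind: str  # ce / ie / fnd / fpd
    abbreviation: str
    predicted: str | None = None
    gold: str | None = None


@dataclass(frozen=True)
class MetricResults:
    """Point estimates (None where undefined) with optional 95% CIs."""

    dr: float | None
    dp: float | None
    ea: float | None
    ta: float | None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


def is_correct_expansion(
    predicted: str,
    gold: str,
    abbreviation: str,
    equivalence: EquivalenceTable | None = None,
) -> bool:
    """Exact normalized match, or joint membership in one clinical
    equivalence set for that abbreviation."""
    predicted, gold = normalize(predicted), normalize(gold)
    if predicted == gold:
        return True
    if equivalence is not None:
        return equivalence.are_equivalent(abbreviation, predicted, gold)
    return False


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def classify_instances(
    gold: Sequence[GoldLabel],
    extracted: Mapping[str, Sequence[ExtractedExpansion]],
    equivalence: EquivalenceTable | None = None,
    exhaustive: bool = False,
    allowlist: Iterable[tuple[str, str]] | None = None,
) -> tuple[MetricCounts, list[Outcome]]:
    """Score extractions against gold labels.

    ``extracted`` maps snippet id to the extractions for that snippet
    (input character spans in snippet coordinates).  A gold label matches an
    extraction when their input spans overlap.  Unmatched extractions count
    as FPD only when ``exhaustive`` is set; ``allowlist`` pairs
    (word, predicted expansion) mark meaning-preserving rewrites of
    non-abbreviations that should not count as errors.
    """
    seen_spans: set[tuple[str, int, int]] = set()
    for g in gold:
        key = (g.snippet_id, g.start, g.end)
        if key in seen_spans:
            raise EvaluationError(f"duplicate gold label at {key}")
        seen_spans.add(key)
    allowed = {(normalize(a), normalize(p)) for a, p in (allowlist or ())}

    outcomes: list[Outcome] = []
    matched: set[tuple[str, int]] = set()  # (snippet_id, extraction index)
    tpd = fnd = fpd = ce = ie = 0
    for g in gold:
        snippet_extractions = extracted.get(g.snippet_id, ())
        hit = None
        for idx, ext in enumerate(snippet_extractions):
            if _overlaps((g.start, g.end), ext.input_char_span):
                hit = (idx, ext)
                break
        if g.expansion is None:
            # word-usage label: a hit is a false positive, a miss is silence
            if hit is not None:
                matched.add((g.snippet_id, hit[0]))
                if (normalize(g.abbreviation), normalize(hit[1].predicted_expansion)) not in allowed:
                    fpd += 1
                    outcomes.append(
                        Outcome(g.snippet_id, FPD, g.abbreviation, hit[1].predicted_expansion)
                    )
            continue
        if hit is None:
            fnd += 1
            outcomes.append(Outcome(g.snippet_id, FND, g.abbreviation, None, g.expansion))
            continue
        matched.add((g.snippet_id, hit[0]))
        tpd += 1
        if is_correct_expansion(
            hit[1].predicted_expansion, g.expansion, g.abbreviation, equivalence
        ):
            ce += 1
            outcomes.append(
                Outcome(g.snippet_id, TPD_CE, g.abbreviation, hit[1].predicted_expansion, g.expansion)
            )
        else:
            ie += 1
            outcomes.append(
                Outcome(g.snippet_id, TPD_IE, g.abbreviation, hit[1].predicted_expansion, g.expansion)
            )

    if exhaustive:
        for snippet_id, extractions in extracted.items():
            for idx, ext in enumerate(extractions):
                if (snippet_id, idx) in matched:
                    continue
                if (normalize(ext.abbreviation), normalize(ext.predicted_expansion)) in allowed:
                    continue
                fpd += 1
                outcomes.append(
                    Outcome(snippet_id, FPD, ext.abbreviation, ext.predicted_expansion)
                )

    return MetricCounts(tpd, fnd, fpd, ce, ie), outcomes


def counts_by_snippet(outcomes: Sequence[Outcome]) -> dict[str, MetricCounts]:
    """Aggregate per-instance outcomes into per-snippet count tallies."""
    per: dict[str, MetricCounts] = {}
    for o in outcomes:
        delta = MetricCounts(
            tpd=1 if o.kind in (TPD_CE, TPD_IE) else 0,
            fnd=1 if o.kind == FND else 0,
            fpd=1 if o.kind == FPD else 0,
            ce=1 if o.kind == TPD_CE else 0,
            ie=1 if o.kind == TPD_IE else 0,
        )
        per[o.snippet_id] = per.get(o.snippet_id, MetricCounts()) + delta
    return per


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def detection_recall(c: MetricCounts) -> float | None:
    return _ratio(c.tpd, c.tpd + c.fnd)


def detection_precision(c: MetricCounts) -> float | None:
    return _ratio(c.tpd, c.tpd + c.fpd)


def expansion_accuracy(c: MetricCounts) -> float | None:
    return _ratio(c.ce, c.tpd)


def total_accuracy(c: MetricCounts) -> float | None:
    return _ratio(c.ce, c.tpd + c.fnd)


METRIC_FUNCTIONS: dict[str, Callable[[MetricCounts], float | None]] = {
    "dr": detection_recall,
    "dp": detection_precision,
    "ea": expansion_accuracy,
    "ta": total_accuracy,
}


def compute_metrics(counts: MetricCounts) -> MetricResults:
    """Point estimates; undefined metrics are None, never 0."""
    return MetricResults(
        dr=detection_recall(counts),
        dp=detection_precision(counts),
        ea=expansion_accuracy(counts),
        ta=total_accuracy(counts),
    )


def bootstrap_ci(
    per_snippet_counts: Sequence[MetricCounts],
    metric: Callable[[MetricCounts], float | None],
    n_boot: int = 400,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Percentile-bootstrap 95% CI over snippets.

    The point estimate comes from the original sample; snippets are
    resampled with replacement ``n_boot`` times and the 2.5/97.5 empirical
    percentiles of the resampled metric form the interval.  Resamples whose
    metric is undefined are dropped from the percentile computation.
    """
    if not per_snippet_counts:
        raise EvaluationError("no snippets to bootstrap over")
    if n_boot < 1:
        raise EvaluationError("n_boot must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    total = MetricCounts()
    for c in per_snippet_counts:
        total = total + c
    point = metric(total)
    if point is None:
        raise EvaluationError("metric undefined on the original sample")
    n = len(per_snippet_counts)
    values = []
    for _ in range(n_boot):
        indices = rng.integers(0, n, size=n)
        resampled = MetricCounts()
        for i in indices:
            resampled = resampled + per_snippet_counts[int(i)]
        v = metric(resampled)
        if v is not None:
            values.append(v)
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(point), float(lo), float(hi)


def evaluate_expansions(
    input_texts: Mapping[str, str],
    gold: Sequence[GoldLabel],
    outputs: Mapping[str, str],
    dictionary: AbbrevDictionary,
    equivalence: EquivalenceTable | None = None,
    scoring: ScoringConfig | None = None,
    exhaustive: bool = False,
    allowlist: Iterable[tuple[str, str]] | None = None,
) -> tuple[MetricCounts, list[Outcome]]:
    """Align each (input, system output) snippet pair, extract attempted
    expansions, and classify them against the gold labels.  This is the
    full evaluation path: tokenize -> global alignment -> pair extraction ->
    instance classification."""
    scoring = scoring or ScoringConfig()
    extracted: dict[str, list[ExtractedExpansion]] = {}
    for snippet_id, text in input_texts.items():
        output = outputs.get(snippet_id, text)
        in_seq = tokenize(text)
        out_seq = tokenize(output)
        result = align(in_seq, out_seq, scoring, dictionary)
        extracted[snippet_id] = extract_pairs(result, in_seq, out_seq, dictionary)
    return classify_instances(
        gold, extracted, equivalence, exhaustive=exhaustive, allowlist=allowlist
    )


def compute_metrics_with_ci(
    outcomes: Sequence[Outcome],
    n_boot: int = 400,
    rng: np.random.Generator | None = None,
    include_dp: bool = True,
) -> MetricResults:
    """Point estimates plus bootstrap CIs from per-instance outcomes."""
    per = list(counts_by_snippet(outcomes).values())
    total = MetricCounts()
    for c in per:
        total = total + c
    results = compute_metrics(total)
    ci: dict[str, tuple[float, float]] = {}
    for name, fn in METRIC_FUNCTIONS.items():
        if name == "dp" and not include_dp:
            continue
        if fn(total) is None:
            continue
        _, lo, hi = bootstrap_ci(per, fn, n_boot=n_boot, rng=rng)
        ci[name] = (lo, hi)
    return MetricResults(results.dr, results.dp, results.ea, results.ta, ci)
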