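# Methods

This note records the models and procedures implemented in `clinabbr`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic fixtures do and do not establish.

## Task framing

Clinical abbreviation deciphering is treated as text-to-text translation:
an input snippet that may contain abbreviations is rewritten with every
abbreviation expanded, and detection happens endogenously — whatever the
system leaves verbatim was "not detected". The package implements the
data generation, alignment, evaluation, and inference-chaining machinery
around such a system; training the translation model itself is out of
scope, and a deterministic table-backed mock stands in for it wherever a
model is needed.

## Sense inventory

A dictionary is a deduplicated many-to-many set of (abbreviation,
expansion) pairs, normalized by lowercasing, trimming, and collapsing
internal whitespace (every worked example in this domain is lowercase, so
normalization costs nothing and removes a class of spurious mismatches).
An abbreviation is *ambiguous* when it has more than one expansion.

Two summary statistics motivate the alignment scoring rules: the fraction
of abbreviations whose expansions share the abbreviation's first
character, and the fraction whose expansions all have the same token
count. The quantifier behind the first statistic is ambiguous in prose
("expansions that start with the same character" — any, or all?), so
`dictionary_stats` defaults to the stricter **all** reading and exposes
`first_char_quantifier="any"` for sensitivity checks. Token counts use
the package-wide tokenizer (below); no external tokenizer is assumed.

Low-quality indicators for dictionary curation (expansion contains its
own abbreviation, contains another dictionary abbreviation, contains
parentheses, not found in a corpus) are pure classifications.
"Contains another abbreviation" matches whole tokens only — substring
matching would flag every expansion containing the letter "a" — and
abbreviations that double as English words are exempted from it, because
expansions legitimately contain words like "no" or "or". The corpus
indicator only activates when the caller supplies corpus counts; no
corpus ships with the package.

## Reverse substitution and WSRS

Reverse substitution replaces dictionary long forms in ordinary text with
their abbreviations, yielding (abbreviated input, original label) pairs.
Long-form detection is token-based with word boundaries, resolved
longest-match-first scanning left to right, so "atrial fibrillation"
shadows a bare "fibrillation" entry inside it. When an expansion has
several abbreviations, one is drawn uniformly per (sentence, expansion),
so repeated mentions in a sentence abbreviate consistently.

Web-scale corpora are heavily skewed — common long forms occur orders of
magnitude more often than rare ones — so WSRS balances the stream:

* snippets longer than `max_chars` = 1024 characters are dropped;
* a snippet containing long forms is kept with probability
  `max_i 1/(n_i + 1)^α_rs`, where `n_i` counts prior substitutions of
  long form *i* in the shard and `α_rs` = 1.0;
* each long-form occurrence in a kept snippet is substituted
  independently with probability `p_substitute` = 0.95;
* abbreviated snippets shorter than `min_tokens` = 3 tokens are dropped;
* snippets not kept, or kept but with zero substitutions, are retained as
  negative (no-substitution) examples with probability
  `1/(n_no_rs + 1)^α_no_rs`, `α_no_rs` = 1.5;
* after all shards, examples are grouped by their rarest substitution and
  each group is capped at `cap_n` = 1000 examples, sampled uniformly
  without replacement with input order preserved.

Decisions that the prose description leaves open, fixed here: the keep
decision reads counters *before* any increments from the same snippet
(the decision is about the snippet as found, not as modified); counters
increment only on actual substitutions, not on candidacy; the 95% draw
applies per long-form occurrence, not per long-form type; ties for the
rarest key break lexicographically for determinism. Counter scope is
configurable — `"worker"` keeps one counter set for the whole shard,
`"document"` (the default) resets at document boundaries, emulating the
per-document variant of the algorithm; the worker scope downsamples more
aggressively.

Note one consequence of increment-on-substitution: over a stream of
identical snippets with one long form and `p_substitute` = 1, the
expected number kept after *m* snippets is **not** the harmonic number
`H_m` (that would require incrementing per candidate); the exact value
follows from enumerating keep sequences, and the tests check the
Monte-Carlo mean against that enumeration (≈ 2.60 for *m* = 5 at
`α_rs` = 1).

Clinical-note test sets use plain rate-based substitution instead: each
occurrence of an expansion with total count *c* is replaced with
probability `min(1, target/c)`, for an expected `target` substitutions
per expansion (expansions rarer than the target are always replaced).
Balanced test-set sampling then performs a single pass in input order,
keeping a snippet iff at least one of its abbreviations has been kept
fewer than two times so far. A three-stage filter for externally labeled
single-abbreviation snippets keeps dictionary pairs, drops snippets where
the target abbreviation appears only in a modified form (interior
punctuation/case variants, detected by stripping periods and hyphens),
and drops snippets over 100 tokens.

## Tokenization and sentence splitting

One tokenizer serves every module: lowercase, split on whitespace, strip
leading/trailing punctuation, keep interior punctuation ("p.m." →
"p.m"), record character offsets. Sentence splitting is rule-based — a
terminator (`.?!`) followed by whitespace — matching how discharge-note
snippets are produced; no statistical sentence model is used. Snippets
are consecutive windows of 1–3 sentences with window lengths drawn
uniformly.

## Alignment

The aligner is a token-level Needleman–Wunsch dynamic program with
match/mismatch/indel costs 0/1/1 (so the optimum without the custom rules
is token edit distance) plus two rules:

* **SFC** (cost 0.5): aligned unequal tokens sharing their first
  character. Most abbreviations begin with their expansion's first
  letter, so this anchors an abbreviation to its expansion's head.
* **EG** (cost 0.6): a run of consecutive output insertions directly
  following an aligned input abbreviation, whose length equals (token
  count − 1) of *some* dictionary sense of that abbreviation. The prose
  description of this rule is ambiguous on two points, resolved as
  follows. (1) The cost prices the whole qualifying run, replacing
  `(len−1) × indel` — the only reading under which the canonical
  "pts with af" example is cheaper than plain insertions while the
  abbreviation still anchors via SFC; a per-token variant is available as
  `ScoringConfig(eg_per_token=True)`. (2) Any aligned abbreviation
  licenses the gap, whether the anchor pair scored SFC or plain mismatch;
  this keeps multi-token expansions extractable for the minority of
  abbreviations that do not share their expansion's first letter.

Dynamic-program ties break deterministically with preference
match > sfc > mismatch > eg-gap > insert > delete, favoring anchored
extraction. Longer runs than the licensed length are priced as the
licensed gap plus residual insertions.

Extraction walks the optimal alignment: every input token that is a
dictionary abbreviation and is not aligned match-to-itself emits its
aligned output token plus any immediately following insertions as the
predicted expansion. A deleted abbreviation token emits an empty
prediction — the text was modified, so the token counts as attempted but
cannot be correct. Output spans of distinct extractions never overlap.

Known limitation: with two abbreviations immediately adjacent, the cost
scheme itself can attribute a neighbor's expansion token to the wrong
abbreviation when their sense token-counts collide (a mismatch-anchored
gap can undercut the correct split by 0.1 under the default costs). This
is a property of the published scoring values, not of the dynamic
program — the enumeration oracle agrees with the DP on such inputs.

## Evaluation

Gold labels carry character spans; an extraction matches a gold label
when their input spans overlap (the span-matching rule is not specified
in prose; overlap of at least one shared token is required here). Matched
labels are TPD, split into CE (exact normalized match or joint membership
in a clinical-equivalence set for that abbreviation) and IE; unmatched
labels are FND; unmatched extractions are FPD, computed only on datasets
flagged exhaustively labeled — on sets where only one abbreviation per
snippet (or only injected ones) is labeled, precision is not meaningful
and is reported as missing. Meaning-preserving rewrites of
non-abbreviations ("post" → "after") count as FPD by default, with an
allowlist to mark them non-errors. Homograph word-usage labels
(`expansion=None`) contribute FPD when expanded and nothing when left
alone. Undefined metrics propagate as missing values, never as zeros.

Confidence intervals: snippets (not instances) are resampled with
replacement 400 times; the 2.5/97.5 empirical percentiles form the 95%
interval around the point estimate computed on the original sample.
Resamples on which a metric is undefined are dropped from the percentile
computation.

## Inference chaining

All drivers prepend the fine-tuning prompt prefix ("expand
abbreviations: ") each round; the model contract is a ranked beam list
with non-positive log-likelihoods, deterministic per input. Iterative
inference feeds the top beam back until it equals the input. Elicitive
inference additionally promotes the second beam at a fixed point when it
differs from the input and its likelihood is *strictly above* the
threshold (probability scale; e.g. 10⁻¹·⁵). Strict comparison is
deliberate: it makes a threshold of 1.0 a true off-switch that reduces
elicitive to iterative inference even when a beam carries log-likelihood
0. After a promotion the driver re-enters full iterative advancement
(the reading most consistent with "continue the process"). Termination
is guaranteed by a visited-input cycle guard (terminating at the last
fixed point with a flag on the trace) and a `max_rounds` cap of 32 — far
above observed chain lengths, bounded cost. Every round (input, beams,
decision) is recorded on a replayable trace.

## Synthetic fixtures

The generators emulate structure, not semantics: abbreviations are 2–3
letter acronyms spelled by per-initial word buckets (so expansions share
the abbreviation's first character, exercising SFC), an optional tail
noun breaks token-count uniformity across senses, a configurable fraction
of abbreviations are drawn from a common-English-word pool, and
equivalence sets are same-length variants of an existing sense. Corpus
frequencies follow a discrete power law over a random rank permutation —
emitted as *exact* planned counts rather than samples, so recounting
verifies them exactly — and a configurable fraction of sentences carry a
native, unexpanded abbreviation, emulating the contamination that real
web text exhibits. Gold snippets carry exact character spans; the default
places a context anchor between abbreviation slots because adjacent
abbreviations can defeat the scoring scheme (see above); adjacency is
available as a stress parameter.

What passing fixture-based tests shows: the machinery is internally
consistent — substitution bookkeeping reconstructs inputs byte-for-byte,
the aligner is optimal under its cost model, a perfect expander scores
DR = DP = EA = TA = 1 end-to-end, and a never-expand baseline scores
DR = 0 with undefined DP. What it does not show: performance of any real
model on real clinical text, robustness to spelling noise, real sentence
segmentation errors, or genuinely adversarial adjacent-expansion
boundaries — template sentences have none of these.

## Numerical and scale choices

Alignment costs are small rational numbers; DP comparisons use an
absolute tolerance of 1e-9 and totals are rounded to 9 decimals.
Simulation sizes in the tests and the acceptance script (thousands of
snippets, hundreds of enumeration pairs, 400 bootstrap resamples) are
chosen so binomial standard errors sit well inside the asserted
tolerances while the whole suite runs in seconds on one CPU. All
randomness flows through explicit `numpy.random.Generator` objects; the
command-line interface derives per-stage generators from one global seed
via `SeedSequence` spawn keys, so each stage is independently
reproducible and two runs with the same configuration are byte-identical.
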