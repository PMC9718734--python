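# clinabbr

Machinery for building and evaluating systems that decipher clinical
abbreviations — the shorthand that makes clinical notes hard to read
("pt" for *patient* or *physical therapy*, "af" for *atrial fibrillation*
or *afebrile*). The deciphering task is framed as translation: an input
snippet with abbreviations is rewritten as the same snippet with every
abbreviation expanded. `clinabbr` provides everything around the
text-to-text model itself:

* **Sense inventory** (`clinabbr.dictionary`) — load, validate, and
  summarize abbreviation–expansion dictionaries, clinical-equivalence
  tables, and lists of abbreviations that double as English words
  ("us", "it").
* **Reverse-substitution corpora** (`clinabbr.wsrs`) — manufacture
  (abbreviated input, expanded label) training pairs from ordinary text by
  replacing dictionary long forms with their abbreviations. Includes
  *web-scale reverse substitution* (WSRS), which balances heavily skewed
  corpora with keep probabilities `p = 1/(n+1)^α` (per-long-form counts
  for substituted snippets, a separate counter for negative examples),
  95% per-occurrence substitution, length filters, and a cap of
  N examples per rarest substitution; plus plain rate-based substitution
  and balanced test-set sampling for clinical-note test sets.
* **Alignment** (`clinabbr.alignment`) — a token-level variant of
  Needleman–Wunsch global alignment that attributes each expansion in a
  model's output to the input token it expands, using
  match/mismatch/indel/SFC/EG costs of 0/1/1/0.5/0.6. SFC discounts a
  mismatch when the two tokens share their first character; EG discounts
  an insertion run behind an abbreviation when its length matches one of
  the abbreviation's dictionary senses.
* **Evaluation** (`clinabbr.evaluation`) — classify extracted pairs into
  TPD/FND/FPD and CE/IE, compute

  `DR = TPD/(TPD+FND)`, `DP = TPD/(TPD+FPD)`, `EA = CE/TPD`,
  `TA = CE/(TPD+FND) = DR × EA`,

  with 400-resample percentile-bootstrap 95% confidence intervals over
  snippets.
* **Inference drivers** (`clinabbr.inference`) — standard, iterative
  (feed the output back until a fixed point), and elicitive inference
  (promote the second beam at a fixed point while its likelihood is above
  a threshold such as 10⁻¹·⁵), over a minimal `generate(text, beam_size)`
  model contract with a deterministic mock for testing.
* **Synthetic fixtures** (`clinabbr.fixtures`) — seeded generators for
  dictionaries, skewed web corpora with native-abbreviation
  contamination, and gold-labeled snippets, so everything above is
  testable without any download.

## Worked example

```python
from clinabbr import AbbrevDictionary, ScoringConfig, align, extract_pairs, tokenize

d = AbbrevDictionary([
    ("pts", "patients"), ("af", "atrial fibrillation"), ("af", "afebrile"),
])
inp, out = tokenize("pts with af"), tokenize("patients with atrial fibrillation")
result = align(inp, out, ScoringConfig(), d)
print(result.total_cost)
for pair in extract_pairs(result, inp, out, d):
    print(pair.abbreviation, "->", pair.predicted_expansion)
```

prints

```
1.6
pts -> patients
af -> atrial fibrillation
```

The cost 1.6 is the optimal alignment under the default scoring: two
same-first-character anchors (0.5 each), one exact match (0), and one
expansion gap (0.6) that lets "atrial fibrillation" tuck in behind "af"
instead of paying a full insertion. The extracted pairs are what the
evaluation module scores against gold labels.

The command-line interface wires the same pieces together:

```bash
clinabbr make-fixtures --out fx --seed 1
clinabbr build-corpus --dict fx/dictionary.tsv --corpus fx/corpus.jsonl --out train --seed 1
clinabbr dict-stats --dict fx/dictionary.tsv
```

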