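import io

import numpy as np
import pytest

from clinabbr import (
    AbbrevDictionary,
    ShardCounters,
    Snippet,
    WsrsConfig,
    balanced_testset_sample,
    cap_by_rarest,
    casi_filter_pipeline,
    extract_snippets,
    find_long_forms,
    format_training_example,
    keep_probability,
    rate_based_reverse_substitution,
    wsrs_sample_shard,
)
from clinabbr.wsrs import (
    NO_SUBSTITUTION,
    LabeledSnippet,
    TrainingExample,
    count_expansions,
    read_examples,
    write_examples,
)


class TestSnippetExtraction:
    DOC = "One. Two. Three. Four. Five. Six."

    def test_covers_all_sentences_in_order(self):
        rng = np.random.default_rng(0)
        snippets = extract_snippets(self.DOC, rng, doc_id="d")
        spans = [s.sentence_span for s in snippets]
        assert spans[0][0] == 0 and spans[-1][1] == 6
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 == s2
        assert all(1 <= e - s <= 3 for s, e in spans)

    def test_single_sentence_document(self):
        snippets = extract_snippets("Only one sentence here.", np.random.default_rng(1))
        assert len(snippets) == 1

    def test_empty_document(self):
        assert extract_snippets("   ", np.random.default_rng(1)) == []

    def test_deterministic_under_seed(self):
        a = extract_snippets(self.DOC, np.random.default_rng(99))
        b = extract_snippets(self.DOC, np.random.default_rng(99))
        assert a == b


class TestFindLongForms:
    def test_canonical_sentence(self, clinical_dict):
        matches = find_long_forms(
            "patients with atrial fibrillation can have chest pain", clinical_dict
        )
        assert [m[0] for m in matches] == [
            "patients",
            "atrial fibrillation",
            "chest pain",
        ]

    def test_no_matches(self, clinical_dict):
        assert find_long_forms("the cat sat", clinical_dict) == []

    def test_longest_match_wins(self):
        d = AbbrevDictionary(
            [("af", "atrial fibrillation"), ("fib", "fibrillation")]
        )
        matches = find_long_forms("has atrial fibrillation today", d)
        assert [m[0] for m in matches] == ["atrial fibrillation"]
        # brute force: the shorter form alone still matches elsewhere
        assert [m[0] for m in find_long_forms("fibrillation noted", d)] == [
            "fibrillation"
        ]

    def test_spans_index_source_text(self, clinical_dict):
        text = "Patients with atrial fibrillation."
        for expansion, (s, e) in find_long_forms(text, clinical_dict):
            assert text[s:e].lower() == expansion


class TestKeepProbability:
    @pytest.mark.parametrize(
        "n,alpha,expected", [(0, 1.0, 1.0), (3, 1.0, 0.25), (3, 1.5, 0.125)]
    )
    def test_values(self, n, alpha, expected):
        assert keep_probability(n, alpha) == pytest.approx(expected)

    def test_strictly_decreasing_in_n_and_alpha(self):
        for alpha in (0.5, 1.0, 1.5):
            values = [keep_probability(n, alpha) for n in range(10)]
            assert all(a > b for a, b in zip(values, values[1:]))
        for n in range(1, 10):
            assert keep_probability(n, 1.0) > keep_probability(n, 1.5)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            keep_probability(-1, 1.0)


def _af_snippets(k, doc_id="d0"):
    return [
        Snippet("patients had atrial fibrillation today.", doc_id=doc_id)
        for _ in range(k)
    ]


AF_DICT = AbbrevDictionary([("af", "atrial fibrillation")])


class TestWsrsSampling:
    def test_first_snippet_always_kept(self):
        config = WsrsConfig(p_substitute=1.0, counter_scope="worker")
        ex = wsrs_sample_shard(
            _af_snippets(1), AF_DICT, config, ShardCounters(), np.random.default_rng(0)
        )
        assert len(ex) == 1 and ex[0].substitutions

    def test_oversized_snippet_excluded(self):
        long_snippet = Snippet("atrial fibrillation " + "x" * 1030, doc_id="d0")
        ex = wsrs_sample_shard(
            [long_snippet],
            AF_DICT,
            WsrsConfig(counter_scope="worker"),
            ShardCounters(),
            np.random.default_rng(0),
        )
        assert ex == []

    def test_min_token_filter(self):
        # abbreviated form "af." is a single token -> dropped
        short = Snippet("atrial fibrillation.", doc_id="d0")
        ex = wsrs_sample_shard(
            [short],
            AF_DICT,
            WsrsConfig(p_substitute=1.0, counter_scope="worker"),
            ShardCounters(),
            np.random.default_rng(0),
        )
        assert ex == []

    def test_reconstruction_invariant(self, clinical_dict, rng):
        snippets = [
            Snippet(
                "the patient with atrial fibrillation had chest pain. "
                "patients were seen in the cardiac care unit.",
                doc_id=f"d{i}",
            )
            for i in range(50)
        ]
        ex = wsrs_sample_shard(
            snippets, clinical_dict, WsrsConfig(), ShardCounters(), rng
        )
        assert any(e.substitutions for e in ex)
        for e in ex:
            assert e.reconstruct_input() == e.input_text
            for sub in e.substitutions:
                assert clinical_dict.has_pair(sub.abbreviation, sub.expansion)
                s, t = sub.input_span
                assert e.input_text[s:t] == sub.abbreviation
                s, t = sub.label_span
                assert e.label_text[s:t] == sub.expansion

    def test_mean_kept_matches_exact_enumeration(self):
        """Sequential frequency-balanced keeping: the Monte-Carlo mean of
        substituted examples over 5 identical single-long-form snippets must
        match exact enumeration of all keep sequences."""

        def exact_expectation(m):
            total = 0.0

            def rec(i, kept, prob):
                nonlocal total
                if i == m:
                    total += prob * kept
                    return
                p = 1.0 / (kept + 1)
                rec(i + 1, kept + 1, prob * p)
                rec(i + 1, kept, prob * (1 - p))

            rec(0, 0, 1.0)
            return total

        config = WsrsConfig(p_substitute=1.0, min_tokens=1, counter_scope="worker")
        rng = np.random.default_rng(2024)
        reps, total = 4000, 0
        for _ in range(reps):
            ex = wsrs_sample_shard(
                _af_snippets(5), AF_DICT, config, ShardCounters(), rng
            )
            total += sum(1 for e in ex if e.substitutions)
        assert total / reps == pytest.approx(exact_expectation(5), abs=0.07)

    def test_degenerate_limit_is_find_and_replace(self, clinical_dict):
        """p_substitute=1 with a vanishing exponent keeps and substitutes
        every eligible snippet."""
        config = WsrsConfig(
            p_substitute=1.0, alpha_rs=1e-9, alpha_no_rs=1.5, counter_scope="worker"
        )
        snippets = [
            Snippet("the patient had atrial fibrillation today.", doc_id=f"d{i}")
            for i in range(30)
        ]
        ex = wsrs_sample_shard(
            snippets, clinical_dict, config, ShardCounters(), np.random.default_rng(0)
        )
        substituted = [e for e in ex if e.substitutions]
        assert len(substituted) == 30
        # "atrial fibrillation" abbreviates to either of its short forms
        assert all(
            e.input_text in ("the pt had af today.", "the pt had afib today.")
            for e in substituted
        )

    def test_realized_substitution_fraction(self, clinical_dict):
        """Across kept snippets each long-form instance is substituted
        independently with probability ~0.95."""
        config = WsrsConfig(alpha_rs=1e-9, counter_scope="worker")
        snippets = [
            Snippet(
                "the patient had atrial fibrillation and chest pain today.",
                doc_id=f"d{i}",
            )
            for i in range(3000)
        ]
        ex = wsrs_sample_shard(
            snippets, clinical_dict, config, ShardCounters(), np.random.default_rng(3)
        )
        n_instances = 3 * 3000  # patient, atrial fibrillation, chest pain
        n_substituted = sum(len(e.substitutions) for e in ex)
        assert n_substituted / n_instances == pytest.approx(0.95, abs=0.01)

    def test_no_substitution_examples_counted_and_keyed(self):
        d = AbbrevDictionary([("zz", "zonal zystic")])  # never matches
        snippets = [Snippet("nothing clinical here at all.", doc_id="d0")] * 10
        counters = ShardCounters()
        ex = wsrs_sample_shard(
            snippets,
            d,
            WsrsConfig(counter_scope="worker"),
            counters,
            np.random.default_rng(0),
        )
        assert all(e.rarest_key == NO_SUBSTITUTION for e in ex)
        assert all(e.input_text == e.label_text for e in ex)
        assert counters.n_no_rs == len(ex) > 0

    def test_document_scope_resets_counters(self):
        config_doc = WsrsConfig(p_substitute=1.0, min_tokens=1)
        snippets = [
            s
            for i in range(40)
            for s in _af_snippets(1, doc_id=f"d{i}")
        ]
        ex = wsrs_sample_shard(
            snippets, AF_DICT, config_doc, ShardCounters(), np.random.default_rng(0)
        )
        # counters reset every document: every snippet sees n_rs = 0
        assert len([e for e in ex if e.substitutions]) == 40

    def test_deterministic_under_seed(self, clinical_dict):
        snippets = [
            Snippet("patients with atrial fibrillation had chest pain.", doc_id=f"d{i}")
            for i in range(20)
        ]
        runs = [
            wsrs_sample_shard(
                snippets,
                clinical_dict,
                WsrsConfig(),
                ShardCounters(),
                np.random.default_rng(77),
            )
            for _ in range(2)
        ]
        assert runs[0] == runs[1]


class TestCapByRarest:
    def _examples(self, key, k):
        return [
            TrainingExample(f"in{i}", f"lab{i}", rarest_key=key) for i in range(k)
        ]

    def test_large_group_capped(self, rng):
        out = cap_by_rarest(self._examples("a", 1500), 1000, rng)
        assert len(out) == 1000

    def test_small_group_untouched(self, rng):
        examples = self._examples("a", 7)
        assert cap_by_rarest(examples, 1000, rng) == examples

    def test_mixed_groups(self, rng):
        examples = self._examples("a", 1500) + self._examples("b", 500)
        out = cap_by_rarest(examples, 1000, rng)
        assert len(out) == 1500
        assert sum(1 for e in out if e.rarest_key == "a") == 1000

    def test_order_preserved(self, rng):
        examples = self._examples("a", 50)
        out = cap_by_rarest(examples, 10, rng)
        indices = [examples.index(e) for e in out]
        assert indices == sorted(indices)


class TestRateBasedRs:
    def test_rates(self):
        assert min(1.0, 10000 / 50000) == pytest.approx(0.2)

    def test_rare_expansion_always_replaced(self, rng):
        d = AbbrevDictionary([("af", "atrial fibrillation")])
        snippets = [
            Snippet("patient had atrial fibrillation today.", doc_id=f"d{i}")
            for i in range(40)
        ]
        counts = count_expansions(snippets, d)
        assert counts["atrial fibrillation"] == 40
        ex = rate_based_reverse_substitution(snippets, d, 10000, counts, rng)
        assert len(ex) == 40
        assert all(e.substitutions for e in ex)

    def test_expected_substitution_count(self):
        d = AbbrevDictionary([("af", "atrial fibrillation")])
        snippets = [
            Snippet("patient had atrial fibrillation today.", doc_id=f"d{i}")
            for i in range(2000)
        ]
        counts = {"atrial fibrillation": 2000}
        target = 400
        totals = []
        for seed in range(10):
            ex = rate_based_reverse_substitution(
                snippets, d, target, counts, np.random.default_rng(seed)
            )
            totals.append(sum(len(e.substitutions) for e in ex))
        assert np.mean(totals) / target == pytest.approx(1.0, abs=0.03)

    def test_invalid_target(self, clinical_dict, rng):
        with pytest.raises(ValueError):
            rate_based_reverse_substitution([], clinical_dict, 0, {}, rng)


class TestBalancedSampling:
    def _example(self, *abbrevs):
        from clinabbr.wsrs import Substitution

        subs = tuple(
            Substitution(f"exp-{a}", a, (i, i + 1), (i, i + 1))
            for i, a in enumerate(abbrevs)
        )
        return TrainingExample("x", "y", substitutions=subs, rarest_key=abbrevs[0])

    def test_first_two_of_each_kept(self):
        stream = [self._example("af") for _ in range(10)]
        assert balanced_testset_sample(stream) == stream[:2]

    def test_unseen_abbreviation_rescues_example(self):
        stream = [
            self._example("af"),
            self._example("af"),
            self._example("af", "pt"),
        ]
        assert balanced_testset_sample(stream) == stream

    def test_matches_bruteforce_replay(self):
        rnd = np.random.default_rng(5)
        abbrevs = ["af", "pt", "cp"]
        stream = [
            self._example(*rnd.choice(abbrevs, size=rnd.integers(1, 3), replace=False))
            for _ in range(60)
        ]
        got = balanced_testset_sample(stream, min_count=2)
        tallies, expected = {}, []
        for ex in stream:
            if any(tallies.get(a, 0) < 2 for a in ex.abbreviations):
                expected.append(ex)
                for a in ex.abbreviations:
                    tallies[a] = tallies.get(a, 0) + 1
        assert got == expected


class TestFormattingAndIo:
    def test_prompt_format(self):
        ex = TrainingExample("pts with af", "patients with atrial fibrillation")
        prompt, target = format_training_example(ex)
        assert prompt == "expand abbreviations: pts with af"
        assert target == "patients with atrial fibrillation"
        assert prompt[len("expand abbreviations: ") :] == ex.input_text

    def test_jsonl_roundtrip(self, clinical_dict, rng):
        snippets = [
            Snippet("patients with atrial fibrillation had chest pain.", doc_id="d0")
        ] * 5
        ex = wsrs_sample_shard(
            snippets,
            clinical_dict,
            WsrsConfig(counter_scope="worker"),
            ShardCounters(),
            rng,
        )
        buffer = io.StringIO()
        write_examples(ex, buffer)
        assert list(read_examples(io.StringIO(buffer.getvalue()))) == ex


class TestCasiFiltering:
    def test_stage_counts(self, clinical_dict):
        records = [
            LabeledSnippet("patient seen with af today", "af", "atrial fibrillation"),
            LabeledSnippet("not a dictionary pair", "af", "atrial flutter"),
            LabeledSnippet("dose at p.m. given", "pm", "evening"),
            LabeledSnippet("word " * 101 + "af here", "af", "afebrile"),
        ]
        d = AbbrevDictionary(
            [("af", "atrial fibrillation"), ("af", "afebrile"), ("pm", "evening")]
        )
        kept, counts = casi_filter_pipeline(records, d)
        assert counts == {
            "input": 4,
            "in_dictionary": 3,
            "unmodified_form": 2,
            "within_token_limit": 1,
        }
        assert kept == records[:1]

    def test_modified_form_with_exact_occurrence_survives(self):
        d = AbbrevDictionary([("pm", "evening")])
        rec = LabeledSnippet("pm dose and p.m. note", "pm", "evening")
        kept, _ = casi_filter_pipeline([rec], d)
        assert kept == [rec]
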