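"""Candidate scoring, tuple assembly, and end-to-end pipelines."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from weakext.corpus import CuratedRecord
from weakext.evaluation import precision_at_k, tuple_prf
from weakext.synthetic import (CorpusSimConfig, default_initial_cues,
                               default_replication_cues,
                               default_sample_lexicon, gen_task1_corpus,
                               gen_task2_corpus)
from weakext.tasks import (CandidateScore, PipelineConfig, assemble_tuples,
                           combine_scores, rank_top_k, run_task1_pipeline,
                           run_task2_pipeline, score_candidates)


def _abc_scores():
    predictions = ([("A", 1)] * 6 + [("A", 0)] * 2 + [("B", 1)] * 2
                   + [("C", 1)] * 2 + [("C", 0)] * 6)
    return score_candidates(predictions, "doc")


class TestScoreCandidates:
    def test_vote_ratio_and_document_share(self):
        scores = {s.canonical: s for s in _abc_scores()}
        assert scores["A"].P_TF == 0.75 and scores["A"].P_IDF == 0.6
        assert scores["B"].P_TF == 1.0 and scores["B"].P_IDF == 0.2
        assert scores["C"].P_TF == 0.25 and scores["C"].P_IDF == 0.2

    def test_single_all_positive_candidate(self):
        s = score_candidates([("A", 1), ("A", 1)], "d")[0]
        assert s.P_TF == 1.0 and s.P_IDF == 1.0

    def test_candidate_without_positives(self):
        scores = score_candidates([("A", 0), ("B", 1)], "d")
        by = {s.canonical: s for s in scores}
        assert by["A"].P_TF == 0.0 and by["A"].P_IDF == 0.0

    def test_document_with_zero_positive_votes(self):
        scores = score_candidates([("A", 0), ("B", 0)], "d")
        assert all(s.P_IDF == 0.0 for s in scores)

    def test_share_sums_to_one_with_any_positive(self):
        assert sum(s.P_IDF for s in _abc_scores()) == pytest.approx(1.0)


class TestCombineScores:
    def test_worked_harmonic_and_arithmetic(self):
        s = CandidateScore("d", "A", V_p=6, V_n=2)
        s.P_IDF = 0.6
        assert combine_scores(s, "harmonic") == pytest.approx(0.6667, abs=1e-4)
        assert combine_scores(s, "arithmetic") == pytest.approx(0.675)

    def test_equal_components_are_fixed_point_of_both_means(self):
        s = CandidateScore("d", "A", V_p=1, V_n=1)
        s.P_IDF = 0.5
        assert combine_scores(s, "harmonic") == pytest.approx(0.5)
        assert combine_scores(s, "arithmetic") == pytest.approx(0.5)

    def test_harmonic_penalises_imbalance(self):
        s = CandidateScore("d", "A", V_p=5, V_n=0)
        s.P_IDF = 0.2
        assert combine_scores(s, "harmonic") == pytest.approx(1 / 3, abs=1e-4)
        assert combine_scores(s, "arithmetic") == pytest.approx(0.6)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_harmonic_never_exceeds_arithmetic(self, a, b):
        s = CandidateScore("d", "A", V_p=1, V_n=0)
        s.P_TF, s.P_IDF = a, b
        assert combine_scores(s, "harmonic") <= \
            combine_scores(s, "arithmetic") + 1e-12


class TestRankTopK:
    def test_worked_example_order(self):
        assert rank_top_k(_abc_scores(), 2, "harmonic") == ["A", "B"]

    def test_k_larger_than_candidates(self):
        assert rank_top_k(_abc_scores(), 10, "harmonic") == ["A", "B", "C"]

    def test_tie_broken_lexicographically(self):
        a = CandidateScore("d", "zeta", 2, 2)
        b = CandidateScore("d", "alpha", 2, 2)
        a.P_IDF = b.P_IDF = 0.5
        assert rank_top_k([a, b], 2) == ["alpha", "zeta"]

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            rank_top_k([], 0)


class TestAssembleTuples:
    def _passage(self, doc, ethnicity):
        from weakext.corpus import Article, TermDictionary
        from weakext.extraction import extract_passages, match_mentions
        art = Article(doc_id=doc, title=f"{ethnicity} cohort", sections=[])
        d = TermDictionary({ethnicity.casefold(): ethnicity})
        return extract_passages(match_mentions(art, d), art)[0]

    def test_duplicates_discarded(self):
        p = self._passage("d1", "European")
        out = assemble_tuples([(p, "initial"), (p, "initial"),
                               (p, "replication")])
        assert out["d1"] == frozenset({("initial", "European"),
                                       ("replication", "European")})

    def test_no_positives_gives_empty(self):
        assert assemble_tuples([]) == {}

    def test_order_invariance(self):
        pa = self._passage("d1", "European")
        pb = self._passage("d1", "Japanese")
        forward = assemble_tuples([(pa, "initial"), (pb, "initial")])
        backward = assemble_tuples([(pb, "initial"), (pa, "initial")])
        assert forward == backward


@pytest.fixture(scope="module")
def small_task1():
    cfg = CorpusSimConfig(n_docs=40, seed=3)
    return gen_task1_corpus(cfg)


@pytest.fixture(scope="module")
def small_task2():
    cfg = CorpusSimConfig(n_docs=40, label_noise=0.2, seed=3)
    return gen_task2_corpus(cfg)


def _split(articles, n_test=10):
    return articles[n_test:], articles[:n_test]


class TestTask1Pipeline:
    def test_precision_above_chance_on_planted_corpus(self, small_task1):
        articles, records, dictionary, gold = small_task1
        train_a, test_a = _split(articles)
        test_ids = {a.doc_id for a in test_a}
        train_r = [r for r in records if r.doc_id not in test_ids]
        preds = run_task1_pipeline(train_a, train_r, test_a, dictionary,
                                   dictionary, PipelineConfig(seed=3))
        ranked = {d: [c for c, _ in v] for d, v in preds.items()}
        gold_records = [CuratedRecord(d, "phenotype",
                                      phenotype_terms=sorted(gold[d]))
                        for d in sorted(test_ids)]
        report = precision_at_k(ranked, gold_records, k=2)
        # ~40 candidate phenotypes per document; chance of a top-2 hit is
        # far below this threshold
        assert report.precision > 0.5

    def test_rerun_with_same_seed_is_identical(self, small_task1):
        articles, records, dictionary, _ = small_task1
        train_a, test_a = _split(articles)
        test_ids = {a.doc_id for a in test_a}
        train_r = [r for r in records if r.doc_id not in test_ids]
        cfg = PipelineConfig(seed=3)
        a = run_task1_pipeline(train_a, train_r, test_a, dictionary,
                               dictionary, cfg)
        b = run_task1_pipeline(train_a, train_r, test_a, dictionary,
                               dictionary, cfg)
        assert a == b

    def test_empty_test_corpus_gives_empty_output(self, small_task1):
        articles, records, dictionary, _ = small_task1
        preds = run_task1_pipeline(articles, records, [], dictionary,
                                   dictionary, PipelineConfig(seed=3))
        assert preds == {}


class TestTask2Pipeline:
    def _run(self, small_task2, method, seed=3):
        articles, records, dictionary, gold = small_task2
        train_a, test_a = _split(articles)
        test_ids = {a.doc_id for a in test_a}
        train_r = [r for r in records if r.doc_id not in test_ids]
        preds = run_task2_pipeline(
            train_a, train_r, test_a, dictionary,
            default_sample_lexicon(), default_initial_cues(),
            default_replication_cues(), PipelineConfig(seed=seed, method=method))
        return preds, {d: gold[d] for d in test_ids}

    def test_extracts_mostly_correct_tuples(self, small_task2):
        preds, gold = self._run(small_task2, "cost_sensitive")
        report = tuple_prf(preds, gold, "micro")
        assert report.f1 > 0.5

    def test_baseline_assigns_both_stages(self, small_task2):
        preds, gold = self._run(small_task2, "baseline")
        report = tuple_prf(preds, gold, "micro")
        assert report.recall == 1.0
        for tuples in preds.values():
            ethnicities = {e for _, e in tuples}
            for eth in ethnicities:
                assert ("initial", eth) in tuples
                assert ("replication", eth) in tuples

    def test_rerun_deterministic(self, small_task2):
        a, _ = self._run(small_task2, "cost_sensitive")
        b, _ = self._run(small_task2, "cost_sensitive")
        assert a == b

    def test_empty_test_corpus(self, small_task2):
        articles, records, dictionary, _ = small_task2
        preds = run_task2_pipeline(
            articles, records, [], dictionary, default_sample_lexicon(),
            default_initial_cues(), default_replication_cues(),
            PipelineConfig(seed=3))
        assert preds == {}
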