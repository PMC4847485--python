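"""Weak-classifier votes and committee-matrix assembly."""

import numpy as np
import pytest

from weakext.committee import (CommitteeMatrix, WeakVote,
                               build_matrix, stage_cue_vote, vote_task1,
                               vote_task2_posneg, vote_task2_stage,
                               weak_label_posneg, weak_label_stage)
from weakext.corpus import Article, CuratedRecord, RuleLexicon, TermDictionary
from weakext.errors import CommitteeError
from weakext.extraction import extract_passages, match_mentions


def _passage(text, dict_entries, title="", abstract=""):
    art = Article(doc_id="doc1", title=title, abstract=abstract,
                  sections=[("Sec", [text])] if text else [])
    d = TermDictionary(dict_entries)
    mentions = match_mentions(art, d)
    return extract_passages(mentions, art, "within_sentence")[0]


def _votes(vote_list):
    return tuple(v.vote for v in vote_list)


class TestTask1Votes:
    def test_substring_only(self):
        # body mention "Diabetes", curated "Type-2 Diabetes": only the
        # sub-string rule fires
        p = _passage("We studied Diabetes in this sample.",
                     {"diabetes": "Diabetes"})
        rec = CuratedRecord("doc1", "phenotype",
                            phenotype_terms=["Type-2 Diabetes"])
        assert _votes(vote_task1(p, rec, None)) == (0, 0, 1, 0, 0)

    def test_compound_token_fires_on_multiword_mention(self):
        p = _passage("Parkinson's disease was the target.",
                     {"parkinson's disease": "Parkinson's disease"})
        rec = CuratedRecord("doc1", "phenotype", phenotype_terms=["Asthma"])
        votes = _votes(vote_task1(p, rec, None))
        assert votes[4] == 1

    def test_exact_match_in_title(self):
        p = _passage("", {"asthma": "Asthma"}, title="Asthma genetics")
        rec = CuratedRecord("doc1", "phenotype", phenotype_terms=["asthma"])
        votes = _votes(vote_task1(p, rec, None))
        assert votes[0] == 1  # title/abstract
        assert votes[1] == 1  # exact (case-insensitive)
        assert votes[2] == 1  # exact implies substring

    def test_hyphen_space_equivalence_in_exact_match(self):
        p = _passage("type 2 diabetes here", {"type 2 diabetes": "T2D"})
        rec = CuratedRecord("doc1", "phenotype",
                            phenotype_terms=["Type-2 Diabetes"])
        votes = _votes(vote_task1(p, rec, None))
        assert votes[1] == 1

    def test_synonym_rule_uses_shared_concept(self):
        p = _passage("adiposity was assessed", {"adiposity": "Obesity"})
        rec = CuratedRecord("doc1", "phenotype", phenotype_terms=["Obesity"])
        synonyms = TermDictionary({"obesity": "C001", "adiposity": "C001"})
        votes = _votes(vote_task1(p, rec, synonyms))
        assert votes[3] == 1
        # without the synonym dictionary the rule stays silent
        assert _votes(vote_task1(p, rec, None))[3] == 0

    def test_exact_implies_substring_on_random_terms(self):
        rng = np.random.default_rng(3)
        terms = ["alpha", "beta trait", "gamma", "delta-x"]
        for _ in range(30):
            surface = str(rng.choice(terms))
            curated = str(rng.choice(terms))
            p = _passage(f"we measured {surface} here", {surface: surface})
            rec = CuratedRecord("doc1", "phenotype", phenotype_terms=[curated])
            votes = _votes(vote_task1(p, rec, None))
            assert votes[1] <= votes[2]


class TestTask2Votes:
    lexicon = RuleLexicon(frozenset({"cohort", "stage"}), "sample_description")
    initial_cues = RuleLexicon(frozenset({"discovery", "first stage"}),
                               "initial_cue")
    replication_cues = RuleLexicon(frozenset({"follow-up", "replication"}),
                                   "replication_cue")

    def test_lexicon_and_weak_label_positive(self):
        p = _passage("the German cohort was genotyped",
                     {"german": "European"})
        rec = CuratedRecord("doc1", "stage_ethnicity",
                            tuples=frozenset({("initial", "European")}))
        votes = vote_task2_posneg(p, rec, self.lexicon, base_model=None,
                                  base_vote=1)
        assert _votes(votes) == (1, 1, 1)

    def test_absent_ethnicity_and_no_lexicon_term(self):
        p = _passage("results in German groups were reported",
                     {"german": "European"})
        rec = CuratedRecord("doc1", "stage_ethnicity",
                            tuples=frozenset({("initial", "East Asian")}))
        votes = vote_task2_posneg(p, rec, self.lexicon, base_model=None,
                                  base_vote=0)
        assert _votes(votes) == (0, 0, 0)

    def test_votes_are_deterministic(self):
        p = _passage("the German cohort", {"german": "European"})
        rec = CuratedRecord("doc1", "stage_ethnicity",
                            tuples=frozenset({("initial", "European")}))
        a = vote_task2_posneg(p, rec, self.lexicon, None, base_vote=1)
        b = vote_task2_posneg(p, rec, self.lexicon, None, base_vote=1)
        assert _votes(a) == _votes(b)

    def test_stage_cue_follow_up_means_replication(self):
        p = _passage("Germans were genotyped in the follow-up phase",
                     {"germans": "European"})
        assert stage_cue_vote(p, self.initial_cues, self.replication_cues) == 0

    def test_stage_cue_discovery_means_initial(self):
        p = _passage("Germans were genotyped in the discovery phase",
                     {"germans": "European"})
        assert stage_cue_vote(p, self.initial_cues, self.replication_cues) == 1

    def test_stage_cue_defaults_to_initial(self):
        p = _passage("Germans were genotyped", {"germans": "European"})
        assert stage_cue_vote(p, self.initial_cues, self.replication_cues) == 1

    def test_weak_stage_label_both_stages_defaults_initial(self):
        p = _passage("German sample", {"german": "European"})
        rec = CuratedRecord("doc1", "stage_ethnicity",
                            tuples=frozenset({("initial", "European"),
                                              ("replication", "European")}))
        assert weak_label_stage(p, rec) == 1

    def test_weak_stage_label_replication_only(self):
        p = _passage("German sample", {"german": "European"})
        rec = CuratedRecord("doc1", "stage_ethnicity",
                            tuples=frozenset({("replication", "European"),
                                              ("initial", "East Asian")}))
        assert weak_label_stage(p, rec) == 0

    def test_posneg_weak_label_checks_either_stage(self):
        p = _passage("German sample", {"german": "European"})
        rec = CuratedRecord("doc1", "stage_ethnicity",
                            tuples=frozenset({("replication", "European")}))
        assert weak_label_posneg(p, rec) == 1

    def test_full_stage_vote_vector(self):
        p = _passage("Germans were genotyped in the follow-up phase",
                     {"germans": "European"})
        rec = CuratedRecord("doc1", "stage_ethnicity",
                            tuples=frozenset({("replication", "European")}))
        votes = vote_task2_stage(p, rec, self.initial_cues,
                                 self.replication_cues, None, base_vote=0)
        assert _votes(votes) == (0, 0, 0)


class TestBuildMatrix:
    def test_assembles_rows_and_columns(self):
        votes = [WeakVote(c, i, (i + j) % 2)
                 for i in range(2)
                 for j, c in enumerate(["a", "b", "c", "d", "e"])]
        m = build_matrix(votes)
        assert m.shape == (2, 5)
        assert m.classifier_ids == ["a", "b", "c", "d", "e"]
        # column j reconstructs classifier j's vote sequence
        for j, c in enumerate(m.classifier_ids):
            expected = [v.vote for v in votes if v.classifier_id == c]
            assert m.M[:, j].tolist() == expected

    def test_duplicate_vote_rejected(self):
        votes = [WeakVote("a", 0, 1), WeakVote("a", 0, 0)]
        with pytest.raises(CommitteeError, match="duplicate"):
            build_matrix(votes)

    def test_missing_vote_rejected(self):
        votes = [WeakVote("a", 0, 1), WeakVote("b", 0, 1), WeakVote("a", 1, 0)]
        with pytest.raises(CommitteeError, match="missing"):
            build_matrix(votes)

    def test_permuting_passages_permutes_rows(self):
        votes = [WeakVote(c, i, (i * 7 + j) % 2)
                 for i in range(4) for j, c in enumerate(["a", "b", "c"])]
        m = build_matrix(votes)
        perm = [2, 0, 3, 1]
        votes_p = [WeakVote(v.classifier_id, perm.index(v.passage_index), v.vote)
                   for v in votes]
        m_p = build_matrix(votes_p)
        # row perm.index(i) of the permuted matrix == row i of the original
        for i in range(4):
            assert m_p.M[perm.index(i)].tolist() == m.M[i].tolist()

    def test_matrix_entries_validated(self):
        with pytest.raises(ValueError, match="0/1"):
            CommitteeMatrix(M=np.array([[2, 0]]), passage_ids=["p"],
                            classifier_ids=["a", "b"])
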