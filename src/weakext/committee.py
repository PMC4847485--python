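"""Weak-classifier committees voting on (passage, curated-record) pairs.

Each committee member gives a hard yes/no vote on whether a candidate
passage supports the curated datum. The phenotype committee has five
rule classifiers; the stage/ethnicity task uses two stacked committees
of three members each (a learned base classifier, a cue-word rule, and
the curated weak label). Votes are collected into the I x J binary
committee matrix consumed by the EM label estimator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .corpus import CuratedRecord, RuleLexicon, TermDictionary, fold
from .errors import CommitteeError, NotFittedError
from .extraction import Passage

TASK1_CLASSIFIERS = ("title_abstract", "exact", "substring", "synonym", "compound")
TASK2_POSNEG_CLASSIFIERS = ("base_lr", "sample_rule", "weak_label")
TASK2_STAGE_CLASSIFIERS = ("base_lr", "stage_cue", "weak_label")


@dataclass(frozen=True)
class WeakVote:
    classifier_id: str
    passage_index: int
    vote: int

    def __post_init__(self) -> None:
        if self.vote not in (0, 1):
            raise ValueError(f"vote must be 0/1, got {self.vote}")


@dataclass
class CommitteeMatrix:
    """I x J binary matrix; rows = passages, columns = committee members."""

    M: np.ndarray
    passage_ids: list[str]
    classifier_ids: list[str]

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M)
        I, J = self.M.shape
        if I < 1 or J < 1:
            raise ValueError("committee matrix must be at least 1x1")
        if len(self.passage_ids) != I or len(self.classifier_ids) != J:
            raise ValueError("id lists must match matrix shape")
        if not np.isin(self.M, (0, 1)).all():
            raise ValueError("committee matrix entries must be 0/1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.M.shape


class LearnedMember:
    """A learned committee member: a fitted scikit-learn binary classifier
    bound to the feature schema its votes are computed from."""

    def __init__(self, schema, estimator=None) -> None:
        self.schema = schema
        self.estimator = estimator

    def votes(self, passages: list[Passage], X=None) -> np.ndarray:
        if self.estimator is None:
            raise NotFittedError("learned committee member has no trained estimator")
        if X is None:
            X = self.schema.transform(passages)
        return np.asarray(self.estimator.predict(X)).astype(int)

    def vote(self, passage: Passage) -> int:
        return int(self.votes([passage])[0])


# ---------------------------------------------------------------------------
# Matching helpers shared by the rules
# ---------------------------------------------------------------------------

def _norm_term(text: str) -> str:
    # hyphen/space equivalence + casefold, so "Type-2 Diabetes" == "type 2 diabetes"
    return re.sub(r"[\s\-]+", " ", fold(text))


def _substring_either(a: str, b: str) -> bool:
    return a in b or b in a


def _contains_term(haystack: str, term: str) -> bool:
    # context windows are whitespace-joined word tokens, so hyphenated
    # lexicon terms ("follow-up") must match their de-hyphenated form
    term = re.sub(r"[\s\-]+", " ", term.strip())
    return re.search(rf"(?<!\w){re.escape(term)}(?!\w)", haystack) is not None


# ---------------------------------------------------------------------------
# Task 1: five phenotype rules
# ---------------------------------------------------------------------------

def vote_task1(
    passage: Passage,
    curated: CuratedRecord,
    synonyms: TermDictionary | None = None,
    passage_index: int = 0,
) -> list[WeakVote]:
    """Five rule votes for a phenotype mention against the curated record.

    Rules in fixed order: (1) mention in title or abstract; (2) exact
    match to a curated term; (3) substring match in either direction;
    (4) exact-or-partial match to a synonym of a curated term; (5) the
    mention is a compound of several space/hyphen-separated tokens.
    """
    mention_norm = _norm_term(passage.mention.surface)
    curated_norms = [_norm_term(t) for t in curated.phenotype_terms]

    in_title_abstract = passage.mention.location in ("title", "abstract")
    exact = any(mention_norm == t for t in curated_norms)
    substring = any(_substring_either(mention_norm, t) for t in curated_norms)

    synonym = False
    if synonyms is not None:
        concepts = {synonyms.lookup(t) for t in curated.phenotype_terms}
        concepts.discard(None)
        for surface, concept in synonyms.entries.items():
            if concept not in concepts:
                continue
            surface_norm = _norm_term(surface)
            if surface_norm in curated_norms:
                continue  # the curated term itself is not its own synonym
            if _substring_either(mention_norm, surface_norm):
                synonym = True
                break

    compound = bool(re.search(r"\S[\s\-]+\S", passage.mention.surface.strip()))

    flags = (in_title_abstract, exact, substring, synonym, compound)
    return [WeakVote(cid, passage_index, int(f))
            for cid, f in zip(TASK1_CLASSIFIERS, flags)]


# ---------------------------------------------------------------------------
# Task 2: positive/negative committee and stage committee
# ---------------------------------------------------------------------------

def weak_label_posneg(passage: Passage, curated: CuratedRecord) -> int:
    """1 iff the passage's canonical ethnicity is curated for either stage."""
    return int(fold(passage.canonical) in {fold(e) for e in curated.ethnicities})


def weak_label_stage(passage: Passage, curated: CuratedRecord) -> int:
    """1 = initial, 0 = replication; an ethnicity curated under both stages
    (or, degenerately, under neither) defaults to initial — the obligatory
    stage of any genome-wide association study."""
    canon = fold(passage.canonical)
    under_initial = canon in {fold(e) for e in curated.ethnicities_for("initial")}
    under_replication = canon in {fold(e) for e in curated.ethnicities_for("replication")}
    if under_replication and not under_initial:
        return 0
    return 1


def _lexicon_hit(passage: Passage, lexicon: RuleLexicon) -> bool:
    window = " ".join(t.casefold() for t in passage.context_tokens())
    return any(_contains_term(window, term) for term in lexicon.terms)


def vote_task2_posneg(
    passage: Passage,
    curated: CuratedRecord,
    lexicon: RuleLexicon,
    base_model: LearnedMember,
    passage_index: int = 0,
    base_vote: int | None = None,
) -> list[WeakVote]:
    """Votes, fixed order: learned base classifier; sample-description
    cue rule; curated weak label. ``base_vote`` short-circuits the model
    call when the vote was batch-computed (e.g. out-of-fold)."""
    if base_vote is None:
        base_vote = base_model.vote(passage)
    rule = int(_lexicon_hit(passage, lexicon))
    weak = weak_label_posneg(passage, curated)
    flags = (base_vote, rule, weak)
    return [WeakVote(cid, passage_index, int(f))
            for cid, f in zip(TASK2_POSNEG_CLASSIFIERS, flags)]


def stage_cue_vote(passage: Passage, initial_cues: RuleLexicon,
                   replication_cues: RuleLexicon) -> int:
    """1 = initial, 0 = replication. When no cue (or both cues) fire the
    rule defaults to initial."""
    has_initial = _lexicon_hit(passage, initial_cues)
    has_replication = _lexicon_hit(passage, replication_cues)
    if has_replication and not has_initial:
        return 0
    return 1


def vote_task2_stage(
    passage: Passage,
    curated: CuratedRecord,
    initial_cues: RuleLexicon,
    replication_cues: RuleLexicon,
    base_model: LearnedMember,
    passage_index: int = 0,
    base_vote: int | None = None,
) -> list[WeakVote]:
    """Stage votes (1=initial, 0=replication) for an upstream-positive passage."""
    if base_vote is None:
        base_vote = base_model.vote(passage)
    cue = stage_cue_vote(passage, initial_cues, replication_cues)
    weak = weak_label_stage(passage, curated)
    flags = (base_vote, cue, weak)
    return [WeakVote(cid, passage_index, int(f))
            for cid, f in zip(TASK2_STAGE_CLASSIFIERS, flags)]


# ---------------------------------------------------------------------------
# Matrix assembly
# ---------------------------------------------------------------------------

def build_matrix(
    votes: list[WeakVote],
    passage_ids: list[str] | None = None,
    classifier_ids: list[str] | None = None,
) -> CommitteeMatrix:
    """Assemble votes into the committee matrix.

    Every (passage, classifier) pair must have voted exactly once; rows
    follow passage-index order, columns the fixed classifier order
    (first-appearance order unless ``classifier_ids`` is given).
    """
    if not votes:
        raise CommitteeError("no votes to assemble")
    if classifier_ids is None:
        classifier_ids = list(dict.fromkeys(v.classifier_id for v in votes))
    n_passages = max(v.passage_index for v in votes) + 1
    if passage_ids is None:
        passage_ids = [str(i) for i in range(n_passages)]
    if len(passage_ids) != n_passages:
        raise CommitteeError(
            f"passage_ids has {len(passage_ids)} entries, votes cover {n_passages}")
    col = {cid: j for j, cid in enumerate(classifier_ids)}
    M = np.full((n_passages, len(classifier_ids)), -1, dtype=np.int8)
    for v in votes:
        if v.classifier_id not in col:
            raise CommitteeError(f"unknown classifier {v.classifier_id!r}")
        i, j = v.passage_index, col[v.classifier_id]
        if M[i, j] != -1:
            raise CommitteeError(
                f"duplicate vote for passage {passage_ids[i]!r}, "
                f"classifier {v.classifier_id!r}")
        M[i, j] = v.vote
    if (M == -1).any():
        i, j = np.argwhere(M == -1)[0]
        raise CommitteeError(
            f"missing vote for passage {passage_ids[i]!r}, "
            f"classifier {classifier_ids[j]!r}")
    return CommitteeMatrix(M=M, passage_ids=list(passage_ids),
                           classifier_ids=list(classifier_ids))


def matrix_to_tsv(matrix: CommitteeMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("passage_id\t" + "\t".join(matrix.classifier_ids) + "\n")
        for pid, row in zip(matrix.passage_ids, matrix.M):
            fh.write(pid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
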