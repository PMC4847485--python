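"""Task post-processing and end-to-end pipelines.

Phenotype task: the trained classifier votes on every mention of every
candidate phenotype in a document; per candidate, V_p positive and V_n
negative votes give two scores, a vote ratio P_TF = V_p/(V_p+V_n) and a
document-share P_IDF = V_p / sum-of-V_p, combined by arithmetic or
harmonic mean to rank candidates.

Stage/ethnicity task: a first classifier separates sample-description
mentions from incidental ones; positives are then classified into the
initial or replication stage, and per-document (stage, ethnicity) tuples
are assembled with duplicates discarded.

The pipeline functions wire the full chain: dictionary matching ->
context windows -> committee votes -> EM reliability -> cost assignment
-> weighted SVM -> task post-processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from . import committee as cm
from .corpus import Article, CuratedRecord, RuleLexicon, Stage, TermDictionary
from .cost_sensitive import CostVariant, assign_costs, predict, train_weighted
from .errors import DegenerateTrainingError
from .extraction import Passage, extract_passages, match_mentions
from .features import Task1FeatureSchema, Task2FeatureSchema
from .label_em import EmVariant, Priors, em_estimate

RankingMethod = Literal["arithmetic", "harmonic"]
Method = Literal["cost_sensitive", "cost_insensitive", "baseline"]


# ---------------------------------------------------------------------------
# Phenotype candidate scoring
# ---------------------------------------------------------------------------

@dataclass
class CandidateScore:
    """Vote tallies and derived scores for one candidate phenotype."""

    doc_id: str
    canonical: str
    V_p: int
    V_n: int
    P_TF: float = field(init=False)
    P_IDF: float = field(init=False)

    def __post_init__(self) -> None:
        if self.V_p < 0 or self.V_n < 0:
            raise ValueError("vote counts must be non-negative")
        total = self.V_p + self.V_n
        self.P_TF = self.V_p / total if total > 0 else 0.0
        self.P_IDF = 0.0  # filled in by score_candidates


def score_candidates(
    predictions: Sequence[tuple[str, int]],
    doc_id: str,
) -> list[CandidateScore]:
    """Aggregate per-mention hard predictions into per-candidate scores.

    ``predictions`` is a sequence of (canonical, label) pairs for one
    document. P_IDF shares a common denominator, the document's total
    positive votes (all P_IDF are 0 when the document has none).
    """
    tallies: dict[str, list[int]] = {}
    for canonical, label in predictions:
        vp_vn = tallies.setdefault(canonical, [0, 0])
        vp_vn[0 if label == 1 else 1] += 1
    scores = [CandidateScore(doc_id, canonical, vp, vn)
              for canonical, (vp, vn) in sorted(tallies.items())]
    total_pos = sum(s.V_p for s in scores)
    if total_pos > 0:
        for s in scores:
            s.P_IDF = s.V_p / total_pos
    return scores


def combine_scores(score: CandidateScore, method: RankingMethod = "harmonic") -> float:
    """Arithmetic or harmonic mean of P_TF and P_IDF (harmonic(0,0) := 0)."""
    a, b = score.P_TF, score.P_IDF
    if method == "arithmetic":
        return (a + b) / 2.0
    if method == "harmonic":
        return 2.0 * a * b / (a + b) if (a + b) > 0 else 0.0
    raise ValueError(f"unknown ranking method {method!r}")


def rank_top_k(
    scores: Iterable[CandidateScore],
    k: int,
    method: RankingMethod = "harmonic",
) -> list[str]:
    """Top-k canonicals by combined score, descending; ties broken by
    higher V_p, then lexicographically — stable and deterministic."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(scores, key=lambda s: (-combine_scores(s, method),
                                           -s.V_p, s.canonical))
    return [s.canonical for s in ranked[:k]]


# ---------------------------------------------------------------------------
# Stage/ethnicity tuple assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageEthnicityTuple:
    doc_id: str
    stage: Stage
    ethnicity: str


def assemble_tuples(
    positives: Iterable[tuple[Passage, Stage]],
) -> dict[str, frozenset[tuple[Stage, str]]]:
    """Group stage-classified positive passages into per-document tuple
    sets; duplicates collapse by set semantics."""
    out: dict[str, set[tuple[Stage, str]]] = {}
    for passage, stage in positives:
        out.setdefault(passage.doc_id, set()).add((stage, passage.canonical))
    return {doc: frozenset(tuples) for doc, tuples in out.items()}


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Shared knobs for both task pipelines."""

    em_variant: EmVariant = "posterior"
    cost_variant: CostVariant = "lemma_consistent"
    priors: Priors = field(default_factory=Priors)
    em_tol: float = 1e-6
    em_max_iter: int = 100
    ranking_method: RankingMethod = "harmonic"
    top_k: int = 2
    reg: float = 1.0
    svm_tol: float = 1e-4
    svm_max_iter: int = 10000
    oof_folds: int = 5
    seed: int = 0
    method: Method = "cost_sensitive"

    def to_dict(self) -> dict:
        return {
            "em_variant": self.em_variant,
            "cost_variant": self.cost_variant,
            "priors": {"k": self.priors.k, "K": self.priors.K,
                       "k_prime": self.priors.k_prime, "K_prime": self.priors.K_prime},
            "em_tol": self.em_tol, "em_max_iter": self.em_max_iter,
            "ranking_method": self.ranking_method, "top_k": self.top_k,
            "reg": self.reg, "svm_tol": self.svm_tol,
            "svm_max_iter": self.svm_max_iter, "oof_folds": self.oof_folds,
            "seed": self.seed, "method": self.method,
        }


def _records_by_doc(records: Iterable[CuratedRecord]) -> dict[str, CuratedRecord]:
    return {rec.doc_id: rec for rec in records}


def _constant_model(n_features: int, label: int, schema_id: str):
    """Degenerate fallback: all training labels in one class, so the
    "classifier" is the constant that class (zero weights, signed bias)."""
    import scipy.sparse as sp
    from .cost_sensitive import WeightedLinearModel
    return WeightedLinearModel(weights=sp.csr_matrix((1, n_features)),
                               bias=1.0 if label == 1 else -1.0,
                               regularization=1.0, schema_id=schema_id)


def _train_or_uniform(X, labels, costs_c, config: PipelineConfig, schema_id: str):
    """Weighted SVM training helper used by both the cost-sensitive route
    (EM-derived labels/costs) and the cost-insensitive route (weak labels,
    unit costs). Falls back to a constant predictor when the training
    labels are single-class (tiny folds)."""
    from .cost_sensitive import CostAssignment
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        return _constant_model(X.shape[1], int(labels[0]), schema_id)
    assignment = CostAssignment(y=labels,
                                c=np.asarray(costs_c, dtype=float),
                                pos_fraction=float(np.mean(labels)),
                                numerator_variant=config.cost_variant)
    return train_weighted(X, assignment, reg=config.reg, seed=config.seed,
                          tol=config.svm_tol, max_iter=config.svm_max_iter,
                          schema_id=schema_id)


def _out_of_fold_votes(X, labels, config: PipelineConfig) -> np.ndarray:
    """Out-of-fold predictions of the learned committee member, so the
    base classifier never votes on its own training rows."""
    labels = np.asarray(labels, dtype=int)
    base = LogisticRegression(max_iter=1000, random_state=config.seed)
    if np.unique(labels).size < 2:
        return labels.copy()
    n_splits = min(config.oof_folds, int(np.bincount(labels).min()))
    if n_splits < 2:
        return base.fit(X, labels).predict(X).astype(int)
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=config.seed)
    return cross_val_predict(base, X, labels, cv=cv).astype(int)


# ---------------------------------------------------------------------------
# Task 1 pipeline
# ---------------------------------------------------------------------------

@dataclass
class Task1Model:
    schema: Task1FeatureSchema
    svm: "object"
    config: PipelineConfig


def train_task1(
    train_articles: Sequence[Article],
    train_records: Sequence[CuratedRecord],
    dictionary: TermDictionary,
    synonyms: TermDictionary | None,
    config: PipelineConfig = PipelineConfig(),
) -> Task1Model:
    """Steps A-E for the phenotype task on the training corpus."""
    records = _records_by_doc(train_records)
    passages: list[Passage] = []
    votes: list[cm.WeakVote] = []
    for article in train_articles:
        record = records.get(article.doc_id)
        if record is None:
            continue
        mentions = match_mentions(article, dictionary)
        for passage in extract_passages(mentions, article, "cross_sentence"):
            votes.extend(cm.vote_task1(passage, record, synonyms,
                                       passage_index=len(passages)))
            passages.append(passage)
    if not passages:
        raise DegenerateTrainingError("no candidate passages in training corpus")

    schema = Task1FeatureSchema().fit(passages)
    X = schema.transform(passages)

    if config.method == "cost_insensitive":
        # direct training on the curated weak label (substring rule), unit costs
        matrix = cm.build_matrix(votes, classifier_ids=list(cm.TASK1_CLASSIFIERS))
        weak = matrix.M[:, cm.TASK1_CLASSIFIERS.index("substring")]
        svm = _train_or_uniform(X, weak, np.ones(len(passages)), config,
                                schema.schema_id)
    else:
        matrix = cm.build_matrix(votes, classifier_ids=list(cm.TASK1_CLASSIFIERS))
        est = em_estimate(matrix, config.priors, tol=config.em_tol,
                          max_iter=config.em_max_iter, variant=config.em_variant)
        costs = assign_costs(est, config.cost_variant)
        svm = _train_or_uniform(X, costs.y, costs.c, config, schema.schema_id)
    return Task1Model(schema=schema, svm=svm, config=config)


def apply_task1(
    model: Task1Model,
    articles: Sequence[Article],
    dictionary: TermDictionary,
) -> dict[str, list[tuple[str, float]]]:
    """Rank candidate phenotypes per document: [(canonical, score), ...]."""
    out: dict[str, list[tuple[str, float]]] = {}
    for article in articles:
        mentions = match_mentions(article, dictionary)
        passages = extract_passages(mentions, article, "cross_sentence")
        if not passages:
            out[article.doc_id] = []
            continue
        X = model.schema.transform(passages)
        labels, _ = predict(model.svm, X)
        scores = score_candidates(
            [(p.canonical, int(l)) for p, l in zip(passages, labels)],
            article.doc_id)
        method = model.config.ranking_method
        ranked = rank_top_k(scores, k=max(len(scores), 1), method=method)
        by_name = {s.canonical: s for s in scores}
        out[article.doc_id] = [
            (name, combine_scores(by_name[name], method)) for name in ranked]
    return out


def run_task1_pipeline(
    train_articles: Sequence[Article],
    train_records: Sequence[CuratedRecord],
    test_articles: Sequence[Article],
    dictionary: TermDictionary,
    synonyms: TermDictionary | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> dict[str, list[tuple[str, float]]]:
    """Train on the curated training corpus, rank phenotypes on the test corpus."""
    model = train_task1(train_articles, train_records, dictionary, synonyms, config)
    return apply_task1(model, test_articles, dictionary)


# ---------------------------------------------------------------------------
# Task 2 pipeline
# ---------------------------------------------------------------------------

@dataclass
class Task2Model:
    schema: Task2FeatureSchema
    posneg_svm: "object"
    stage_svm: "object | None"
    config: PipelineConfig


def _task2_training_passages(
    articles: Sequence[Article],
    records: dict[str, CuratedRecord],
    dictionary: TermDictionary,
) -> list[Passage]:
    passages: list[Passage] = []
    for article in articles:
        if article.doc_id not in records:
            continue
        mentions = match_mentions(article, dictionary)
        passages.extend(extract_passages(mentions, article, "within_sentence"))
    return passages


def train_task2(
    train_articles: Sequence[Article],
    train_records: Sequence[CuratedRecord],
    dictionary: TermDictionary,
    sample_lexicon: RuleLexicon,
    initial_cues: RuleLexicon,
    replication_cues: RuleLexicon,
    config: PipelineConfig = PipelineConfig(),
) -> Task2Model:
    """Steps A-E twice: positive/negative committee, then stage committee."""
    records = _records_by_doc(train_records)
    passages = _task2_training_passages(train_articles, records, dictionary)
    if not passages:
        raise DegenerateTrainingError("no candidate passages in training corpus")
    schema = Task2FeatureSchema().fit(passages)
    X = schema.transform(passages)
    weak_pos = np.array([cm.weak_label_posneg(p, records[p.doc_id]) for p in passages])

    if config.method == "cost_insensitive":
        posneg_svm = _train_or_uniform(X, weak_pos, np.ones(len(passages)),
                                       config, schema.schema_id)
        train_positive = weak_pos == 1
    else:
        base_votes = _out_of_fold_votes(X, weak_pos, config)
        votes: list[cm.WeakVote] = []
        for i, p in enumerate(passages):
            votes.extend(cm.vote_task2_posneg(
                p, records[p.doc_id], sample_lexicon, base_model=None,
                passage_index=i, base_vote=int(base_votes[i])))
        matrix = cm.build_matrix(votes,
                                 classifier_ids=list(cm.TASK2_POSNEG_CLASSIFIERS))
        est = em_estimate(matrix, config.priors, tol=config.em_tol,
                          max_iter=config.em_max_iter, variant=config.em_variant)
        costs = assign_costs(est, config.cost_variant)
        posneg_svm = _train_or_uniform(X, costs.y, costs.c, config,
                                       schema.schema_id)
        train_positive = costs.y == 1

    # stage committee on the positively labelled training passages
    stage_idx = np.flatnonzero(train_positive)
    stage_svm = None
    if stage_idx.size:
        stage_passages = [passages[i] for i in stage_idx]
        X_stage = X[stage_idx]
        weak_stage = np.array([cm.weak_label_stage(p, records[p.doc_id])
                               for p in stage_passages])
        if np.unique(weak_stage).size == 2:
            if config.method == "cost_insensitive":
                stage_svm = _train_or_uniform(X_stage, weak_stage,
                                              np.ones(stage_idx.size), config,
                                              schema.schema_id)
            else:
                base_votes = _out_of_fold_votes(X_stage, weak_stage, config)
                votes = []
                for i, p in enumerate(stage_passages):
                    votes.extend(cm.vote_task2_stage(
                        p, records[p.doc_id], initial_cues, replication_cues,
                        base_model=None, passage_index=i,
                        base_vote=int(base_votes[i])))
                matrix = cm.build_matrix(
                    votes, classifier_ids=list(cm.TASK2_STAGE_CLASSIFIERS))
                est = em_estimate(matrix, config.priors, tol=config.em_tol,
                                  max_iter=config.em_max_iter,
                                  variant=config.em_variant)
                costs = assign_costs(est, config.cost_variant)
                if np.unique(costs.y).size < 2:
                    stage_svm = None  # cue rule decides stages downstream
                else:
                    stage_svm = train_weighted(
                        X_stage, costs, reg=config.reg, seed=config.seed,
                        tol=config.svm_tol, max_iter=config.svm_max_iter,
                        schema_id=schema.schema_id)
    return Task2Model(schema=schema, posneg_svm=posneg_svm,
                      stage_svm=stage_svm, config=config)


def apply_task2(
    model: Task2Model,
    articles: Sequence[Article],
    dictionary: TermDictionary,
    initial_cues: RuleLexicon | None = None,
    replication_cues: RuleLexicon | None = None,
) -> dict[str, frozenset[tuple[Stage, str]]]:
    """Extract per-document (stage, ethnicity) tuple sets."""
    positives: list[tuple[Passage, Stage]] = []
    out: dict[str, frozenset[tuple[Stage, str]]] = {}
    for article in articles:
        out[article.doc_id] = frozenset()
        mentions = match_mentions(article, dictionary)
        passages = extract_passages(mentions, article, "within_sentence")
        if not passages:
            continue
        X = model.schema.transform(passages)
        labels, _ = predict(model.posneg_svm, X)
        pos_idx = np.flatnonzero(labels == 1)
        if pos_idx.size == 0:
            continue
        if model.stage_svm is not None:
            stage_labels, _ = predict(model.stage_svm, X[pos_idx])
        elif initial_cues is not None and replication_cues is not None:
            stage_labels = np.array([
                cm.stage_cue_vote(passages[i], initial_cues, replication_cues)
                for i in pos_idx])
        else:
            stage_labels = np.ones(pos_idx.size, dtype=int)
        for i, s in zip(pos_idx, stage_labels):
            positives.append((passages[i], "initial" if s == 1 else "replication"))
    out.update(assemble_tuples(positives))
    return out


def baseline_task2(
    articles: Sequence[Article],
    dictionary: TermDictionary,
) -> dict[str, frozenset[tuple[Stage, str]]]:
    """Assign-all baseline: every tagged ethnicity goes to both stages."""
    out: dict[str, frozenset[tuple[Stage, str]]] = {}
    for article in articles:
        tagged = {m.canonical for m in match_mentions(article, dictionary)}
        out[article.doc_id] = frozenset(
            (stage, eth) for eth in tagged for stage in ("initial", "replication"))
    return out


def run_task2_pipeline(
    train_articles: Sequence[Article],
    train_records: Sequence[CuratedRecord],
    test_articles: Sequence[Article],
    dictionary: TermDictionary,
    sample_lexicon: RuleLexicon,
    initial_cues: RuleLexicon,
    replication_cues: RuleLexicon,
    config: PipelineConfig = PipelineConfig(),
) -> dict[str, frozenset[tuple[Stage, str]]]:
    """Train both committees on the curated corpus, extract tuples on test."""
    if config.method == "baseline":
        return baseline_task2(test_articles, dictionary)
    model = train_task2(train_articles, train_records, dictionary,
                        sample_lexicon, initial_cues, replication_cues, config)
    return apply_task2(model, test_articles, dictionary,
                       initial_cues, replication_cues)


__all__ = [
    "CandidateScore", "StageEthnicityTuple", "PipelineConfig",
    "score_candidates", "combine_scores", "rank_top_k", "assemble_tuples",
    "train_task1", "apply_task1", "run_task1_pipeline",
    "train_task2", "apply_task2", "baseline_task2", "run_task2_pipeline",
]
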