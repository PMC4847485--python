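"""Evaluation metrics and the article-based cross-validation harness.

Precision-at-k for the phenotype ranking task (a document counts as a
hit when any of its top-k predictions matches any curated gold term,
case-insensitively), and tuple-level precision/recall/F1 for the
stage/ethnicity task with both micro averaging (TP/FP/FN pooled over
documents) and macro averaging (per-document precision and recall
averaged first; the macro F1 is the harmonic mean of the two macro
averages, not the mean of per-document F1s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .corpus import Article, CuratedRecord, RuleLexicon, Stage, TermDictionary, fold
from .tasks import PipelineConfig, run_task1_pipeline, run_task2_pipeline

logger = logging.getLogger(__name__)

TupleSet = frozenset[tuple[Stage, str]]


@dataclass
class EvaluationReport:
    metric: Literal["p_at_k", "micro_prf", "macro_prf"]
    precision: float
    recall: float
    f1: float
    n_docs: int
    n_tuples: int = 0
    k: int | None = None

    def __post_init__(self) -> None:
        for v in (self.precision, self.recall, self.f1):
            if not (0.0 <= v <= 1.0):
                raise ValueError("precision/recall/f1 must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {"metric": self.metric, "k": self.k,
                "precision": self.precision, "recall": self.recall,
                "f1": self.f1, "n_docs": self.n_docs, "n_tuples": self.n_tuples}


def _harmonic(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


# ---------------------------------------------------------------------------
# Precision at k
# ---------------------------------------------------------------------------

def precision_at_k(
    ranked: Mapping[str, Sequence[str]],
    gold: Iterable[CuratedRecord],
    k: int = 2,
) -> EvaluationReport:
    """Fraction of documents whose top-k ranking hits any gold term.

    Documents with empty gold sets are excluded from the denominator;
    documents missing from ``ranked`` count as misses.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    hits = 0
    n_docs = 0
    for record in gold:
        gold_terms = {fold(t) for t in record.phenotype_terms}
        if not gold_terms:
            continue
        n_docs += 1
        predictions = ranked.get(record.doc_id)
        if not predictions:
            logger.warning("no predictions for document %s; counted as a miss",
                           record.doc_id)
            continue
        top = [fold(t) for t in list(predictions)[:k]]
        if any(t in gold_terms for t in top):
            hits += 1
    value = hits / n_docs if n_docs else 0.0
    return EvaluationReport(metric="p_at_k", k=k, precision=value,
                            recall=value, f1=value, n_docs=n_docs)


# ---------------------------------------------------------------------------
# Tuple-level precision/recall/F1
# ---------------------------------------------------------------------------

def _fold_tuples(tuples: Iterable[tuple[Stage, str]]) -> frozenset[tuple[str, str]]:
    return frozenset((stage, fold(eth)) for stage, eth in tuples)


def tuple_prf(
    predicted: Mapping[str, TupleSet],
    gold: Mapping[str, TupleSet],
    averaging: Literal["micro", "macro"] = "micro",
) -> EvaluationReport:
    """Set comparison of (stage, ethnicity) tuples keyed by document.

    A predicted tuple present in the document's gold set is a true
    positive, otherwise a false positive; a gold tuple never predicted is
    a false negative. Documents with empty gold *and* empty prediction
    contribute precision = recall = 1 to the macro average; a document
    with gold tuples but no predictions contributes precision 0.
    """
    doc_ids = sorted(set(predicted) | set(gold))
    tp = fp = fn = 0
    per_p, per_r = [], []
    n_tuples = 0
    for doc in doc_ids:
        pred = _fold_tuples(predicted.get(doc, frozenset()))
        gld = _fold_tuples(gold.get(doc, frozenset()))
        n_tuples += len(gld)
        doc_tp = len(pred & gld)
        doc_fp = len(pred - gld)
        doc_fn = len(gld - pred)
        tp, fp, fn = tp + doc_tp, fp + doc_fp, fn + doc_fn
        if not pred and not gld:
            per_p.append(1.0)
            per_r.append(1.0)
        else:
            per_p.append(doc_tp / len(pred) if pred else 0.0)
            per_r.append(doc_tp / len(gld) if gld else 1.0)
    if averaging == "micro":
        precision = tp / (tp + fp) if (tp + fp) else 0.0
        recall = tp / (tp + fn) if (tp + fn) else 0.0
        return EvaluationReport(metric="micro_prf", precision=precision,
                                recall=recall, f1=_harmonic(precision, recall),
                                n_docs=len(doc_ids), n_tuples=n_tuples)
    if averaging == "macro":
        precision = float(np.mean(per_p)) if per_p else 0.0
        recall = float(np.mean(per_r)) if per_r else 0.0
        return EvaluationReport(metric="macro_prf", precision=precision,
                                recall=recall, f1=_harmonic(precision, recall),
                                n_docs=len(doc_ids), n_tuples=n_tuples)
    raise ValueError(f"unknown averaging {averaging!r}")


# ---------------------------------------------------------------------------
# Article-based cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CrossValidationResult:
    fold_assignments: list[list[str]]
    fold_reports: list[EvaluationReport]
    pooled_micro: EvaluationReport | None
    pooled_macro: EvaluationReport | None
    pooled_p_at_k: EvaluationReport | None
    pooled_predictions: dict


def make_folds(doc_ids: Sequence[str], folds: int, seed: int) -> list[list[str]]:
    """Shuffle articles with the seed and split at article granularity."""
    if len(doc_ids) < folds:
        raise ValueError(f"need at least {folds} documents, got {len(doc_ids)}")
    rng = np.random.default_rng(seed)
    order = list(doc_ids)
    rng.shuffle(order)
    return [sorted(order[i::folds]) for i in range(folds)]


def cross_validate(
    articles: Sequence[Article],
    records: Sequence[CuratedRecord],
    task: Literal["phenotype", "stage_ethnicity"],
    dictionary: TermDictionary,
    config: PipelineConfig = PipelineConfig(),
    folds: int = 5,
    seed: int = 0,
    synonyms: TermDictionary | None = None,
    sample_lexicon: RuleLexicon | None = None,
    initial_cues: RuleLexicon | None = None,
    replication_cues: RuleLexicon | None = None,
    gold: Mapping[str, TupleSet] | None = None,
) -> CrossValidationResult:
    """k-fold article-based cross-validation of either task pipeline.

    Each fold trains on the other folds' articles and predicts its own;
    predictions are pooled over all folds before the final metric
    computation (so pooled micro TP equals the sum of fold TPs). For the
    stage/ethnicity task ``gold`` defaults to the curated tuple sets.
    """
    by_doc = {a.doc_id: a for a in articles}
    curated_docs = sorted(r.doc_id for r in records if r.doc_id in by_doc)
    fold_assignments = make_folds(curated_docs, folds, seed)
    rec_by_doc = {r.doc_id: r for r in records}

    pooled: dict = {}
    fold_reports: list[EvaluationReport] = []
    for fold_docs in fold_assignments:
        test_set = set(fold_docs)
        train_articles = [by_doc[d] for d in curated_docs if d not in test_set]
        train_records = [rec_by_doc[d] for d in curated_docs if d not in test_set]
        test_articles = [by_doc[d] for d in fold_docs]
        if task == "phenotype":
            preds = run_task1_pipeline(train_articles, train_records,
                                       test_articles, dictionary, synonyms, config)
            ranked = {doc: [c for c, _ in pairs] for doc, pairs in preds.items()}
            pooled.update(ranked)
            fold_reports.append(precision_at_k(
                ranked, [rec_by_doc[d] for d in fold_docs], k=config.top_k))
        else:
            preds = run_task2_pipeline(
                train_articles, train_records, test_articles, dictionary,
                sample_lexicon, initial_cues, replication_cues, config)
            pooled.update(preds)
            fold_gold = {d: (gold[d] if gold is not None else rec_by_doc[d].tuples)
                         for d in fold_docs}
            fold_reports.append(tuple_prf(preds, fold_gold, "micro"))

    if task == "phenotype":
        pooled_report = precision_at_k(
            pooled, [rec_by_doc[d] for d in curated_docs], k=config.top_k)
        return CrossValidationResult(fold_assignments, fold_reports,
                                     None, None, pooled_report, pooled)
    all_gold = {d: (gold[d] if gold is not None else rec_by_doc[d].tuples)
                for d in curated_docs}
    return CrossValidationResult(
        fold_assignments, fold_reports,
        tuple_prf(pooled, all_gold, "micro"),
        tuple_prf(pooled, all_gold, "macro"),
        None, pooled)


__all__ = [
    "EvaluationReport", "CrossValidationResult", "precision_at_k",
    "tuple_prf", "cross_validate", "make_folds",
]
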