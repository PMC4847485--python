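"""Feature schemas turning passages into sparse vectors.

Two schemas, one per task:

* :class:`Task1FeatureSchema` (phenotype ranking) — character n-grams
  (n=2..4) of the mention string, word (1,2)-grams and character n-grams
  of the context window, each block TF-IDF weighted with smoothed IDF
  ``log((1+N)/(1+df))+1`` and L2-normalised per block, plus binary
  positional flags (in-title, in-abstract, one flag per training section
  title).

* :class:`Task2FeatureSchema` (stage/ethnicity) — a one-hot indicator of
  the canonical entity, Porter-stemmed context (1,2)-gram TF-IDF,
  section-title TF-IDF, two normalised position features (offset from
  article start and from section start) and the same-article mention
  count of the entity. The full vector is standardised to zero mean /
  unit variance per dimension using training statistics, as the
  downstream linear SVM expects comparable feature scales.

Blocks occupy disjoint, stable index ranges, so a fitted schema gives
deterministic vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfVectorizer

from ._porter import porter_stem
from .corpus import fold
from .errors import NotFittedError
from .extraction import Passage


@dataclass(frozen=True)
class FeatureVector:
    """Sparse vector as parallel (strictly increasing) index/value lists."""

    indices: tuple[int, ...]
    values: tuple[float, ...]
    schema_id: str

    def __post_init__(self) -> None:
        if len(self.indices) != len(self.values):
            raise ValueError("indices and values must be parallel")
        if any(b <= a for a, b in zip(self.indices, self.indices[1:])):
            raise ValueError("indices must be strictly increasing")


def _rows_to_feature_vectors(X: sp.spmatrix | np.ndarray, schema_id: str) -> list[FeatureVector]:
    X = sp.csr_matrix(X)
    out = []
    for i in range(X.shape[0]):
        row = X.getrow(i).tocoo()
        order = np.argsort(row.col)
        out.append(FeatureVector(tuple(int(c) for c in row.col[order]),
                                 tuple(float(v) for v in row.data[order]),
                                 schema_id))
    return out


def _mention_text(p: Passage) -> str:
    return fold(p.mention.surface)


def _context_text(p: Passage) -> str:
    return " ".join(t.casefold() for t in p.context_tokens())


def _stemmed_context(p: Passage) -> str:
    return " ".join(porter_stem(t.casefold()) for t in p.context_tokens())


def _identity_tokenizer(text: str) -> list[str]:
    return text.split(" ") if text else []


def _fit_text_block(vectorizer: TfidfVectorizer, docs: list[str]) -> None:
    # an all-empty block (e.g. no section titles in a plain-text corpus)
    # gets a placeholder vocabulary instead of failing to fit
    try:
        vectorizer.fit(docs)
    except ValueError:
        vectorizer.fit(["__none__"])


class _SchemaBase:
    schema_id: str = ""

    def __init__(self) -> None:
        self._fitted = False

    def _check_fitted(self) -> None:
        if not self._fitted:
            raise NotFittedError(f"{type(self).__name__} must be fitted before use")

    @property
    def n_features(self) -> int:
        self._check_fitted()
        return self._n_features

    def featurize(self, passage: Passage) -> FeatureVector:
        """Single-passage convenience wrapper around :meth:`transform`."""
        return _rows_to_feature_vectors(self.transform([passage]), self.schema_id)[0]


class Task1FeatureSchema(_SchemaBase):
    """Mention/context n-gram TF-IDF blocks + positional flags (phenotype task)."""

    schema_id = "task1/v1"

    def __init__(self, char_ngrams: tuple[int, int] = (2, 4),
                 word_ngrams: tuple[int, int] = (1, 2)) -> None:
        super().__init__()
        self._mention_chars = TfidfVectorizer(
            analyzer="char", ngram_range=char_ngrams, norm="l2", smooth_idf=True)
        self._context_words = TfidfVectorizer(
            analyzer="word", tokenizer=_identity_tokenizer, token_pattern=None,
            ngram_range=word_ngrams, norm="l2", smooth_idf=True)
        self._context_chars = TfidfVectorizer(
            analyzer="char", ngram_range=char_ngrams, norm="l2", smooth_idf=True)

    def fit(self, passages: list[Passage]) -> "Task1FeatureSchema":
        _fit_text_block(self._mention_chars, [_mention_text(p) for p in passages])
        _fit_text_block(self._context_words, [_context_text(p) for p in passages])
        _fit_text_block(self._context_chars, [_context_text(p) or " " for p in passages])
        titles = sorted({fold(p.mention.section_title) for p in passages
                         if p.mention.section_title})
        self._section_index = {t: i for i, t in enumerate(titles)}
        self._n_features = (
            len(self._mention_chars.vocabulary_)
            + len(self._context_words.vocabulary_)
            + len(self._context_chars.vocabulary_)
            + 2 + len(self._section_index))
        self._fitted = True
        return self

    def transform(self, passages: list[Passage]) -> sp.csr_matrix:
        self._check_fitted()
        blocks = [
            self._mention_chars.transform([_mention_text(p) for p in passages]),
            self._context_words.transform([_context_text(p) for p in passages]),
            self._context_chars.transform([_context_text(p) or " " for p in passages]),
        ]
        pos = sp.lil_matrix((len(passages), 2 + len(self._section_index)))
        for i, p in enumerate(passages):
            if p.mention.location == "title":
                pos[i, 0] = 1.0
            elif p.mention.location == "abstract":
                pos[i, 1] = 1.0
            j = self._section_index.get(fold(p.mention.section_title))
            if j is not None:
                pos[i, 2 + j] = 1.0
        blocks.append(pos.tocsr())
        return sp.hstack(blocks, format="csr")


class Task2FeatureSchema(_SchemaBase):
    """Entity indicator + stemmed-context TF-IDF + position features, standardised."""

    schema_id = "task2/v1"

    def __init__(self, word_ngrams: tuple[int, int] = (1, 2)) -> None:
        super().__init__()
        self._context = TfidfVectorizer(
            analyzer="word", tokenizer=_identity_tokenizer, token_pattern=None,
            ngram_range=word_ngrams, norm="l2", smooth_idf=True)
        self._section = TfidfVectorizer(
            analyzer="word", tokenizer=_identity_tokenizer, token_pattern=None,
            ngram_range=(1, 1), norm="l2", smooth_idf=True)

    def fit(self, passages: list[Passage]) -> "Task2FeatureSchema":
        entities = sorted({fold(p.canonical) for p in passages})
        self._entity_index = {e: i for i, e in enumerate(entities)}
        _fit_text_block(self._context, [_stemmed_context(p) for p in passages])
        _fit_text_block(self._section, [fold(p.mention.section_title) for p in passages])
        raw = self._raw_transform(passages)
        self._mean = np.asarray(raw.mean(axis=0)).ravel()
        sq_mean = np.asarray(raw.multiply(raw).mean(axis=0)).ravel()
        var = np.maximum(sq_mean - self._mean ** 2, 0.0)
        self._scale = np.sqrt(var)
        self._scale[self._scale == 0.0] = 1.0
        self._n_features = raw.shape[1]
        self._fitted = True
        return self

    def _raw_transform(self, passages: list[Passage]) -> sp.csr_matrix:
        one_hot = sp.lil_matrix((len(passages), len(self._entity_index)))
        extra = np.zeros((len(passages), 3))
        for i, p in enumerate(passages):
            j = self._entity_index.get(fold(p.canonical))
            if j is not None:
                one_hot[i, j] = 1.0
            extra[i] = (p.rel_doc_pos, p.rel_sec_pos, p.entity_doc_count)
        blocks = [
            one_hot.tocsr(),
            self._context.transform([_stemmed_context(p) or "" for p in passages]),
            self._section.transform([fold(p.mention.section_title) for p in passages]),
            sp.csr_matrix(extra),
        ]
        return sp.hstack(blocks, format="csr")

    def transform(self, passages: list[Passage]) -> np.ndarray:
        """Dense standardised matrix (training mean/variance per dimension)."""
        self._check_fitted()
        if len(passages) == 0:
            return np.zeros((0, self._n_features))
        raw = np.asarray(self._raw_transform(passages).todense())
        return (raw - self._mean) / self._scale


def to_matrix(vectors: list[FeatureVector], n_features: int) -> sp.csr_matrix:
    """Assemble FeatureVectors back into a CSR matrix (schema dimension given)."""
    rows, cols, vals = [], [], []
    for i, fv in enumerate(vectors):
        rows.extend([i] * len(fv.indices))
        cols.extend(fv.indices)
        vals.extend(fv.values)
    return sp.csr_matrix((vals, (rows, cols)), shape=(len(vectors), n_features))


__all__ = [
    "FeatureVector", "Task1FeatureSchema", "Task2FeatureSchema", "to_matrix",
]
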