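"""Importance-reweighting costs and the cost-weighted linear SVM.

Classification with noisy labels can be reduced to cost-sensitive
learning by weighting each example with the density ratio
p(y|x) / p_rho(y|x) between the clean and the noise-perturbed label
distribution. With the EM reliability estimate p̂_i standing in for
p(y=+|x) and the hardened-label class rate standing in for the
perturbed marginal, the cost of misclassifying example i is

    y_i = round(p̂_i)
    c_i = p̂_i / pos_fraction                if y_i = 1
    c_i = (1 - p̂_i) / (1 - pos_fraction)    if y_i = 0   (lemma_consistent)
    c_i = p̂_i / (1 - pos_fraction)          if y_i = 0   (paper_literal)

where pos_fraction = sum_i y_i / I. The default ``lemma_consistent``
numerator uses the estimated probability of the assigned label, so that
an example confidently labelled negative gets a high cost; the
``paper_literal`` variant keeps the alternative printed form in which a
likely-positive example mislabelled negative is the one rewarded.

The weighted learner is an L2-regularised hinge-loss linear SVM
(liblinear) in which example i's loss term is multiplied by c_i.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.sparse as sp
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC

from .errors import DegenerateTrainingError
from .label_em import LabelEstimate

CostVariant = Literal["lemma_consistent", "paper_literal"]

_COST_FLOOR = 1e-9  # keeps costs strictly positive in the degenerate p̂=0 corner


@dataclass
class CostAssignment:
    """Hard labels y and per-example misclassification costs c."""

    y: np.ndarray
    c: np.ndarray
    pos_fraction: float
    numerator_variant: CostVariant

    def __post_init__(self) -> None:
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be binary")
        if not ((self.c > 0) & np.isfinite(self.c)).all():
            raise ValueError("costs must be positive and finite")


def assign_costs(
    est: LabelEstimate | np.ndarray,
    variant: CostVariant = "lemma_consistent",
) -> CostAssignment:
    """Derive hard labels and importance-reweighting costs from p̂."""
    p_hat = est.p_hat if isinstance(est, LabelEstimate) else np.asarray(est, dtype=float)
    if p_hat.size == 0:
        raise ValueError("empty label estimate")
    if variant not in ("lemma_consistent", "paper_literal"):
        raise ValueError(f"unknown variant {variant!r}")
    y = np.floor(p_hat + 0.5).astype(int)  # half-up: 0.5 -> 1
    pos_fraction = float(y.mean())
    # a class that is empty contributes no examples; its denominator is
    # conventionally 1 so the formula stays defined
    denom_pos = pos_fraction if pos_fraction > 0 else 1.0
    denom_neg = (1.0 - pos_fraction) if pos_fraction < 1 else 1.0
    if variant == "lemma_consistent":
        neg_numerator = 1.0 - p_hat
    else:
        neg_numerator = p_hat
    c = np.where(y == 1, p_hat / denom_pos, neg_numerator / denom_neg)
    c = np.maximum(c, _COST_FLOOR)
    return CostAssignment(y=y, c=c, pos_fraction=pos_fraction,
                          numerator_variant=variant)


@dataclass
class WeightedLinearModel:
    """A trained cost-weighted linear SVM (sparse weights + bias)."""

    weights: sp.csr_matrix  # shape (1, n_features)
    bias: float
    regularization: float
    schema_id: str = ""
    loss: str = "hinge"

    @property
    def n_features(self) -> int:
        return self.weights.shape[1]

    def decision_values(self, X) -> np.ndarray:
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension {X.shape[1]} != model dimension {self.n_features}")
        return np.asarray(X @ self.weights.T.toarray().ravel()).ravel() + self.bias

    def to_json(self) -> str:
        coo = self.weights.tocoo()
        return json.dumps({
            "schema_id": self.schema_id,
            "n_features": int(self.n_features),
            "bias": self.bias,
            "regularization": self.regularization,
            "loss": self.loss,
            "weights": [[int(j), float(v)] for j, v in
                        sorted(zip(coo.col, coo.data))],
        }, sort_keys=True)

    @classmethod
    def from_json(cls, data: str) -> "WeightedLinearModel":
        obj = json.loads(data)
        cols = [j for j, _ in obj["weights"]]
        vals = [v for _, v in obj["weights"]]
        weights = sp.csr_matrix((vals, ([0] * len(cols), cols)),
                                shape=(1, obj["n_features"]))
        return cls(weights=weights, bias=obj["bias"],
                   regularization=obj["regularization"],
                   schema_id=obj["schema_id"], loss=obj["loss"])


def train_weighted(
    X,
    costs: CostAssignment,
    reg: float = 1.0,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 10000,
    schema_id: str = "",
) -> WeightedLinearModel:
    """Fit the cost-weighted L2/hinge linear SVM.

    Minimises ``reg * ||w||^2 / 2 + sum_i c_i * hinge(y_i, f(x_i))`` (so
    scaling all costs and ``reg`` by the same factor leaves the solution
    unchanged). Requires at least one example of each class.
    """
    if X.shape[0] != costs.y.size:
        raise ValueError("feature count does not match cost count")
    classes = np.unique(costs.y)
    if classes.size < 2:
        raise DegenerateTrainingError(
            f"training labels contain a single class ({classes.tolist()})")
    svc = LinearSVC(loss="hinge", C=1.0 / reg, tol=tol, max_iter=max_iter,
                    random_state=seed, fit_intercept=True)
    with warnings.catch_warnings():
        # dual coordinate descent routinely stops at max_iter on dense
        # standardised text features; the solution is still usable
        warnings.simplefilter("ignore", ConvergenceWarning)
        svc.fit(X, costs.y, sample_weight=costs.c)
    return WeightedLinearModel(
        weights=sp.csr_matrix(svc.coef_),
        bias=float(svc.intercept_[0]),
        regularization=reg,
        schema_id=schema_id,
    )


def predict(model: WeightedLinearModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Hard labels (margin >= 0 -> 1) and raw margins for vote counting."""
    margins = model.decision_values(X)
    return (margins >= 0).astype(int), margins


__all__ = [
    "CostAssignment", "WeightedLinearModel", "assign_costs",
    "train_weighted", "predict",
]
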