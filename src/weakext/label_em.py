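"""EM estimation of label reliability from a committee vote matrix.

Given the I x J binary vote matrix M, the estimator alternates between a
per-passage positive-probability update and a per-classifier error-rate
update, both Laplace-smoothed:

    p_i(t) = ( sum_j (1 - e_j(t-1)) * M_ij + k ) / (J + K)

    e_j(t) = ( sum_i [ p_i(t) (1 - M_ij) + (1 - p_i(t)) M_ij ] + k' ) / (I + K')
                                                     ("disagreement" variant)
    e_j(t) = ( sum_i p_i(t) M_ij + k' ) / (I + K')   ("paper_literal" variant)

starting from e_j(0) = 0 and iterating synchronously until the maximum
absolute change in p drops below ``tol``. The ``disagreement`` variant
reads the error-rate update as the expected disagreement between a
classifier's votes and the current soft labels, which is consistent with
the p-update's use of (1 - e_j) as classifier reliability; the
``paper_literal`` variant keeps the alternative form in which e_j grows
with agreement on probable positives. Both are score-style updates: p_i
is a smoothed reliability-weighted vote fraction, not a calibrated Bayes
posterior — its scale is compressed into [k/(J+K), (J+k)/(J+K)], so the
e-update systematically overestimates error rates and hardening p at 0.5
is more conservative than majority vote.

The default ``posterior`` variant is therefore the maximum-likelihood
EM for the same one-coin model (one scalar error rate per classifier):
the E-step computes the Bayes posterior

    p_i ∝ pi * prod_j (1-e_j)^{M_ij} e_j^{1-M_ij}        (and its complement)

with the class prior pi re-estimated as mean(p), and the M-step is the
smoothed expected-disagreement update above. On conditionally
independent committees it recovers the true error rates and gives hard
labels at least as accurate as majority voting; the two score-style
variants are retained for fidelity to the original recurrences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .committee import CommitteeMatrix

EmVariant = Literal["posterior", "disagreement", "paper_literal"]


@dataclass(frozen=True)
class Priors:
    """Laplace pseudo-counts: k/K for the passage update, k'/K' for the
    classifier update. Defaults correspond to uniform Beta(1,1) smoothing."""

    k: float = 1.0
    K: float = 2.0
    k_prime: float = 1.0
    K_prime: float = 2.0

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.K and self.K > 0):
            raise ValueError("require 0 <= k <= K and K > 0")
        if not (0 <= self.k_prime <= self.K_prime and self.K_prime > 0):
            raise ValueError("require 0 <= k' <= K' and K' > 0")


@dataclass
class LabelEstimate:
    """EM output: per-passage positive probabilities and per-classifier
    error rates, with convergence diagnostics."""

    p_hat: np.ndarray
    e_hat: np.ndarray
    iterations: int
    converged: bool
    update_variant: EmVariant

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        for arr in (self.p_hat, self.e_hat):
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError("probabilities must lie in [0, 1]")

    def hard_labels(self) -> np.ndarray:
        """Round half-up: p = 0.5 hardens to 1."""
        return np.floor(self.p_hat + 0.5).astype(int)


def _as_matrix(M) -> np.ndarray:
    if isinstance(M, CommitteeMatrix):
        M = M.M
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("committee matrix must be 2-D")
    if not np.isin(M, (0.0, 1.0)).all():
        raise ValueError("committee matrix entries must be binary 0/1")
    return M


def em_estimate(
    M: CommitteeMatrix | np.ndarray,
    priors: Priors = Priors(),
    tol: float = 1e-6,
    max_iter: int = 100,
    variant: EmVariant = "posterior",
) -> LabelEstimate:
    """Run the alternating label/error-rate updates to a fixed point.

    Returns the estimate after at most ``max_iter`` synchronous
    iterations; ``converged`` is False if the tolerance was not reached
    (the result is still returned).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if variant not in ("posterior", "disagreement", "paper_literal"):
        raise ValueError(f"unknown variant {variant!r}")
    A = _as_matrix(M)
    I, J = A.shape
    converged = False
    iterations = 0
    if variant == "posterior":
        # one-coin maximum-likelihood EM; init p = smoothed vote fraction
        p = (A.sum(axis=1) + priors.k) / (J + priors.K)
        e = np.zeros(J)
        for _ in range(max_iter):
            iterations += 1
            disagree = p[:, None] * (1.0 - A) + (1.0 - p)[:, None] * A
            e = (disagree.sum(axis=0) + priors.k_prime) / (I + priors.K_prime)
            e = np.clip(e, 1e-12, 1.0 - 1e-12)
            prior = float(np.clip(p.mean(), 1e-12, 1.0 - 1e-12))
            ll1 = (A @ np.log(1.0 - e) + (1.0 - A) @ np.log(e)) + np.log(prior)
            ll0 = (A @ np.log(e) + (1.0 - A) @ np.log(1.0 - e)) + np.log1p(-prior)
            top = np.maximum(ll1, ll0)
            w1 = np.exp(ll1 - top)
            p_new = w1 / (w1 + np.exp(ll0 - top))
            if np.abs(p_new - p).max() < tol:
                converged = True
                p = p_new
                break
            p = p_new
        return LabelEstimate(p_hat=p, e_hat=e, iterations=iterations,
                             converged=converged, update_variant=variant)

    e = np.zeros(J)
    p_prev: np.ndarray | None = None
    for _ in range(max_iter):
        iterations += 1
        p = (A @ (1.0 - e) + priors.k) / (J + priors.K)
        if variant == "disagreement":
            disagree = p[:, None] * (1.0 - A) + (1.0 - p)[:, None] * A
            e = (disagree.sum(axis=0) + priors.k_prime) / (I + priors.K_prime)
        else:
            e = ((p[:, None] * A).sum(axis=0) + priors.k_prime) / (I + priors.K_prime)
        if p_prev is not None and np.abs(p - p_prev).max() < tol:
            converged = True
            p_prev = p
            break
        p_prev = p
    return LabelEstimate(p_hat=p_prev, e_hat=e, iterations=iterations,
                         converged=converged, update_variant=variant)


def majority_vote(M: CommitteeMatrix | np.ndarray) -> np.ndarray:
    """Baseline hard labels: 1 iff at least half the votes are 1 (ties -> 1)."""
    A = _as_matrix(M)
    J = A.shape[1]
    return (2 * A.sum(axis=1) >= J).astype(int)


class CommitteeLabelModel:
    """Model-style front end to the EM label estimator.

    Mirrors the model/results idiom of statistical modelling packages::

        results = CommitteeLabelModel(matrix, priors=Priors()).fit()
        results.p_hat, results.e_hat
        print(results.summary())
    """

    def __init__(self, matrix: CommitteeMatrix | np.ndarray,
                 priors: Priors = Priors()) -> None:
        self.matrix = matrix
        self.priors = priors
        self._A = _as_matrix(matrix)

    def fit(self, tol: float = 1e-6, max_iter: int = 100,
            variant: EmVariant = "posterior") -> "LabelModelResults":
        est = em_estimate(self.matrix, self.priors, tol=tol,
                          max_iter=max_iter, variant=variant)
        return LabelModelResults(self, est)


class LabelModelResults:
    """Fit results: estimates, hard labels and a text summary."""

    def __init__(self, model: CommitteeLabelModel, estimate: LabelEstimate) -> None:
        self.model = model
        self.estimate = estimate

    @property
    def p_hat(self) -> np.ndarray:
        return self.estimate.p_hat

    @property
    def e_hat(self) -> np.ndarray:
        return self.estimate.e_hat

    def hard_labels(self) -> np.ndarray:
        return self.estimate.hard_labels()

    def summary(self) -> str:
        est = self.estimate
        I, J = self.model._A.shape
        ids = (self.model.matrix.classifier_ids
               if isinstance(self.model.matrix, CommitteeMatrix)
               else [f"clf_{j}" for j in range(J)])
        lines = [
            "Committee label model (EM)",
            "=" * 45,
            f"passages: {I}    classifiers: {J}",
            f"variant: {est.update_variant}    priors: k={self.model.priors.k}/"
            f"K={self.model.priors.K}, k'={self.model.priors.k_prime}/"
            f"K'={self.model.priors.K_prime}",
            f"iterations: {est.iterations}    converged: {est.converged}",
            f"positive fraction (rounded p): {est.hard_labels().mean():.4f}",
            "-" * 45,
            f"{'classifier':<20}{'error rate':>12}",
        ]
        for cid, e in zip(ids, est.e_hat):
            lines.append(f"{cid:<20}{e:>12.4f}")
        return "\n".join(lines)


__all__ = [
    "Priors", "LabelEstimate", "em_estimate", "majority_vote",
    "CommitteeLabelModel", "LabelModelResults",
]
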