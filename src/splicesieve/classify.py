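"""L1-regularized logistic regression over junction feature vectors.

The labelled POTENTIAL_FP subset (coded 1) is regressed on the feature
vectors against the remaining junctions (coded 0). Counts at positions far
from the splice site are noisy and rarely informative, so an L1 penalty
promotes a sparse weight vector, selecting discriminative positions
agnostically. Each junction — including the labelled ones — is then scored
by its posterior probability of belonging to the false-positive class and
discarded when the posterior exceeds the threshold (default 0.5, strict
inequality).

The fit delegates to scikit-learn's saga solver, which leaves the intercept
unpenalized: in the strong-penalty limit all weights vanish and the
posterior collapses to the class prior, as it should.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .core import (
    ContractViolation,
    FPLabel,
    JunctionDecision,
    JunctionKey,
    Status,
)
from .overhang import FeatureVector

logger = logging.getLogger(__name__)

DEFAULT_L1_C = 1.0
DEFAULT_THRESHOLD = 0.5
SOLVER_TOL = 1e-6
SOLVER_MAX_ITER = 10_000


class NoLabeledClassError(ValueError):
    """Both classes are required to fit the semi-supervised filter."""


@dataclass
class FilterModel:
    """Fitted sparse logistic weights for the false-positive class."""

    weights: np.ndarray
    intercept: float
    l1_strength: float
    n_train: int
    n_labeled_fp: int

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.weights))


def _as_matrix(features: Sequence[FeatureVector]) -> np.ndarray:
    X = np.vstack([f.x for f in features])
    if not np.all(np.isfinite(X)):
        raise ContractViolation("non-finite feature values")
    return X


def fit_filter_model(
    features: Sequence[FeatureVector],
    labels: Sequence[FPLabel],
    l1_strength: float = DEFAULT_L1_C,
    seed: int = 0,
) -> FilterModel:
    """Fit the L1-penalized logistic model (POTENTIAL_FP coded 1).

    ``l1_strength`` is scikit-learn's inverse penalty C: smaller C means a
    stronger penalty and a sparser weight vector. Deterministic given the
    seed and solver tolerance. Raises NoLabeledClassError when only one
    class is present.
    """
    if len(features) != len(labels):
        raise ContractViolation("features and labels differ in length")
    X = _as_matrix(features)
    y = np.array([1 if lab.is_potential_fp else 0 for lab in labels])
    if len(set(y)) < 2:
        raise NoLabeledClassError(
            "need at least one POTENTIAL_FP and one PRESUMED_OK junction"
        )
    clf = LogisticRegression(
        l1_ratio=1.0,  # pure L1 penalty
        C=l1_strength,
        solver="saga",
        tol=SOLVER_TOL,
        max_iter=SOLVER_MAX_ITER,
        random_state=seed,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf.fit(X, y)
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        logger.warning("logistic fit did not converge; using last iterate")
    return FilterModel(
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        l1_strength=l1_strength,
        n_train=len(y),
        n_labeled_fp=int(y.sum()),
    )


def posterior_fp(model: FilterModel, x: FeatureVector) -> float:
    """Posterior probability of the false-positive class: logistic(b + w.x)."""
    if x.x.shape != model.weights.shape:
        raise ContractViolation(
            f"feature length {x.x.shape} != model length {model.weights.shape}"
        )
    return float(expit(model.intercept + model.weights @ x.x))


def apply_filter(
    junctions: Mapping[JunctionKey, tuple[FeatureVector, FPLabel]],
    model: FilterModel,
    threshold: float = DEFAULT_THRESHOLD,
    hard_labels: bool = False,
) -> dict[JunctionKey, JunctionDecision]:
    """Score every junction and discard those with posterior > threshold.

    With ``hard_labels`` the labelled POTENTIAL_FP junctions are discarded
    unconditionally (AUTO_DISCARDED) instead of being given the chance of a
    rescue by a low posterior.
    """
    if not 0.0 < threshold < 1.0:
        raise ContractViolation(f"threshold must lie in (0, 1), got {threshold}")
    decisions: dict[JunctionKey, JunctionDecision] = {}
    for key, (fv, label) in junctions.items():
        post = posterior_fp(model, fv)
        if hard_labels and label.is_potential_fp:
            status = Status.AUTO_DISCARDED
        else:
            status = Status.DISCARDED if post > threshold else Status.ACCEPTED
        decisions[key] = JunctionDecision(
            key=key, posterior_fp=post, status=status, label=label
        )
    return decisions


def dump_model(model: FilterModel, path: str, o_min: int = 1) -> None:
    """Write (position, weight) rows plus the intercept as TSV."""
    with open(path, "w") as fh:
        fh.write("position\tweight\n")
        fh.write(f"intercept\t{model.intercept:.10g}\n")
        for i, w in enumerate(model.weights):
            fh.write(f"{o_min + i}\t{w:.10g}\n")
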