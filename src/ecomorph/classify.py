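"""Discriminant-based sex assignment from pelvic shape variables.

Sex differences concentrate in the pelvic girdle, so specimens of
unknown sex are assigned by a linear discriminant trained on specimens
with unambiguous sex; an assignment is only accepted when its posterior
probability clears a threshold (default 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import train_test_split


@dataclass
class DiscriminantModel:
    estimator: LinearDiscriminantAnalysis
    classes: np.ndarray
    n_features: int
    shrinkage: float | None


@dataclass
class AssignmentResult:
    specimen_id: str
    predicted: str
    posterior: float
    accepted: bool


def lda_fit(
    X: pd.DataFrame | np.ndarray,
    labels,
    shrinkage: float | None = 0.1,
    priors: str = "frequency",
) -> DiscriminantModel:
    """Fit a linear discriminant with pooled within-class covariance.

    Because shape spaces are high-dimensional relative to sample sizes,
    the pooled covariance is shrunk toward its diagonal (coefficient
    ``shrinkage``); pass None to disable on full-rank data. Priors
    default to training class frequencies.
    """
    x = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least two training rows")
    prior_vec = counts / counts.sum() if priors == "frequency" else np.full(len(classes), 1 / len(classes))
    if shrinkage is None:
        est = LinearDiscriminantAnalysis(solver="svd", priors=prior_vec)
    else:
        est = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=float(shrinkage), priors=prior_vec)
    est.fit(x, y)
    return DiscriminantModel(estimator=est, classes=classes, n_features=x.shape[1], shrinkage=shrinkage)


def lda_assign(
    model: DiscriminantModel,
    X: pd.DataFrame | np.ndarray,
    threshold: float = 0.8,
    ids=None,
) -> list[AssignmentResult]:
    """Assign classes, accepting only posteriors at or above ``threshold``."""
    x = np.asarray(X, dtype=float)
    if x.ndim != 2 or x.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} features, got {x.shape}")
    if ids is None:
        ids = list(X.index) if isinstance(X, pd.DataFrame) else [str(i) for i in range(len(x))]
    post = model.estimator.predict_proba(x)
    best = post.argmax(axis=1)
    return [
        AssignmentResult(
            specimen_id=str(ids[i]),
            predicted=str(model.estimator.classes_[best[i]]),
            posterior=float(post[i, best[i]]),
            accepted=bool(post[i, best[i]] >= threshold),
        )
        for i in range(len(x))
    ]


@dataclass
class SplitValidation:
    accuracy: float
    acceptance_rate: float
    n_test: int
    n_accepted: int


def split_validate(
    X: pd.DataFrame | np.ndarray,
    labels,
    train_fraction: float = 0.6,
    seed: int = 0,
    threshold: float = 0.8,
    shrinkage: float | None = 0.1,
    max_attempts: int = 10,
) -> SplitValidation:
    """Accuracy of sex assignment under a stratified train/test split.

    Fits on a random ``train_fraction`` of rows (stratified by class),
    assigns the rest, and reports accuracy among accepted assignments
    plus the acceptance rate. A split that loses a class is redrawn with
    a derived seed.
    """
    x = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    last_err = None
    for attempt in range(max_attempts):
        try:
            x_tr, x_te, y_tr, y_te = train_test_split(
                x, y, train_size=train_fraction, random_state=(seed + attempt) % 2**31, stratify=y
            )
            model = lda_fit(x_tr, y_tr, shrinkage=shrinkage)
        except ValueError as exc:
            last_err = exc
            continue
        results = lda_assign(model, x_te, threshold=threshold)
        accepted = [(r, truth) for r, truth in zip(results, y_te) if r.accepted]
        if not accepted:
            return SplitValidation(accuracy=float("nan"), acceptance_rate=0.0, n_test=len(y_te), n_accepted=0)
        correct = sum(r.predicted == str(truth) for r, truth in accepted)
        return SplitValidation(
            accuracy=correct / len(accepted),
            acceptance_rate=len(accepted) / len(y_te),
            n_test=len(y_te),
            n_accepted=len(accepted),
        )
    raise ValueError(f"could not form a valid split after {max_attempts} attempts: {last_err}")
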