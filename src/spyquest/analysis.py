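"""Win/loss outcome analysis: SMOTE rebalancing plus logistic regression.

Game outcomes are typically imbalanced (most players win), so the minority
class is grown to parity with SMOTE — synthetic samples interpolated between
a minority point and one of its k nearest minority neighbours — before a
binary logistic regression predicts win/loss from session measures such as
the number of suspects the player eliminated.  Rebalancing is applied to the
training fold only; evaluation reports accuracy and per-class
precision/recall/F1 at a 0.5 threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .errors import EmptyTestSet, NonConvergence, TooFewMinoritySamples

DEFAULT_FEATURES = ("n_player_eliminated",)


@dataclass
class LabelledDataset:
    """Numeric session features with binary WIN(1)/LOSS(0) labels."""

    features: np.ndarray  # shape (n_sessions, n_features)
    labels: np.ndarray  # shape (n_sessions,), values in {0, 1}
    feature_names: tuple[str, ...]

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D")
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must align")
        if np.isnan(self.features).any():
            raise ValueError("features contain missing values")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")

    @property
    def class_counts(self) -> dict[int, int]:
        values, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}

    @classmethod
    def from_session_table(
        cls,
        table: pd.DataFrame,
        feature_names: tuple[str, ...] = DEFAULT_FEATURES,
    ) -> "LabelledDataset":
        usable = table[~table[list(feature_names)].isna().any(axis=1)]
        return cls(
            features=usable[list(feature_names)].to_numpy(dtype=float),
            labels=usable["won"].astype(bool).astype(int).to_numpy(),
            feature_names=tuple(feature_names),
        )


def smote_oversample(
    dataset: LabelledDataset, k: int = 5, seed: int = 0
) -> LabelledDataset:
    """Grow the minority class to parity by k-NN interpolation.

    Each synthetic point is ``x_i + u * (x_nn - x_i)`` with ``u ~ U(0, 1)``
    and ``x_nn`` one of the k nearest minority neighbours of ``x_i``
    (Euclidean distance on standardised features).  Majority rows are
    untouched; an already balanced dataset is returned unchanged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = dataset.class_counts
    if len(counts) < 2:
        raise TooFewMinoritySamples("both classes must be present")
    minority = min(counts, key=counts.get)
    majority = next(c for c in counts if c != minority)
    n_min, n_maj = counts[minority], counts[majority]
    if n_min == n_maj:
        return dataset
    if n_min < 2:
        raise TooFewMinoritySamples(
            f"minority class has {n_min} sample(s); need >= 2"
        )
    x_min = dataset.features[dataset.labels == minority]
    k_eff = min(k, n_min - 1)
    scale = x_min.std(axis=0)
    scale[scale == 0] = 1.0
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(x_min / scale)
    _, neighbor_idx = nn.kneighbors(x_min / scale)
    neighbor_idx = neighbor_idx[:, 1:]  # drop self

    rng = np.random.default_rng(seed)
    n_new = n_maj - n_min
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k_eff, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    x_i = x_min[base]
    x_nn = x_min[neighbor_idx[base, pick]]
    synthetic = x_i + u[:, None] * (x_nn - x_i)

    features = np.vstack([dataset.features, synthetic])
    labels = np.concatenate(
        [dataset.labels, np.full(n_new, minority, dtype=int)]
    )
    return LabelledDataset(features, labels, dataset.feature_names)


@dataclass
class WinLossModel:
    """Fitted binary logistic regression for game outcomes."""

    intercept: float
    coef: np.ndarray
    feature_names: tuple[str, ...]
    converged: bool = True
    separation: bool = False

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        z = self.intercept + np.asarray(features, dtype=float) @ self.coef
        return 1.0 / (1.0 + np.exp(-z))

    def predict(self, features: np.ndarray) -> np.ndarray:
        return (self.predict_proba(features) >= 0.5).astype(int)


_RIDGE_LAMBDA = 1e-6


def fit_winloss_model(train: LabelledDataset, seed: int = 0) -> WinLossModel:
    """Fit win/loss logistic regression by iterative maximum likelihood.

    Newton iterations with tolerance 1e-8 and at most 100 iterations.
    Perfectly separated data is flagged and refitted with a tiny ridge
    penalty (lambda = 1e-6) so coefficients stay finite; genuine
    non-convergence raises ``NonConvergence`` carrying the last iterate.
    """
    if len(set(train.labels.tolist())) < 2:
        raise ValueError("both classes must be present to fit")
    exog = sm.add_constant(train.features, has_constant="add")
    separation = False
    result = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            result = sm.Logit(train.labels, exog).fit(
                method="newton", maxiter=100, tol=1e-8, disp=0
            )
        except PerfectSeparationError:
            separation = True
        if any(
            issubclass(w.category, PerfectSeparationWarning) for w in caught
        ):
            separation = True

    if separation or result is None or not np.isfinite(result.params).all():
        from sklearn.linear_model import LogisticRegression

        ridge = LogisticRegression(
            C=1.0 / _RIDGE_LAMBDA, tol=1e-8, max_iter=1000
        ).fit(train.features, train.labels)
        return WinLossModel(
            intercept=float(ridge.intercept_[0]),
            coef=ridge.coef_[0].copy(),
            feature_names=train.feature_names,
            converged=True,
            separation=True,
        )

    if not result.mle_retvals.get("converged", False):
        raise NonConvergence(
            "logistic regression did not converge within 100 iterations",
            params=result.params,
        )
    params = np.asarray(result.params, dtype=float)
    return WinLossModel(
        intercept=float(params[0]),
        coef=params[1:].copy(),
        feature_names=train.feature_names,
        converged=True,
        separation=False,
    )


@dataclass
class ClassifierReport:
    """Held-out evaluation of a win/loss model at a 0.5 threshold."""

    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    confusion: dict[str, int]
    n_test: int
    split: str = ""
    seed: int | None = None
    separation: bool = False

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": dict(self.precision),
            "recall": dict(self.recall),
            "f1": dict(self.f1),
            "confusion": dict(self.confusion),
            "n_test": self.n_test,
            "split": self.split,
            "seed": self.seed,
            "separation": self.separation,
        }


def evaluate_classifier(
    model: WinLossModel, test: LabelledDataset
) -> ClassifierReport:
    """Accuracy and per-class precision/recall/F1 on a held-out test set."""
    if len(test.labels) == 0:
        raise EmptyTestSet("test set is empty")
    preds = model.predict(test.features)
    prec, rec, f1, _ = precision_recall_fscore_support(
        test.labels, preds, labels=[0, 1], zero_division=0.0
    )
    cm = confusion_matrix(test.labels, preds, labels=[0, 1])
    return ClassifierReport(
        accuracy=float((preds == test.labels).mean()),
        precision={"loss": float(prec[0]), "win": float(prec[1])},
        recall={"loss": float(rec[0]), "win": float(rec[1])},
        f1={"loss": float(f1[0]), "win": float(f1[1])},
        confusion={
            "tn": int(cm[0, 0]),
            "fp": int(cm[0, 1]),
            "fn": int(cm[1, 0]),
            "tp": int(cm[1, 1]),
        },
        n_test=int(len(test.labels)),
        separation=model.separation,
    )


def analyze_outcomes(
    dataset: LabelledDataset,
    seed: int = 0,
    test_size: float = 0.2,
    k: int = 5,
) -> tuple[WinLossModel, ClassifierReport]:
    """The full pipeline: stratified split, SMOTE on the training fold only,
    logistic fit, held-out evaluation."""
    x_tr, x_te, y_tr, y_te = train_test_split(
        dataset.features,
        dataset.labels,
        test_size=test_size,
        stratify=dataset.labels,
        random_state=seed,
    )
    train = LabelledDataset(x_tr, y_tr, dataset.feature_names)
    test = LabelledDataset(x_te, y_te, dataset.feature_names)
    balanced = smote_oversample(train, k=k, seed=seed)
    model = fit_winloss_model(balanced, seed=seed)
    report = evaluate_classifier(model, test)
    report.split = f"stratified {1 - test_size:.0%}/{test_size:.0%}"
    report.seed = seed
    return model, report
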