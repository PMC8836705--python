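"""Linear-SVM classifier producing methylation variant pathogenicity scores.

A binary support vector machine with linear kernel is trained on beta
values at the signature probes: cases versus negatives (matched controls
alone, or controls plus cohorts of other disorders for the specificity
design). The cost hyperparameter is chosen by stratified 10-fold
cross-validated accuracy over a log-spaced grid; classes are weighted
inversely to their sizes because the specificity design is extremely
imbalanced (tens of cases against well over a thousand negatives).

The raw SVM output is a signed margin. To report a 0-1 MVP score the
margin is passed through a Platt sigmoid

    score = 1 / (1 + exp(A * d + B))

whose parameters are fit on *out-of-fold* decision values, so the
calibration never sees a margin from a model trained on the same sample.
Scores near 1 mean the sample's methylation profile matches the signature;
scores near 0 mean it does not.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .selection import Episignature

DEFAULT_COST_GRID = (0.001, 0.01, 0.1, 1.0, 10.0)


@dataclass(frozen=True)
class TrainConfig:
    n_folds: int = 10
    cost_grid: tuple[float, ...] = DEFAULT_COST_GRID
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not self.cost_grid:
            raise ValueError("cost grid must be non-empty")


@dataclass
class MVPModel:
    probe_ids: list[str]
    weights: np.ndarray
    bias: float
    sigmoid_a: float
    sigmoid_b: float
    cost: float
    cv_accuracy: float
    probe_means: np.ndarray          # training means, used to impute missing probes
    training_composition: dict = field(default_factory=dict)

    def decision_values(self, beta: pd.DataFrame) -> pd.Series:
        x = _feature_matrix(beta, self.probe_ids, self.probe_means)
        return pd.Series(x @ self.weights + self.bias, index=beta.columns)

    def save(self, path) -> None:
        payload = {
            "probe_ids": self.probe_ids,
            "weights": [float(w) for w in self.weights],
            "bias": self.bias,
            "sigmoid_a": self.sigmoid_a,
            "sigmoid_b": self.sigmoid_b,
            "cost": self.cost,
            "cv_accuracy": self.cv_accuracy,
            "probe_means": [float(v) for v in self.probe_means],
            "training_composition": self.training_composition,
        }
        pathlib.Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "MVPModel":
        payload = json.loads(pathlib.Path(path).read_text())
        return cls(
            probe_ids=payload["probe_ids"],
            weights=np.asarray(payload["weights"], dtype=float),
            bias=float(payload["bias"]),
            sigmoid_a=float(payload["sigmoid_a"]),
            sigmoid_b=float(payload["sigmoid_b"]),
            cost=float(payload["cost"]),
            cv_accuracy=float(payload["cv_accuracy"]),
            probe_means=np.asarray(payload["probe_means"], dtype=float),
            training_composition=payload.get("training_composition", {}),
        )


def _feature_matrix(beta: pd.DataFrame, probe_ids, probe_means, max_missing=0.05):
    """Samples-x-probes feature matrix; mean-imputes up to 5% missing probes."""
    missing = [p for p in probe_ids if p not in beta.index]
    if len(missing) > len(probe_ids) * max_missing:
        raise ValueError(
            f"{len(missing)}/{len(probe_ids)} signature probes missing (> {max_missing:.0%})"
        )
    x = np.empty((beta.shape[1], len(probe_ids)))
    pos = {p: i for i, p in enumerate(probe_ids)}
    present = [p for p in probe_ids if p in beta.index]
    sub = beta.loc[present].to_numpy(dtype=float).T
    for j, p in enumerate(present):
        x[:, pos[p]] = sub[:, j]
    for p in missing:
        x[:, pos[p]] = probe_means[pos[p]]
    return x


def fit_platt(decision_values: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fit the Platt sigmoid P(case | d) = 1/(1+exp(A d + B)).

    Uses the standard smoothed targets (t+ = (N+ + 1)/(N+ + 2),
    t- = 1/(N- + 2)) and minimizes the cross-entropy by BFGS.
    """
    d = np.asarray(decision_values, dtype=float)
    y = np.asarray(y)
    n_pos = int((y == 1).sum())
    n_neg = len(y) - n_pos
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(ab):
        a, b = ab
        z = a * d + b
        # stable log(1+exp(z)) formulations
        log1p_ez = np.where(z > 0, z + np.log1p(np.exp(-z)), np.log1p(np.exp(z)))
        return float(np.sum(t * log1p_ez + (1.0 - t) * (log1p_ez - z)))

    res = minimize(nll, x0=np.array([-1.0, 0.0]), method="BFGS")
    a, b = res.x
    if a >= 0:  # degenerate fit (e.g. constant decisions): force monotone-increasing score
        a = -1e-3
    return float(a), float(b)


def _sigmoid_score(d: np.ndarray, a: float, b: float) -> np.ndarray:
    z = a * d + b
    return 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))


def train_mvp(
    beta_at_signature: pd.DataFrame,
    labels,
    config: TrainConfig = TrainConfig(),
) -> MVPModel:
    """Train the linear SVM and its MVP calibration.

    ``labels`` maps each sample to ``"case"`` or anything else (negative).
    Cost is selected by stratified k-fold CV accuracy, ties resolved toward
    the smallest cost (strongest regularization); Platt calibration is fit
    on the out-of-fold decision values at the chosen cost, and the final
    SVM is refit on all samples.
    """
    lab = pd.Series(labels).reindex(beta_at_signature.columns)
    y = (lab == "case").astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both a case and a negative class")
    n_folds = min(config.n_folds, int((y == 1).sum()), int((y == 0).sum()))
    if n_folds < 2:
        raise ValueError("each class needs >= 2 samples for cross-validation")
    probe_ids = list(beta_at_signature.index)
    x = beta_at_signature.to_numpy(dtype=float).T
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=config.seed)
    splits = list(skf.split(x, y))

    accuracies = {}
    oof = {}
    for c in config.cost_grid:
        dec = np.zeros(len(y))
        correct = 0
        for train_idx, test_idx in splits:
            clf = SVC(kernel="linear", C=c, class_weight="balanced")
            clf.fit(x[train_idx], y[train_idx])
            dec[test_idx] = clf.decision_function(x[test_idx])
            correct += int((clf.predict(x[test_idx]) == y[test_idx]).sum())
        accuracies[c] = correct / len(y)
        oof[c] = dec
    best = max(sorted(config.cost_grid), key=lambda c: (accuracies[c], -c))

    a, b = fit_platt(oof[best], y)
    clf = SVC(kernel="linear", C=best, class_weight="balanced")
    clf.fit(x, y)
    weights = clf.coef_.ravel().copy()
    bias = float(clf.intercept_[0])
    comp = lab.value_counts().to_dict()
    return MVPModel(
        probe_ids=probe_ids,
        weights=weights,
        bias=bias,
        sigmoid_a=a,
        sigmoid_b=b,
        cost=float(best),
        cv_accuracy=float(accuracies[best]),
        probe_means=x.mean(axis=0),
        training_composition={str(k): int(v) for k, v in comp.items()},
    )


def score_samples(model: MVPModel, beta: pd.DataFrame) -> pd.DataFrame:
    """MVP scores for each sample (column) of ``beta``.

    Returns a frame indexed by sample id with ``decision_value`` (signed
    margin) and ``mvp_score`` in [0, 1], in input order. Samples must carry
    at least 95% of the signature probes; the rest are mean-imputed.
    """
    d = model.decision_values(beta)
    scores = _sigmoid_score(d.to_numpy(), model.sigmoid_a, model.sigmoid_b)
    return pd.DataFrame({"decision_value": d, "mvp_score": scores}, index=d.index)


def train_specificity_model(
    beta: pd.DataFrame,
    labels,
    other_cohort_ids: dict[str, list[str]],
    signature: Episignature,
    config: TrainConfig = TrainConfig(),
) -> tuple[MVPModel, pd.DataFrame]:
    """Two-stage specificity design: negatives = controls + other disorders.

    ``other_cohort_ids`` maps cohort name to its sample ids (all present in
    ``beta``). Returns the model and a per-sample score table annotated
    with cohort membership, from which per-cohort score distributions can
    be read.
    """
    if not other_cohort_ids:
        raise ValueError("specificity training requires >= 1 other cohort")
    lab = pd.Series(labels).copy()
    cohort_of = {}
    for name, ids in other_cohort_ids.items():
        for sid in ids:
            lab[sid] = "other"
            cohort_of[sid] = name
    cols = [s for s in beta.columns if s in lab.index and lab[s] in ("case", "control", "other")]
    sub = beta.loc[signature.probe_ids, cols]
    train_lab = lab[cols]
    model = train_mvp(sub, train_lab, config)
    scores = score_samples(model, sub)
    scores["cohort"] = [
        "case" if train_lab[s] == "case"
        else cohort_of.get(s, "control")
        for s in scores.index
    ]
    return model, scores
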