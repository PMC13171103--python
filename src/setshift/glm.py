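"""Logistic decoding of trial outcome from pre-choice population activity.

The predictors are the first three principal components of the 5 s
pre-choice population means of a random 40% neuron subsample; the target
is the trial outcome (correct = 1).  Fitting maximizes the L2-penalized
Bernoulli log-likelihood by Newton iterations (IRLS); the intercept is not
penalized.  Probabilities strictly above 0.5 predict a correct choice;
exactly 0.5 maps to incorrect, so the rule is sign(linear score) with
zero assigned to class 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .hmm import balance_trials, prechoice_matrix, trial_features
from .synth import Session


@dataclass
class LogisticModel:
    weights: np.ndarray  # intercept first
    l2: float
    converged: bool
    log_likelihood_trace: list = field(default_factory=list)


def _penalized_ll(w: np.ndarray, Xd: np.ndarray, y: np.ndarray, l2: float) -> float:
    score = Xd @ w
    # log sigma(s) = -log(1 + e^{-s}) computed stably
    ll = -(np.logaddexp(0.0, -score) * y + np.logaddexp(0.0, score) * (1 - y)).sum()
    return float(ll - 0.5 * l2 * (w[1:] ** 2).sum())


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    l2: float = 1e-3,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticModel:
    """Newton/IRLS fit of the penalized logistic model (intercept unpenalized)."""
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("training outcomes are single-class")
    n, d = X.shape
    Xd = np.hstack([np.ones((n, 1)), X])
    w = np.zeros(d + 1)
    pen = np.zeros(d + 1)
    pen[1:] = l2
    trace = [_penalized_ll(w, Xd, y, l2)]
    converged = False
    for _ in range(max_iter):
        p = expit(Xd @ w)
        grad = Xd.T @ (y - p) - pen * w
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        W = np.maximum(p * (1 - p), 1e-12)
        H = (Xd * W[:, None]).T @ Xd + np.diag(pen + 1e-12)
        step = np.linalg.solve(H, grad)
        # backtracking keeps the penalized log-likelihood non-decreasing
        t = 1.0
        cur = trace[-1]
        for _bt in range(30):
            cand = w + t * step
            if _penalized_ll(cand, Xd, y, l2) >= cur - 1e-12:
                break
            t *= 0.5
        w = w + t * step
        trace.append(_penalized_ll(w, Xd, y, l2))
    return LogisticModel(weights=w, l2=l2, converged=converged, log_likelihood_trace=trace)


def predict_proba(model: LogisticModel, X: np.ndarray) -> np.ndarray:
    Xd = np.hstack([np.ones((X.shape[0], 1)), X])
    return expit(Xd @ model.weights)


def predict_choice(model: LogisticModel, X: np.ndarray) -> np.ndarray:
    """1 iff probability strictly above 0.5 (linear score > 0)."""
    Xd = np.hstack([np.ones((X.shape[0], 1)), X])
    return (Xd @ model.weights > 0.0).astype(int)


def _stratified_split(
    y: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray] | None:
    """Outcome-stratified train mask; None when a side would be single-class."""
    n = y.size
    train = np.zeros(n, dtype=bool)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if idx.size < 2:
            return None
        k = int(round(train_fraction * idx.size))
        k = min(max(k, 1), idx.size - 1)
        chosen = rng.choice(idx, size=k, replace=False)
        train[chosen] = True
    return train, ~train


def choice_decode_bootstrap(
    session: Session,
    n_iterations: int = 1000,
    neuron_fraction: float = 0.4,
    train_fraction: float = 0.9,
    n_components: int = 3,
    balance_target: int = 31,
    l2: float = 1e-3,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Held-out outcome-prediction accuracy over bootstrap iterations."""
    rng = np.random.default_rng() if rng is None else rng
    matrix = prechoice_matrix(session)
    outcomes = (session.trials["outcome"] == "correct").to_numpy().astype(int)
    n_trials, n_neurons = matrix.shape
    rows = []
    for i in range(n_iterations):
        cols = rng.choice(
            n_neurons,
            size=max(1, int(round(neuron_fraction * n_neurons))),
            replace=False,
        )
        idx = balance_trials(n_trials, balance_target, rng)
        X = matrix[np.ix_(idx, np.sort(cols))]
        y = outcomes[idx]
        row = {"iteration": i, "valid": False, "accuracy": np.nan}
        split = _stratified_split(y, train_fraction, rng)
        if split is not None:
            train, test = split
            try:
                feats = trial_features(X, n_components)
                model = fit_logistic(feats[train], y[train], l2=l2)
                pred = predict_choice(model, feats[test])
                row["valid"] = True
                row["accuracy"] = float((pred == y[test]).mean())
            except (ValueError, np.linalg.LinAlgError):
                pass
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_choice_decode(df: pd.DataFrame) -> dict:
    valid = df[df["valid"]]
    vals = valid["accuracy"].to_numpy()
    return {
        "n_iterations": int(len(df)),
        "failure_rate": 1.0 - len(valid) / len(df),
        "accuracy": {
            "median": float(np.median(vals)) if vals.size else None,
            "mean": float(vals.mean()) if vals.size else None,
            "sem": float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0,
        },
    }
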