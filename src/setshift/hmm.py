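"""Two-state Gaussian HMM decoding of behavioral states from population activity.

Per trial, the feature vector is the mean z-scored pre-choice (5 s)
activity of a random neuron subsample, reduced to a few principal
components.  K-means initializes a diagonal-covariance Gaussian HMM that
is fitted with Baum-Welch (log-space forward-backward) on 90% of trials
and decoded with Viterbi over the full chronological sequence.  Hidden
states are mapped to early/late by majority overlap with the behavioral
labels on the training trials; performance is the fraction of correctly
predicted trial states and the signed offset between the predicted and
behavioral switch points.  Sessions are balanced to a common trial count
by with-replacement upsampling that keeps duplicates adjacent to their
source trial, preserving the single early-to-late transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .behavior import StateLabeling, label_states
from .preprocess import FluorescenceMatrix, extract_window, zscore_per_neuron
from .synth import Session
from .tuning import PRECHOICE_WINDOW, trial_mean_prechoice

VAR_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# Features


def prechoice_matrix(session: Session) -> np.ndarray:
    """[n_trials, n_neurons] mean z-scored activity in the 5 s before choice."""
    F = zscore_per_neuron(FluorescenceMatrix.from_session(session))
    tensor = extract_window(F, session.trials, PRECHOICE_WINDOW)
    return trial_mean_prechoice(tensor)


def trial_features(matrix: np.ndarray, n_components: int) -> np.ndarray:
    """PCA scores of the trial-by-neuron matrix (centered, SVD-based).

    Deterministic sign convention: each component's largest-magnitude
    loading is made positive.
    """
    n_trials, n_dims = matrix.shape
    if n_components > n_dims:
        raise ValueError(f"n_components {n_components} exceeds dimension {n_dims}")
    xc = matrix - matrix.mean(axis=0, keepdims=True)
    if np.allclose(xc, 0.0):
        raise ValueError("degenerate session: constant activity across trials")
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    vt = vt[:n_components]
    flip = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    return xc @ vt.T


# ---------------------------------------------------------------------------
# K-means initialization


def _lloyd(X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100):
    n = X.shape[0]
    centers = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.zeros(n, dtype=int)
    for it in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        if np.any(np.bincount(new_labels, minlength=k) == 0):
            return None, None, np.inf
        if it > 0 and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            centers[j] = X[labels == j].mean(axis=0)
    wcss = float(((X - centers[labels]) ** 2).sum())
    return labels, centers, wcss


def kmeans_init(
    X: np.ndarray,
    k: int = 2,
    rng: np.random.Generator | None = None,
    n_restarts: int = 10,
    max_attempts: int = 20,
) -> np.ndarray:
    """Best-of-n-restarts Lloyd assignment (lowest within-cluster SS)."""
    rng = np.random.default_rng() if rng is None else rng
    if X.shape[0] < 2 * k:
        raise ValueError("need at least 2k points")
    best_labels, best_wcss = None, np.inf
    attempts = 0
    restarts = 0
    while restarts < n_restarts and attempts < n_restarts + max_attempts:
        attempts += 1
        labels, _, wcss = _lloyd(X, k, rng)
        if labels is None:
            continue  # empty cluster: re-seed
        restarts += 1
        if wcss < best_wcss:
            best_labels, best_wcss = labels, wcss
    if best_labels is None:
        raise RuntimeError("k-means failed: empty cluster on every attempt")
    return best_labels


# ---------------------------------------------------------------------------
# HMM


@dataclass
class HmmModel:
    initial: np.ndarray  # [k]
    transition: np.ndarray  # [k, k], row-stochastic
    means: np.ndarray  # [k, d]
    variances: np.ndarray  # [k, d], diagonal
    log_likelihood_trace: list = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return self.initial.size


def init_from_assignment(X: np.ndarray, labels: np.ndarray, k: int = 2) -> HmmModel:
    """Seed emission and transition parameters from a hard assignment."""
    d = X.shape[1]
    means = np.zeros((k, d))
    variances = np.ones((k, d))
    for j in range(k):
        pts = X[labels == j]
        means[j] = pts.mean(axis=0)
        variances[j] = np.maximum(pts.var(axis=0), VAR_FLOOR)
    counts = np.ones((k, k))  # Laplace smoothing keeps rows stochastic
    for a, b in zip(labels[:-1], labels[1:]):
        counts[a, b] += 1.0
    transition = counts / counts.sum(axis=1, keepdims=True)
    initial = np.full(k, 1.0 / k)
    initial[labels[0]] += 1.0
    initial /= initial.sum()
    return HmmModel(initial=initial, transition=transition, means=means, variances=variances)


def _log_emission(model: HmmModel, X: np.ndarray) -> np.ndarray:
    """[T, k] diagonal-Gaussian log densities."""
    diff = X[:, None, :] - model.means[None, :, :]
    var = model.variances[None, :, :]
    return -0.5 * (np.log(2 * np.pi * var) + diff**2 / var).sum(axis=2)


_LOG_FLOOR = 1e-300  # log(0) -> -690, numerically equivalent to -inf


def forward_backward(model: HmmModel, X: np.ndarray):
    """Log-space forward-backward.

    Returns (log_gamma [T, k], xi_sum [k, k], loglik); no underflow for any
    practical T because all recursions stay in log space.
    """
    logB = _log_emission(model, X)
    T, k = logB.shape
    logA = np.log(np.maximum(model.transition, _LOG_FLOOR))
    log_alpha = np.empty((T, k))
    log_alpha[0] = np.log(np.maximum(model.initial, _LOG_FLOOR)) + logB[0]
    for t in range(1, T):
        log_alpha[t] = logB[t] + np.logaddexp.reduce(
            log_alpha[t - 1][:, None] + logA, axis=0
        )
    loglik = float(logsumexp(log_alpha[-1]))
    log_beta = np.zeros((T, k))
    for t in range(T - 2, -1, -1):
        log_beta[t] = np.logaddexp.reduce(
            logA + (logB[t + 1] + log_beta[t + 1])[None, :], axis=1
        )
    log_gamma = log_alpha + log_beta - loglik
    log_xi = (
        log_alpha[:-1, :, None]
        + logA[None, :, :]
        + (logB[1:] + log_beta[1:])[:, None, :]
        - loglik
    )
    xi_sum = np.exp(log_xi).sum(axis=0)
    return log_gamma, xi_sum, loglik


def fit_baum_welch(
    X: np.ndarray, init: HmmModel, max_iter: int = 100, tol: float = 1e-4
) -> HmmModel:
    """EM on the chronological sequence with diagonal-Gaussian emissions."""
    model = HmmModel(
        initial=init.initial.copy(),
        transition=init.transition.copy(),
        means=init.means.copy(),
        variances=init.variances.copy(),
    )
    prev = -np.inf
    for it in range(max_iter):
        with np.errstate(invalid="ignore", divide="ignore"):
            log_gamma, xi_sum, loglik = forward_backward(model, X)
        if not np.isfinite(loglik):
            raise RuntimeError(f"non-finite likelihood at EM iteration {it}")
        model.log_likelihood_trace.append(loglik)
        if loglik - prev < tol and it > 0:
            break
        prev = loglik
        gamma = np.exp(log_gamma)  # [T, k]
        occ = np.maximum(gamma.sum(axis=0), 1e-12)  # [k]
        model.initial = gamma[0] / gamma[0].sum()
        rows = xi_sum.sum(axis=1, keepdims=True)
        model.transition = np.where(rows > 0, xi_sum / np.maximum(rows, 1e-300), model.transition)
        model.transition /= model.transition.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            means = (gamma.T @ X) / occ[:, None]
            sq = (gamma.T @ (X**2)) / occ[:, None]
        model.means = means
        model.variances = np.maximum(sq - means**2, VAR_FLOOR)
    return model


def viterbi(model: HmmModel, X: np.ndarray) -> np.ndarray:
    """Most probable hidden path in log space; ties break to the lower index."""
    logB = _log_emission(model, X)
    T, k = logB.shape
    logA = np.log(np.maximum(model.transition, _LOG_FLOOR))
    delta = np.log(np.maximum(model.initial, _LOG_FLOOR)) + logB[0]
    back = np.zeros((T, k), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logA  # [from, to]
        back[t] = cand.argmax(axis=0)  # argmax takes the lowest index on ties
        delta = cand[back[t], np.arange(k)] + logB[t]
    path = np.zeros(T, dtype=int)
    path[-1] = int(delta.argmax())
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


# ---------------------------------------------------------------------------
# Protocol: balancing, mapping, bootstrap


def balance_trials(
    n_trials: int, target: int = 31, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Source-trial index sequence upsampled to ``target`` positions.

    Extra indices are drawn with replacement and inserted adjacent to their
    source trial (the output is sorted by source index), so a single
    early-to-late transition in the source labels stays single.
    """
    if n_trials < 2:
        raise ValueError("need at least two trials")
    if target < n_trials:
        raise ValueError("downsampling not supported: target below n_trials")
    rng = np.random.default_rng() if rng is None else rng
    extra = rng.integers(0, n_trials, size=target - n_trials)
    return np.sort(np.concatenate([np.arange(n_trials), extra]))


def _map_states(
    path: np.ndarray, behav: np.ndarray, train_mask: np.ndarray, k: int = 2
) -> np.ndarray:
    """Hidden-state -> behavior-label map by overlap on training trials.

    behav is 0 (early) / 1 (late).  The hidden state with the greater
    late-trial overlap becomes late and the other early (relative majority:
    an absolute rule would map both states to early whenever the neural
    transition leads the behavioral switch by more than the terminal run
    length).  Ties go to the state occupying later sequence positions; a
    hidden state absent from the training trials takes the complement of
    the present one's absolute majority.
    """
    present = [h for h in range(k) if np.any(train_mask & (path == h))]
    mapping = np.zeros(k, dtype=int)
    if len(present) < k and len(present) == 1:
        h = present[0]
        sel = train_mask & (path == h)
        mapping[h] = 1 if behav[sel].mean() > 0.5 else 0
        for other in range(k):
            if other != h:
                mapping[other] = 1 - mapping[h]
        return mapping
    frac_late = np.zeros(k)
    mean_pos = np.zeros(k)
    for h in range(k):
        sel = train_mask & (path == h)
        frac_late[h] = behav[sel].mean()
        mean_pos[h] = np.flatnonzero(sel).mean()
    order = np.lexsort((mean_pos, frac_late))  # ties broken by mean position
    late_state = order[-1]
    mapping[late_state] = 1
    return mapping


@dataclass
class DecodeOutcome:
    predicted: np.ndarray  # per balanced position: 0 early / 1 late
    state_accuracy: float
    accuracy_heldout: float
    delta_switch: float
    valid: bool


def decode_session(
    matrix: np.ndarray,
    labeling: StateLabeling,
    trial_ids: np.ndarray,
    rng: np.random.Generator,
    neuron_fraction: float = 0.4,
    train_fraction: float = 0.9,
    n_components: int = 3,
    balance_target: int = 31,
) -> DecodeOutcome:
    """One bootstrap iteration of the HMM state-decoding protocol."""
    n_trials, n_neurons = matrix.shape
    cols = rng.choice(
        n_neurons, size=max(1, int(round(neuron_fraction * n_neurons))), replace=False
    )
    idx = balance_trials(n_trials, balance_target, rng)
    X = matrix[np.ix_(idx, np.sort(cols))]
    behav = (labeling.states[idx] == "late").astype(int)

    try:
        feats = trial_features(X, n_components)
        labels0 = kmeans_init(feats, 2, rng)
        init = init_from_assignment(feats, labels0, 2)
    except (ValueError, RuntimeError):
        return DecodeOutcome(np.array([]), np.nan, np.nan, np.nan, False)

    T = idx.size
    n_train = int(round(train_fraction * T))
    train_pos = np.sort(rng.choice(T, size=n_train, replace=False))
    train_mask = np.zeros(T, dtype=bool)
    train_mask[train_pos] = True

    try:
        model = fit_baum_welch(feats[train_mask], init)
        path = viterbi(model, feats)  # full sequence keeps temporal context
    except RuntimeError:
        return DecodeOutcome(np.array([]), np.nan, np.nan, np.nan, False)

    mapping = _map_states(path, behav, train_mask)
    pred = mapping[path]

    acc_all = float((pred == behav).mean())
    held = ~train_mask
    acc_held = float((pred[held] == behav[held]).mean()) if held.sum() else np.nan

    if pred[-1] != 1:
        return DecodeOutcome(pred, acc_all, acc_held, np.nan, False)
    run_start = T - 1
    while run_start > 0 and pred[run_start - 1] == 1:
        run_start -= 1
    predicted_switch_trial = int(trial_ids[idx[run_start]])
    delta = float(predicted_switch_trial - labeling.switch_point)
    return DecodeOutcome(pred, acc_all, acc_held, delta, True)


def decode_bootstrap(
    session: Session,
    labeling: StateLabeling | None = None,
    n_iterations: int = 1000,
    neuron_fraction: float = 0.4,
    train_fraction: float = 0.9,
    n_components: int = 3,
    balance_target: int = 31,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Repeat the decoding protocol over random neuron subsamples.

    Returns one row per iteration (valid flag, all-trial and held-out
    accuracy, delta switch point in trials).
    """
    if session.n_neurons < 5:
        raise ValueError("need at least 5 neurons")
    rng = np.random.default_rng() if rng is None else rng
    if labeling is None:
        labeling = label_states(session.trials)
    matrix = prechoice_matrix(session)
    trial_ids = session.trials["trial_id"].to_numpy()
    rows = []
    for i in range(n_iterations):
        out = decode_session(
            matrix,
            labeling,
            trial_ids,
            rng,
            neuron_fraction,
            train_fraction,
            n_components,
            balance_target,
        )
        rows.append(
            {
                "iteration": i,
                "valid": out.valid,
                "accuracy_all": out.state_accuracy,
                "accuracy_heldout": out.accuracy_heldout,
                "delta_switch": out.delta_switch,
            }
        )
    return pd.DataFrame(rows)


def summarize_decode(df: pd.DataFrame) -> dict:
    """Median / mean +- SEM per metric, plus the failure rate.

    Each metric is summarized over the iterations on which it is defined:
    accuracies over every decoded iteration, delta_switch only over
    iterations with a terminal predicted-late run (valid).  failure_rate
    is the fraction of iterations without a defined delta_switch.
    """
    valid = df[df["valid"]]
    out = {"n_iterations": int(len(df)), "failure_rate": 1.0 - len(valid) / len(df)}
    for coln in ("accuracy_all", "accuracy_heldout", "delta_switch"):
        vals = df[coln].dropna().to_numpy()
        if vals.size:
            out[coln] = {
                "median": float(np.median(vals)),
                "mean": float(vals.mean()),
                "sem": float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0,
            }
        else:
            out[coln] = {"median": None, "mean": None, "sem": None}
    return out
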