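"""Single-neuron tuning: ROC analysis of pre-choice activity.

Each neuron's mean z-scored activity in the 5 s before the choice is
compared between two trial sets for three contrasts: switch (early vs late
state), history (previous trial correct vs incorrect), and choice (upcoming
outcome correct vs incorrect).  Discriminability is the ROC area under the
curve; significance is a two-sided label-permutation test on |AUC - 0.5|
with add-one correction.  Neurons with p < alpha are responsive; responsive
to two or more variables is mixed tuning.  Group fractions are pooled over
sessions and compared with Pearson chi-squared tests (df = 1, no continuity
correction).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import StateLabeling, label_states
from .preprocess import AlignedTensor, FluorescenceMatrix, extract_window, zscore_per_neuron
from .synth import Session

PRECHOICE_WINDOW = (-5.0, 0.0)


def trial_mean_prechoice(tensor: AlignedTensor) -> np.ndarray:
    """Per-trial, per-neuron mean over all bins in the window."""
    return tensor.values.mean(axis=2)


def _rank_auc(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Column-wise AUC via the Mann-Whitney rank formula (ties give 0.5).

    values: [n_trials, n_neurons]; labels: boolean positives per trial.
    """
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be non-empty")
    ranks = stats.rankdata(values, axis=0)
    u = ranks[labels].sum(axis=0) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def roc_auc(values, labels) -> float:
    """AUC = P(positive > negative) + 0.5 P(tie) for scalar trial values."""
    values = np.asarray(values, dtype=float).reshape(-1, 1)
    labels = np.asarray(labels).astype(bool)
    return float(_rank_auc(values, labels)[0])


def permutation_auc_pvalues(
    values: np.ndarray, labels: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided permutation test for every neuron (column).

    Returns (auc, p).  p = (1 + #{|AUC* - .5| >= |AUC - .5|}) / (n_perm + 1),
    with the same uniform label permutation applied to all neurons.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    ranks = stats.rankdata(values, axis=0)  # [n_trials, n_neurons]
    offset = n1 * (n1 + 1) / 2.0
    denom = n1 * n0
    auc = (ranks[labels].sum(axis=0) - offset) / denom

    n_trials = labels.size
    sel = np.zeros((n_perm, n_trials))
    for i in range(n_perm):
        sel[i, rng.permutation(n_trials)[:n1]] = 1.0
    perm_auc = (sel @ ranks - offset) / denom  # [n_perm, n_neurons]
    exceed = (np.abs(perm_auc - 0.5) >= np.abs(auc - 0.5)[None, :] - 1e-12).sum(axis=0)
    p = (1.0 + exceed) / (n_perm + 1.0)
    return auc, p


def permutation_pvalue(values, labels, n_perm: int, rng: np.random.Generator) -> float:
    """Scalar-version permutation p-value for one neuron."""
    values = np.asarray(values, dtype=float).reshape(-1, 1)
    _, p = permutation_auc_pvalues(values, labels, n_perm, rng)
    return float(p[0])


def _contrast_labels(trials: pd.DataFrame, labeling: StateLabeling) -> dict:
    """Trial masks and label vectors for the three contrasts.

    Returns {name: (row_mask, positive_labels)}; history drops trial 1.
    """
    outcomes = (trials["outcome"] == "correct").to_numpy()
    n = outcomes.size
    all_rows = np.ones(n, dtype=bool)
    hist_rows = np.zeros(n, dtype=bool)
    hist_rows[1:] = True
    return {
        "switch": (all_rows, labeling.late_mask),
        "history": (hist_rows, np.concatenate([[False], outcomes[:-1]])[hist_rows]),
        "choice": (all_rows, outcomes),
    }


def classify_session(
    session: Session,
    labeling: StateLabeling | None = None,
    alpha: float = 0.05,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    min_class: int = 2,
) -> pd.DataFrame:
    """Per-neuron tuning table for one session.

    Columns: auc_*, p_* and responsive_* per contrast, plus mixed and
    responsive_any.  A contrast whose smaller class has fewer than
    ``min_class`` trials is unclassifiable for the whole session: AUC and p
    are NaN and the flag is False.
    """
    rng = np.random.default_rng() if rng is None else rng
    if labeling is None:
        labeling = label_states(session.trials)
    F = zscore_per_neuron(FluorescenceMatrix.from_session(session))
    tensor = extract_window(F, session.trials, PRECHOICE_WINDOW)
    means = trial_mean_prechoice(tensor)  # [n_trials, n_neurons]

    n_neurons = means.shape[1]
    out = pd.DataFrame({"neuron_id": np.arange(n_neurons)})
    for name, (rows, labels) in _contrast_labels(session.trials, labeling).items():
        vals = means[rows]
        labels = np.asarray(labels).astype(bool)
        n1 = int(labels.sum())
        n0 = labels.size - n1
        if min(n1, n0) < min_class:
            out[f"auc_{name}"] = np.nan
            out[f"p_{name}"] = np.nan
            out[f"responsive_{name}"] = False
            continue
        auc, p = permutation_auc_pvalues(vals, labels, n_perm, rng)
        out[f"auc_{name}"] = auc
        out[f"p_{name}"] = p
        out[f"responsive_{name}"] = p < alpha
    flags = out[[f"responsive_{v}" for v in ("choice", "history", "switch")]]
    out["responsive_any"] = flags.any(axis=1)
    out["mixed"] = flags.sum(axis=1) >= 2
    return out


def fraction_table(results_by_group: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pooled 2x2 counts (responsive vs not) per variable and group.

    ``results_by_group`` maps group name to the concatenated tuning tables
    of that group's sessions.  Also tabulates the overall responsive
    fraction and the mixed fraction among responsive neurons.
    """
    rows = []
    for variable in ("choice", "history", "switch", "any"):
        col = "responsive_any" if variable == "any" else f"responsive_{variable}"
        for group, df in results_by_group.items():
            k = int(df[col].sum())
            n = len(df)
            rows.append(
                {
                    "variable": variable,
                    "group": group,
                    "responsive": k,
                    "total": n,
                    "percent": round(100.0 * k / n) if n else np.nan,
                }
            )
    for group, df in results_by_group.items():
        resp = df[df["responsive_any"]]
        k, n = int(resp["mixed"].sum()), len(resp)
        rows.append(
            {
                "variable": "mixed_among_responsive",
                "group": group,
                "responsive": k,
                "total": n,
                "percent": round(100.0 * k / n) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def chi_squared_2x2(table) -> tuple[float, float]:
    """Pearson chi-squared (df=1, no continuity correction) on a 2x2 table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table < 0):
        raise ValueError("negative cell count")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def compare_fractions(fractions: pd.DataFrame, group_a: str, group_b: str) -> pd.DataFrame:
    """Chi-squared group comparison for every tabulated variable."""
    rows = []
    for variable, sub in fractions.groupby("variable", sort=False):
        a = sub[sub["group"] == group_a].iloc[0]
        b = sub[sub["group"] == group_b].iloc[0]
        table = [
            [a["responsive"], a["total"] - a["responsive"]],
            [b["responsive"], b["total"] - b["responsive"]],
        ]
        stat, p = chi_squared_2x2(table)
        rows.append(
            {
                "variable": variable,
                f"fraction_{group_a}": a["responsive"] / a["total"],
                f"fraction_{group_b}": b["responsive"] / b["total"],
                "chi2": stat,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
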