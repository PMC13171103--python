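"""Population state-trajectory geometry.

Early- and late-state population trajectories are trial-averaged z-scored
activity in 50 ms bins over the ten seconds centered on the choice,
smoothed with a Gaussian kernel, embedded with PCA fitted jointly on both
states, and compared through the per-bin Euclidean distance in PC space
and the mean per-PC Pearson correlation (vector similarity).  Neuron-level
bootstrap: each iteration uses a random 80% of neurons; the default is 20
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from sklearn.decomposition import PCA

from .behavior import StateLabeling, label_states
from .preprocess import FluorescenceMatrix, extract_window, zscore_per_neuron
from .synth import Session

TRAJECTORY_WINDOW = (-5.0, 5.0)
BIN_WIDTH = 0.05
SMOOTH_SIGMA_S = 0.15
N_COMPONENTS = 6


@dataclass
class StateTrajectory:
    values: np.ndarray  # [n_bins, n_neurons_subset]
    state: str
    bin_centers: np.ndarray


@dataclass
class GeometryMetrics:
    distance_series: np.ndarray
    bin_centers: np.ndarray
    prechoice_mean: float
    prechoice_peak: float
    similarity: float
    variance_explained: np.ndarray


def state_trajectory_matrices(
    session: Session, labeling: StateLabeling | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-session early/late trial-averaged matrices [n_bins, n_neurons]."""
    if labeling is None:
        labeling = label_states(session.trials)
    F = zscore_per_neuron(FluorescenceMatrix.from_session(session))
    tensor = extract_window(F, session.trials, TRAJECTORY_WINDOW, BIN_WIDTH)
    early_mask = labeling.early_mask
    late_mask = labeling.late_mask
    if early_mask.sum() == 0 or late_mask.sum() == 0:
        raise ValueError("both states need at least one trial")
    early = tensor.values[early_mask].mean(axis=0).T  # [n_bins, n_neurons]
    late = tensor.values[late_mask].mean(axis=0).T
    return early, late, tensor.bin_centers


def stack_group_trajectories(
    sessions: list[Session],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack per-session state trajectories neuron-wise on the common grid."""
    earlies, lates, centers = [], [], None
    for s in sessions:
        e, l, centers = state_trajectory_matrices(s)
        earlies.append(e)
        lates.append(l)
    return np.hstack(earlies), np.hstack(lates), centers


def _smooth(traj: np.ndarray, sigma_s: float = SMOOTH_SIGMA_S) -> np.ndarray:
    """Gaussian smoothing along time, per neuron (truncated at 3 sigma)."""
    if sigma_s <= 0:
        return traj
    return gaussian_filter1d(traj, sigma=sigma_s / BIN_WIDTH, axis=0, truncate=3.0)


def build_state_trajectories(
    early: np.ndarray,
    late: np.ndarray,
    bin_centers: np.ndarray,
    subset_fraction: float = 0.8,
    n_iterations: int = 20,
    rng: np.random.Generator | None = None,
    smooth_sigma_s: float = SMOOTH_SIGMA_S,
) -> list[tuple[StateTrajectory, StateTrajectory]]:
    """Neuron-bootstrap trajectory pairs from full state matrices.

    Each iteration samples floor(subset_fraction * N) neurons without
    replacement (both states share the subset) and smooths per neuron.
    """
    if not 0.0 < subset_fraction <= 1.0:
        raise ValueError("subset_fraction must be in (0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    n = early.shape[1]
    k = max(1, int(np.floor(subset_fraction * n)))
    pairs = []
    for _ in range(n_iterations):
        cols = np.sort(rng.choice(n, size=k, replace=False)) if k < n else np.arange(n)
        e = _smooth(early[:, cols], smooth_sigma_s)
        l = _smooth(late[:, cols], smooth_sigma_s)
        pairs.append(
            (
                StateTrajectory(e, "early", bin_centers),
                StateTrajectory(l, "late", bin_centers),
            )
        )
    return pairs


def pca_embed(
    pair: tuple[StateTrajectory, StateTrajectory], n_components: int = N_COMPONENTS
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint PCA of both trajectories; returns (early_pc, late_pc, var_explained).

    The model is fitted on the row-concatenation of both state matrices
    (2*n_bins x n_neurons, centered per neuron) so distances between the
    embedded trajectories live in a single space.
    """
    early, late = pair
    if early.values.shape != late.values.shape:
        raise ValueError("state trajectories must share the neuron subset")
    stacked = np.vstack([early.values, late.values])
    k = min(n_components, stacked.shape[1], stacked.shape[0])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(stacked)
    n_bins = early.values.shape[0]
    return scores[:n_bins], scores[n_bins:], pca.explained_variance_ratio_


def distance_metrics(
    early_pc: np.ndarray,
    late_pc: np.ndarray,
    bin_centers: np.ndarray,
    variance_explained: np.ndarray | None = None,
    similarity_value: float | None = None,
) -> GeometryMetrics:
    """Per-bin Euclidean distance in PC space with pre-choice summaries.

    Pre-choice statistics are over bins whose centers fall in (-5, 0).
    """
    series = np.linalg.norm(early_pc - late_pc, axis=1)
    pre = (bin_centers > -5.0) & (bin_centers < 0.0)
    return GeometryMetrics(
        distance_series=series,
        bin_centers=bin_centers,
        prechoice_mean=float(series[pre].mean()),
        prechoice_peak=float(series[pre].max()),
        similarity=similarity_value if similarity_value is not None else np.nan,
        variance_explained=(
            variance_explained if variance_explained is not None else np.array([])
        ),
    )


def similarity(early_pc: np.ndarray, late_pc: np.ndarray) -> float:
    """Mean over retained PCs of Pearson r between the two state time series.

    Zero-variance PC series are excluded from the mean.
    """
    if early_pc.shape[0] < 2:
        raise ValueError("need at least two bins")
    rs = []
    for c in range(early_pc.shape[1]):
        x, y = early_pc[:, c], late_pc[:, c]
        if x.std() == 0 or y.std() == 0:
            continue
        rs.append(np.corrcoef(x, y)[0, 1])
    if not rs:
        raise ValueError("all PC series degenerate")
    return float(np.mean(rs))


def geometry_bootstrap(
    early: np.ndarray,
    late: np.ndarray,
    bin_centers: np.ndarray,
    subset_fraction: float = 0.8,
    n_iterations: int = 20,
    n_components: int = N_COMPONENTS,
    rng: np.random.Generator | None = None,
) -> list[GeometryMetrics]:
    """Full geometry pipeline per bootstrap iteration."""
    rng = np.random.default_rng() if rng is None else rng
    out = []
    for pair in build_state_trajectories(
        early, late, bin_centers, subset_fraction, n_iterations, rng
    ):
        e_pc, l_pc, var = pca_embed(pair, n_components)
        sim = similarity(e_pc, l_pc)
        out.append(distance_metrics(e_pc, l_pc, bin_centers, var, sim))
    return out
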