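"""HMM decoder: features, k-means init, Baum-Welch, Viterbi, protocol."""

import numpy as np
import pytest

from setshift import (
    GeneratorConfig,
    balance_trials,
    fit_baum_welch,
    forward_backward,
    generate_session,
    kmeans_init,
    label_states,
    viterbi,
)
from setshift.hmm import (
    HmmModel,
    decode_bootstrap,
    init_from_assignment,
    summarize_decode,
    trial_features,
    _map_states,
)


def _random_model(rng, k=2, d=2):
    initial = rng.dirichlet(np.ones(k))
    transition = rng.dirichlet(np.ones(k), size=k)
    means = rng.normal(0, 2, size=(k, d))
    variances = rng.uniform(0.3, 2.0, size=(k, d))
    return HmmModel(initial=initial, transition=transition, means=means, variances=variances)


def _sample(model, T, rng):
    k, d = model.means.shape
    states = np.zeros(T, dtype=int)
    states[0] = rng.choice(k, p=model.initial)
    for t in range(1, T):
        states[t] = rng.choice(k, p=model.transition[states[t - 1]])
    X = model.means[states] + rng.normal(size=(T, d)) * np.sqrt(model.variances[states])
    return X, states


def _brute_force_path(model, X):
    from itertools import product

    logB = -0.5 * (
        np.log(2 * np.pi * model.variances[None])
        + (X[:, None, :] - model.means[None]) ** 2 / model.variances[None]
    ).sum(axis=2)
    best, best_lp = None, -np.inf
    T = X.shape[0]
    for path in product(range(model.initial.size), repeat=T):
        lp = np.log(model.initial[path[0]]) + logB[0, path[0]]
        for t in range(1, T):
            lp += np.log(model.transition[path[t - 1], path[t]]) + logB[t, path[t]]
        if lp > best_lp:
            best_lp, best = lp, path
    return np.array(best)


def test_trial_features_projection_identity(rng):
    X = rng.normal(size=(20, 8))
    feats = trial_features(X, 3)
    xc = X - X.mean(0)
    # reconstruct via the same SVD basis: projection energy bounded by total
    assert feats.shape == (20, 3)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    np.testing.assert_allclose(np.abs(feats), np.abs(xc @ vt[:3].T), atol=1e-9)


def test_trial_features_rejects_excess_components(rng):
    with pytest.raises(ValueError):
        trial_features(rng.normal(size=(10, 2)), 3)
    with pytest.raises(ValueError):
        trial_features(np.ones((10, 4)), 2)  # constant -> degenerate


def test_kmeans_separates_planted_clusters(rng):
    a = rng.normal(0, 0.2, size=(15, 2))
    b = rng.normal(5, 0.2, size=(12, 2))
    X = np.vstack([a, b])
    labels = kmeans_init(X, 2, rng)
    assert len(set(labels[:15])) == 1 and len(set(labels[15:])) == 1
    assert labels[0] != labels[-1]


def test_kmeans_duplicate_points_zero_wcss(rng):
    X = np.vstack([np.zeros((5, 2)), np.ones((5, 2))])
    labels = kmeans_init(X, 2, rng)
    from setshift.hmm import _lloyd

    # best assignment found has zero within-cluster sum of squares
    groups = [X[labels == j] for j in range(2)]
    wcss = sum(((g - g.mean(0)) ** 2).sum() for g in groups)
    assert wcss == pytest.approx(0.0, abs=1e-12)


def test_forward_backward_posteriors_normalize(rng):
    for _ in range(10):
        model = _random_model(rng)
        X, _ = _sample(model, 40, rng)
        log_gamma, _, loglik = forward_backward(model, X)
        np.testing.assert_allclose(np.exp(log_gamma).sum(axis=1), 1.0, atol=1e-9)
        assert np.isfinite(loglik)


def test_loglik_matches_hmmlearn(rng):
    """Forward log-likelihood agrees with hmmlearn for identical params."""
    hmmlearn = pytest.importorskip("hmmlearn.hmm")
    for _ in range(5):
        model = _random_model(rng)
        X, _ = _sample(model, 60, rng)
        _, _, loglik = forward_backward(model, X)
        ref = hmmlearn.GaussianHMM(n_components=2, covariance_type="diag", init_params="")
        ref.startprob_ = model.initial
        ref.transmat_ = model.transition
        ref.means_ = model.means
        ref.covars_ = model.variances
        assert loglik == pytest.approx(ref.score(X), abs=1e-8)


def test_baum_welch_monotone_loglik(rng):
    for _ in range(25):
        model = _random_model(rng)
        X, _ = _sample(model, 30, rng)
        labels = kmeans_init(X, 2, rng)
        fitted = fit_baum_welch(X, init_from_assignment(X, labels))
        trace = np.array(fitted.log_likelihood_trace)
        assert np.all(np.diff(trace) >= -1e-6)
        assert np.allclose(fitted.transition.sum(axis=1), 1.0, atol=1e-9)


def test_baum_welch_parameter_recovery(rng):
    """Self-transition 0.9 and means +-2 recovered from T=500 samples."""
    true = HmmModel(
        initial=np.array([0.5, 0.5]),
        transition=np.array([[0.9, 0.1], [0.1, 0.9]]),
        means=np.array([[-2.0], [2.0]]),
        variances=np.ones((2, 1)),
    )
    X, _ = _sample(true, 500, rng)
    labels = kmeans_init(X, 2, rng)
    fitted = fit_baum_welch(X, init_from_assignment(X, labels))
    order = np.argsort(fitted.means[:, 0])
    means = fitted.means[order, 0]
    assert abs(means[0] + 2.0) < 0.2 and abs(means[1] - 2.0) < 0.2
    self_trans = np.diag(fitted.transition[order][:, order])
    assert np.abs(self_trans - 0.9).max() < 0.05


def test_viterbi_matches_exhaustive_enumeration(rng):
    for _ in range(10):
        model = _random_model(rng)
        T = int(rng.integers(3, 9))
        X, _ = _sample(model, T, rng)
        np.testing.assert_array_equal(viterbi(model, X), _brute_force_path(model, X))


def test_viterbi_tie_breaks_to_state_zero():
    model = HmmModel(
        initial=np.array([0.5, 0.5]),
        transition=np.full((2, 2), 0.5),
        means=np.zeros((2, 1)),
        variances=np.ones((2, 1)),
    )
    X = np.zeros((6, 1))
    np.testing.assert_array_equal(viterbi(model, X), np.zeros(6, dtype=int))


def test_viterbi_strong_separation_matches_nearest_mean(rng):
    model = HmmModel(
        initial=np.array([0.5, 0.5]),
        transition=np.full((2, 2), 0.5),
        means=np.array([[-5.0], [5.0]]),
        variances=np.ones((2, 1)),
    )
    X = rng.choice([-5.0, 5.0], size=(50, 1)) + rng.normal(0, 0.1, size=(50, 1))
    path = viterbi(model, X)
    np.testing.assert_array_equal(path, (X[:, 0] > 0).astype(int))


def test_balance_trials_identity_and_errors(rng):
    np.testing.assert_array_equal(balance_trials(31, 31, rng), np.arange(31))
    with pytest.raises(ValueError):
        balance_trials(20, 10, rng)
    with pytest.raises(ValueError):
        balance_trials(1, 31, rng)


def test_balance_trials_preserves_single_transition(rng):
    states = np.array([0] * 12 + [1] * 8)
    for _ in range(200):
        idx = balance_trials(20, 31, rng)
        assert idx.size == 31
        seq = states[idx]
        assert (np.diff(seq) != 0).sum() == 1  # still one early->late switch


def test_map_states_label_swap_symmetry(rng):
    behav = np.array([0] * 20 + [1] * 11)
    path = (np.arange(31) >= 15).astype(int)
    train = np.ones(31, bool)
    m1 = _map_states(path, behav, train)
    m2 = _map_states(1 - path, behav, train)
    np.testing.assert_array_equal(m1[path], m2[1 - path])


def test_decode_bootstrap_recovers_strong_switch(small_session):
    lab = label_states(small_session.trials)
    df = decode_bootstrap(
        small_session, lab, n_iterations=60, rng=np.random.default_rng(2)
    )
    s = summarize_decode(df)
    assert s["accuracy_all"]["median"] >= 0.8
    # neural switch leads behavior by the configured 3 trials
    assert -4.5 <= s["delta_switch"]["median"] <= -1.5


def test_decode_bootstrap_null_features_near_chance():
    """With no tuned neurons the held-out accuracy centers near the
    majority-class rate of the behavioral labels."""
    cfg = GeneratorConfig.preset(
        "control",
        n_neurons=40,
        tuning_fractions=(0.0, 0.0, 0.0),
        event_gain=0.0,
        switch_trial=("fixed", 12),
    )
    session = generate_session(cfg, 31)
    lab = label_states(session.trials)
    df = decode_bootstrap(session, lab, n_iterations=80, rng=np.random.default_rng(4))
    s = summarize_decode(df)
    majority = max(lab.late_mask.mean(), 1 - lab.late_mask.mean())
    assert abs(s["accuracy_heldout"]["mean"] - majority) < 0.2


def test_decode_noise_monotonicity():
    """State-decoding accuracy decreases with the generator noise level."""
    from scipy.stats import spearmanr

    levels = [1.0, 2.0, 4.0, 8.0, 16.0]
    accs = []
    for noise in levels:
        vals = []
        for seed in range(3):
            cfg = GeneratorConfig.preset(
                "control", n_neurons=40, noise_sd=noise, switch_trial=("fixed", 12)
            )
            session = generate_session(cfg, 50 + seed)
            lab = label_states(session.trials)
            df = decode_bootstrap(
                session, lab, n_iterations=40, rng=np.random.default_rng(seed)
            )
            vals.append(summarize_decode(df)["accuracy_all"]["mean"])
        accs.append(np.mean(vals))
    rho = spearmanr(levels, accs).statistic
    assert rho < -0.8
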