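"""Generator: outcome sequences, traces, cohort structure, serialization."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from setshift import (
    GeneratorConfig,
    calcium_kernel,
    generate_cohort,
    generate_outcome_sequence,
    generate_session,
    generate_traces,
    label_states,
    read_session,
    write_session,
)
from setshift.synth import CRITERION_RUN, _longest_run


def test_config_validation_rejects_degenerate_values():
    with pytest.raises(ValueError):
        GeneratorConfig(p_correct_early=1.0)
    with pytest.raises(ValueError):
        GeneratorConfig(rise_tau=0.5, decay_tau=0.1)
    with pytest.raises(ValueError):
        GeneratorConfig(inter_choice_interval=8.0)
    with pytest.raises(ValueError):
        GeneratorConfig(tuning_fractions=(0.1, 1.2, 0.1))
    with pytest.raises(ValueError):
        GeneratorConfig(switch_trial=("bogus", 3))


def test_group_preset_directions():
    c = GeneratorConfig.preset("control")
    t = GeneratorConfig.preset("test")
    assert all(tf >= cf for tf, cf in zip(t.tuning_fractions, c.tuning_fractions))
    assert t.separation_scale < c.separation_scale
    assert t.mixed_tuning_rate > c.mixed_tuning_rate


def test_fixed_switch_forces_terminal_run():
    cfg = GeneratorConfig(switch_trial=("fixed", 5))
    trials = generate_outcome_sequence(cfg, np.random.default_rng(3))
    outcomes = (trials["outcome"] == "correct").to_numpy()
    assert outcomes[4:].all()  # trials 5..end all correct
    assert outcomes.size == 4 + CRITERION_RUN
    lab = label_states(trials)
    assert lab.switch_point == 5


def test_outcome_sequence_is_deterministic():
    cfg = GeneratorConfig()
    a = generate_outcome_sequence(cfg, np.random.default_rng(5))
    b = generate_outcome_sequence(cfg, np.random.default_rng(5))
    pd.testing.assert_frame_equal(a, b)


def test_trial_table_invariants():
    cfg = GeneratorConfig()
    for seed in range(20):
        trials = generate_outcome_sequence(cfg, np.random.default_rng(seed))
        outcomes = (trials["outcome"] == "correct").to_numpy()
        assert outcomes[-CRITERION_RUN:].all()
        assert trials["correct_rejection"].sum() >= 2
        gaps = np.diff(trials["choice_time_s"].to_numpy())
        assert (gaps >= 10.0).all()  # +-5 s windows never overlap


def test_early_accuracy_matches_rejection_aware_oracle():
    """Mean early accuracy equals an independent oracle that replicates the
    generator's admissibility rules (no >=6 correct run, final trial an
    error) on raw Bernoulli draws."""
    cfg = GeneratorConfig(p_correct_early=0.5, n_trials_nominal=14)
    rng = np.random.default_rng(42)
    accs = []
    for _ in range(4000):
        trials = generate_outcome_sequence(cfg, rng)
        lab = label_states(trials)
        early = (trials["outcome"][: lab.switch_point - 1] == "correct").to_numpy()
        accs.append(early.mean())
    observed = np.mean(accs)

    # oracle: same geometric early-length draw, raw Bernoulli, same rejections
    orng = np.random.default_rng(2024)
    oracle_accs = []
    mean_excess = cfg.n_trials_nominal - CRITERION_RUN - cfg.min_early_trials
    while len(oracle_accs) < 4000:
        n_early = cfg.min_early_trials + orng.geometric(1.0 / max(1, mean_excess))
        n_early = min(n_early, 25)
        out = orng.random(n_early) < 0.5
        if out[-1] or _longest_run(out) >= CRITERION_RUN:
            continue
        oracle_accs.append(out.mean())
    expected = np.mean(oracle_accs)
    se = np.std(oracle_accs, ddof=1) / np.sqrt(len(oracle_accs))
    assert abs(observed - expected) < 3 * np.hypot(se, np.std(accs, ddof=1) / np.sqrt(len(accs)))


def test_kernel_impulse_shape():
    """Unit impulse through the peak-normalized kernel peaks after onset and
    decays below 5% of peak within 2 s (closed-form double exponential)."""
    dt = 0.05
    h = calcium_kernel(0.1, 0.5, dt, normalize="peak")
    assert h.max() == pytest.approx(1.0)
    peak_idx = int(h.argmax())
    assert peak_idx > 0
    t = np.arange(h.size) * dt
    # analytic check of the peak location: t* = ln(d/r) * rd/(d-r)
    t_star = np.log(0.5 / 0.1) * (0.1 * 0.5) / (0.5 - 0.1)
    assert abs(t[peak_idx] - t_star) <= dt
    after_2s = h[t >= 2.0]
    assert (after_2s < 0.05).all()


def test_area_kernel_preserves_boxcar_plateau():
    dt = 0.05
    h = calcium_kernel(0.1, 0.5, dt, normalize="area")
    box = np.zeros(400)
    box[100:200] = 1.7
    out = np.convolve(box, h)[:400]
    assert out[150:200].max() == pytest.approx(1.7, rel=0.02)


def test_noiseless_switch_neuron_separates_states():
    cfg = GeneratorConfig(
        n_neurons=1,
        noise_sd=1e-9,
        tuning_fractions=(0.0, 0.0, 1.0),
        event_gain=0.0,
        shared_gain_sd=0.0,
        neural_lead_trials=0,
        switch_trial=("fixed", 8),
    )
    rng = np.random.default_rng(0)
    trials = generate_outcome_sequence(cfg, rng)
    session = generate_traces(cfg, trials, rng)
    lab = label_states(trials)
    fr = cfg.frame_rate
    means = []
    for c in trials["choice_time_s"]:
        stop = int(round(c * fr))
        means.append(session.traces[0, stop - 100 : stop].mean())
    means = np.asarray(means)
    assert means[lab.late_mask].min() > means[lab.early_mask].max()


def test_untuned_neurons_are_exchangeable(control_session, control_labeling):
    """Pre-choice means of fully untuned neurons carry no state information:
    permutation p-values are uniform (flag rate ~ alpha, mean p ~ 0.5)."""
    from setshift.hmm import prechoice_matrix
    from setshift.tuning import permutation_auc_pvalues

    m = prechoice_matrix(control_session)
    untuned = (control_session.truth["tuned_variables"] == "").to_numpy()
    rng = np.random.default_rng(7)
    _, p = permutation_auc_pvalues(
        m[:, untuned], control_labeling.late_mask, 500, rng
    )
    assert 0.2 < p.mean() < 0.8
    assert (p < 0.05).mean() < 0.25  # ~alpha at ~70 neurons


def test_cohort_structure_and_determinism():
    cc = GeneratorConfig.preset("control", n_neurons=10)
    ct = GeneratorConfig.preset("test", n_neurons=10)
    cohort = generate_cohort(cc, ct, n_per_group=4, seed=17)
    assert len(cohort) == 8
    groups = [s.meta["group"] for s in cohort]
    assert groups.count("control") == 4 and groups.count("test") == 4
    cohort2 = generate_cohort(cc, ct, n_per_group=4, seed=17)
    for a, b in zip(cohort, cohort2):
        np.testing.assert_array_equal(a.traces, b.traces)
        pd.testing.assert_frame_equal(a.trials, b.trials)


def test_cohort_truth_fraction_matches_configured():
    """Pooled ground-truth switch-tuned fraction within the binomial 95% CI
    of the configured probability (marginal draw, before mixed promotion)."""
    cc = GeneratorConfig.preset("control", n_neurons=150, mixed_tuning_rate=0.0)
    ct = GeneratorConfig.preset("test", n_neurons=150, mixed_tuning_rate=0.0)
    cohort = generate_cohort(cc, ct, n_per_group=4, seed=5)
    for group, p0 in (("control", 0.17), ("test", 0.25)):
        truth = pd.concat(
            [s.truth for s in cohort if s.meta["group"] == group], ignore_index=True
        )
        frac = truth["tuned_variables"].str.contains("switch").mean()
        n = len(truth)
        half = 1.96 * np.sqrt(p0 * (1 - p0) / n)
        assert abs(frac - p0) < half + 1e-12


def test_sample_cap_guards_memory():
    cfg = GeneratorConfig(max_samples=100)
    rng = np.random.default_rng(0)
    trials = generate_outcome_sequence(cfg, rng)
    with pytest.raises(ValueError, match="cap"):
        generate_traces(cfg, trials, rng)


def test_session_roundtrip(tmp_path, small_session):
    write_session(small_session, tmp_path / "sess")
    back = read_session(tmp_path / "sess")
    assert np.abs(back.traces - small_session.traces).max() < 1e-6
    assert np.abs(back.sample_times - small_session.sample_times).max() < 1e-9
    pd.testing.assert_frame_equal(
        back.trials.assign(stage=back.trials["stage"].astype(str)),
        small_session.trials,
        check_exact=False,
        atol=1e-9,
    )
    assert back.meta["group"] == small_session.meta["group"]
    assert (
        back.truth["tuned_variables"].tolist()
        == small_session.truth["tuned_variables"].tolist()
    )


def test_session_meta_echoes_config(small_session):
    cfg_echo = small_session.meta["config"]
    assert cfg_echo["n_neurons"] == 40
    assert dataclasses.asdict(GeneratorConfig(**{
        **{k: tuple(v) if isinstance(v, list) else v for k, v in cfg_echo.items()}
    })) == {**cfg_echo, "tuning_fractions": tuple(cfg_echo["tuning_fractions"]),
            "switch_trial": tuple(cfg_echo["switch_trial"])}
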