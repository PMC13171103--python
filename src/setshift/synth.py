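"""Synthetic set-shifting sessions: behavior plus calcium traces.

A session emulates one extra-dimensional-shift (EDS) recording: a trial
sequence with an early trial-and-error block followed by a terminal run of
consecutive correct trials (the behavioral criterion is six consecutive
correct digs with at least two correct rejections), and a fluorescence
matrix in which subsets of neurons carry pre-choice drives locked to
choice outcome, trial history, or the early/late switch state.

The two group presets, ``control`` and ``test``, encode the qualitative
group effect the analyses are designed to detect: the test group has
larger tuned fractions and broader (multi-variable) tuning, but noisier
shared response gain, less state-dependent remapping, and a longer lag
between the neural and behavioral state transitions, so population
decoders perform worse on test sessions even though more neurons pass the
single-cell responsiveness test.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

VARIABLES = ("choice", "history", "switch")

#: Behavioral criterion: consecutive correct digs / minimum correct rejections.
CRITERION_RUN = 6
CRITERION_REJECTIONS = 2


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic session generator.

    Amplitudes are in z-units of the pre-z-scoring trace; ``noise_sd`` is the
    i.i.d. per-sample baseline noise.  The tuned-drive amplitude of a
    switch neuron is ``effect_size * separation_scale`` so that
    ``separation_scale`` acts as a multiplier on the early-vs-late
    population mean shift.
    """

    n_neurons: int = 100
    frame_rate: float = 20.0
    n_trials_nominal: int = 18
    inter_choice_interval: float = 14.0
    p_correct_early: float = 0.5
    #: ("fixed", k) pins the first late trial at k; ("geometric", p) draws the
    #: early-block length as min_early_trials + Geometric(p).  None derives a
    #: geometric p so the mean session length matches n_trials_nominal.
    switch_trial: tuple | None = None
    #: Minimum early-block length: the rule change is uncued, so some
    #: trial-and-error trials always precede the terminal correct run.
    min_early_trials: int = 5
    #: (choice, history, switch) marginal tuning probabilities.
    tuning_fractions: tuple[float, float, float] = (0.10, 0.06, 0.17)
    #: Probability that a singly tuned neuron gains one extra variable.
    mixed_tuning_rate: float = 0.10
    effect_size: float = 0.45
    separation_scale: float = 2.2
    #: Trials by which the neural state transition precedes the behavioral
    #: switch point (rule acquisition shows in population activity before
    #: performance reaches criterion).
    neural_lead_trials: int = 3
    #: Fraction of the full switch drive carried by the lead trials (rule
    #: acquisition is gradual: the state signal is present but not yet at
    #: its rule-following amplitude before the behavioral switch).
    lead_drive_fraction: float = 0.75
    #: SD of the shared per-trial gain fluctuation multiplying the phasic
    #: choice and history drives (the tonic switch-state drive is not
    #: modulated).  Being common across neurons it acts along the
    #: population coding axes, so it limits population decodability in a
    #: way that averaging over neurons cannot remove, while leaving
    #: single-neuron discriminability comparatively intact.
    shared_gain_sd: float = 0.15
    rise_tau: float = 0.1
    decay_tau: float = 0.5
    noise_sd: float = 2.0
    #: Per-motif loading SD of the shared peri-choice population response;
    #: gives trajectories their low-rank structure.
    event_gain: float = 1.4
    #: Correlation between the early-state and late-state motif loadings of
    #: switch-tuned neurons.  Low values mean the population response
    #: remaps across the switch (distinct state trajectories); values near
    #: 1 mean the response fails to reorganize, leaving the two state
    #: vectors similar.
    state_motif_corr: float = 0.0
    p_correct_rejection: float = 0.5
    group: str = "control"
    jitter: float = 1.0
    max_samples: int = 2_000_000

    def __post_init__(self):
        probs = {
            "p_correct_early": self.p_correct_early,
            "mixed_tuning_rate": self.mixed_tuning_rate,
            "p_correct_rejection": self.p_correct_rejection,
            **{f"tuning_fraction_{v}": f for v, f in zip(VARIABLES, self.tuning_fractions)},
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.p_correct_early >= 1.0:
            raise ValueError(
                "p_correct_early=1 makes early and late states indistinguishable"
            )
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ValueError("kernel time constants must be positive")
        if self.rise_tau >= self.decay_tau:
            raise ValueError("rise_tau must be smaller than decay_tau")
        if self.inter_choice_interval < 12.0:
            raise ValueError(
                "inter_choice_interval below 12 s lets +-5 s choice windows overlap"
            )
        if self.n_neurons < 1:
            raise ValueError("need at least one neuron")
        if self.neural_lead_trials < 0:
            raise ValueError("neural_lead_trials must be non-negative")
        if self.shared_gain_sd < 0:
            raise ValueError("shared_gain_sd must be non-negative")
        if not -1.0 <= self.state_motif_corr <= 1.0:
            raise ValueError("state_motif_corr must be in [-1, 1]")
        if not 0.0 <= self.lead_drive_fraction <= 1.0:
            raise ValueError("lead_drive_fraction must be in [0, 1]")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.switch_trial is not None:
            kind, value = self.switch_trial
            if kind == "fixed":
                if int(value) < 1:
                    raise ValueError("fixed switch index must be >= 1")
            elif kind == "geometric":
                if not 0.0 < value <= 1.0:
                    raise ValueError("geometric switch parameter must be in (0, 1]")
            else:
                raise ValueError(f"unknown switch_trial kind {kind!r}")

    @classmethod
    def preset(cls, group: str, **overrides) -> "GeneratorConfig":
        """Default configurations for the two experimental groups."""
        if group == "control":
            base = dict(group="control")
        elif group == "test":
            base = dict(
                group="test",
                n_trials_nominal=26,
                min_early_trials=12,
                tuning_fractions=(0.17, 0.13, 0.25),
                mixed_tuning_rate=0.22,
                effect_size=0.55,
                separation_scale=2.0,
                neural_lead_trials=7,
                shared_gain_sd=0.85,
                state_motif_corr=0.9,
            )
        else:
            raise ValueError(f"unknown group {group!r}")
        base.update(overrides)
        return cls(**base)


@dataclass
class Session:
    """One recording: traces, sample times, trial table, metadata, truth."""

    traces: np.ndarray  # [n_neurons, n_samples]
    sample_times: np.ndarray  # seconds
    trials: pd.DataFrame
    meta: dict
    truth: pd.DataFrame | None = None

    @property
    def n_neurons(self) -> int:
        return self.traces.shape[0]

    @property
    def frame_rate(self) -> float:
        return float(self.meta["frame_rate_hz"])

    def validate(self) -> None:
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("non-finite trace values")
        ct = self.trials["choice_time_s"].to_numpy()
        if not np.all(np.diff(ct) > 0):
            raise ValueError("choice times not strictly increasing")
        t0, t1 = self.sample_times[0], self.sample_times[-1]
        if ct[0] < t0 + 5.0 or ct[-1] > t1 - 5.0:
            raise ValueError("choice window extends beyond the recording")


def _draw_early_length(config: GeneratorConfig, rng: np.random.Generator) -> int:
    spec = config.switch_trial
    if spec is None:
        mean_excess = max(
            1, config.n_trials_nominal - CRITERION_RUN - config.min_early_trials
        )
        spec = ("geometric", 1.0 / mean_excess)
    kind, value = spec
    if kind == "fixed":
        return int(value) - 1
    return config.min_early_trials + int(rng.geometric(value))


def _sample_early_block(
    n_early: int, p_correct: float, rng: np.random.Generator, max_tries: int = 1000
) -> np.ndarray:
    """Early outcomes, resampled until observable.

    Two rejection rules: no correct run of CRITERION_RUN or longer (the real
    session would already have ended), and the final early trial is an error
    (otherwise the terminal correct run would absorb the end of the early
    block and the planted switch would not be identifiable from behavior).
    """
    if n_early == 0:
        return np.zeros(0, dtype=bool)
    for _ in range(max_tries):
        out = rng.random(n_early) < p_correct
        if n_early >= 1 and out[-1]:
            continue
        if _longest_run(out) >= CRITERION_RUN:
            continue
        return out
    raise RuntimeError("could not sample an admissible early block")


def _longest_run(correct: np.ndarray) -> int:
    best = run = 0
    for c in correct:
        run = run + 1 if c else 0
        best = max(best, run)
    return best


def generate_outcome_sequence(
    config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw one trial table: outcomes, correct rejections, choice times."""
    n_early = min(_draw_early_length(config, rng), 25)
    early = _sample_early_block(n_early, config.p_correct_early, rng)
    outcomes = np.concatenate([early, np.ones(CRITERION_RUN, dtype=bool)])
    n_trials = outcomes.size

    rejection = np.zeros(n_trials, dtype=bool)
    correct_idx = np.flatnonzero(outcomes)
    rejection[correct_idx] = rng.random(correct_idx.size) < config.p_correct_rejection
    if rejection.sum() < CRITERION_REJECTIONS:
        rejection[correct_idx[-CRITERION_REJECTIONS:]] = True

    gaps = config.inter_choice_interval + rng.uniform(
        -config.jitter, config.jitter, size=n_trials
    )
    choice_times = np.cumsum(gaps)

    return pd.DataFrame(
        {
            "trial_id": np.arange(1, n_trials + 1),
            "stage": "EDS",
            "choice_time_s": choice_times,
            "outcome": np.where(outcomes, "correct", "incorrect"),
            "correct_rejection": rejection,
        }
    )


def calcium_kernel(
    rise_tau: float, decay_tau: float, dt: float, normalize: str = "area"
) -> np.ndarray:
    """Difference-of-exponentials kernel sampled at dt.

    ``normalize="peak"`` scales the maximum to 1 (impulse-response form);
    ``normalize="area"`` scales the discrete sum to 1 so that convolving a
    boxcar drive preserves its plateau amplitude in z-units.
    """
    t = np.arange(0.0, 6.0 * decay_tau, dt)
    h = np.exp(-t / decay_tau) - np.exp(-t / rise_tau)
    if normalize == "peak":
        return h / h.max()
    if normalize == "area":
        return h / h.sum()
    raise ValueError(f"unknown normalization {normalize!r}")


def _assign_tuning(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Boolean [n_neurons, 3] tuned-variable matrix with mixed-tuning coupling."""
    fr = np.asarray(config.tuning_fractions)
    tuned = rng.random((config.n_neurons, 3)) < fr[None, :]
    single = tuned.sum(axis=1) == 1
    promote = single & (rng.random(config.n_neurons) < config.mixed_tuning_rate)
    for i in np.flatnonzero(promote):
        others = np.flatnonzero(~tuned[i])
        w = fr[others]
        w = w / w.sum() if w.sum() > 0 else np.full(others.size, 1 / others.size)
        tuned[i, rng.choice(others, p=w)] = True
    return tuned


def _event_motifs(window_t: np.ndarray) -> np.ndarray:
    """Three smooth peri-choice temporal motifs on the (-5, +5) s grid."""
    centers = (-3.0, -1.0, 1.5)
    widths = (1.2, 0.8, 1.5)
    return np.stack(
        [np.exp(-0.5 * ((window_t - c) / w) ** 2) for c, w in zip(centers, widths)]
    )


def generate_traces(
    config: GeneratorConfig, trials: pd.DataFrame, rng: np.random.Generator
) -> Session:
    """Simulate the fluorescence matrix for a drawn trial table.

    Each neuron is baseline i.i.d. Gaussian noise plus, per tuned variable, a
    boxcar drive over the 5 s before each choice on which the variable's
    preferred condition holds, convolved with the calcium kernel.  A shared
    peri-choice response (random per-neuron loadings on three temporal
    motifs) gives the population its event-locked low-rank structure;
    switch-tuned neurons remap their loadings across the neural state
    transition by ``state_motif_corr``.  Phasic drives carry a shared
    per-trial gain fluctuation; the tonic switch drive does not.
    """
    fr = config.frame_rate
    dt = 1.0 / fr
    choice_times = trials["choice_time_s"].to_numpy()
    duration = choice_times[-1] + 6.0
    n_samples = int(round(duration * fr))
    if n_samples > config.max_samples:
        raise ValueError(
            f"session would need {n_samples} samples (cap {config.max_samples})"
        )
    times = np.arange(n_samples) * dt

    tuned = _assign_tuning(config, rng)
    signs = rng.choice([-1.0, 1.0], size=(config.n_neurons, 3))
    loadings_early = rng.normal(0.0, config.event_gain, size=(config.n_neurons, 3))
    # Switch-tuned neurons remap their peri-choice response across the
    # neural state transition; everyone else keeps the same loadings.
    rho = config.state_motif_corr
    fresh = rng.normal(0.0, config.event_gain, size=(config.n_neurons, 3))
    loadings_late = loadings_early.copy()
    sw = tuned[:, 2]
    loadings_late[sw] = rho * loadings_early[sw] + np.sqrt(1 - rho**2) * fresh[sw]

    outcomes = (trials["outcome"] == "correct").to_numpy()
    n_trials = outcomes.size
    # Late state: maximal terminal run of correct trials (by construction the
    # last CRITERION_RUN trials; recomputed here from the outcomes).
    run = 0
    for o in outcomes[::-1]:
        if not o:
            break
        run += 1
    late = np.zeros(n_trials, dtype=bool)
    late[n_trials - run :] = True
    # Neural late state leads the behavioral switch point by a few trials
    # (rule acquisition is visible in population activity before performance
    # reaches criterion); always leaves at least one neural-early trial.
    switch_point = n_trials - run + 1
    lead = min(config.neural_lead_trials, max(switch_point - 2, 0))
    neural_late = np.zeros(n_trials, dtype=bool)
    neural_late[switch_point - 1 - lead :] = True

    conditions = np.zeros((3, n_trials))
    conditions[0] = outcomes.astype(float)  # choice: upcoming outcome correct
    conditions[1, 1:] = outcomes[:-1].astype(float)  # history: previous correct
    conditions[1, 0] = np.nan  # first trial carries no history drive
    conditions[2] = neural_late.astype(float)  # switch: (neural) late state
    conditions[2, (switch_point - 1 - lead) : (switch_point - 1)] = (
        config.lead_drive_fraction
    )

    amps = np.array(
        [
            config.effect_size,
            config.effect_size,
            config.effect_size * config.separation_scale,
        ]
    )

    # Shared multiplicative gain fluctuations, one independent stream per
    # phasic variable (choice, history); the tonic switch drive is stable.
    gain = 1.0 + rng.normal(0.0, config.shared_gain_sd, size=(2, n_trials))

    drive = np.zeros((config.n_neurons, n_samples))
    window_len = int(round(5.0 * fr))
    for t_idx, c in enumerate(choice_times):
        stop = int(round(c * fr))
        start = stop - window_len
        for v in range(3):
            cond = conditions[v, t_idx]
            if not np.isfinite(cond) or cond == 0.0:
                continue
            rows = np.flatnonzero(tuned[:, v])
            if rows.size:
                amp_t = cond * amps[v] * (gain[v, t_idx] if v < 2 else 1.0)
                drive[rows, start:stop] += (signs[rows, v] * amp_t)[:, None]

    # Shared peri-choice response; switch-tuned loadings depend on the
    # neural state of the trial.
    half = int(round(5.0 * fr))
    window_t = (np.arange(2 * half) - half) * dt
    motifs = _event_motifs(window_t)  # [3, 2*half]
    shared = np.zeros((config.n_neurons, n_samples))
    motif_early = loadings_early @ motifs  # [n_neurons, 2*half]
    motif_late = loadings_late @ motifs
    for t_idx, c in enumerate(choice_times):
        stop = int(round(c * fr))
        sl = slice(stop - half, stop + half)
        width = shared[:, sl].shape[1]
        block = motif_late if neural_late[t_idx] else motif_early
        shared[:, sl] += block[:, :width]

    kernel = calcium_kernel(config.rise_tau, config.decay_tau, dt, normalize="area")
    signal = drive + shared
    for i in range(config.n_neurons):
        signal[i] = np.convolve(signal[i], kernel)[:n_samples]

    traces = signal + rng.normal(0.0, config.noise_sd, size=signal.shape)

    truth = pd.DataFrame(
        {
            "neuron_id": np.arange(config.n_neurons),
            "tuned_variables": [
                "|".join(v for v, t in zip(VARIABLES, row) if t) for row in tuned
            ],
        }
    )
    meta = {
        "mouse_id": "m0",
        "group": config.group,
        "frame_rate_hz": fr,
        "seed": None,
        "config": dataclasses.asdict(config),
    }
    session = Session(
        traces=traces, sample_times=times, trials=trials, meta=meta, truth=truth
    )
    session.validate()
    return session


def generate_session(config: GeneratorConfig, seed) -> Session:
    """Convenience wrapper: one seeded session (behavior + traces)."""
    rng = np.random.default_rng(seed)
    trials = generate_outcome_sequence(config, rng)
    session = generate_traces(config, trials, rng)
    session.meta["seed"] = (
        int(seed) if np.isscalar(seed) and not isinstance(seed, np.random.SeedSequence)
        else None
    )
    return session


def generate_cohort(
    config_control: GeneratorConfig,
    config_test: GeneratorConfig,
    n_per_group: int,
    seed: int,
) -> list[Session]:
    """Deterministic cohort: n_per_group sessions per group from one master seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_per_group)
    sessions = []
    for g, config in (("c", config_control), ("t", config_test)):
        for i in range(n_per_group):
            child = children.pop(0)
            s = generate_session(config, child)
            s.meta["mouse_id"] = f"{g}{i + 1}"
            s.meta["seed"] = seed
            sessions.append(s)
    return sessions


# ---------------------------------------------------------------------------
# Session directory layout: traces.csv / trials.csv / meta.json / truth.csv

_FLOAT_FMT = "%.9g"


def write_session(session: Session, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traces = pd.DataFrame(
        session.traces.T,
        columns=[f"n{i}" for i in range(session.n_neurons)],
    )
    traces.insert(0, "time_s", session.sample_times)
    traces.to_csv(out / "traces.csv", index=False, float_format=_FLOAT_FMT)
    session.trials.to_csv(out / "trials.csv", index=False, float_format=_FLOAT_FMT)
    with open(out / "meta.json", "w") as fh:
        json.dump(session.meta, fh, indent=1, sort_keys=True)
    if session.truth is not None:
        session.truth.to_csv(out / "truth.csv", index=False)
    return out


def read_session(in_dir: str | Path) -> Session:
    src = Path(in_dir)
    traces = pd.read_csv(src / "traces.csv")
    times = traces.pop("time_s").to_numpy()
    trials = pd.read_csv(src / "trials.csv")
    with open(src / "meta.json") as fh:
        meta = json.load(fh)
    truth_path = src / "truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else None
    if truth is not None:
        truth["tuned_variables"] = truth["tuned_variables"].fillna("")
    return Session(
        traces=traces.to_numpy().T,
        sample_times=times,
        trials=trials,
        meta=meta,
        truth=truth,
    )
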