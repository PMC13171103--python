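"""Shared preprocessing primitives.

Per-neuron z-scoring across the whole session, non-overlapping temporal
binning, choice-aligned window extraction, and threshold-based detection of
calcium transients with frequency/amplitude/duration summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import Session


@dataclass
class FluorescenceMatrix:
    """values [n_neurons, n_samples] on a uniform clock."""

    values: np.ndarray
    sample_times: np.ndarray
    units: str = "raw"  # or "zscored"

    def __post_init__(self):
        dt = np.diff(self.sample_times)
        if dt.size and (np.any(dt <= 0) or np.ptp(dt) > 1e-9):
            raise ValueError("sample_times must be strictly increasing and uniform")

    @property
    def dt(self) -> float:
        return float(self.sample_times[1] - self.sample_times[0])

    @classmethod
    def from_session(cls, session: Session) -> "FluorescenceMatrix":
        return cls(values=session.traces, sample_times=session.sample_times)


@dataclass
class AlignedTensor:
    """Choice-aligned activity: values [n_trials, n_neurons, n_bins].

    Bins are half-open [t, t + bin_width) in choice-relative time, shared
    across trials.
    """

    values: np.ndarray
    window: tuple[float, float]
    bin_width: float = 0.05

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]

    @property
    def bin_centers(self) -> np.ndarray:
        start = self.window[0]
        return start + (np.arange(self.n_bins) + 0.5) * self.bin_width


def zscore_per_neuron(F: FluorescenceMatrix) -> FluorescenceMatrix:
    """Z-score each neuron across the entire session (sample SD, n-1)."""
    if F.units != "raw":
        raise ValueError("input already z-scored")
    sd = F.values.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance neuron(s): {bad.tolist()}")
    z = (F.values - F.values.mean(axis=1, keepdims=True)) / sd[:, None]
    return FluorescenceMatrix(values=z, sample_times=F.sample_times, units="zscored")


def bin_activity(F: FluorescenceMatrix, bin_width: float) -> FluorescenceMatrix:
    """Average samples into non-overlapping bins; trailing partial bin dropped."""
    dt = F.dt
    if bin_width < dt - 1e-12:
        raise ValueError(f"bin_width {bin_width} below sample spacing {dt}")
    n_samples = F.values.shape[1]
    duration = n_samples * dt
    n_bins = int(np.floor(duration / bin_width + 1e-9))
    rel = F.sample_times - F.sample_times[0]
    idx = np.floor(rel / bin_width + 1e-9).astype(int)
    keep = idx < n_bins
    counts = np.bincount(idx[keep], minlength=n_bins)
    sums = np.apply_along_axis(
        lambda row: np.bincount(idx[keep], weights=row[keep], minlength=n_bins),
        1,
        F.values,
    )
    binned = sums / counts
    centers = F.sample_times[0] + (np.arange(n_bins) + 0.5) * bin_width
    return FluorescenceMatrix(values=binned, sample_times=centers, units=F.units)


def extract_window(
    F: FluorescenceMatrix,
    trials: pd.DataFrame,
    window: tuple[float, float],
    bin_width: float = 0.05,
) -> AlignedTensor:
    """Choice-aligned tensor with shared choice-relative bin edges.

    A sample at time t belongs to bin k of trial with choice time c iff
    t - c is in [start + k*bw, start + (k+1)*bw).
    """
    start, end = window
    n_bins = int(round((end - start) / bin_width))
    choice_times = trials["choice_time_s"].to_numpy()
    t0, t1 = F.sample_times[0], F.sample_times[-1]
    bad = [
        int(tid)
        for tid, c in zip(trials["trial_id"], choice_times)
        if c + start < t0 - 1e-9 or c + end > t1 + F.dt + 1e-9
    ]
    if bad:
        raise ValueError(f"window out of recording for trial_ids {bad}")

    n_trials = choice_times.size
    n_neurons = F.values.shape[0]
    out = np.empty((n_trials, n_neurons, n_bins))
    for i, c in enumerate(choice_times):
        lo = np.searchsorted(F.sample_times, c + start - bin_width)
        hi = np.searchsorted(F.sample_times, c + end + bin_width)
        rel = F.sample_times[lo:hi] - c
        k = np.floor((rel - start) / bin_width + 1e-9).astype(int)
        keep = (k >= 0) & (k < n_bins)
        kk = k[keep]
        counts = np.bincount(kk, minlength=n_bins)
        if np.any(counts == 0):
            raise ValueError(f"empty aligned bin on trial {i + 1}")
        block = F.values[:, lo:hi][:, keep]
        order = np.argsort(kk, kind="stable")
        edges = np.searchsorted(kk[order], np.arange(n_bins + 1))
        sorted_block = block[:, order]
        sums = np.add.reduceat(sorted_block, edges[:-1], axis=1)
        out[i] = sums / counts
    return AlignedTensor(values=out, window=window, bin_width=bin_width)


@dataclass
class TransientSet:
    """Detected calcium transients and per-neuron summaries."""

    events: list  # per neuron: list of (onset_s, peak_amplitude_z, duration_s)
    summary: pd.DataFrame = field(default=None)


def detect_transients(
    F: FluorescenceMatrix, theta_on: float = 2.0, theta_off: float = 0.5
) -> TransientSet:
    """Threshold-crossing transient detection on z-scored traces.

    An event starts when the trace crosses above ``theta_on`` and ends when
    it next falls below ``theta_off``.  Amplitude is the maximum z within
    the event; duration is the time spent above half that amplitude inside
    the event (full-width-at-half-maximum convention).
    """
    if F.units != "zscored":
        raise ValueError("detect_transients expects z-scored input")
    if theta_off >= theta_on:
        raise ValueError("theta_off must be below theta_on")
    dt = F.dt
    minutes = F.values.shape[1] * dt / 60.0
    events: list[list[tuple[float, float, float]]] = []
    rows = []
    for j, x in enumerate(F.values):
        ev = []
        i, n = 0, x.size
        while i < n:
            if x[i] >= theta_on:
                k = i
                while k < n and x[k] >= theta_off:
                    k += 1
                seg = x[i:k]
                amp = float(seg.max())
                dur = float(np.count_nonzero(seg >= amp / 2.0) * dt)
                ev.append((float(F.sample_times[i]), amp, dur))
                i = k
            else:
                i += 1
        events.append(ev)
        n_ev = len(ev)
        rows.append(
            {
                "neuron_id": j,
                "n_events": n_ev,
                "freq_per_min": n_ev / minutes,
                "mean_amp_z": float(np.mean([e[1] for e in ev])) if n_ev else np.nan,
                "mean_dur_s": float(np.mean([e[2] for e in ev])) if n_ev else np.nan,
            }
        )
    return TransientSet(events=events, summary=pd.DataFrame(rows))
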