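"""Epoch container, ERP preprocessing, and P2 mean-amplitude extraction.

The event-related-potential (ERP) branch of the pipeline quantifies the P2
component — a positive deflection peaking roughly 140–200 ms after stimulus
onset — as the mean voltage at the parietal midline electrode Pz in that
window, separately for congruent and incongruent dot-probe trials.

Preprocessing follows the fixed order

    average re-reference -> band-pass filter -> baseline correction
    -> artifact rejection -> per-condition trial averaging

Each step is a pure function ``EpochSet -> EpochSet`` so the order is explicit
at the call site (see :func:`preprocess`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "EpochSet",
    "RejectionLog",
    "ErpSummary",
    "rereference_average",
    "bandpass",
    "baseline_correct",
    "reject_artifacts",
    "p2_mean_amplitude",
    "preprocess",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class EpochSet:
    """Epoched multichannel EEG data.

    Parameters
    ----------
    data:
        Voltages in microvolts, shape ``(n_channels, n_samples, n_trials)``.
    channel_labels:
        Unique channel names, e.g. ``["Fp1", ..., "Pz", ...]``.
    sampling_rate:
        Sampling frequency in Hz.
    window:
        Epoch window ``(start_ms, end_ms)`` relative to stimulus onset;
        ``n_samples`` must equal ``(end - start) / 1000 * sampling_rate``.
    conditions:
        Per-trial condition labels, length ``n_trials``.
    """

    data: np.ndarray
    channel_labels: list[str]
    sampling_rate: float
    window: tuple[float, float]
    conditions: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.conditions = np.asarray(self.conditions)
        if self.data.ndim != 3:
            raise ValueError("data must be (channels, samples, trials)")
        n_ch, n_samp, n_tr = self.data.shape
        if len(self.channel_labels) != n_ch:
            raise ValueError("channel_labels length does not match data")
        if len(set(self.channel_labels)) != n_ch:
            raise ValueError("channel labels must be unique")
        start, end = self.window
        expected = round((end - start) / 1000.0 * self.sampling_rate)
        if n_samp != expected:
            raise ValueError(
                f"samples={n_samp} inconsistent with window {self.window} "
                f"at {self.sampling_rate} Hz (expected {expected})"
            )
        if len(self.conditions) != n_tr:
            raise ValueError("conditions length does not match trial count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        start, _ = self.window
        return start + np.arange(self.n_samples) / self.sampling_rate * 1000.0

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def copy_with(self, data: np.ndarray | None = None,
                  conditions: np.ndarray | None = None) -> "EpochSet":
        return EpochSet(
            data=self.data.copy() if data is None else data,
            channel_labels=list(self.channel_labels),
            sampling_rate=self.sampling_rate,
            window=self.window,
            conditions=self.conditions.copy() if conditions is None else conditions,
        )


@dataclass
class RejectionLog:
    """Outcome of amplitude-based artifact rejection."""

    threshold_uv: float
    kept: np.ndarray          # boolean mask over original trials
    n_in: int
    n_kept: int

    @property
    def n_rejected(self) -> int:
        return self.n_in - self.n_kept

    @property
    def all_rejected(self) -> bool:
        return self.n_kept == 0


@dataclass
class ErpSummary:
    """Per-subject P2 mean amplitudes by condition."""

    subject: str
    group: str
    p2: dict[str, float] = field(default_factory=dict)       # condition -> uV
    n_valid: dict[str, int] = field(default_factory=dict)    # condition -> trials


# ---------------------------------------------------------------------------
# preprocessing steps
# ---------------------------------------------------------------------------

def rereference_average(epochs: EpochSet) -> EpochSet:
    """Re-reference to the common average.

    Subtracts, at every sample of every trial, the mean across channels; the
    across-channel mean of the output is therefore exactly zero.
    """
    if epochs.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    data = epochs.data - epochs.data.mean(axis=0, keepdims=True)
    return epochs.copy_with(data=data)


def bandpass(epochs: EpochSet, low: float, high: float) -> EpochSet:
    """Zero-phase Butterworth band-pass filter applied per channel and trial.

    A 4th-order (two second-order sections) Butterworth design is run
    forward and backward (``sosfiltfilt``), preserving phase — required
    because the same filtered epochs feed phase-based connectivity.
    """
    nyq = epochs.sampling_rate / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < Nyquist ({nyq} Hz); "
            f"got ({low}, {high})"
        )
    sos = signal.butter(4, [low, high], btype="bandpass",
                        fs=epochs.sampling_rate, output="sos")
    data = signal.sosfiltfilt(sos, epochs.data, axis=1)
    return epochs.copy_with(data=np.ascontiguousarray(data))


def baseline_correct(epochs: EpochSet,
                     baseline: tuple[float, float] = (-100.0, 0.0)) -> EpochSet:
    """Subtract the mean of the pre-stimulus baseline per channel and trial."""
    t = epochs.times_ms()
    lo, hi = baseline
    if not (epochs.window[0] <= lo < hi <= epochs.window[1]):
        raise ValueError(f"baseline {baseline} outside epoch {epochs.window}")
    mask = (t >= lo) & (t <= hi)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    base = epochs.data[:, mask, :].mean(axis=1, keepdims=True)
    return epochs.copy_with(data=epochs.data - base)


def reject_artifacts(epochs: EpochSet, threshold: float = 100.0
                     ) -> tuple[EpochSet, RejectionLog]:
    """Drop trials with any sample exceeding ``threshold`` microvolts.

    Pure selection: surviving waveforms are returned unmodified. Zero
    survivors is not an error; it is signalled by ``RejectionLog.all_rejected``.
    """
    peak = np.abs(epochs.data).max(axis=(0, 1))          # per trial
    kept = peak <= threshold
    log = RejectionLog(threshold_uv=float(threshold), kept=kept,
                       n_in=epochs.n_trials, n_kept=int(kept.sum()))
    out = epochs.copy_with(data=epochs.data[:, :, kept],
                           conditions=epochs.conditions[kept])
    return out, log


# ---------------------------------------------------------------------------
# P2 extraction
# ---------------------------------------------------------------------------

def p2_mean_amplitude(epochs: EpochSet,
                      channel: str = "Pz",
                      window: tuple[float, float] = (140.0, 200.0),
                      conditions: Sequence[str] | None = None,
                      ) -> dict[str, float]:
    """Per-condition P2 mean amplitude at one channel.

    For each condition, averages over its valid trials the mean voltage in
    ``window`` (inclusive, ms post-stimulus) at ``channel``.

    Parameters
    ----------
    conditions:
        Conditions to report. Defaults to every condition present in the
        epochs. A requested condition with no trials raises ``ValueError``.
    """
    ci = epochs.channel_index(channel)
    t = epochs.times_ms()
    lo, hi = window
    if not (epochs.window[0] <= lo < hi <= epochs.window[1]):
        raise ValueError(f"P2 window {window} outside epoch {epochs.window}")
    mask = (t >= lo) & (t <= hi)
    per_trial = epochs.data[ci][mask, :].mean(axis=0)     # (n_trials,)

    wanted = list(conditions) if conditions is not None else \
        list(dict.fromkeys(epochs.conditions.tolist()))
    out: dict[str, float] = {}
    for cond in wanted:
        sel = epochs.conditions == cond
        if not sel.any():
            raise ValueError(f"no valid trials for condition {cond!r}")
        out[cond] = float(per_trial[sel].mean())
    return out


def p2_trial_counts(epochs: EpochSet) -> dict[str, int]:
    """Number of valid trials per condition in an epoch set."""
    vals, counts = np.unique(epochs.conditions, return_counts=True)
    return {str(v): int(c) for v, c in zip(vals, counts)}


def preprocess(epochs: EpochSet,
               band: tuple[float, float] = (1.0, 40.0),
               baseline: tuple[float, float] = (-100.0, 0.0),
               reject_threshold: float = 100.0,
               ) -> tuple[EpochSet, RejectionLog]:
    """Run the fixed preprocessing chain and return cleaned epochs + log.

    Order: average re-reference -> band-pass ``band`` -> baseline correction
    -> amplitude-based artifact rejection.
    """
    out = rereference_average(epochs)
    out = bandpass(out, *band)
    out = baseline_correct(out, baseline)
    return reject_artifacts(out, reject_threshold)
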