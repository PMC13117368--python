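"""Seeded synthetic dot-probe EEG study generator.

Emulates the two-group, two-condition structure of a dot-probe study of
attentional bias in high- vs low-social-anxiety (HSA/LSA) adolescents:

* 100 trials per subject (40 congruent / 40 incongruent / 20 neutral) in
  3 blocks, probe side balanced;
* condition-dependent reaction times (truncated normal, lower bound 100 ms)
  with a configurable lapse/error rate;
* −100…+500 ms epochs at 500 Hz over a 32-channel 10/20 montage carrying
  (a) 1/f plus white background noise,
  (b) a P2-like Gaussian deflection at Pz whose amplitude differs by group
      and condition (defaults follow the target study's group means), and
  (c) theta-band phase coupling between designated channel pairs whose
      strength (von-Mises concentration kappa) differs by group, the HSA
      group being the more weakly coupled.

Everything is driven by a single integer seed; identical configurations
produce bit-identical datasets.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .erp import EpochSet

__all__ = [
    "Montage",
    "standard_montage_32",
    "SimulationConfig",
    "SubjectRecord",
    "StudyDataset",
    "generate_trial_schedule",
    "simulate_reaction_times",
    "simulate_epochs",
    "simulate_study",
    "write_dataset",
    "read_dataset",
]

GROUPS = ("hsa", "lsa")
CONDITIONS = ("congruent", "incongruent", "neutral")

# trial counts per session: 40 congruent, 40 incongruent, 20 neutral
N_TRIALS = 100
CONDITION_COUNTS = {"congruent": 40, "incongruent": 40, "neutral": 20}
N_BLOCKS = 3


# ---------------------------------------------------------------------------
# montage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Montage:
    """EEG channel montage: labels, 2-D scalp positions, hemisphere tags.

    Positions are schematic head-circle coordinates (x: left −1 … +1 right,
    y: posterior −1 … +1 anterior); hemisphere is derived from the 10/20
    label convention (odd digit = left, even = right, trailing z = midline).
    """

    labels: tuple[str, ...]
    positions: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("montage labels must be unique")
        if len(self.positions) != len(self.labels):
            raise ValueError("positions/labels length mismatch")

    @property
    def hemisphere_map(self) -> dict[str, str]:
        return {lab: hemisphere_of(lab) for lab in self.labels}

    def __len__(self) -> int:
        return len(self.labels)


def hemisphere_of(label: str) -> str:
    """Hemisphere tag from a 10/20 label: left, right or midline."""
    tail = label.rstrip()
    if tail[-1] in "zZ":
        return "midline"
    digits = "".join(ch for ch in tail if ch.isdigit())
    if not digits:
        raise ValueError(f"cannot infer hemisphere from label {label!r}")
    return "left" if int(digits[-1]) % 2 == 1 else "right"


_STANDARD_32 = [
    # label, (x, y) — schematic 10/20 layout
    ("Fp1", (-0.31, 0.95)), ("Fp2", (0.31, 0.95)),
    ("F7", (-0.81, 0.59)), ("F3", (-0.40, 0.55)), ("Fz", (0.0, 0.50)),
    ("F4", (0.40, 0.55)), ("F8", (0.81, 0.59)),
    ("FT7", (-0.95, 0.31)), ("FC3", (-0.45, 0.28)), ("FCz", (0.0, 0.25)),
    ("FC4", (0.45, 0.28)), ("FT8", (0.95, 0.31)),
    ("T7", (-1.0, 0.0)), ("C3", (-0.50, 0.0)), ("Cz", (0.0, 0.0)),
    ("C4", (0.50, 0.0)), ("T8", (1.0, 0.0)),
    ("TP7", (-0.95, -0.31)), ("CP3", (-0.45, -0.28)), ("CPz", (0.0, -0.25)),
    ("CP4", (0.45, -0.28)), ("TP8", (0.95, -0.31)),
    ("P7", (-0.81, -0.59)), ("P3", (-0.40, -0.55)), ("Pz", (0.0, -0.50)),
    ("P4", (0.40, -0.55)), ("P8", (0.81, -0.59)),
    ("PO3", (-0.35, -0.75)), ("PO4", (0.35, -0.75)),
    ("O1", (-0.31, -0.95)), ("Oz", (0.0, -0.95)), ("O2", (0.31, -0.95)),
]


def standard_montage_32() -> Montage:
    """32-channel 10/20 scalp montage (mastoids excluded) including Pz."""
    labels, pos = zip(*_STANDARD_32)
    return Montage(labels=labels, positions=pos)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _default_p2_mean() -> dict[str, dict[str, float]]:
    # group -> condition -> microvolts. Congruent/incongruent follow the
    # target study's group means; neutral (not analysed in the ERP branch)
    # sits at the per-group average of the two.
    return {
        "hsa": {"congruent": 0.330, "incongruent": 0.197, "neutral": 0.264},
        "lsa": {"congruent": 1.625, "incongruent": 1.625, "neutral": 1.625},
    }


def _default_rt_mean() -> dict[str, dict[str, float]]:
    # HSA shows a vigilance pattern (slow disengagement from threat);
    # LSA is near-flat across conditions.
    return {
        "hsa": {"congruent": 540.0, "incongruent": 585.0, "neutral": 560.0},
        "lsa": {"congruent": 555.0, "incongruent": 560.0, "neutral": 557.0},
    }


def _default_rt_sd() -> dict[str, dict[str, float]]:
    return {g: {c: 90.0 for c in CONDITIONS} for g in GROUPS}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    n_hsa: int = 27
    n_lsa: int = 18
    sampling_rate: float = 500.0
    epoch_window: tuple[float, float] = (-100.0, 500.0)
    montage: Montage = field(default_factory=standard_montage_32)

    # P2 component (at Pz)
    p2_mean: dict[str, dict[str, float]] = field(default_factory=_default_p2_mean)
    p2_latency_ms: float = 170.0
    p2_width_ms: float = 40.0          # ~2 sigma of the Gaussian bump
    p2_between_sd: float = 2.1         # between-subject amplitude SD, uV

    # background noise
    noise_sd: float = 1.0              # white component, uV
    pink_sd: float = 1.0               # 1/f component, uV
    one_over_f_exponent: float = 1.0   # spectral exponent beta (power ~ 1/f^beta)

    # theta phase coupling
    coupled_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [("O1", "O2"), ("P7", "P8")])
    coupling_amplitude: float = 2.0    # uV
    coupling_kappa: dict[str, float] = field(
        default_factory=lambda: {"hsa": 1.0, "lsa": 3.0})
    theta_freq: float = 6.0            # Hz
    jitter_interval_ms: float = 100.0  # von-Mises phase-jitter knot spacing

    # behavior
    rt_mean_ms: dict[str, dict[str, float]] = field(default_factory=_default_rt_mean)
    rt_sd_ms: dict[str, dict[str, float]] = field(default_factory=_default_rt_sd)
    error_rate: float = 0.05

    # amplitude outliers for rejection tests (off by default)
    artifact_fraction: float = 0.0
    artifact_amplitude: float = 150.0  # uV

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_hsa <= 0 or self.n_lsa <= 0:
            raise ValueError("group sizes must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        start, end = self.epoch_window
        if not (start < 0.0 < end):
            raise ValueError("epoch window must straddle stimulus onset")
        lo = self.p2_latency_ms - self.p2_width_ms
        hi = self.p2_latency_ms + self.p2_width_ms
        if not (0.0 <= lo and hi <= end):
            raise ValueError("P2 window (latency +/- width) outside post-stimulus epoch")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        for g, kappa in self.coupling_kappa.items():
            if kappa < 0:
                raise ValueError(f"coupling_kappa[{g!r}] must be >= 0")
        for g in self.rt_sd_ms:
            for c, sd in self.rt_sd_ms[g].items():
                if sd < 0:
                    raise ValueError(f"rt_sd_ms[{g!r}][{c!r}] must be >= 0")
        labels = set(self.montage.labels)
        if "Pz" not in labels:
            raise ValueError("montage must contain Pz")
        for a, b in self.coupled_pairs:
            for ch in (a, b):
                if ch not in labels:
                    raise ValueError(f"coupled-pair channel {ch!r} not in montage")

    @property
    def n_samples(self) -> int:
        start, end = self.epoch_window
        return round((end - start) / 1000.0 * self.sampling_rate)

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["montage"] = {"labels": list(self.montage.labels),
                        "positions": [list(p) for p in self.montage.positions]}
        d["coupled_pairs"] = [list(p) for p in self.coupled_pairs]
        d["epoch_window"] = list(self.epoch_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        m = d.get("montage")
        if isinstance(m, dict):
            d["montage"] = Montage(labels=tuple(m["labels"]),
                                   positions=tuple(tuple(p) for p in m["positions"]))
        d["epoch_window"] = tuple(d["epoch_window"])
        d["coupled_pairs"] = [tuple(p) for p in d.get("coupled_pairs", [])]
        return cls(**d)


# ---------------------------------------------------------------------------
# trial schedule and reaction times
# ---------------------------------------------------------------------------

def generate_trial_schedule(seed) -> pd.DataFrame:
    """Randomised 100-trial dot-probe schedule (40/40/20, 3 blocks).

    Probe side is balanced within each condition. Returns a DataFrame with
    columns ``trial_id`` (1-based presentation order), ``block`` (1–3),
    ``condition`` and ``probe_side``.
    """
    rng = np.random.default_rng(seed)
    conds: list[str] = []
    sides: list[str] = []
    for cond, n in CONDITION_COUNTS.items():
        conds += [cond] * n
        sides += ["left"] * (n // 2) + ["right"] * (n - n // 2)
    order = rng.permutation(N_TRIALS)
    conds = [conds[i] for i in order]
    sides = [sides[i] for i in order]
    # blocks as even as possible: 34/33/33
    base, extra = divmod(N_TRIALS, N_BLOCKS)
    blocks = np.repeat(np.arange(1, N_BLOCKS + 1),
                       [base + (i < extra) for i in range(N_BLOCKS)])
    return pd.DataFrame({
        "trial_id": np.arange(1, N_TRIALS + 1),
        "block": blocks,
        "condition": conds,
        "probe_side": sides,
    })


def simulate_reaction_times(schedule: pd.DataFrame, config: SimulationConfig,
                            group: str, seed) -> pd.DataFrame:
    """Attach reaction times and correctness to a trial schedule.

    RTs are truncated-normal (lower bound 100 ms) with per-(group, condition)
    mean and SD from ``config``; correctness is Bernoulli(1 − error_rate).
    ``rt_sd_ms = 0`` is the documented degenerate case: every RT equals its
    condition mean exactly.
    """
    from scipy import stats

    if group not in config.rt_mean_ms:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    out = schedule.copy()
    rt = np.empty(len(out), dtype=float)
    for cond in out["condition"].unique():
        mean = config.rt_mean_ms[group][cond]
        sd = config.rt_sd_ms[group][cond]
        if sd < 0:
            raise ValueError("rt_sd_ms must be >= 0")
        sel = (out["condition"] == cond).to_numpy()
        if sd == 0.0:
            rt[sel] = mean
        else:
            a = (100.0 - mean) / sd     # standardised lower bound
            rt[sel] = stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                                          size=int(sel.sum()), random_state=rng)
    out["rt"] = rt
    out["correct"] = rng.random(len(out)) >= config.error_rate
    return out


# ---------------------------------------------------------------------------
# epochs
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
                n_samples: int, beta: float, sd: float) -> np.ndarray:
    """1/f^beta-shaped Gaussian noise with stationary SD ``sd`` along axis 1."""
    if sd == 0.0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    w = np.zeros_like(freqs)
    w[1:] = freqs[1:] ** (-beta / 2.0)          # no DC component
    # analytic variance of irfft(rfft(white) * w) per sample
    c = np.full(len(w), 2.0)
    c[0] = 1.0
    if n_samples % 2 == 0:
        c[-1] = 1.0
    var = float((c * w ** 2).sum()) / n_samples
    shaped = np.fft.irfft(spec * w[None, :, None], n=n_samples, axis=1)
    return shaped * (sd / np.sqrt(var))


def _phase_jitter(rng: np.random.Generator, kappa: float, n_trials: int,
                  n_samples: int, interp: np.ndarray) -> np.ndarray:
    """Slowly varying von-Mises phase jitter, one series per trial.

    Draws iid von-Mises(0, kappa) offsets at evenly spaced knots and
    interpolates the unit phasor between knots, giving a smooth phase
    process whose marginal at the knots is exactly von-Mises. kappa = 0
    yields uniform (fully incoherent) offsets.
    """
    n_knots = interp.shape[1]
    knots = rng.vonmises(0.0, kappa, size=(n_trials, n_knots))
    z = np.exp(1j * knots) @ interp.T           # (n_trials, n_samples)
    return np.angle(z)


def _knot_interp_matrix(n_samples: int, n_knots: int) -> np.ndarray:
    """Linear interpolation weights, shape (n_samples, n_knots)."""
    pos = np.linspace(0.0, n_knots - 1.0, n_samples)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_knots - 1)
    frac = pos - lo
    mat = np.zeros((n_samples, n_knots))
    mat[np.arange(n_samples), lo] += 1.0 - frac
    mat[np.arange(n_samples), hi] += frac
    return mat


def simulate_epochs(schedule: pd.DataFrame, config: SimulationConfig,
                    group: str, seed) -> EpochSet:
    """Generate one subject's epoch array for a trial schedule.

    Per trial and channel: 1/f + white Gaussian noise; a Gaussian-bump P2
    at Pz with per-(group, condition) amplitude plus a subject-level offset
    drawn once from N(0, p2_between_sd); and, for each configured coupled
    pair, a shared theta sinusoid whose per-channel phase offsets follow a
    slowly varying von-Mises process with concentration
    ``coupling_kappa[group]``.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    mont = config.montage
    labels = list(mont.labels)
    n_ch, n_tr = len(labels), len(schedule)
    n_samp = config.n_samples
    fs = config.sampling_rate
    start_ms, _ = config.epoch_window
    t = start_ms / 1000.0 + np.arange(n_samp) / fs       # seconds

    # subject-level P2 amplitude offset (shared across conditions -> induces
    # the within-subject correlation of a mixed design)
    subject_offset = rng.normal(0.0, config.p2_between_sd) \
        if config.p2_between_sd > 0 else 0.0

    data = np.zeros((n_ch, n_samp, n_tr))
    if config.noise_sd > 0:
        data += rng.standard_normal(data.shape) * config.noise_sd
    data += _pink_noise(rng, data.shape, n_samp,
                        config.one_over_f_exponent, config.pink_sd)

    # P2 Gaussian bump at Pz
    pz = labels.index("Pz")
    sigma_s = (config.p2_width_ms / 2.0) / 1000.0
    bump = np.exp(-0.5 * ((t - config.p2_latency_ms / 1000.0) / sigma_s) ** 2)
    cond_arr = schedule["condition"].to_numpy()
    amp = np.array([config.p2_mean[group][c] for c in cond_arr]) + subject_offset
    data[pz] += bump[:, None] * amp[None, :]

    # theta-band phase coupling
    kappa = config.coupling_kappa[group]
    if config.coupled_pairs and config.coupling_amplitude != 0.0:
        interp = _knot_interp_matrix(
            n_samp, max(2, round((t[-1] - t[0]) * 1000.0
                                 / config.jitter_interval_ms) + 1))
        omega_t = 2.0 * np.pi * config.theta_freq * t    # (n_samp,)
        for ch_a, ch_b in config.coupled_pairs:
            psi0 = rng.uniform(0.0, 2.0 * np.pi, size=n_tr)
            common = omega_t[None, :] + psi0[:, None]    # (n_tr, n_samp)
            for ch in (ch_a, ch_b):
                delta = _phase_jitter(rng, kappa, n_tr, n_samp, interp)
                data[labels.index(ch)] += (
                    config.coupling_amplitude * np.cos(common + delta)
                ).T

    # optional amplitude outliers (for artifact-rejection tests)
    if config.artifact_fraction > 0:
        spiked = rng.random(n_tr) < config.artifact_fraction
        width = max(1, int(0.040 * fs))                  # 40 ms pulse
        for tr in np.flatnonzero(spiked):
            ch = rng.integers(n_ch)
            s0 = rng.integers(0, n_samp - width)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            data[ch, s0:s0 + width, tr] += sign * config.artifact_amplitude

    return EpochSet(data=data, channel_labels=labels, sampling_rate=fs,
                    window=config.epoch_window, conditions=cond_arr.copy())


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    trials: pd.DataFrame
    epochs: EpochSet


@dataclass
class StudyDataset:
    subjects: list[SubjectRecord]
    config: SimulationConfig
    seed: int

    def __post_init__(self) -> None:
        expected = self.config.n_hsa + self.config.n_lsa
        if len(self.subjects) != expected:
            raise ValueError("subject count does not match config group sizes")
        for rec in self.subjects:
            if rec.epochs.n_trials != len(rec.trials):
                raise ValueError(
                    f"{rec.subject_id}: epochs do not map 1:1 to trial rows")

    def by_group(self, group: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == group]


def simulate_study(config: SimulationConfig) -> StudyDataset:
    """Simulate the full two-group study from ``config.seed``.

    Per-subject seeds are spawned deterministically from the master seed, so
    the same config always yields the same dataset and any one subject is
    reproducible in isolation.
    """
    config.validate()
    n_total = config.n_hsa + config.n_lsa
    children = np.random.SeedSequence(config.seed).spawn(n_total)
    subjects: list[SubjectRecord] = []
    for i, child in enumerate(children):
        group = "hsa" if i < config.n_hsa else "lsa"
        s_sched, s_rt, s_epochs = child.spawn(3)
        schedule = generate_trial_schedule(s_sched)
        trials = simulate_reaction_times(schedule, config, group, s_rt)
        epochs = simulate_epochs(schedule, config, group, s_epochs)
        subjects.append(SubjectRecord(
            subject_id=f"sub-{i + 1:02d}", group=group,
            trials=trials, epochs=epochs))
    return StudyDataset(subjects=subjects, config=config, seed=config.seed)


# ---------------------------------------------------------------------------
# on-disk format
# ---------------------------------------------------------------------------
# One directory per subject:
#   sub-XX/trials.csv      trial table (trial_id, block, condition,
#                          probe_side, rt, correct)
#   sub-XX/epochs.npy      float64 array (channels, samples, trials)
#   sub-XX/epochs.json     sidecar: channel labels, sampling rate, epoch
#                          window, per-epoch condition, group
# plus a top-level config.json echo of the SimulationConfig.

def write_dataset(dataset: StudyDataset, path: str | Path) -> None:
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    (root / "config.json").write_text(
        json.dumps({"seed": dataset.seed,
                    "config": dataset.config.to_dict()}, indent=2))
    for rec in dataset.subjects:
        d = root / rec.subject_id
        d.mkdir(exist_ok=True)
        rec.trials.to_csv(d / "trials.csv", index=False)
        np.save(d / "epochs.npy", rec.epochs.data)
        (d / "epochs.json").write_text(json.dumps({
            "subject_id": rec.subject_id,
            "group": rec.group,
            "channel_labels": rec.epochs.channel_labels,
            "sampling_rate": rec.epochs.sampling_rate,
            "window": list(rec.epochs.window),
            "conditions": [str(c) for c in rec.epochs.conditions],
        }, indent=2))


def read_dataset(path: str | Path) -> StudyDataset:
    root = Path(path)
    meta = json.loads((root / "config.json").read_text())
    config = SimulationConfig.from_dict(meta["config"])
    subjects = []
    for d in sorted(p for p in root.iterdir() if p.is_dir()):
        side = json.loads((d / "epochs.json").read_text())
        epochs = EpochSet(
            data=np.load(d / "epochs.npy"),
            channel_labels=list(side["channel_labels"]),
            sampling_rate=side["sampling_rate"],
            window=tuple(side["window"]),
            conditions=np.array(side["conditions"]),
        )
        subjects.append(SubjectRecord(
            subject_id=side["subject_id"], group=side["group"],
            trials=pd.read_csv(d / "trials.csv"), epochs=epochs))
    return StudyDataset(subjects=subjects, config=config, seed=meta["seed"])
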