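"""Synthetic multichannel EEG epoch generation.

Each omission epoch is a linear sum of independent parts:

* a frontocentral negative component: fixed spatial weight map times a Hann
  temporal bump centered at the component peak latency, trial amplitude drawn
  around the participant's condition mean;
* a note-identity-specific pattern: one fixed random spatial map per note per
  participant, times a tapered boxcar over an early latency window, scaled by
  a per-condition amplitude (zero by default when unfamiliar);
* spatially correlated 1/f^alpha background noise;
* optional large frontal step-decay artifacts in a recorded subset of epochs.

All randomness flows from explicit seeds; every injected quantity is logged
in a :class:`GroundTruth` so downstream estimates can be checked against the
generator without re-simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import montage
from .design import NOTES, ExperimentSchedule

CONDITIONS = ("familiar", "unfamiliar")


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


def _cond_map(value, name: str) -> dict[str, float]:
    if isinstance(value, dict):
        missing = [c for c in CONDITIONS if c not in value]
        if missing:
            raise ConfigError(f"{name} missing condition(s) {missing}")
        return {c: float(value[c]) for c in CONDITIONS}
    return {c: float(value) for c in CONDITIONS}


@dataclass
class SimulationConfig:
    n_participants: int = 25
    fs: float = 1000.0
    epoch_span: tuple[float, float] = (-400.0, 400.0)
    channels: tuple[str, ...] = montage.CHANNELS
    oN1_mean: dict[str, float] = field(
        default_factory=lambda: {"familiar": -1.95, "unfamiliar": -1.37})
    oN1_between_sd: dict[str, float] = field(
        default_factory=lambda: {"familiar": 1.17, "unfamiliar": 0.98})
    condition_correlation: float = 0.75
    oN1_within_sd: float = 0.5
    oN1_peak_ms: float = 109.0
    oN1_kernel_halfwidth_ms: float = 25.0
    oN1_topography: dict[str, float] | None = None
    note_pattern_amp: dict[str, float] = field(
        default_factory=lambda: {"familiar": 0.8, "unfamiliar": 0.0})
    note_pattern_window_ms: tuple[float, float] = (50.0, 90.0)
    note_pattern_ramp_ms: float = 5.0
    noise_sd: float = 6.0
    noise_spectrum_exponent: float = 1.0
    noise_spatial_scale: float = 0.35
    artifact_fraction: float = 0.0
    artifact_amp: float = 160.0
    artifact_tau_ms: float = 150.0
    dtype: str = "float64"   # "float32" roughly halves simulation cost
    seed: int = 0

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.oN1_mean = _cond_map(self.oN1_mean, "oN1_mean")
        self.oN1_between_sd = _cond_map(self.oN1_between_sd, "oN1_between_sd")
        self.note_pattern_amp = _cond_map(self.note_pattern_amp,
                                          "note_pattern_amp")
        if self.fs <= 0:
            raise ConfigError("fs must be positive")
        lo, hi = self.epoch_span
        if lo > -200.0 or hi < 300.0:
            raise ConfigError("epoch_span must cover at least -200..300 ms")
        for name, val in [("oN1_within_sd", self.oN1_within_sd),
                          ("noise_sd", self.noise_sd)]:
            if val < 0:
                raise ConfigError(f"{name} must be non-negative")
        if any(v < 0 for v in self.oN1_between_sd.values()):
            raise ConfigError("oN1_between_sd must be non-negative")
        if not 0.0 <= self.artifact_fraction <= 1.0:
            raise ConfigError("artifact_fraction outside [0, 1]")
        if self.artifact_fraction > 0 and self.artifact_amp <= 80.0:
            raise ConfigError("artifact_amp must exceed the 80 uV rejection "
                              "threshold when artifacts are enabled")
        if self.oN1_topography is not None:
            missing = [c for c in self.oN1_topography if c not in self.channels]
            if missing:
                raise ConfigError(f"topography channel(s) not in montage: "
                                  f"{missing}")
            if sum(abs(v) for v in self.oN1_topography.values()) == 0:
                raise ConfigError("topography is identically zero")

    @property
    def time_axis(self) -> np.ndarray:
        step = 1000.0 / self.fs
        lo, hi = self.epoch_span
        n = int(round((hi - lo) / step)) + 1
        return lo + step * np.arange(n)

    def topography_vector(self) -> np.ndarray:
        if self.oN1_topography is None:
            return montage.frontocentral_topography(self.channels)
        w = np.array([self.oN1_topography.get(c, 0.0) for c in self.channels])
        roi_idx = montage.channel_indices(self.channels, montage.ROI)
        roi_mean = w[roi_idx].mean()
        if roi_mean == 0:
            raise ConfigError("topography has zero mean over the ROI; cannot "
                              "normalize")
        return w / roi_mean


@dataclass
class EpochSet:
    """Epochs of one participant in one condition, with per-epoch labels."""

    data: np.ndarray            # (n_epochs, n_channels, n_samples), uV
    time_axis: np.ndarray       # ms
    labels: np.ndarray          # note per epoch
    retained: np.ndarray        # bool per epoch
    fs: float
    condition: str
    participant_id: str
    channels: tuple[str, ...] = montage.CHANNELS
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.labels = np.asarray(self.labels)
        self.retained = np.asarray(self.retained, dtype=bool)
        n, c, s = self.data.shape
        if len(self.time_axis) != s:
            raise ValueError("time_axis length does not match data")
        if len(self.labels) != n or len(self.retained) != n:
            raise ValueError("labels/retained length does not match data")
        if c != len(self.channels):
            raise ValueError("channel count does not match montage")
        steps = np.diff(self.time_axis)
        if len(steps) and (np.any(steps <= 0)
                           or not np.allclose(steps, 1000.0 / self.fs)):
            raise ValueError("time_axis must increase in steps of 1000/fs ms")
        bad = set(np.unique(self.labels)) - set(NOTES)
        if bad:
            raise ValueError(f"unknown note label(s): {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def copy(self, **updates) -> "EpochSet":
        base = dict(
            data=self.data.copy(), time_axis=self.time_axis.copy(),
            labels=self.labels.copy(), retained=self.retained.copy(),
            fs=self.fs, condition=self.condition,
            participant_id=self.participant_id, channels=self.channels,
            provenance=list(self.provenance),
        )
        base.update(updates)
        return EpochSet(**base)

    def retained_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.labels[self.retained]:
            out[lab] = out.get(lab, 0) + 1
        return out


@dataclass
class GroundTruth:
    """Everything injected into one participant's data, frozen pre-analysis."""

    participant_id: str
    config: SimulationConfig
    oN1_amplitude: dict[str, float]
    note_patterns: dict[str, np.ndarray]       # note -> (n_channels,)
    artifact_indices: dict[str, np.ndarray]    # condition -> epoch indices
    labels: dict[str, np.ndarray]              # condition -> note per epoch

    def expected_epoch(self, condition: str, note: str,
                       time_axis: np.ndarray) -> np.ndarray:
        """Noiseless (n_channels, n_samples) expectation of one omission epoch."""
        cfg = self.config
        topo = cfg.topography_vector()
        k1 = hann_bump(time_axis, cfg.oN1_peak_ms, cfg.oN1_kernel_halfwidth_ms)
        out = self.oN1_amplitude[condition] * topo[:, None] * k1[None, :]
        amp = cfg.note_pattern_amp[condition]
        if amp != 0.0:
            k2 = tapered_boxcar(time_axis, cfg.note_pattern_window_ms,
                                cfg.note_pattern_ramp_ms)
            out = out + amp * self.note_patterns[note][:, None] * k2[None, :]
        return out

    def expected_average(self, condition: str,
                         time_axis: np.ndarray) -> np.ndarray:
        """Noiseless expectation of the epoch average, at realized label mix."""
        labs = self.labels[condition]
        acc = np.zeros((len(self.config.channels), len(time_axis)))
        for note in np.unique(labs):
            acc += (np.sum(labs == note) / len(labs)
                    * self.expected_epoch(condition, note, time_axis))
        return acc


def hann_bump(time_axis: np.ndarray, peak_ms: float,
              halfwidth_ms: float) -> np.ndarray:
    """Unit-peak Hann bump supported on peak +- halfwidth."""
    x = (np.asarray(time_axis) - peak_ms) / halfwidth_ms
    out = np.where(np.abs(x) <= 1.0, np.cos(np.pi * x / 2.0) ** 2, 0.0)
    return out


def tapered_boxcar(time_axis: np.ndarray, window_ms: tuple[float, float],
                   ramp_ms: float) -> np.ndarray:
    """Boxcar over *window_ms* with raised-cosine ramps of *ramp_ms*."""
    t = np.asarray(time_axis, dtype=float)
    lo, hi = window_ms
    out = np.zeros_like(t)
    inside = (t >= lo) & (t <= hi)
    out[inside] = 1.0
    if ramp_ms > 0:
        up = inside & (t < lo + ramp_ms)
        down = inside & (t > hi - ramp_ms)
        out[up] = 0.5 - 0.5 * np.cos(np.pi * (t[up] - lo) / ramp_ms)
        out[down] = 0.5 - 0.5 * np.cos(np.pi * (hi - t[down]) / ramp_ms)
    return out


def _noise(rng: np.random.Generator, n_epochs: int, config: SimulationConfig,
           mixing: np.ndarray) -> np.ndarray:
    """Spatially correlated noise with power spectrum ~ 1/f^alpha.

    Synthesized directly in the frequency domain (complex Gaussian spectrum
    shaped by f^(-alpha/2), DC excluded) and normalized per epoch so the
    per-channel RMS equals ``noise_sd``; the spatial mixing matrix has
    unit-variance marginals.
    """
    from scipy import fft as sfft

    n_ch = len(config.channels)
    n_samp = len(config.time_axis)
    dtype = np.dtype(config.dtype)
    if config.noise_sd == 0.0:
        return np.zeros((n_epochs, n_ch, n_samp), dtype=dtype)
    alpha = config.noise_spectrum_exponent
    if alpha != 0.0:
        n_bins = n_samp // 2 + 1
        freqs = np.fft.rfftfreq(n_samp, d=1.0 / config.fs)
        gain = np.zeros(n_bins, dtype=dtype)
        gain[1:] = freqs[1:] ** (-alpha / 2.0)
        re = rng.standard_normal((n_epochs, n_ch, n_bins), dtype=np.float32)
        im = rng.standard_normal((n_epochs, n_ch, n_bins), dtype=np.float32)
        spec = (re.astype(dtype) + 1j * im.astype(dtype)) * gain
        shaped = sfft.irfft(spec, n=n_samp, axis=2)
        scale = np.sqrt(np.mean(shaped ** 2, axis=(1, 2), keepdims=True))
        shaped /= scale
    else:
        shaped = rng.standard_normal((n_epochs, n_ch, n_samp),
                                     dtype=np.float32).astype(dtype)
    mixed = np.matmul(mixing.astype(dtype), shaped)
    return (config.noise_sd * mixed).astype(dtype, copy=False)


def _spatial_mixing(config: SimulationConfig) -> np.ndarray:
    if config.noise_spatial_scale <= 0:
        return np.eye(len(config.channels))
    d = montage.distance_matrix(config.channels)
    cov = np.exp(-(d ** 2) / (2.0 * config.noise_spatial_scale ** 2))
    cov += 1e-6 * np.eye(len(config.channels))
    chol = np.linalg.cholesky(cov)
    # rescale rows so marginal variances are exactly 1
    return chol / np.sqrt((chol ** 2).sum(axis=1, keepdims=True))


def _artifact(time_axis: np.ndarray, onset_ms: float, amp: float,
              tau_ms: float, channels: tuple[str, ...]) -> np.ndarray:
    wave = np.where(time_axis >= onset_ms,
                    np.exp(-(time_axis - onset_ms) / tau_ms), 0.0)
    chan_w = np.zeros(len(channels))
    for name, w in (("Fp1", 1.0), ("Fp2", 0.9), ("F7", 0.5), ("F8", 0.45)):
        if name in channels:
            chan_w[channels.index(name)] = w
    return amp * chan_w[:, None] * wave[None, :]


def simulate_participant(
    schedule: ExperimentSchedule,
    config: SimulationConfig,
    participant_seed: int | np.random.SeedSequence,
    participant_id: str = "sub-01",
    amplitudes: dict[str, float] | None = None,
) -> tuple[dict[str, EpochSet], GroundTruth]:
    """Generate omission epochs for both conditions of one participant.

    *amplitudes* overrides the participant's true component amplitude per
    condition (used by :func:`simulate_cohort` to inject between-participant
    variability); defaults to the population means.
    """
    rng = np.random.default_rng(participant_seed)
    time_axis = config.time_axis
    topo = config.topography_vector()
    mixing = _spatial_mixing(config)
    k_on1 = hann_bump(time_axis, config.oN1_peak_ms,
                      config.oN1_kernel_halfwidth_ms)
    k_pat = tapered_boxcar(time_axis, config.note_pattern_window_ms,
                           config.note_pattern_ramp_ms)
    amps = dict(config.oN1_mean if amplitudes is None else amplitudes)

    # per-participant fixed spatial pattern per note, unit RMS across channels
    patterns: dict[str, np.ndarray] = {}
    for note in NOTES:
        p = mixing @ rng.standard_normal(len(config.channels))
        patterns[note] = p / np.sqrt(np.mean(p ** 2))

    conditions = [c for c in CONDITIONS
                  if any(t.condition == c and t.omitted
                         for t in schedule.trials)]
    if not conditions:
        raise ConfigError("schedule contains no omission trials")
    epoch_sets: dict[str, EpochSet] = {}
    artifact_idx: dict[str, np.ndarray] = {}
    labels_by_cond: dict[str, np.ndarray] = {}
    for cond in conditions:
        labels = np.array([t.note for t in schedule.trials
                           if t.condition == cond and t.omitted])
        n_ep = len(labels)
        data = _noise(rng, n_ep, config, mixing)
        trial_amp = rng.normal(amps[cond], config.oN1_within_sd, size=n_ep)
        data += trial_amp[:, None, None] * topo[None, :, None] * k_on1[None, None, :]
        pat_amp = config.note_pattern_amp[cond]
        if pat_amp != 0.0:
            for note in np.unique(labels):
                sel = labels == note
                data[sel] += (pat_amp * patterns[note][None, :, None]
                              * k_pat[None, None, :])
        n_art = int(round(config.artifact_fraction * n_ep))
        idx = np.sort(rng.choice(n_ep, size=n_art, replace=False))
        for i in idx:
            onset = rng.uniform(-150.0, 150.0)
            data[i] += _artifact(time_axis, onset, config.artifact_amp,
                                 config.artifact_tau_ms, config.channels)
        artifact_idx[cond] = idx
        labels_by_cond[cond] = labels
        epoch_sets[cond] = EpochSet(
            data=data, time_axis=time_axis.copy(), labels=labels,
            retained=np.ones(n_ep, dtype=bool), fs=config.fs, condition=cond,
            participant_id=participant_id, channels=config.channels,
            provenance=["simulate"],
        )

    truth = GroundTruth(participant_id, replace(config), amps, patterns,
                        artifact_idx, labels_by_cond)
    return epoch_sets, truth


@dataclass
class CohortTruth:
    participants: list[GroundTruth]

    def amplitude_table(self) -> pd.DataFrame:
        rows = [(gt.participant_id, cond, gt.oN1_amplitude[cond])
                for gt in self.participants for cond in CONDITIONS]
        return pd.DataFrame(rows, columns=["participant", "condition",
                                           "amplitude_uV"])


def simulate_cohort(
    config: SimulationConfig,
    schedule: ExperimentSchedule,
) -> tuple[list[dict[str, EpochSet]], CohortTruth]:
    """Simulate ``config.n_participants`` participants.

    True component amplitudes are drawn around the condition means with the
    configured between-participant SD; a shared participant factor (weight
    ``condition_correlation``) correlates the two conditions so paired
    differences have realistic variance.  All per-participant seeds derive
    from ``config.seed``.
    """
    if config.n_participants < 1:
        raise ConfigError("n_participants must be >= 1")
    ss = np.random.SeedSequence(config.seed)
    pop_seed, *part_seeds = ss.spawn(config.n_participants + 1)
    pop_rng = np.random.default_rng(pop_seed)
    rho = config.condition_correlation
    if not 0.0 <= rho <= 1.0:
        raise ConfigError("condition_correlation outside [0, 1]")

    cohort: list[dict[str, EpochSet]] = []
    truths: list[GroundTruth] = []
    for p in range(config.n_participants):
        shared = pop_rng.standard_normal()
        amps = {}
        for cond in CONDITIONS:
            own = pop_rng.standard_normal()
            z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
            amps[cond] = config.oN1_mean[cond] + config.oN1_between_sd[cond] * z
        pid = f"sub-{p + 1:02d}"
        epoch_sets, truth = simulate_participant(schedule, config,
                                                 part_seeds[p], pid, amps)
        cohort.append(epoch_sets)
        truths.append(truth)
    return cohort, CohortTruth(truths)
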