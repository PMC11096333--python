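"""Epoch preprocessing: zero-phase FIR band-pass, threshold rejection,
baseline correction, and the participant inclusion gate for decoding.

Stage order is fixed — filter, (component-rejection slot, skipped), crop,
reject, baseline — and recorded in each EpochSet's provenance so the order
is testable.  Rejection is flag-based and never mutates sample data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from . import montage
from .simulate import EpochSet


class FilterError(ValueError):
    """Data too short for the requested FIR design."""


@dataclass
class PreprocessConfig:
    band: tuple[float, float] | None = (0.5, 25.0)   # None skips filtering
    # Transition bandwidths (low edge, high edge), Hz.  None = conventional
    # heuristic (quarter of the cutoff, clamped to [2, cutoff] Hz), which for
    # a 0.5 Hz edge implies a ~6600-tap kernel at 1000 Hz — far longer than
    # an 801-sample epoch.  The default below is the widest design whose
    # kernel fits the default epoch; DC leakage it admits is removed by
    # baseline correction.
    transition_bandwidth: tuple[float, float] | None = (4.5, 6.25)
    rejection_threshold: float = 80.0
    baseline_window: tuple[float, float] = (-200.0, 0.0)
    analysis_window: tuple[float, float] = (-200.0, 300.0)
    roi: tuple[str, ...] = montage.ROI
    min_trials_per_class: int = 50
    min_retention_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.band is not None:
            lo, hi = self.band
            if not 0 < lo < hi:
                raise ValueError("band must satisfy 0 < low < high")
        if self.rejection_threshold <= 0:
            raise ValueError("rejection_threshold must be positive")
        b0, b1 = self.baseline_window
        a0, a1 = self.analysis_window
        if not (a0 <= b0 < b1 <= a1):
            raise ValueError("baseline window must lie within analysis window")


def heuristic_transition_bandwidth(band: tuple[float, float]
                                   ) -> tuple[float, float]:
    """Conventional Hamming-design rule: quarter of each cutoff, clamped."""
    return tuple(min(max(0.25 * f, 2.0), f) for f in band)


def design_fir(band: tuple[float, float], fs: float,
               transition_bandwidth: tuple[float, float] | None = None
               ) -> np.ndarray:
    """Hamming-windowed sinc band-pass kernel.

    Kernel length follows the Hamming rule N = 3.3 / (min transition width)
    expressed in samples, rounded up to odd so the filter is exactly
    linear-phase (zero-phase after delay compensation).
    """
    if transition_bandwidth is None:
        transition_bandwidth = heuristic_transition_bandwidth(band)
    tbw = min(transition_bandwidth)
    if tbw <= 0:
        raise ValueError("transition bandwidth must be positive")
    n_taps = int(np.ceil(3.3 * fs / tbw))
    if n_taps % 2 == 0:
        n_taps += 1
    return signal.firwin(n_taps, band, window="hamming", pass_zero=False,
                         fs=fs)


def apply_fir_zero_phase(data: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """One-pass symmetric-FIR filtering with group-delay compensation.

    Edges are reflect-padded by half the kernel length.  Requires the time
    axis (last axis) to be at least as long as the kernel.
    """
    n_samp = data.shape[-1]
    n_taps = len(kernel)
    if n_samp < n_taps:
        raise FilterError(
            f"epoch has {n_samp} samples but the designed kernel needs "
            f"{n_taps}; widen the transition bandwidth or provide at least "
            f"{n_taps} samples of padding")
    from scipy import fft as sfft

    half = n_taps // 2
    pad = [(0, 0)] * (data.ndim - 1) + [(half, half)]
    padded = np.pad(data, pad, mode="reflect")
    length = padded.shape[-1]
    nfft = sfft.next_fast_len(length + n_taps - 1)
    kern = kernel.astype(padded.dtype, copy=False)
    spec = sfft.rfft(padded, n=nfft, axis=-1)
    spec *= sfft.rfft(kern, n=nfft)
    full = sfft.irfft(spec, n=nfft, axis=-1)
    # 'valid' part of the linear convolution = delay-compensated output
    return np.ascontiguousarray(full[..., n_taps - 1:length])


def bandpass_filter(epochs: EpochSet, band: tuple[float, float] = (0.5, 25.0),
                    transition_bandwidth: tuple[float, float] | None = (4.5, 6.25),
                    ) -> EpochSet:
    """Zero-phase Hamming-windowed sinc band-pass of every epoch."""
    kernel = design_fir(band, epochs.fs, transition_bandwidth)
    out = epochs.copy(data=apply_fir_zero_phase(epochs.data, kernel))
    out.provenance.append(f"filter[{band[0]}-{band[1]}Hz,n={len(kernel)}]")
    return out


def ica_slot(epochs: EpochSet) -> EpochSet:
    """Placeholder for component-based artifact removal (intentionally a
    no-op: synthetic artifacts are threshold-detectable)."""
    out = epochs.copy()
    out.provenance.append("ica:skipped")
    return out


def crop(epochs: EpochSet, window: tuple[float, float]) -> EpochSet:
    """Restrict epochs to *window* (ms, inclusive endpoints)."""
    t = epochs.time_axis
    sel = (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9)
    if not sel.any():
        raise ValueError(f"crop window {window} outside epoch span "
                         f"({t[0]}..{t[-1]} ms)")
    out = epochs.copy(data=epochs.data[:, :, sel], time_axis=t[sel])
    out.provenance.append(f"crop[{window[0]}..{window[1]}ms]")
    return out


def reject_artifacts(epochs: EpochSet, threshold: float = 80.0,
                     window: tuple[float, float] | None = None,
                     ) -> tuple[EpochSet, pd.DataFrame]:
    """Flag epochs whose absolute voltage exceeds *threshold* anywhere.

    Non-destructive: data are kept, only the ``retained`` flags change.
    Returns the flagged EpochSet and a rejection log (one row per rejected
    epoch: index, peak voltage, channel of the peak).
    """
    t = epochs.time_axis
    if window is None:
        sel = np.ones(len(t), dtype=bool)
    else:
        sel = (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9)
        if not sel.any():
            raise ValueError(f"rejection window {window} outside epoch span")
    absdata = np.abs(epochs.data[:, :, sel])
    peak = absdata.max(axis=(1, 2))
    bad = peak > threshold
    rows = []
    for i in np.flatnonzero(bad):
        ch, _ = np.unravel_index(np.argmax(absdata[i]), absdata[i].shape)
        rows.append((epochs.participant_id, epochs.condition, int(i),
                     float(peak[i]), epochs.channels[ch]))
    log = pd.DataFrame(rows, columns=["participant", "condition",
                                      "epoch_index", "peak_uV", "channel"])
    out = epochs.copy(retained=epochs.retained & ~bad)
    out.provenance.append(f"reject[{threshold}uV,n={int(bad.sum())}]")
    return out, log


def baseline_correct(epochs: EpochSet,
                     baseline_window: tuple[float, float] = (-200.0, 0.0),
                     ) -> EpochSet:
    """Subtract each epoch's per-channel mean over the baseline window."""
    t = epochs.time_axis
    sel = (t >= baseline_window[0] - 1e-9) & (t <= baseline_window[1] + 1e-9)
    if not sel.any():
        raise ValueError(f"baseline window {baseline_window} contains no "
                         "samples")
    means = epochs.data[:, :, sel].mean(axis=2, keepdims=True)
    out = epochs.copy(data=epochs.data - means)
    out.provenance.append(f"baseline[{baseline_window[0]}..{baseline_window[1]}ms]")
    return out


@dataclass
class InclusionDecision:
    included: bool
    reasons: list[str] = field(default_factory=list)


def check_inclusion(retained_counts: dict[str, int],
                    scheduled_counts: dict[str, int],
                    config: PreprocessConfig) -> InclusionDecision:
    """Gate a participant's decoding eligibility.

    Excluded when any note class retains fewer than ``min_trials_per_class``
    epochs or less than ``min_retention_fraction`` of its scheduled epochs.
    ERP analysis is not affected by this gate.
    """
    reasons = []
    for note, scheduled in scheduled_counts.items():
        kept = retained_counts.get(note, 0)
        if kept > scheduled:
            raise ValueError(f"retained count {kept} exceeds scheduled "
                             f"{scheduled} for note {note}")
        if kept < config.min_trials_per_class:
            reasons.append(f"note {note}: {kept} retained < "
                           f"{config.min_trials_per_class} trial floor")
        if scheduled and kept / scheduled < config.min_retention_fraction:
            reasons.append(f"note {note}: retention {kept}/{scheduled} = "
                           f"{kept / scheduled:.2f} < "
                           f"{config.min_retention_fraction:.2f}")
    return InclusionDecision(included=not reasons, reasons=reasons)


def preprocess_epochs(epochs: EpochSet, config: PreprocessConfig
                      ) -> tuple[EpochSet, pd.DataFrame]:
    """Full stage chain: filter -> ica slot -> crop -> reject -> baseline."""
    if config.band is None:
        out = epochs.copy()
        out.provenance.append("filter:skipped")
    else:
        out = bandpass_filter(epochs, config.band, config.transition_bandwidth)
    out = ica_slot(out)
    out = crop(out, config.analysis_window)
    out, log = reject_artifacts(out, config.rejection_threshold)
    out = baseline_correct(out, config.baseline_window)
    return out, log
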