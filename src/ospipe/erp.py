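"""Event-related potential averaging and component-window measurement.

The component measurement interval is derived from the data: the familiar
and unfamiliar grand averages are combined, the most negative point within a
predefined search range is taken as the peak, and the interval peak +- a
fixed half-width becomes the measurement window.  Window endpoints are
inclusive (99-119 ms at 1000 Hz spans 21 samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import montage
from .simulate import EpochSet


@dataclass
class ERPWaveform:
    data: np.ndarray           # (n_channels, n_samples), uV
    time_axis: np.ndarray      # ms
    n_epochs_averaged: int
    condition: str
    level: str = "participant"  # or "grand"
    channels: tuple[str, ...] = montage.CHANNELS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.n_epochs_averaged < 1:
            raise ValueError("n_epochs_averaged must be >= 1")
        if self.data.shape != (len(self.channels), len(self.time_axis)):
            raise ValueError("data shape does not match channels/time axis")


@dataclass(frozen=True)
class MeasurementWindow:
    lo: float
    hi: float
    peak_latency: float
    polarity: str = "negative"
    at_search_edge: bool = False

    def __post_init__(self) -> None:
        if not self.lo <= self.peak_latency <= self.hi:
            raise ValueError("peak latency outside window")


def average_epochs(epochs: EpochSet, retained_only: bool = True) -> ERPWaveform:
    """Pointwise mean over (retained) epochs."""
    mask = epochs.retained if retained_only else np.ones(epochs.n_epochs, bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no retained epochs to average")
    return ERPWaveform(epochs.data[mask].mean(axis=0), epochs.time_axis.copy(),
                       n, epochs.condition, "participant", epochs.channels)


def grand_average(waveforms: list[ERPWaveform]) -> ERPWaveform:
    """Unweighted mean across participant waveforms (same condition/axis)."""
    if not waveforms:
        raise ValueError("no waveforms to average")
    ref = waveforms[0]
    for w in waveforms[1:]:
        if not np.array_equal(w.time_axis, ref.time_axis):
            raise ValueError("waveforms have mismatched time axes")
    data = np.mean([w.data for w in waveforms], axis=0)
    return ERPWaveform(data, ref.time_axis.copy(), len(waveforms),
                       ref.condition, "grand", ref.channels)


def roi_mean(waveform: ERPWaveform,
             roi: tuple[str, ...] = montage.ROI) -> np.ndarray:
    """Unweighted mean time series over the ROI channels."""
    idx = montage.channel_indices(waveform.channels, roi)
    return waveform.data[idx].mean(axis=0)


def define_oN1_window(
    grand_roi_familiar: np.ndarray,
    grand_roi_unfamiliar: np.ndarray,
    time_axis: np.ndarray,
    search: tuple[float, float] = (50.0, 110.0),
    half_width: float = 10.0,
    polarity: str = "negative",
) -> MeasurementWindow:
    """Peak-plus-half-width rule on the combined (condition-mean) grand average.

    The two condition series are averaged, the extremum of the requested
    polarity is located within *search* (ties broken toward the earliest
    sample), and the window is peak +- half_width.  A flag is raised when the
    peak sits exactly on a search boundary.
    """
    a = np.asarray(grand_roi_familiar, dtype=float)
    b = np.asarray(grand_roi_unfamiliar, dtype=float)
    t = np.asarray(time_axis, dtype=float)
    if a.shape != t.shape or b.shape != t.shape:
        raise ValueError("series and time axis shapes differ")
    combined = (a + b) / 2.0
    sel = (t >= search[0] - 1e-9) & (t <= search[1] + 1e-9)
    if not sel.any():
        raise ValueError(f"search window {search} outside data span")
    seg = combined[sel]
    tseg = t[sel]
    i = int(np.argmin(seg) if polarity == "negative" else np.argmax(seg))
    peak = float(tseg[i])
    edge = i == 0 or i == len(tseg) - 1
    return MeasurementWindow(peak - half_width, peak + half_width, peak,
                             polarity, at_search_edge=edge)


def mean_amplitude(series: np.ndarray, time_axis: np.ndarray,
                   window: MeasurementWindow) -> float:
    """Mean of samples with window.lo <= t <= window.hi (inclusive)."""
    t = np.asarray(time_axis, dtype=float)
    sel = (t >= window.lo - 1e-9) & (t <= window.hi + 1e-9)
    if not sel.any():
        raise ValueError(f"window ({window.lo}, {window.hi}) contains no "
                         "samples")
    return float(np.asarray(series, dtype=float)[sel].mean())


def amplitude_table(rows: list[tuple[str, str, int, float]]) -> pd.DataFrame:
    """Per-participant amplitude table (participant, condition, n, uV)."""
    return pd.DataFrame(rows, columns=["participant", "condition", "n_epochs",
                                       "amplitude_uV"])
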