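"""34-channel 10-20 montage: names, approximate 2D positions, ROI definition.

Positions are the standard azimuthal-equidistant ("topoplot") projection of
10-20 electrode locations onto the unit disc, adequate for building smooth
spatial weight maps and distance-based noise covariance.  They are not
digitized coordinates and carry no forward-model meaning.
"""

from __future__ import annotations

import numpy as np

#: Scalp channels in recording order.
CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz",
    "FC1", "FC2", "FC5", "FC6", "FT9", "FT10",
    "C3", "C4", "T7", "T8", "Cz",
    "CP1", "CP2", "CP5", "CP6", "TP9", "TP10",
    "P3", "P4", "P7", "P8", "Pz",
    "O1", "O2", "Iz", "PO9", "PO10",
)

#: Frontocentral region of interest used for component measurement.
ROI: tuple[str, ...] = ("Fz", "FC1", "FC2", "Cz")

# (x, y) on the unit disc; +y = nasion, +x = right ear.
_POS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.25, 0.78), "Fp2": (0.25, 0.78),
    "F7": (-0.67, 0.49), "F3": (-0.34, 0.41), "Fz": (0.0, 0.40),
    "F4": (0.34, 0.41), "F8": (0.67, 0.49),
    "FT9": (-0.90, 0.28), "FC5": (-0.57, 0.22), "FC1": (-0.20, 0.20),
    "FC2": (0.20, 0.20), "FC6": (0.57, 0.22), "FT10": (0.90, 0.28),
    "T7": (-0.82, 0.0), "C3": (-0.40, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.40, 0.0), "T8": (0.82, 0.0),
    "TP9": (-0.90, -0.28), "CP5": (-0.57, -0.22), "CP1": (-0.20, -0.20),
    "CP2": (0.20, -0.20), "CP6": (0.57, -0.22), "TP10": (0.90, -0.28),
    "P7": (-0.67, -0.49), "P3": (-0.34, -0.41), "Pz": (0.0, -0.40),
    "P4": (0.34, -0.41), "P8": (0.67, -0.49),
    "PO9": (-0.55, -0.72), "PO10": (0.55, -0.72),
    "O1": (-0.25, -0.78), "O2": (0.25, -0.78), "Iz": (0.0, -0.92),
}


def positions(channels: tuple[str, ...] = CHANNELS) -> np.ndarray:
    """Return (n_channels, 2) array of 2D positions in channel order."""
    missing = [c for c in channels if c not in _POS]
    if missing:
        raise KeyError(f"no position for channel(s): {missing}")
    return np.array([_POS[c] for c in channels], dtype=float)


def distance_matrix(channels: tuple[str, ...] = CHANNELS) -> np.ndarray:
    """Pairwise Euclidean distances between channel positions."""
    p = positions(channels)
    diff = p[:, None, :] - p[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


def frontocentral_topography(
    channels: tuple[str, ...] = CHANNELS,
    roi: tuple[str, ...] = ROI,
    center: tuple[float, float] = (0.0, 0.15),
    sigma: float = 0.45,
) -> np.ndarray:
    """Smooth frontocentral weight map, normalized so the ROI mean weight is 1.

    A Gaussian bump centered between Fz and Cz.  With this normalization a
    component of amplitude ``a`` produces an ROI-mean deflection of exactly
    ``a`` at its temporal peak.
    """
    p = positions(channels)
    d2 = ((p - np.asarray(center)) ** 2).sum(axis=1)
    w = np.exp(-d2 / (2.0 * sigma ** 2))
    roi_idx = [channels.index(c) for c in roi]
    return w / w[roi_idx].mean()


def channel_indices(channels: tuple[str, ...], subset: tuple[str, ...]) -> list[int]:
    """Indices of *subset* within *channels*; raises naming missing channels."""
    missing = [c for c in subset if c not in channels]
    if missing:
        raise KeyError(f"channel(s) not in montage: {missing}")
    return [channels.index(c) for c in subset]
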