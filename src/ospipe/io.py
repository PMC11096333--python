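"""Serialization: HDF5 epoch containers with CSV label sidecars.

Layout of the HDF5 file:

* datasets ``data`` (epochs x channels x samples, uV), ``time`` (ms),
  ``labels`` (note strings), ``retained`` (bool);
* attributes ``fs``, ``condition``, ``participant_id``, ``montage``
  (channel names), ``provenance``.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .simulate import EpochSet


def save_epochs(epochs: EpochSet, path: str | Path,
                label_sidecar: bool = True) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip",
                         compression_opts=4)
        f.create_dataset("time", data=epochs.time_axis)
        f.create_dataset("labels",
                         data=np.asarray(epochs.labels, dtype="S4"))
        f.create_dataset("retained", data=epochs.retained)
        f.attrs["fs"] = epochs.fs
        f.attrs["condition"] = epochs.condition
        f.attrs["participant_id"] = epochs.participant_id
        f.attrs["montage"] = list(epochs.channels)
        f.attrs["provenance"] = list(epochs.provenance)
    if label_sidecar:
        pd.DataFrame({
            "epoch_index": np.arange(epochs.n_epochs),
            "label": epochs.labels,
            "retained": epochs.retained,
        }).to_csv(path.with_suffix(".labels.csv"), index=False)


def load_epochs(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            time_axis=f["time"][()],
            labels=f["labels"][()].astype("U4"),
            retained=f["retained"][()].astype(bool),
            fs=float(f.attrs["fs"]),
            condition=str(f.attrs["condition"]),
            participant_id=str(f.attrs["participant_id"]),
            channels=tuple(str(c) for c in f.attrs["montage"]),
            provenance=[str(s) for s in f.attrs["provenance"]],
        )


def write_csv_with_header(df: pd.DataFrame, path: str | Path,
                          header_lines: list[str]) -> None:
    """Write a CSV preceded by ``#``-prefixed provenance comment lines."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_csv_with_header(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
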