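"""Data exchange: HDF5 epoch containers, TSV result tables, FIF adapter.

The native exchange container is a single HDF5 file with named arrays
(``data`` in fT, ``time`` in ms, ``labels`` as UTF-8 strings) plus a JSON
sidecar recording the subject id, units and sample rate.  Result curves and
grids are written as TSV with a JSON metadata sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .simulate import EpochSet

__all__ = [
    "write_epochs",
    "read_epochs",
    "write_table",
    "read_table",
    "epochs_from_fif",
]


def write_epochs(epochs: EpochSet, path: str | Path) -> Path:
    """Write an :class:`EpochSet` as HDF5 + JSON sidecar; returns the path."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip", compression_opts=1)
        f.create_dataset("time", data=epochs.time)
        labels = np.asarray(epochs.condition_labels, dtype=object)
        f.create_dataset("labels", data=labels.astype("S"))
    sidecar = {
        "subject_id": epochs.subject_id,
        "units": "fT",
        "sample_rate_hz": epochs.sample_rate,
        "n_trials": int(epochs.n_trials),
        "n_sensors": int(epochs.n_sensors),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    with h5py.File(path, "r") as f:
        data = f["data"][...]
        time = f["time"][...]
        labels = np.array([s.decode() for s in f["labels"][...]], dtype=object)
    return EpochSet(
        data=data,
        condition_labels=labels,
        time=time,
        subject_id=sidecar["subject_id"],
        sample_rate=float(sidecar["sample_rate_hz"]),
    )


def write_table(df: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> Path:
    """Write a result table as TSV with a JSON metadata sidecar."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    if metadata is not None:
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(metadata, indent=2))
    return path


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return df, meta


def epochs_from_fif(
    path: str | Path,
    condition_labels: np.ndarray | list[str],
    subject_id: str,
    tesla_to_ft: float = 1e15,
) -> EpochSet:
    """Adapter: read sensor epochs from a FIF file into an :class:`EpochSet`.

    ``condition_labels`` must give one condition per epoch (FIF event codes
    do not carry the hue/polarity vocabulary).  Requires ``mne``.
    """
    import mne  # deferred: optional dependency

    epo = mne.read_epochs(str(path), preload=True, verbose="error")
    data = epo.get_data() * tesla_to_ft
    time = epo.times * 1000.0
    labels = np.asarray(condition_labels, dtype=object)
    if len(labels) != data.shape[0]:
        raise ValueError(
            f"{len(labels)} labels for {data.shape[0]} epochs in {path}"
        )
    return EpochSet(
        data=data.astype(np.float32),
        condition_labels=labels,
        time=time,
        subject_id=subject_id,
        sample_rate=float(epo.info["sfreq"]),
    )
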