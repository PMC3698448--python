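"""On-disk formats: NIfTI volumes, montage text, and the epoch container.

Epoch sets are stored as an NPZ archive (data, time axis, channel names,
alignment) with the trial table alongside as TSV, so every piece of metadata
stays greppable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .erp import EpochSet
from .montage import read_montage, write_montage  # re-export  # noqa: F401
from .volumes import read_volume, write_volume  # re-export  # noqa: F401


def save_epochs(epochs: EpochSet, path: str | Path) -> Path:
    path = Path(path)
    np.savez_compressed(
        path,
        data=epochs.data,
        times=epochs.times,
        channels=np.array(epochs.channels),
        alignment=np.array(epochs.alignment),
    )
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    epochs.trials.to_csv(_trials_path(path), sep="\t", index=False)
    return path


def load_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    with np.load(path, allow_pickle=False) as z:
        data = z["data"]
        times = z["times"]
        channels = [str(c) for c in z["channels"]]
        alignment = str(z["alignment"])
    trials = pd.read_csv(_trials_path(path), sep="\t")
    return EpochSet(data=data, times=times, channels=channels, trials=trials, alignment=alignment)


def _trials_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".trials.tsv")
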