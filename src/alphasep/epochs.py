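"""Epoched EEG container and its HDF5 representation.

The universal input to every analysis stage is a trials x channels x samples
tensor with per-trial condition labels, a sampling rate and an ordered channel
list. Epochs are stored in plain HDF5 with datasets ``data``, ``labels``,
``srate``, ``time_zero_s`` and ``channels``, plus an optional ``montage``
group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from .montage import Montage


@dataclass
class EpochSet:
    """Trials x channels x samples EEG tensor with labels.

    Attributes
    ----------
    data
        Signal tensor, shape ``(n_trials, n_channels, n_samples)``.
    srate
        Sampling rate in Hz.
    labels
        Integer condition label per trial.
    channels
        Channel names in data order.
    time_zero_s
        Time (s) of sample 0 relative to the alignment event; sample ``i``
        occurs at ``time_zero_s + i / srate``.
    """

    data: np.ndarray
    srate: float
    labels: np.ndarray
    channels: tuple[str, ...]
    time_zero_s: float = 0.0
    subject_id: str = "S0"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.channels = tuple(self.channels)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.data.shape[0] != self.labels.shape[0]:
            raise ValueError("one label per trial required")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel list does not match data")
        if self.n_trials == 0:
            raise ValueError("empty epoch set")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.time_zero_s + np.arange(self.n_samples) / self.srate

    @property
    def condition_ids(self) -> np.ndarray:
        return np.unique(self.labels)

    def copy_with(self, **changes) -> "EpochSet":
        return replace(self, **changes)


def save_epochs(path, epochs: EpochSet, montage: Montage | None = None) -> None:
    """Write an :class:`EpochSet` (and optionally its montage) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("labels", data=epochs.labels)
        f.create_dataset("srate", data=float(epochs.srate))
        f.create_dataset("time_zero_s", data=float(epochs.time_zero_s))
        f.create_dataset("channels", data=np.array(epochs.channels, dtype="S"))
        f.attrs["subject_id"] = epochs.subject_id
        if montage is not None:
            g = f.create_group("montage")
            for name, group in (
                ("channel_names", montage.channel_names),
                ("left_posterior", montage.left_posterior),
                ("right_posterior", montage.right_posterior),
                ("stim_cluster", montage.stim_cluster),
                ("channel_sides", montage.channel_sides),
            ):
                g.create_dataset(name, data=np.array(group, dtype="S"))


def load_epochs(path) -> tuple[EpochSet, Montage | None]:
    """Read an :class:`EpochSet` (and montage, if present) from HDF5."""
    with h5py.File(path, "r") as f:
        epochs = EpochSet(
            data=f["data"][()],
            srate=float(f["srate"][()]),
            labels=f["labels"][()],
            channels=tuple(c.decode() for c in f["channels"][()]),
            time_zero_s=float(f["time_zero_s"][()]),
            subject_id=str(f.attrs.get("subject_id", "S0")),
        )
        montage = None
        if "montage" in f:
            g = f["montage"]
            decode = lambda k: tuple(c.decode() for c in g[k][()])  # noqa: E731
            montage = Montage(
                channel_names=decode("channel_names"),
                left_posterior=decode("left_posterior"),
                right_posterior=decode("right_posterior"),
                stim_cluster=decode("stim_cluster"),
                channel_sides=decode("channel_sides"),
            )
    return epochs, montage
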