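"""Epoched-recording container and HDF5 persistence.

The :class:`EpochSet` is the pipeline's universal input: one participant's
epoched multi-channel recording (epochs x channels x samples, microvolts)
with a per-epoch condition label -- ``"SE"`` for successfully and ``"UE"``
for unsuccessfully encoded stimuli.  Time 0 is stimulus onset.

On disk a cohort lives in a single HDF5 file with one group per
participant::

    /<participant_id>/
        data       float32, (n_epochs, n_channels, n_samples), microvolts
        times      float64, (n_samples,), seconds relative to stimulus
        condition  variable-length strings, (n_epochs,), "SE" | "UE"
        attrs: sampling_rate (Hz), channels (list of role labels)

Unknown extra attributes are preserved on read and rewritten on write so
containers produced by newer code remain usable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

CONDITIONS = ("SE", "UE")


class FormatError(ValueError):
    """A container is missing a required dataset or attribute."""


@dataclass
class EpochSet:
    """One participant's epoched recording with condition labels."""

    participant_id: str
    channels: tuple[str, ...]
    sampling_rate: float
    times: np.ndarray          # (n_samples,), seconds, 0 = stimulus onset
    data: np.ndarray           # (n_epochs, n_channels, n_samples), microvolts
    condition: np.ndarray      # (n_epochs,), "SE" | "UE"
    extra_attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = tuple(str(c) for c in self.channels)
        self.times = np.asarray(self.times, dtype=float)
        self.data = np.asarray(self.data)
        self.condition = np.asarray(self.condition, dtype=object)
        self.validate()

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, channels, samples)")
        n_ep, n_ch, n_s = self.data.shape
        if n_ch != len(self.channels):
            raise ValueError("channel axis does not match channel labels")
        if self.times.shape != (n_s,):
            raise ValueError("times does not match the sample axis")
        dt = np.diff(self.times)
        if n_s > 1:
            if not np.all(dt > 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.sampling_rate, rtol=1e-6, atol=1e-9):
                raise ValueError("times must be uniform at 1/sampling_rate")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.condition.shape != (n_ep,):
            raise ValueError("condition does not match the epoch axis")
        labels = set(self.condition.tolist())
        if not labels <= set(CONDITIONS):
            raise ValueError(f"condition labels must be in {CONDITIONS}, got {labels}")
        for c in CONDITIONS:
            if np.sum(self.condition == c) < 1:
                raise ValueError(f"at least one epoch per condition required; none for {c}")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def condition_mask(self, condition: str) -> np.ndarray:
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
        return self.condition == condition

    def channel_index(self, role: str) -> int:
        try:
            return self.channels.index(role)
        except ValueError:
            raise KeyError(f"channel role {role!r} not in {self.channels}") from None

    def select_epochs(self, idx: np.ndarray) -> "EpochSet":
        """New EpochSet restricted to the given epoch indices (order kept)."""
        return EpochSet(
            participant_id=self.participant_id,
            channels=self.channels,
            sampling_rate=self.sampling_rate,
            times=self.times,
            data=self.data[idx],
            condition=self.condition[idx],
            extra_attrs=dict(self.extra_attrs),
        )


def write_epoch_container(epoch_sets, path) -> None:
    """Write one EpochSet or a cohort of them to an HDF5 container."""
    if isinstance(epoch_sets, EpochSet):
        epoch_sets = [epoch_sets]
    with h5py.File(path, "w") as f:
        for es in epoch_sets:
            g = f.create_group(es.participant_id)
            g.create_dataset("data", data=es.data.astype(np.float32))
            g.create_dataset("times", data=es.times.astype(np.float64))
            g.create_dataset(
                "condition",
                data=np.asarray(es.condition, dtype=object),
                dtype=h5py.string_dtype(),
            )
            g.attrs["sampling_rate"] = float(es.sampling_rate)
            g.attrs["channels"] = list(es.channels)
            for k, v in es.extra_attrs.items():
                g.attrs[k] = v


def _read_group(g: h5py.Group, pid: str) -> EpochSet:
    for member in ("data", "times", "condition"):
        if member not in g:
            raise FormatError(f"participant {pid!r}: missing dataset {member!r}")
    for attr in ("sampling_rate", "channels"):
        if attr not in g.attrs:
            raise FormatError(f"participant {pid!r}: missing attribute {attr!r}")
    cond = np.array([c.decode() if isinstance(c, bytes) else str(c)
                     for c in g["condition"][()]], dtype=object)
    extra = {k: g.attrs[k] for k in g.attrs if k not in ("sampling_rate", "channels")}
    return EpochSet(
        participant_id=pid,
        channels=tuple(str(c) for c in g.attrs["channels"]),
        sampling_rate=float(g.attrs["sampling_rate"]),
        times=g["times"][()],
        data=g["data"][()],
        condition=cond,
        extra_attrs=extra,
    )


def read_epoch_container(path, participant_id: str | None = None):
    """Read a container; returns a list of EpochSet, or one if an id is given."""
    with h5py.File(path, "r") as f:
        if participant_id is not None:
            if participant_id not in f:
                raise FormatError(f"participant {participant_id!r} not in container")
            return _read_group(f[participant_id], participant_id)
        return [_read_group(f[pid], pid) for pid in sorted(f.keys())]
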