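"""Core data containers for multichannel magnetometer recordings.

A :class:`Recording` is the single currency passed between pipeline stages:
a channels x samples field matrix (tesla) plus per-channel geometry, stimulus
events and artifact-window annotations.  On-disk format is one ``.npy`` array
plus a JSON sidecar holding everything else; an optional FIF export is
available when the ``mne`` ecosystem library is importable, but nothing in
the pipeline requires it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SensorChannel", "Recording", "load_recording"]

AXIS_LABELS = ("radial", "tangential_1", "tangential_2")


@dataclass(frozen=True)
class SensorChannel:
    """One measurement axis of a physical OPM sensor.

    Up to three channels (one radial, two tangential) share a ``sensor_id``:
    the physical housing measures the field along mutually orthogonal axes.

    Parameters
    ----------
    channel_id : str
        Unique channel name, e.g. ``"S03-rad"``.
    sensor_id : str
        Physical housing name; shared by co-located channels.
    position : ndarray, shape (3,)
        Sensitive-cell position in metres, head-centred coordinates.
    orientation : ndarray, shape (3,)
        Unit vector of the measurement axis.
    axis_label : {"radial", "tangential_1", "tangential_2"}
    """

    channel_id: str
    sensor_id: str
    position: np.ndarray
    orientation: np.ndarray
    axis_label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, float))
        object.__setattr__(self, "orientation", np.asarray(self.orientation, float))
        if self.axis_label not in AXIS_LABELS:
            raise ValueError(f"axis_label must be one of {AXIS_LABELS}")
        n = np.linalg.norm(self.orientation)
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"orientation of {self.channel_id} not unit norm: {n}")

    def to_dict(self) -> dict:
        return {
            "channel_id": self.channel_id,
            "sensor_id": self.sensor_id,
            "position": self.position.tolist(),
            "orientation": self.orientation.tolist(),
            "axis_label": self.axis_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SensorChannel":
        return cls(d["channel_id"], d["sensor_id"],
                   np.array(d["position"]), np.array(d["orientation"]),
                   d["axis_label"])


@dataclass
class Recording:
    """Timestamped multichannel field data with geometry and annotations.

    Attributes
    ----------
    sampling_rate : float
        Samples per second (the study system ran at 1200 Hz).
    channels : list of SensorChannel
    data : ndarray, shape (n_channels, n_samples)
        Magnetic field in tesla.
    events : list of (float, str)
        (time in seconds, label) with label in {"tone", "base", "oddball"},
        sorted ascending.
    artifact_windows : list of (float, float)
        Half-open [start, end) windows in seconds flagged as artifactual.
    meta : dict
        Free-form provenance (seed, generator parameters, ground truth).
    """

    sampling_rate: float
    channels: list
    data: np.ndarray
    events: list = field(default_factory=list)
    artifact_windows: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data shape {self.data.shape} inconsistent with "
                f"{len(self.channels)} channels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        self.events = sorted([(float(t), str(lbl)) for t, lbl in self.events])
        dur = self.duration
        for a, b in self.artifact_windows:
            if not (0.0 <= a <= b <= dur + 1e-9):
                raise ValueError(f"artifact window ({a}, {b}) outside [0, {dur}]")
        self.artifact_windows = [(float(a), float(b))
                                 for a, b in self.artifact_windows]

    # -- basic accessors -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def channel_ids(self) -> list:
        return [c.channel_id for c in self.channels]

    def event_times(self, label: str | None = None) -> np.ndarray:
        return np.array([t for t, lbl in self.events
                         if label is None or lbl == label])

    def copy(self, data: np.ndarray | None = None, **overrides) -> "Recording":
        """Shallow-copy metadata, deep-copy (or replace) the data array."""
        kw = dict(
            sampling_rate=self.sampling_rate,
            channels=list(self.channels),
            data=self.data.copy() if data is None else data,
            events=list(self.events),
            artifact_windows=list(self.artifact_windows),
            meta=dict(self.meta),
        )
        kw.update(overrides)
        return Recording(**kw)

    def pick_axis(self, axis_label: str) -> "Recording":
        """Restrict to channels of one measurement axis (e.g. ``"radial"``)."""
        idx = [i for i, c in enumerate(self.channels)
               if c.axis_label == axis_label]
        if not idx:
            raise ValueError(f"no channels with axis_label {axis_label!r}")
        return self.copy(data=self.data[idx].copy(),
                         channels=[self.channels[i] for i in idx])

    # -- persistence -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write ``<path>.npy`` (data) and ``<path>.json`` (sidecar)."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.save(path.with_suffix(".npy"), self.data)
        sidecar = {
            "sampling_rate": self.sampling_rate,
            "channels": [c.to_dict() for c in self.channels],
            "events": [[t, lbl] for t, lbl in self.events],
            "artifact_windows": [list(w) for w in self.artifact_windows],
            "meta": _jsonable(self.meta),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    def to_mne(self):
        """Export to an ``mne.io.RawArray`` (requires the optional mne dep)."""
        import mne  # local import: the pipeline must not require mne

        info = mne.create_info(self.channel_ids(), self.sampling_rate, "mag")
        for ch, sc in zip(info["chs"], self.channels):
            ch["loc"][:3] = sc.position
            ch["loc"][3:6] = sc.orientation
        return mne.io.RawArray(self.data, info, verbose="error")


def load_recording(path: str | Path) -> Recording:
    """Load a Recording written by :meth:`Recording.save`."""
    path = Path(path)
    data = np.load(path.with_suffix(".npy"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return Recording(
        sampling_rate=sidecar["sampling_rate"],
        channels=[SensorChannel.from_dict(d) for d in sidecar["channels"]],
        data=data,
        events=[(t, lbl) for t, lbl in sidecar["events"]],
        artifact_windows=[tuple(w) for w in sidecar["artifact_windows"]],
        meta=sidecar["meta"],
    )


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays so json.dumps accepts them."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
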