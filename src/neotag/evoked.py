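"""Evoked-response analysis: epoching, averaging, and peak metrics.

The evoked paradigm presents tones at 500-600 ms SOA; the analysis epochs
the preprocessed recording from -70 to 500 ms around each tone, rejects
epochs that intersect artifact windows, baseline-corrects on the 70 ms
prestimulus period, and averages within (then across) participants.  For
triaxial sensors the response along the two tangential axes is summarised by
its norm.  Headline metrics are the latency of the across-channel RMS peak,
the peak amplitude at the moment the response's principal component peaks,
and that amplitude's ratio to the baseline standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .layout import match_channels
from .preproc import ArtifactMask
from .recording import Recording

__all__ = [
    "EpochSet",
    "Evoked",
    "EvokedMetrics",
    "make_epochs",
    "baseline_correct",
    "average_epochs",
    "group_average",
    "tangential_norm",
    "evoked_metrics",
]

DEFAULT_WINDOW = (-0.070, 0.500)
DEFAULT_BASELINE = (-0.070, 0.0)


@dataclass
class EpochSet:
    """Windowed trials (trial x channel x time) around stimulus events."""

    epochs: np.ndarray
    sampling_rate: float
    channels: list
    window: tuple = DEFAULT_WINDOW
    baseline: tuple = DEFAULT_BASELINE
    event_times: list = field(default_factory=list)   # kept events, seconds
    n_rejected: int = 0
    axis_mode: str = "per_channel"

    def __post_init__(self) -> None:
        if not (self.window[0] <= self.baseline[0]
                and self.baseline[1] <= self.window[1]):
            raise ValueError("baseline must lie inside the epoch window")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def times(self) -> np.ndarray:
        n = self.epochs.shape[-1]
        return self.window[0] + np.arange(n) / self.sampling_rate


@dataclass
class Evoked:
    """Trial-averaged response (channel x time)."""

    mean: np.ndarray
    sampling_rate: float
    channels: list
    window: tuple = DEFAULT_WINDOW
    baseline: tuple = DEFAULT_BASELINE
    n_epochs: int = 0
    axis_mode: str = "per_channel"

    @property
    def times(self) -> np.ndarray:
        n = self.mean.shape[-1]
        return self.window[0] + np.arange(n) / self.sampling_rate

    def rms(self) -> np.ndarray:
        """Root-mean-square across channels at each time point."""
        return np.sqrt(np.mean(self.mean**2, axis=0))


@dataclass
class EvokedMetrics:
    """Peak latency (s), amplitude (T) and amplitude/baseline-sd SNR."""

    peak_latency: float | None
    amplitude: float | None
    snr: float | None
    peak_channel: int | None = None


# --------------------------------------------------------------------------

def make_epochs(recording: Recording, mask: ArtifactMask | None = None,
                window: tuple = DEFAULT_WINDOW,
                baseline: tuple = DEFAULT_BASELINE,
                label: str | None = None) -> EpochSet:
    """One epoch per event whose window fits inside the recording.

    Epochs overlapping the (already extended) artifact mask are rejected;
    kept + rejected equals the number of events with full windows.
    """
    fs = recording.sampling_rate
    i_lo = int(round(window[0] * fs))
    i_hi = int(round(window[1] * fs))
    sample_mask = (mask.sample_mask(recording.n_samples, fs)
                   if mask is not None else
                   np.zeros(recording.n_samples, bool))
    bad_cum = np.r_[0, np.cumsum(sample_mask)]

    kept, kept_times, rejected = [], [], 0
    for t, lbl in recording.events:
        if label is not None and lbl != label:
            continue
        i0 = int(round(t * fs))
        a, b = i0 + i_lo, i0 + i_hi
        if a < 0 or b > recording.n_samples:
            continue
        if bad_cum[b] - bad_cum[a] > 0:
            rejected += 1
            continue
        kept.append(recording.data[:, a:b])
        kept_times.append(t)
    if not kept:
        warnings.warn("all epochs rejected or no events in range")
        epochs = np.zeros((0, recording.n_channels, i_hi - i_lo))
    else:
        epochs = np.stack(kept)
    return EpochSet(epochs=epochs, sampling_rate=fs,
                    channels=list(recording.channels), window=window,
                    baseline=baseline, event_times=kept_times,
                    n_rejected=rejected)


def baseline_correct(eset: EpochSet) -> EpochSet:
    """Subtract each epoch-channel's mean over the prestimulus baseline."""
    t = eset.times
    sel = (t >= eset.baseline[0]) & (t < eset.baseline[1])
    if not sel.any():
        raise ValueError("baseline interval contains no samples")
    corrected = eset.epochs - eset.epochs[..., sel].mean(axis=-1,
                                                         keepdims=True)
    return EpochSet(epochs=corrected, sampling_rate=eset.sampling_rate,
                    channels=eset.channels, window=eset.window,
                    baseline=eset.baseline, event_times=eset.event_times,
                    n_rejected=eset.n_rejected, axis_mode=eset.axis_mode)


def average_epochs(eset: EpochSet) -> Evoked:
    """Arithmetic mean across trials (one participant's evoked response)."""
    if eset.n_epochs == 0:
        raise ValueError("cannot average an empty epoch set")
    return Evoked(mean=eset.epochs.mean(axis=0),
                  sampling_rate=eset.sampling_rate, channels=eset.channels,
                  window=eset.window, baseline=eset.baseline,
                  n_epochs=eset.n_epochs, axis_mode=eset.axis_mode)


def group_average(evokeds: list, template_channels=None) -> Evoked:
    """Across-participant mean on a shared template layout.

    Channels are matched to the template (first participant's montage by
    default) by optimal assignment on 2D-projected positions; the result is
    invariant to participant order.
    """
    if not evokeds:
        raise ValueError("no evoked responses to average")
    template = list(template_channels) if template_channels is not None \
        else list(evokeds[0].channels)
    n_t = evokeds[0].mean.shape[-1]
    acc = np.zeros((len(template), n_t))
    cnt = np.zeros((len(template), 1))
    for ev in evokeds:
        idx = match_channels(template, ev.channels)
        for t, p in enumerate(idx):
            if p >= 0:
                acc[t] += ev.mean[p]
                cnt[t] += 1
    cnt[cnt == 0] = np.nan
    return Evoked(mean=acc / cnt, sampling_rate=evokeds[0].sampling_rate,
                  channels=template, window=evokeds[0].window,
                  baseline=evokeds[0].baseline,
                  n_epochs=sum(e.n_epochs for e in evokeds),
                  axis_mode=evokeds[0].axis_mode)


def _combine_tangential(data: np.ndarray, channels: list):
    """sqrt(t1^2 + t2^2) per sensor; data indexed (..., channel, time)."""
    by_sensor: dict = {}
    for i, ch in enumerate(channels):
        if ch.axis_label in ("tangential_1", "tangential_2"):
            by_sensor.setdefault(ch.sensor_id, {})[ch.axis_label] = i
    pairs = [(v["tangential_1"], v["tangential_2"])
             for sid, v in sorted(by_sensor.items()) if len(v) == 2]
    if not pairs:
        raise ValueError("no sensor has both tangential channels")
    i1, i2 = np.array(pairs).T
    out_channels = [channels[i] for i in i1]
    return np.hypot(np.take(data, i1, axis=-2),
                    np.take(data, i2, axis=-2)), out_channels


def tangential_norm(obj):
    """Per-sensor norm of the two tangential axes (Evoked or EpochSet).

    Computed at the individual level before any group averaging; the result
    is non-negative and invariant to rotations of the tangential frame.
    """
    if isinstance(obj, Evoked):
        data, chans = _combine_tangential(obj.mean, obj.channels)
        return Evoked(mean=data, sampling_rate=obj.sampling_rate,
                      channels=chans, window=obj.window,
                      baseline=obj.baseline, n_epochs=obj.n_epochs,
                      axis_mode="tangential_norm")
    if isinstance(obj, EpochSet):
        data, chans = _combine_tangential(obj.epochs, obj.channels)
        return EpochSet(epochs=data, sampling_rate=obj.sampling_rate,
                        channels=chans, window=obj.window,
                        baseline=obj.baseline, event_times=obj.event_times,
                        n_rejected=obj.n_rejected,
                        axis_mode="tangential_norm")
    raise TypeError("expected Evoked or EpochSet")


def evoked_metrics(evoked: Evoked,
                   peak_method: str = "pc") -> EvokedMetrics:
    """Peak latency, amplitude and baseline-referenced SNR of a response.

    * latency: argmax of the across-channel RMS within the poststimulus
      interval (0, window end];
    * amplitude: the largest absolute channel value at the moment t* where
      the response's first spatial principal component's time course peaks
      (``peak_method="pc"``), or at the RMS peak (``peak_method="rms"``);
    * snr: amplitude divided by that same channel's standard deviation over
      the baseline period (scale-invariant).

    An all-zero response has no defined peak: all fields are None.
    """
    t = evoked.times
    post = t > 0
    if not np.any(np.abs(evoked.mean) > 0):
        return EvokedMetrics(None, None, None)

    rms = evoked.rms()
    peak_latency = float(t[post][np.argmax(rms[post])])

    if peak_method == "pc":
        u, _, _ = np.linalg.svd(evoked.mean, full_matrices=False)
        score = u[:, 0] @ evoked.mean           # time course of spatial PC1
        t_star = float(t[post][np.argmax(np.abs(score[post]))])
    elif peak_method == "rms":
        t_star = peak_latency
    else:
        raise ValueError("peak_method must be 'pc' or 'rms'")
    j = int(np.argmin(np.abs(t - t_star)))
    ch = int(np.argmax(np.abs(evoked.mean[:, j])))
    amplitude = float(np.abs(evoked.mean[ch, j]))

    base = (t >= evoked.baseline[0]) & (t < evoked.baseline[1])
    sd = float(evoked.mean[ch, base].std())
    snr = amplitude / sd if sd > 0 else float("inf")
    return EvokedMetrics(peak_latency=peak_latency, amplitude=amplitude,
                         snr=snr, peak_channel=ch)
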