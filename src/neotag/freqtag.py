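"""Frequency-tagging analysis: oddball-locked epochs and the spectral SNR.

The oddball paradigm presents tones at a steady base rate (3 Hz) with every
fourth tone an oddball, so a brain that detects the change produces spectral
lines at the oddball frequency (0.75 Hz) and its harmonics on top of the
base-rate lines.  The analysis chain:

1. cut artifact-free 20 s epochs starting at oddball tones (all epochs then
   share the stimulus phase, so stimulus-locked components add coherently);
2. FFT each epoch and average the complex coefficients across epochs —
   coherent components survive, noise power drops as 1/n;
3. power = squared magnitude of the averaged coefficients;
4. SNR of each bin = its power divided by the mean power of the flanking
   bins 0.1-0.4 Hz away on both sides (at the 0.05 Hz grid of a 20 s epoch:
   7 bins per side, endpoints inclusive).

The SNR is the headline statistic: ~1 where there is no narrowband signal,
regardless of the noise floor's colour, and scale-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layout import match_channels
from .preproc import ArtifactMask
from .recording import Recording

__all__ = [
    "FourierSet",
    "SpectrumSNR",
    "oddball_epochs",
    "fft_epochs",
    "average_coefficients",
    "spectrum_snr",
    "power_and_snr",
    "tangential_snr",
    "group_average_snr",
]

FREQUENCIES_OF_INTEREST = (0.75, 1.5, 3.0)


@dataclass
class FourierSet:
    """Complex Fourier coefficients of stimulus-locked epochs.

    ``coefficients`` has shape (n_epochs, n_channels, n_bins), from an
    unnormalised real FFT (numpy ``rfft`` convention, recorded in ``meta``);
    ``freq_grid`` spacing is exactly 1/epoch_length (0.05 Hz for 20 s).
    """

    coefficients: np.ndarray
    freq_grid: np.ndarray
    sampling_rate: float
    epoch_length: float
    channels: list
    epoch_starts: list = field(default_factory=list)
    n_rejected: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return self.coefficients.shape[0]


@dataclass
class SpectrumSNR:
    """Per-channel power spectrum and its flanking-bin SNR.

    ``valid`` flags bins whose flanks fit entirely inside the grid; the SNR
    elsewhere is NaN rather than extrapolated.  A zero-power flank yields
    ``snr = +inf`` (kept distinct from NaN).
    """

    freqs: np.ndarray
    power: np.ndarray                    # (n_channels, n_bins)
    snr: np.ndarray
    valid: np.ndarray                    # (n_bins,) bool
    channels: list
    axis_mode: str = "per_channel"
    frequencies_of_interest: tuple = FREQUENCIES_OF_INTEREST
    flank_exclude: float = 0.1
    flank_extent: float = 0.4

    def at(self, freq: float, channel: int | None = None):
        """SNR at the grid bin nearest ``freq`` (per channel or max)."""
        i = int(np.argmin(np.abs(self.freqs - freq)))
        col = self.snr[:, i]
        return float(col[channel]) if channel is not None else col


# --------------------------------------------------------------------------
# epoching & averaging
# --------------------------------------------------------------------------

def oddball_epochs(recording: Recording, mask: ArtifactMask | None = None,
                   length: float = 20.0) -> FourierSet:
    """Artifact-free, non-overlapping epochs starting at oddball events.

    Candidates are taken at every oddball event whose ``length``-second
    window fits inside the recording; windows intersecting the mask are
    skipped; of the survivors a greedy non-overlapping selection is made in
    time order from the recording start.  Returns the FFT of each epoch.
    """
    fs = recording.sampling_rate
    n_len = int(round(length * fs))
    sample_mask = (mask.sample_mask(recording.n_samples, fs)
                   if mask is not None else
                   np.zeros(recording.n_samples, bool))
    bad_cum = np.r_[0, np.cumsum(sample_mask)]

    starts, rejected = [], 0
    last_end = -1
    for t in recording.event_times("oddball"):
        i0 = int(round(t * fs))
        if i0 + n_len > recording.n_samples:
            continue
        if bad_cum[i0 + n_len] - bad_cum[i0] > 0:
            rejected += 1
            continue
        if i0 < last_end:
            continue                        # overlaps an accepted epoch
        starts.append(i0)
        last_end = i0 + n_len
    epochs = np.stack([recording.data[:, i0:i0 + n_len] for i0 in starts]) \
        if starts else np.zeros((0, recording.n_channels, n_len))
    return fft_epochs(epochs, fs, recording.channels,
                      epoch_starts=[i0 / fs for i0 in starts],
                      n_rejected=rejected)


def fft_epochs(epochs: np.ndarray, sampling_rate: float, channels,
               epoch_starts=(), n_rejected: int = 0) -> FourierSet:
    """Unnormalised real FFT of (n_epochs, n_channels, n_samples) epochs."""
    n_len = epochs.shape[-1]
    coeffs = np.fft.rfft(epochs, axis=-1)
    return FourierSet(
        coefficients=coeffs,
        freq_grid=np.fft.rfftfreq(n_len, 1.0 / sampling_rate),
        sampling_rate=sampling_rate,
        epoch_length=n_len / sampling_rate,
        channels=list(channels),
        epoch_starts=list(epoch_starts),
        n_rejected=n_rejected,
        meta={"fft_convention": "numpy rfft, unnormalised"},
    )


def average_coefficients(fset: FourierSet) -> np.ndarray:
    """Arithmetic mean of the complex coefficients across epochs.

    Stimulus-locked components share their phase across epochs and add
    coherently; incoherent noise power falls as 1/n_epochs.
    """
    if fset.n_epochs == 0:
        raise ValueError("no epochs to average")
    return fset.coefficients.mean(axis=0)


# --------------------------------------------------------------------------
# SNR
# --------------------------------------------------------------------------

def spectrum_snr(power: np.ndarray, freqs: np.ndarray,
                 flank_exclude: float = 0.1, flank_extent: float = 0.4):
    """Flanking-bin SNR of a power spectrum on a uniform frequency grid.

    ``snr[f] = power[f] / mean(power[g] for 0.1 <= |g - f| <= 0.4 Hz)``,
    endpoints inclusive.  Returns ``(snr, valid)`` where invalid bins (flanks
    extending off the grid) are NaN.
    """
    power = np.atleast_2d(power)
    df = freqs[1] - freqs[0]
    k_lo = int(np.ceil(flank_exclude / df - 1e-9))
    k_hi = int(np.floor(flank_extent / df + 1e-9))
    if k_hi < k_lo:
        raise ValueError("flank interval narrower than the grid spacing")
    offsets = np.arange(k_lo, k_hi + 1)
    n_bins = power.shape[1]
    acc = np.zeros_like(power)
    for k in offsets:
        acc[:, k:] += power[:, :n_bins - k]
        acc[:, :n_bins - k] += power[:, k:]
    valid = np.zeros(n_bins, bool)
    valid[k_hi:n_bins - k_hi] = True
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = power / (acc / (2 * len(offsets)))
    snr[:, ~valid] = np.nan
    return snr, valid


def power_and_snr(avg_coefficients: np.ndarray, freq_grid: np.ndarray,
                  channels, flank_exclude: float = 0.1,
                  flank_extent: float = 0.4) -> SpectrumSNR:
    """Power spectrum (squared magnitude) and its flanking-bin SNR."""
    power = np.abs(np.atleast_2d(avg_coefficients)) ** 2
    snr, valid = spectrum_snr(power, freq_grid, flank_exclude, flank_extent)
    return SpectrumSNR(freqs=freq_grid, power=power, snr=snr, valid=valid,
                       channels=list(channels),
                       flank_exclude=flank_exclude,
                       flank_extent=flank_extent)


def tangential_snr(spec: SpectrumSNR) -> SpectrumSNR:
    """Per-sensor norm of the SNRs of the two tangential axes.

    Note the order of operations: this is the norm of SNRs, not the SNR of a
    normed field.  Only sensors carrying both tangential channels enter the
    result; the two flat-noise axes combine to a baseline of sqrt(2).
    ``power`` rows carry the norm of the axis powers for bookkeeping only.
    """
    by_sensor: dict = {}
    for i, ch in enumerate(spec.channels):
        if ch.axis_label in ("tangential_1", "tangential_2"):
            by_sensor.setdefault(ch.sensor_id, {})[ch.axis_label] = i
    rows, out_channels = [], []
    for sid in sorted(by_sensor):
        axes = by_sensor[sid]
        if len(axes) == 2:
            rows.append((axes["tangential_1"], axes["tangential_2"]))
            out_channels.append(spec.channels[axes["tangential_1"]])
    if not rows:
        raise ValueError("no sensor has both tangential channels")
    i1, i2 = np.array(rows).T
    return SpectrumSNR(
        freqs=spec.freqs,
        power=np.hypot(spec.power[i1], spec.power[i2]),
        snr=np.hypot(spec.snr[i1], spec.snr[i2]),
        valid=spec.valid, channels=out_channels,
        axis_mode="tangential_norm",
        flank_exclude=spec.flank_exclude, flank_extent=spec.flank_extent)


def group_average_snr(specs: list, template_channels=None) -> SpectrumSNR:
    """Arithmetic mean of individual SNR spectra across participants.

    SNR (not power) is averaged, matching each participant's channels to a
    shared template layout (the first participant's by default) by optimal
    2D-projected assignment.  Participant order does not matter.
    """
    if not specs:
        raise ValueError("no spectra to average")
    template = list(template_channels) if template_channels is not None \
        else list(specs[0].channels)
    n_bins = len(specs[0].freqs)
    acc = np.zeros((len(template), n_bins))
    cnt = np.zeros((len(template), 1))
    for spec in specs:
        idx = match_channels(template, spec.channels)
        for t, p in enumerate(idx):
            if p >= 0:
                acc[t] += spec.snr[p]
                cnt[t] += 1
    cnt[cnt == 0] = np.nan
    return SpectrumSNR(
        freqs=specs[0].freqs, power=np.full_like(acc, np.nan),
        snr=acc / cnt, valid=specs[0].valid, channels=template,
        axis_mode=specs[0].axis_mode,
        flank_exclude=specs[0].flank_exclude,
        flank_extent=specs[0].flank_extent)
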