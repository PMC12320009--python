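"""Preprocessing chain for wearable-magnetometer recordings.

The stages mirror what newborn OPM data needs before any evoked or spectral
analysis, in the order the pipeline applies them:

1. heartbeat-component removal by ICA (fitted on artifact-free, 1-40 Hz
   band-passed data; components flagged by a flanking-bin spectral SNR rule);
2. artifact-window linear interpolation, then zero-phase band-pass and notch
   filtering (interpolating first avoids filter ringing at artifact edges);
3. robust z-score sample rejection (threshold 5 on 1-s-smoothed amplitude)
   and 1.5 s window extension;
4. projection of the first principal components of the artifact-free data
   (removes the large-scale ambient-field residuals that dominate wearable
   arrays).

All operations take and return :class:`~neotag.recording.Recording`; masks
travel as :class:`ArtifactMask` (merged half-open windows in seconds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .recording import Recording

__all__ = [
    "ArtifactMask",
    "ComponentDecomposition",
    "interpolate_artifacts",
    "bandpass",
    "notch",
    "detect_noise_peaks",
    "robust_zscore_reject",
    "extend_windows",
    "project_out_pcs",
    "remove_heartbeat_components",
    "estimate_heart_rate_ranges",
]

MAD_SCALE = 1.4826  # consistency constant: MAD -> sd for Gaussian data


def _merge_windows(windows):
    """Sort and merge overlapping/touching (start, end) windows."""
    out = []
    for a, b in sorted((float(a), float(b)) for a, b in windows):
        if b <= a:
            continue
        if out and a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [tuple(w) for w in out]


@dataclass
class ArtifactMask:
    """Half-open artifact windows [start, end) in seconds, merged."""

    windows: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.windows = _merge_windows(self.windows)

    def sample_mask(self, n_samples: int, fs: float) -> np.ndarray:
        m = np.zeros(n_samples, bool)
        for a, b in self.windows:
            m[max(int(np.floor(a * fs)), 0):
              min(int(np.ceil(b * fs)), n_samples)] = True
        return m

    def union(self, other: "ArtifactMask") -> "ArtifactMask":
        return ArtifactMask(self.windows + other.windows)

    def total_duration(self) -> float:
        return sum(b - a for a, b in self.windows)

    @classmethod
    def from_sample_mask(cls, m: np.ndarray, fs: float) -> "ArtifactMask":
        m = np.asarray(m, bool)
        if not m.any():
            return cls([])
        d = np.diff(m.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if m[0]:
            starts = np.r_[0, starts]
        if m[-1]:
            ends = np.r_[ends, len(m)]
        return cls([(s / fs, e / fs) for s, e in zip(starts, ends)])


@dataclass
class ComponentDecomposition:
    """Linear unmixing result plus the bookkeeping of removed components."""

    mixing: np.ndarray                   # channels x components
    sources: np.ndarray                  # components x fit-samples
    mean: np.ndarray                     # channel means of the fit data
    method: str
    component_power: np.ndarray          # components x frequency bins
    freq_grid: np.ndarray
    removed_components: list = field(default_factory=list)


# --------------------------------------------------------------------------
# windows & interpolation
# --------------------------------------------------------------------------

def interpolate_artifacts(recording: Recording,
                          mask: ArtifactMask) -> Recording:
    """Replace data inside artifact windows by straight lines.

    Each channel's samples inside a window are replaced by the line joining
    the last pre-window and first post-window samples; windows touching a
    recording edge hold the nearest valid value instead of extrapolating.
    Applying twice is a no-op.
    """
    out = recording.copy()
    fs = recording.sampling_rate
    n = recording.n_samples
    for a, b in mask.windows:
        i0 = max(int(np.floor(a * fs)), 0)
        i1 = min(int(np.ceil(b * fs)), n)
        if i1 <= i0:
            continue
        left = i0 - 1
        right = i1
        idx = np.arange(i0, i1)
        if left < 0 and right >= n:
            out.data[:, i0:i1] = 0.0
        elif left < 0:
            out.data[:, i0:i1] = out.data[:, right][:, None]
        elif right >= n:
            out.data[:, i0:i1] = out.data[:, left][:, None]
        else:
            frac = (idx - left) / (right - left)
            out.data[:, i0:i1] = (out.data[:, left][:, None]
                                  + np.outer(out.data[:, right]
                                             - out.data[:, left], frac))
    return out


def extend_windows(mask: ArtifactMask, pad: float = 1.5,
                   duration: float | None = None) -> ArtifactMask:
    """Grow each window by ``pad`` seconds on both sides, clip and merge."""
    win = [(a - pad, b + pad) for a, b in mask.windows]
    win = [(max(a, 0.0), b if duration is None else min(b, duration))
           for a, b in win]
    return ArtifactMask(win)


# --------------------------------------------------------------------------
# filtering
# --------------------------------------------------------------------------

def bandpass(recording: Recording, low: float, high: float,
             hp_order: int = 4, lp_order: int = 12) -> Recording:
    """Zero-phase Butterworth band-pass (applied forward-backward).

    Implemented as a high-pass / low-pass cascade with asymmetric orders:
    the low edge only needs to kill DC and drift (order 4 suffices), while
    the high edge must attenuate 50 Hz mains by > 40 dB with a passband
    topping out at 40 Hz, which requires the steeper order-12 rolloff.
    Zero phase matters here: response latencies are headline outputs, and a
    causal filter would delay them.
    """
    nyq = recording.sampling_rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"need 0 < low < high < Nyquist ({nyq} Hz)")
    sos_hp = signal.butter(hp_order, low, btype="highpass", output="sos",
                           fs=recording.sampling_rate)
    sos_lp = signal.butter(lp_order, high, btype="lowpass", output="sos",
                           fs=recording.sampling_rate)
    n = recording.n_samples
    # pad by a few filter time constants: scipy's default padding is far
    # too short for sub-hertz high-pass corners and leaves slow transients
    lp_pad = min(n - 1, int(10 * recording.sampling_rate / high))
    hp_pad = min(n - 1, int(3 * recording.sampling_rate / low))
    data = signal.sosfiltfilt(sos_lp, recording.data, axis=1, padlen=lp_pad)
    data = signal.sosfiltfilt(sos_hp, data, axis=1, padlen=hp_pad)
    return recording.copy(data=data)


def notch(recording: Recording, freqs, q: float = 30.0) -> Recording:
    """Zero-phase IIR notch at each frequency in ``freqs`` (quality Q=30)."""
    data = recording.data.copy()
    for f0 in np.atleast_1d(freqs):
        b, a = signal.iirnotch(float(f0), q, fs=recording.sampling_rate)
        data = signal.filtfilt(b, a, data, axis=1)
    return recording.copy(data=data)


def detect_noise_peaks(recording: Recording, band=(13.0, 40.0),
                       factor: float = 10.0, resolution: float = 0.25,
                       baseline_halfwidth: float = 2.0) -> list:
    """Frequencies of narrowband noise peaks within ``band``.

    The median-across-channels Welch power spectrum is compared with a local
    median-smoothed baseline (window ±``baseline_halfwidth`` Hz); contiguous
    runs of bins exceeding ``factor`` x baseline are reported by their peak
    bin.  Automates the by-eye identification of line-noise peaks that
    precedes notch filtering.
    """
    fs = recording.sampling_rate
    nperseg = min(int(round(fs / resolution)), recording.n_samples)
    f, pxx = signal.welch(recording.data, fs=fs, nperseg=nperseg, axis=1)
    med = np.median(pxx, axis=0)
    k = max(int(round(baseline_halfwidth / (f[1] - f[0]))) * 2 + 1, 3)
    pad = k // 2
    padded = np.r_[med[pad:0:-1], med, med[-2:-pad - 2:-1]]
    baseline = np.array([np.median(padded[i:i + k]) for i in range(len(med))])
    in_band = (f >= band[0]) & (f <= band[1])
    hot = in_band & (med > factor * baseline)
    peaks = []
    i = 0
    while i < len(hot):
        if hot[i]:
            j = i
            while j + 1 < len(hot) and hot[j + 1]:
                j += 1
            seg = slice(i, j + 1)
            peaks.append(float(f[seg][np.argmax(med[seg])]))
            i = j + 1
        else:
            i += 1
    return peaks


# --------------------------------------------------------------------------
# sample rejection
# --------------------------------------------------------------------------

def robust_zscore_reject(recording: Recording, threshold: float = 5.0,
                         smooth_window: float = 1.0) -> ArtifactMask:
    """Channel-wise robust z-score rejection of high-amplitude samples.

    Per channel, the amplitude |x| is smoothed with a ``smooth_window``-long
    square (moving-average) window, robust-standardised as
    ``z = (a - median) / (1.4826 * MAD)``, and samples with z > threshold on
    ANY channel are masked.  Channels with zero MAD (constant amplitude)
    contribute no rejections.
    """
    fs = recording.sampling_rate
    w = max(int(round(smooth_window * fs)), 1)
    kernel = np.ones(w) / w
    bad = np.zeros(recording.n_samples, bool)
    if not np.isfinite(threshold):
        return ArtifactMask([])
    for x in recording.data:
        a = np.convolve(np.abs(x), kernel, mode="same")
        med = np.median(a)
        mad = np.median(np.abs(a - med))
        if mad == 0:
            continue
        z = (a - med) / (MAD_SCALE * mad)
        bad |= z > threshold
    return ArtifactMask.from_sample_mask(bad, fs)


# --------------------------------------------------------------------------
# spatial projections
# --------------------------------------------------------------------------

def project_out_pcs(recording: Recording, mask: ArtifactMask | None = None,
                    n: int = 3) -> Recording:
    """Project out the top spatial principal components of artifact-free data.

    The PCs are computed from the channel covariance of mask-excluded samples
    only; the projector ``I - U U^T`` is then applied to ALL samples.  Output
    variance along the removed subspace is zero on the fitting samples by
    construction.  ``n=0`` is the identity.
    """
    if n == 0:
        return recording.copy()
    if n >= recording.n_channels:
        raise ValueError("n must be smaller than the channel count")
    good = np.ones(recording.n_samples, bool)
    if mask is not None:
        good &= ~mask.sample_mask(recording.n_samples,
                                  recording.sampling_rate)
    if good.sum() < n:
        raise ValueError("not enough artifact-free samples to fit PCs")
    X = recording.data[:, good]
    Xc = X - X.mean(axis=1, keepdims=True)
    cov = Xc @ Xc.T / max(Xc.shape[1] - 1, 1)
    _, vecs = np.linalg.eigh(cov)
    U = vecs[:, -n:]                                  # top-n spatial PCs
    out = recording.copy(data=recording.data - U @ (U.T @ recording.data))
    out.meta = {**out.meta, "projected_pcs": n}
    return out


# --------------------------------------------------------------------------
# heartbeat-component removal (ICA)
# --------------------------------------------------------------------------

def _segment_power_spectrum(x: np.ndarray, fs: float,
                            seg_len: float = 20.0):
    """Power spectrum of a 1-D trace on the tagging frequency grid.

    Consecutive non-overlapping ``seg_len`` (20 s) segments give the 0.05 Hz
    grid used everywhere else; segment POWERS are averaged (coefficient
    averaging would cancel components that are not stimulus-locked, such as
    heartbeats, which is precisely what must be detected here).
    """
    nseg = int(round(seg_len * fs))
    if len(x) < nseg:
        nseg = len(x)
    n_segments = len(x) // nseg
    freqs = np.fft.rfftfreq(nseg, 1.0 / fs)
    power = np.zeros(len(freqs))
    for k in range(n_segments):
        c = np.fft.rfft(x[k * nseg:(k + 1) * nseg])
        power += np.abs(c) ** 2
    return power / max(n_segments, 1), freqs


def remove_heartbeat_components(recording: Recording,
                                mask: ArtifactMask | None = None,
                                heart_ranges=((1.0, 1.5), (2.2, 2.5)),
                                snr_threshold: float = 7.5,
                                exclude_freqs=(),
                                n_components: int | None = None,
                                seed: int = 0, max_retries: int = 5,
                                tol: float = 1e-3, max_iter: int = 1000):
    """Remove heartbeat ICA components by the spectral-SNR rule.

    A FastICA unmixing (non-Gaussianity maximising) is fitted on the
    artifact-free part of the recording band-passed 1-40 Hz.  A component is
    flagged as cardiac when the maximum of its power-spectrum SNR (the
    flanking-bin definition of :mod:`neotag.freqtag`) inside any of the
    ``heart_ranges`` exceeds ``snr_threshold`` (7.5).  Flagged components'
    contributions are subtracted from the full, unfiltered recording.

    ``exclude_freqs`` drops specific bins from the evaluation: in the
    oddball paradigm the stimulus harmonics (1.5 and 2.25 Hz) fall inside
    the parent and newborn heart-rate bands, and a cleanly separated neural
    component would otherwise be mistaken for a heartbeat — a spectral line
    exactly at a stimulus harmonic is evidence of stimulus locking, which
    heartbeats do not have.

    Returns (cleaned Recording, ComponentDecomposition).  Non-convergence is
    retried with fresh seeds up to ``max_retries`` times, then raised.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    from .freqtag import spectrum_snr

    fs = recording.sampling_rate
    filt = bandpass(recording, 1.0, min(40.0, 0.45 * fs))
    good = np.ones(recording.n_samples, bool)
    if mask is not None:
        good &= ~mask.sample_mask(recording.n_samples, fs)
    X = filt.data[:, good].T                           # samples x channels
    n_comp = n_components or min(recording.n_channels, 40)

    # retry schedule: the symmetric (parallel) update can stall when part of
    # the whitened space is near-Gaussian sensor noise with no contrast
    # gradient; one-unit deflation converges reliably there, and shrinking
    # the component count drops the contrast-free directions entirely while
    # keeping the high-variance artifact components
    schedule = [("parallel", n_comp, tol), ("deflation", n_comp, tol),
                ("deflation", max(n_comp // 2, 4), tol),
                ("deflation", max(n_comp // 2, 4), 10 * tol),
                ("deflation", 4, 10 * tol)][:max_retries]
    ica = None
    for attempt, (alg, k, t) in enumerate(schedule):
        cand = FastICA(n_components=k, whiten="unit-variance",
                       algorithm=alg, random_state=seed + attempt,
                       max_iter=max_iter, tol=t)
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always", ConvergenceWarning)
            S_fit = cand.fit_transform(X)
            if not any(issubclass(w.category, ConvergenceWarning)
                       for w in wlist):
                ica = cand
                n_comp = k
                break
    if ica is None:
        raise RuntimeError(
            f"ICA failed to converge in {len(schedule)} seeded attempts")

    A = ica.mixing_                                    # channels x comps
    Wu = ica.components_                               # comps x channels

    # flag by spectral SNR of each fitted component trace in the heart bands
    powers, freqs = [], None
    flagged = []
    for k in range(n_comp):
        p, freqs = _segment_power_spectrum(S_fit[:, k], fs)
        powers.append(p)
        snr, valid = spectrum_snr(p[None, :], freqs)
        allowed = valid.copy()
        df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0
        for f_ex in exclude_freqs:
            allowed &= np.abs(freqs - f_ex) > 0.5 * df
        best = (None, 0.0)
        for lo, hi in heart_ranges:
            sel = (freqs >= lo) & (freqs <= hi) & allowed
            if sel.any():
                i = np.flatnonzero(sel)[np.argmax(snr[0, sel])]
                if snr[0, i] > best[1]:
                    best = (float(freqs[i]), float(snr[0, i]))
        if best[0] is not None and best[1] > snr_threshold:
            flagged.append({"index": k, "peak_freq": best[0],
                            "snr": best[1],
                            "reason": f"heart-band SNR {best[1]:.1f} > "
                                      f"{snr_threshold}"})

    out = recording.copy()
    if flagged:
        idx = [f["index"] for f in flagged]
        centred = recording.data - recording.data.mean(axis=1, keepdims=True)
        S_full = Wu @ centred                          # comps x samples
        out.data = recording.data - A[:, idx] @ S_full[idx]

    decomp = ComponentDecomposition(
        mixing=A, sources=S_fit.T, mean=X.mean(axis=0),
        method="fastica", component_power=np.array(powers),
        freq_grid=freqs, removed_components=flagged)
    return out, decomp


def estimate_heart_rate_ranges(decomp: ComponentDecomposition,
                               half_width: float = 0.15,
                               search_band=(0.8, 3.5)) -> list:
    """Heart-rate frequency ranges from previously flagged components.

    For each removed component, the dominant spectral peak within
    ``search_band`` (0.8-3.5 Hz spans parent to newborn rates) gives a range
    of peak +/- ``half_width`` (0.15 Hz, so a 2.35 Hz newborn heart maps to
    the 2.2-2.5 Hz band).  Overlapping ranges are merged.
    """
    ranges = []
    sel = (decomp.freq_grid >= search_band[0]) & \
          (decomp.freq_grid <= search_band[1])
    for comp in decomp.removed_components:
        p = decomp.component_power[comp["index"]]
        f = decomp.freq_grid[sel][np.argmax(p[sel])]
        ranges.append((float(f - half_width), float(f + half_width)))
    return _merge_windows(ranges)
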