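"""Synthetic newborn OPM-MEG recordings with known ground truth.

Emulates the study conditions this package analyses: ~5-minute recordings at
1200 Hz from a ~27-sensor scalp array (partly triaxial), containing either

* an **evoked paradigm** — tones every 500–600 ms, each eliciting a biphasic
  auditory response peaking ~260 ms poststimulus in bilateral temporal
  sources; or
* an **oddball paradigm** — tones at a steady 3 Hz with every fourth tone an
  oddball (0.75 Hz), eliciting a steady-state response whose period-4
  amplitude modulation puts spectral lines at 0.75 Hz and its harmonics;

plus the nuisance structure wearable magnetometer data actually has:
newborn (~2.2-2.5 Hz) and parent (~1-1.5 Hz) heartbeat artifacts, 1/f and
linear drift, and sparse high-amplitude movement bursts.

Neural fields are injected through the same spherical-conductor forward
model the inverse stage uses (:mod:`neotag.forward`), so every downstream
quantity — epochs, spectra, statistics, source maps — has a known truth
recorded in ``Recording.meta``.

All randomness flows from one seed; per-component sub-streams are derived
deterministically with ``numpy.random.SeedSequence.spawn``, so identical
(config, seed) gives a bit-identical Recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as sstats

from .forward import dipole_field
from .recording import Recording, SensorChannel

__all__ = [
    "SimulationConfig",
    "make_sensor_array",
    "generate_evoked_recording",
    "generate_oddball_recording",
    "add_artifacts",
]


@dataclass
class SimulationConfig:
    """Generator parameters; defaults mirror the emulated study conditions.

    Amplitudes are tesla at the best-coupled channel.  Evoked responses of
    1-month-olds measured a few mm off the scalp are of order 1 pT, OPM white
    noise is tens of fT/sqrt(Hz), and heartbeat artifacts (especially the
    newborn's, directly under the array) reach several pT — the defaults sit
    in those ranges.
    """

    duration: float = 300.0               # s
    sampling_rate: float = 1200.0         # Hz
    head_radius: float = 0.065            # m
    n_sensors: int = 27
    triaxial_count: int = 20
    # evoked paradigm
    soa_range: tuple = (0.5, 0.6)         # s, uniform random
    tone_duration: float = 0.1            # s (incl. fades; event label only)
    fade: float = 0.015                   # s
    evoked_peak_latency: float = 0.26     # s
    evoked_amplitude: float = 1.0e-12     # T at best channel
    # oddball paradigm
    base_rate: float = 3.0                # Hz
    oddball_period: int = 4               # every Nth tone is an oddball
    base_amplitude: float = 0.6e-12       # T, per-tone steady-state response
    oddball_extra_amplitude: float = 0.3e-12  # T, added on oddball tones
    # sources: bilateral temporal dipoles (head-centred, m); orientations are
    # projected onto the local tangential plane (radial dipoles are silent)
    dipole_positions: tuple = ((0.0, 0.042, 0.015), (0.0, -0.042, 0.015))
    dipole_orientations: tuple = ((1.0, 0.0, 0.3), (1.0, 0.0, 0.3))
    # artifacts & noise
    infant_heart_rate: tuple = (2.2, 2.5)  # Hz, range of the per-run rate
    parent_heart_rate: tuple = (1.0, 1.5)
    infant_heart_amplitude: float = 3.0e-12
    parent_heart_amplitude: float = 1.5e-12
    white_noise: float = 0.5e-12          # T rms per sample, per channel
    ambient_field: float = 20.0e-12       # T rms, homogeneous 1/f field
    pink_noise: float = 0.2e-12           # T rms, per-channel 1/f
    drift_amplitude: float = 2.0e-12      # T max linear drift over recording
    burst_rate: float = 2.0               # movement bursts per minute
    burst_amplitude: float = 300.0e-12    # T
    burst_duration: tuple = (0.3, 1.0)    # s
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sampling_rate, self.base_rate, self.duration) <= 0:
            raise ValueError("rates and duration must be positive")
        if self.soa_range[0] > self.soa_range[1]:
            raise ValueError("soa_range must be (lo, hi) with lo <= hi")
        for name in ("evoked_amplitude", "base_amplitude",
                     "oddball_extra_amplitude", "white_noise", "pink_noise",
                     "ambient_field", "infant_heart_amplitude",
                     "parent_heart_amplitude", "burst_amplitude",
                     "drift_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


# --------------------------------------------------------------------------
# sensor array
# --------------------------------------------------------------------------

def _fibonacci_directions(n: int) -> np.ndarray:
    """n near-uniform unit vectors (golden-angle spiral on the sphere)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = np.pi * (1.0 + 5.0**0.5) * i
    s = np.sqrt(1.0 - z**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _tangential_frame(radial: np.ndarray):
    """Two unit tangential axes orthogonal to a radial direction."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(radial @ ref) > 0.99:
        ref = np.array([1.0, 0.0, 0.0])
    t1 = np.cross(ref, radial)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(radial, t1)
    return t1, t2


def make_sensor_array(n_sensors: int = 27, head_radius: float = 0.065,
                      triaxial_count: int = 20, seed: int | None = None,
                      standoff: float = 0.004,
                      min_spacing_deg: float = 10.0) -> list:
    """Place a cap of biaxial/triaxial OPMs on the upper part of the head.

    Candidate directions come from a Fibonacci spiral restricted to the upper
    ~3/4 of the sphere with the occipital patch excluded (the newborn rests
    on the back of the head, so no sensors sit there); ``n_sensors`` are then
    chosen by farthest-point sampling.  Triaxial housings are assigned
    preferentially to lateral (temporal) positions, the rest are biaxial
    (radial + one tangential axis).  Sensors sit ``standoff`` (4 mm) off the
    scalp, the thermal gap of heated-cell OPMs.

    Coordinates: x anterior, y left, z up, origin at the sphere centre.

    Raises
    ------
    ValueError if the requested count cannot be packed at ``min_spacing_deg``
    minimum angular spacing, or triaxial_count is out of range.
    """
    if not 1 <= triaxial_count <= n_sensors:
        raise ValueError("need 1 <= triaxial_count <= n_sensors")
    if head_radius <= 0:
        raise ValueError("head_radius must be positive")
    cand = _fibonacci_directions(max(16 * n_sensors, 256))
    keep = cand[:, 2] > -0.5                       # upper ~3/4 of the sphere
    occipital = (cand[:, 0] < -0.55) & (cand[:, 2] < 0.4)
    cand = cand[keep & ~occipital]

    # farthest-point sampling, deterministically seeded start
    rng = np.random.default_rng(seed)
    start = int(rng.integers(len(cand))) if seed is not None else 0
    chosen = [start]
    dmin = cand @ cand[start]
    for _ in range(n_sensors - 1):
        nxt = int(np.argmin(dmin))                 # smallest cos = farthest
        chosen.append(nxt)
        dmin = np.maximum(dmin, cand @ cand[nxt])
    dirs = cand[chosen]

    if n_sensors > 1:
        cosmat = dirs @ dirs.T
        np.fill_diagonal(cosmat, -1.0)
        if np.degrees(np.arccos(np.clip(cosmat.max(), -1, 1))) < min_spacing_deg:
            raise ValueError(
                f"{n_sensors} sensors cannot be packed at "
                f">= {min_spacing_deg} deg spacing on the allowed cap")

    # triaxial housings go to the most lateral (largest |y|) positions
    order = np.argsort(-np.abs(dirs[:, 1]))
    triaxial = np.zeros(n_sensors, bool)
    triaxial[order[:triaxial_count]] = True

    channels = []
    for k, d in enumerate(dirs):
        sid = f"S{k:02d}"
        pos = d * (head_radius + standoff)
        t1, t2 = _tangential_frame(d)
        channels.append(SensorChannel(f"{sid}-rad", sid, pos, d, "radial"))
        channels.append(SensorChannel(f"{sid}-tan1", sid, pos, t1,
                                      "tangential_1"))
        if triaxial[k]:
            channels.append(SensorChannel(f"{sid}-tan2", sid, pos, t2,
                                          "tangential_2"))
    return channels


# --------------------------------------------------------------------------
# source waveforms
# --------------------------------------------------------------------------

def _biphasic_bump(fs: float, peak_latency: float,
                   length: float = 0.5) -> np.ndarray:
    """Difference-of-Gammas evoked waveform, unit peak at ``peak_latency``.

    The raw difference of two gamma densities (second, opposite-sign lobe
    delayed ~1.7x) is computed once, its argmax located, and the time axis
    rescaled so that the positive peak lands exactly on the requested latency
    (to within one sample).
    """
    t = np.arange(int(round(length * fs))) / fs
    g1 = sstats.gamma.pdf(t, a=6.0, scale=0.26 / 5.0)
    g2 = sstats.gamma.pdf(t, a=9.0, scale=0.44 / 8.0)
    w = g1 / g1.max() - 0.55 * g2 / g2.max()
    t_peak = t[np.argmax(w)]
    w = np.interp(t * (t_peak / peak_latency), t, w, left=0.0, right=0.0)
    return w / w.max()


def _tone_bump(fs: float, width: float = 0.15) -> np.ndarray:
    """Short monophasic bump for per-tone steady-state responses."""
    t = np.arange(int(round(3 * width * fs))) / fs
    w = sstats.gamma.pdf(t, a=4.0, scale=width / 4.0)
    return w / w.max()


def _dipole_topographies(config: SimulationConfig, channels: list):
    """Unit field topography of each configured dipole (tangentialised)."""
    pos = np.array([c.position for c in channels])
    ori = np.array([c.orientation for c in channels])
    centre = np.zeros(3)
    topos = []
    for dp, do in zip(config.dipole_positions, config.dipole_orientations):
        dp = np.asarray(dp, float)
        do = np.asarray(do, float)
        rad = dp / np.linalg.norm(dp)
        do = do - (do @ rad) * rad                 # silent radial part removed
        do /= np.linalg.norm(do)
        topos.append(dipole_field(pos, ori, dp, do, centre))
    return np.array(topos)                         # (n_dipoles, n_channels)


def _inject(topos: np.ndarray, trace: np.ndarray,
            amplitude: float) -> np.ndarray:
    """Project a shared source trace through all dipoles, scaled so a unit
    trace peak gives ``amplitude`` at the best-coupled channel."""
    pattern = topos.sum(axis=0)
    peak = np.abs(pattern).max()
    scale = amplitude / peak if peak > 0 else 0.0
    return (pattern * scale)[:, None] * trace[None, :]


# --------------------------------------------------------------------------
# paradigms
# --------------------------------------------------------------------------

def generate_evoked_recording(config: SimulationConfig,
                              channels: list) -> Recording:
    """Tones at uniform-random SOAs, each driving the bilateral dipoles.

    Ground truth stored in ``meta``: the per-event source waveform, event
    times, and the injection scale per channel.
    """
    if not channels:
        raise ValueError("empty sensor array")
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    ss = np.random.SeedSequence(config.seed)
    rng_evt, rng_noise = [np.random.default_rng(s) for s in ss.spawn(2)]

    bump = _biphasic_bump(fs, config.evoked_peak_latency)
    margin = len(bump) / fs
    t_evt, t = [], config.soa_range[0]
    while t < config.duration - margin:
        t_evt.append(t)
        t += rng_evt.uniform(*config.soa_range)
    if not t_evt:
        raise ValueError("duration too short for a single event")

    trace = np.zeros(n)
    for te in t_evt:
        i0 = int(round(te * fs))
        seg = min(len(bump), n - i0)
        trace[i0:i0 + seg] += bump[:seg]

    topos = _dipole_topographies(config, channels)
    data = _inject(topos, trace, config.evoked_amplitude)
    data += rng_noise.normal(0.0, config.white_noise, data.shape)

    meta = {
        "paradigm": "evoked",
        "seed": config.seed,
        "config": config.to_dict(),
        "source_template": bump.tolist(),
        "evoked_peak_latency": config.evoked_peak_latency,
        "event_times": list(map(float, t_evt)),
    }
    return Recording(fs, channels, data,
                     events=[(te, "tone") for te in t_evt], meta=meta)


def generate_oddball_recording(config: SimulationConfig,
                               channels: list) -> Recording:
    """Exactly periodic tones at ``base_rate``; every Nth is an oddball.

    Each tone elicits a bump of amplitude ``base_amplitude``; oddball tones
    get ``oddball_extra_amplitude`` on top.  The resulting period-4 amplitude
    modulation of the 3 Hz steady state creates spectral lines at the oddball
    frequency (0.75 Hz) and its harmonics on top of the base-rate harmonics.
    """
    if not channels:
        raise ValueError("empty sensor array")
    if config.oddball_period < 2:
        raise ValueError("oddball_period must be >= 2")
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    ss = np.random.SeedSequence(config.seed)
    rng_noise = np.random.default_rng(ss.spawn(1)[0])

    n_tones = int(np.floor(config.duration * config.base_rate))
    t_evt = np.arange(n_tones) / config.base_rate
    is_odd = (np.arange(n_tones) % config.oddball_period
              == config.oddball_period - 1)

    bump = _tone_bump(fs)
    base_trace = np.zeros(n)
    odd_trace = np.zeros(n)
    for te, odd in zip(t_evt, is_odd):
        i0 = int(round(te * fs))
        seg = min(len(bump), n - i0)
        base_trace[i0:i0 + seg] += bump[:seg]
        if odd:
            odd_trace[i0:i0 + seg] += bump[:seg]

    topos = _dipole_topographies(config, channels)
    data = (_inject(topos, base_trace, config.base_amplitude)
            + _inject(topos, odd_trace, config.oddball_extra_amplitude))
    data += rng_noise.normal(0.0, config.white_noise, data.shape)

    events = [(float(te), "oddball" if odd else "base")
              for te, odd in zip(t_evt, is_odd)]
    meta = {
        "paradigm": "oddball",
        "seed": config.seed,
        "config": config.to_dict(),
        "base_amplitude": config.base_amplitude,
        "oddball_extra_amplitude": config.oddball_extra_amplitude,
        "oddball_frequency": config.base_rate / config.oddball_period,
    }
    return Recording(fs, channels, data, events=events, meta=meta)


# --------------------------------------------------------------------------
# artifacts
# --------------------------------------------------------------------------

def _pseudo_ecg(fs: float, duration: float, rate: float, jitter: float,
                rng: np.random.Generator) -> np.ndarray:
    """Spiky quasi-periodic heartbeat trace, unit peak.

    Each beat is a narrow positive spike (QRS-like) flanked by two shallow
    slow lobes; beat-to-beat intervals jitter by ``jitter`` (fractional sd).
    """
    n = int(round(duration * fs))
    trace = np.zeros(n)
    # R spike plus a broad T-like lobe; the lobe carries enough slow power
    # that the fundamental dominates the in-band spectrum (the estimator of
    # heart-rate ranges picks the dominant 0.8-3.5 Hz peak)
    tt = np.arange(-0.2, 0.35, 1 / fs)
    beat = (np.exp(-0.5 * (tt / 0.025) ** 2)
            - 0.25 * np.exp(-0.5 * ((tt + 0.06) / 0.025) ** 2)
            + 0.8 * np.exp(-0.5 * ((tt - 0.16) / 0.07) ** 2))
    t = rng.uniform(0, 1.0 / rate)
    while t < duration:
        i0 = int(round((t - 0.2) * fs))
        lo, hi = max(i0, 0), min(i0 + len(beat), n)
        if hi > lo:
            trace[lo:hi] += beat[lo - i0:hi - i0]
        t += (1.0 / rate) * (1.0 + jitter * rng.standard_normal())
    return trace / max(np.abs(trace).max(), 1e-30)


def _pink_noise(shape, rng: np.random.Generator, fs: float) -> np.ndarray:
    """Gaussian noise with a 1/f power spectrum, unit rms per channel."""
    n_ch, n = shape
    freqs = np.fft.rfftfreq(n, 1 / fs)
    gain = np.zeros_like(freqs)
    gain[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = (rng.standard_normal((n_ch, len(freqs)))
            + 1j * rng.standard_normal((n_ch, len(freqs)))) * gain
    x = np.fft.irfft(spec, n=n, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x


def add_artifacts(recording: Recording,
                  config: SimulationConfig) -> Recording:
    """Overlay heartbeats, 1/f + drift, and movement bursts on a recording.

    * Heartbeats: rank-1 spatial pattern x pseudo-ECG, one for the newborn
      (rate drawn in ``infant_heart_rate``) and one for the parent; the
      drawn rates and patterns go to ``meta`` as ground truth.
    * Ambient 1/f drift: a quasi-homogeneous vector field (three independent
      1/f traces for Bx, By, Bz) coupling through each channel's
      orientation — spatially rank-3, which is what makes the downstream
      principal-component projection effective; plus smaller per-channel
      independent 1/f sensor noise and linear drift.
    * Movement bursts: Poisson-count smooth high-amplitude transients; their
      windows are recorded in ``meta["injected_burst_windows"]`` (ground
      truth for mask-recovery tests) but NOT in ``artifact_windows`` — the
      preprocessing stage must find them itself.
    """
    fs = recording.sampling_rate
    n = recording.n_samples
    n_ch = recording.n_channels
    out = recording.copy()
    ss = np.random.SeedSequence(config.seed + 7919)   # independent stream
    r_heart, r_pink, r_drift, r_burst = [
        np.random.default_rng(s) for s in ss.spawn(4)]

    meta = dict(out.meta)
    hearts = {}
    for who, rate_range, amp in (
            ("infant", config.infant_heart_rate, config.infant_heart_amplitude),
            ("parent", config.parent_heart_rate, config.parent_heart_amplitude)):
        if amp <= 0:
            continue
        rate = float(r_heart.uniform(*rate_range))
        ecg = _pseudo_ecg(fs, recording.duration, rate, 0.02, r_heart)
        pattern = r_heart.standard_normal(n_ch)
        pattern /= np.linalg.norm(pattern)
        out.data += amp * pattern[:, None] * ecg[None, :]
        hearts[who] = {"rate": rate, "pattern": pattern.tolist()}
    if hearts:
        meta["heartbeats"] = hearts

    if config.ambient_field > 0:
        field = config.ambient_field * _pink_noise((3, n), r_pink, fs)
        ori = np.array([c.orientation for c in recording.channels])
        out.data += ori @ field
    if config.pink_noise > 0:
        out.data += config.pink_noise * _pink_noise((n_ch, n), r_pink, fs)
    if config.drift_amplitude > 0:
        slopes = r_drift.uniform(-1, 1, n_ch) * config.drift_amplitude
        out.data += slopes[:, None] * (np.arange(n) / n)[None, :]

    windows = []
    if config.burst_rate > 0 and config.burst_amplitude > 0:
        n_bursts = r_burst.poisson(config.burst_rate * recording.duration / 60)
        for _ in range(n_bursts):
            dur = r_burst.uniform(*config.burst_duration)
            t0 = r_burst.uniform(0, recording.duration - dur)
            i0, i1 = int(t0 * fs), int((t0 + dur) * fs)
            # broadband wiggle under a smooth envelope: movement artifacts
            # carry power across the analysis band, not just near DC
            carrier = r_burst.standard_normal(i1 - i0)
            k = max(int(fs / 30), 1)
            carrier = np.convolve(carrier, np.ones(k) / k, mode="same")
            carrier /= max(np.abs(carrier).max(), 1e-30)
            envelope = np.hanning(i1 - i0) * carrier
            pattern = r_burst.standard_normal(n_ch)
            pattern /= np.abs(pattern).max()
            out.data[:, i0:i1] += (config.burst_amplitude
                                   * pattern[:, None] * envelope[None, :])
            windows.append((t0, t0 + dur))
    meta["injected_burst_windows"] = [list(w) for w in sorted(windows)]
    out.meta = meta
    return out
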