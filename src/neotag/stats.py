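"""Inference machinery: step-down maximum statistics and gated comparisons.

Family-wise error over channels x times (or channels x frequencies) is
controlled with maximum statistics: the observed map is thresholded at the
95th percentile of the null distribution of the map's maximum, built from
surrogate data.  Two surrogate constructions implement the null hypothesis
"no stimulus-locked response" while preserving the nuisance structure:

* **sign-flip** (time domain): each epoch — or each participant at the group
  level — gets one random +/-1 applied to all its channels and time points
  before re-averaging;
* **phase randomisation** (frequency domain): each epoch x frequency-bin
  Fourier coefficient is rotated by a random phase, the same phase on every
  channel, preserving each epoch's magnitude spectrum exactly.

The *step-down* refinement re-runs the maximum over the not-yet-significant
elements only, masking winners iteration by iteration, which recovers power
lost to the largest effects while keeping FWER control.

Scalar group comparisons use two-tailed t-tests gated by Shapiro-Wilk
normality (falling back to Wilcoxon signed-rank / rank-sum), and Pearson
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

__all__ = [
    "SurrogateStream",
    "MaxStatResult",
    "ComparisonResult",
    "signflip_surrogates",
    "phase_surrogates",
    "stepdown_maxstat",
    "compare_samples",
    "correlate",
]


class SurrogateStream:
    """Replayable seeded stream of surrogate statistic maps.

    ``replay()`` yields chunks of shape (n_chunk, n_elements); every replay
    re-derives the random stream from the stored seed, so each step-down
    iteration sees the identical surrogate sample.
    """

    def __init__(self, draw_chunk, n_surrogates: int, n_elements: int,
                 seed: int, chunk_size: int = 200):
        self._draw_chunk = draw_chunk
        self.n_surrogates = int(n_surrogates)
        self.n_elements = int(n_elements)
        self.seed = seed
        self.chunk_size = int(chunk_size)

    def replay(self):
        rng = np.random.default_rng(self.seed)
        done = 0
        while done < self.n_surrogates:
            k = min(self.chunk_size, self.n_surrogates - done)
            yield self._draw_chunk(rng, k)
            done += k

    def maxima(self, element_mask=None) -> np.ndarray:
        """Max over (unmasked) elements of every surrogate map."""
        sel = (slice(None) if element_mask is None
               else np.asarray(element_mask, bool))
        out = np.empty(self.n_surrogates)
        i = 0
        for chunk in self.replay():
            m = chunk[:, sel] if element_mask is not None else chunk
            out[i:i + len(chunk)] = m.max(axis=1)
            i += len(chunk)
        return out


@dataclass
class MaxStatResult:
    """Outcome of the step-down maximum-statistics test."""

    observed: np.ndarray                 # original map shape
    significant: np.ndarray              # bool, same shape
    p_values: np.ndarray                 # same shape, in [1/(n+1), 1]
    thresholds: list                     # one per step-down iteration
    n_surrogates: int
    alpha: float
    seed: int
    n_iterations: int = 0


@dataclass
class ComparisonResult:
    """A single two-tailed comparison (or correlation) between samples."""

    test_name: str
    statistic: float
    p_value: float
    n: int
    normality_p: float | None = None
    direction: int = 0                   # sign of mean(a) - mean(b)
    z: float | None = None
    r: float | None = None
    extra: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# surrogate constructions
# --------------------------------------------------------------------------

def signflip_surrogates(epochs: np.ndarray, n_surrogates: int = 10000,
                        seed: int = 0, chunk_size: int = 200,
                        exhaustive: bool = False) -> SurrogateStream:
    """Sign-flip surrogate maps ``|mean_i s_i x_i|`` for epoch stacks.

    ``epochs`` is (n_units, ...) — units are epochs at the individual level
    or participant evoked maps at the group level.  Each surrogate draws one
    +/-1 per unit, applied to all of that unit's channels and time points.
    With ``exhaustive=True`` all 2**n_units sign patterns are enumerated
    instead (the brute-force oracle; requires small n_units).
    """
    X = np.asarray(epochs, float).reshape(len(epochs), -1)
    n_units, n_elements = X.shape
    if exhaustive:
        if n_units > 16:
            raise ValueError("exhaustive enumeration limited to <= 16 units")
        n_surrogates = 2 ** n_units
        patterns = (((np.arange(n_surrogates)[:, None]
                      >> np.arange(n_units)[None, :]) & 1) * 2 - 1)

        def draw(rng, k, _state=[0]):
            s = patterns[_state[0]:_state[0] + k]
            _state[0] = (_state[0] + k) % n_surrogates
            return np.abs(s @ X) / n_units
    else:
        def draw(rng, k):
            s = rng.integers(0, 2, size=(k, n_units)) * 2 - 1
            return np.abs(s @ X) / n_units

    return SurrogateStream(draw, n_surrogates, n_elements, seed, chunk_size)


def phase_surrogates(coefficients: np.ndarray, freq_grid: np.ndarray,
                     frequencies_of_interest=(0.75, 1.5, 3.0),
                     n_surrogates: int = 10000, seed: int = 0,
                     chunk_size: int = 50, granularity: str = "per_bin",
                     statistic: str = "snr_of_mean",
                     channel_pairs=None,
                     flank_exclude: float = 0.1,
                     flank_extent: float = 0.4) -> SurrogateStream:
    """Phase-randomisation surrogate SNR maps for the tagging statistic.

    ``coefficients`` is (n_units, n_channels, n_bins) — epochs at the
    individual level, participants' epoch-averaged coefficients at the group
    level.  Per surrogate, each unit x bin receives a random phase factor
    ``e^{i theta}`` applied to every channel (``granularity="per_bin"``), or
    one phase per unit for all bins (``"per_epoch"``); each unit's magnitude
    spectrum is preserved exactly.

    ``statistic`` selects the map the null distribution is built for:

    * ``"snr_of_mean"`` (individual level): ``coefficients`` is one
      (n_epochs, n_channels, n_bins) array; epochs are re-averaged as
      complex coefficients, then power and the flanking-bin SNR are
      computed — the statistic of an epoch-averaged spectrum;
    * ``"mean_snr"`` (group level): ``coefficients`` is a LIST of such
      per-participant epoch arrays; each participant's epochs are
      phase-randomised and re-averaged, the participant's SNR computed, and
      the SNRs averaged across participants — the statistic of a
      group-averaged SNR spectrum.  (Rotating an already-averaged spectrum
      would leave its own SNR unchanged, hence the epoch-level input.)

    ``channel_pairs``, an optional (2, n_pairs) index array, norm-combines
    channel rows of each SNR map as ``hypot(snr[i1], snr[i2])`` before any
    across-unit averaging (the tangential-norm statistic).  Maps are
    restricted to the frequencies of interest: shape (n_rows * n_foi).
    Only the bins needed for the evaluated SNRs (targets plus flanks) are
    carried, which keeps 10,000 surrogates cheap.
    """
    from .freqtag import spectrum_snr

    if granularity not in ("per_bin", "per_epoch"):
        raise ValueError("granularity must be 'per_bin' or 'per_epoch'")
    if statistic not in ("snr_of_mean", "mean_snr"):
        raise ValueError("statistic must be 'snr_of_mean' or 'mean_snr'")
    if statistic == "mean_snr":
        groups = [np.asarray(c, complex) for c in coefficients]
        n_channels = groups[0].shape[1]
    else:
        C = np.asarray(coefficients, complex)
        n_units, n_channels, _ = C.shape
    df = freq_grid[1] - freq_grid[0]
    k_flank = int(np.floor(flank_extent / df + 1e-9))
    foi_idx = [int(np.argmin(np.abs(freq_grid - f)))
               for f in frequencies_of_interest]
    needed = sorted({j for i in foi_idx
                     for j in range(i - k_flank, i + k_flank + 1)})
    if needed[0] < 0 or needed[-1] >= len(freq_grid):
        raise ValueError("frequency grid does not cover the flanks of the "
                         "frequencies of interest")
    sub_freqs = freq_grid[needed]
    target_cols = [needed.index(i) for i in foi_idx]
    n_bins = len(needed)
    pairs = None if channel_pairs is None else np.asarray(channel_pairs, int)
    n_rows = n_channels if pairs is None else pairs.shape[1]
    if statistic == "mean_snr":
        subs = [g[:, :, needed] for g in groups]
    else:
        sub = C[:, :, needed]                            # (u, ch, b)

    def _snr_map(power):
        snr, _ = spectrum_snr(power, sub_freqs, flank_exclude, flank_extent)
        snr = snr[:, target_cols]
        if pairs is not None:
            snr = np.hypot(snr[pairs[0]], snr[pairs[1]])
        return snr

    def _phases(rng, shape):
        if granularity == "per_bin":
            theta = rng.uniform(0, 2 * np.pi, size=shape)
        else:
            theta = rng.uniform(0, 2 * np.pi, size=shape[:-1] + (1,))
            theta = np.broadcast_to(theta, shape).copy()
        return np.exp(1j * theta)

    def draw(rng, k):
        maps = np.empty((k, n_rows, len(target_cols)))
        if statistic == "snr_of_mean":
            phase = _phases(rng, (k, len(sub), n_bins))
            avg = np.einsum("kub,ucb->kcb", phase, sub) / len(sub)
            power = np.abs(avg) ** 2
            for i in range(k):
                maps[i] = _snr_map(power[i])
        else:
            for i in range(k):
                acc = np.zeros((n_rows, len(target_cols)))
                for g in subs:
                    phase = _phases(rng, (len(g), n_bins))
                    avg = np.einsum("ub,ucb->cb", phase, g) / len(g)
                    acc += _snr_map(np.abs(avg) ** 2)
                maps[i] = acc / len(subs)
        return maps.reshape(k, -1)

    return SurrogateStream(draw, n_surrogates,
                           n_rows * len(target_cols), seed, chunk_size)


# --------------------------------------------------------------------------
# step-down maximum statistics
# --------------------------------------------------------------------------

def stepdown_maxstat(observed: np.ndarray, stream: SurrogateStream,
                     alpha: float = 0.05) -> MaxStatResult:
    """Iterative step-down maximum-statistics test.

    Iteration k: the threshold is the 95th percentile (``1 - alpha``,
    "higher" convention) of each surrogate map's maximum over the currently
    unmasked elements; elements with ``observed > threshold`` become
    significant and are masked for the next iteration; the loop stops when
    an iteration adds none (or nothing testable remains).  Each element's
    empirical p-value, ``(1 + #{surrogate max >= observed}) / (1 + n)``, is
    recorded at the iteration where its fate was decided, so p > 0 always
    and significant elements satisfy p <= alpha.
    """
    obs = np.asarray(observed, float)
    flat = obs.ravel()
    testable = np.isfinite(flat)
    significant = np.zeros(flat.shape, bool)
    p_values = np.full(flat.shape, np.nan)
    thresholds: list = []

    n = stream.n_surrogates
    n_iter = 0
    while True:
        active = testable & ~significant
        if not active.any():
            break
        maxima = stream.maxima(active)
        thr = float(np.quantile(maxima, 1.0 - alpha, method="higher"))
        thresholds.append(thr)
        n_iter += 1
        srt = np.sort(maxima)
        # p = (1 + #{max >= obs}) / (1 + n) via sorted search
        exceed = n - np.searchsorted(srt, flat[active], side="left")
        p_act = (1.0 + exceed) / (1.0 + n)
        newly = active & (flat > thr)
        p_values[active] = p_act
        if not newly.any():
            break
        significant |= newly

    return MaxStatResult(observed=obs,
                         significant=significant.reshape(obs.shape),
                         p_values=p_values.reshape(obs.shape),
                         thresholds=thresholds, n_surrogates=n,
                         alpha=alpha, seed=stream.seed,
                         n_iterations=n_iter)


# --------------------------------------------------------------------------
# scalar comparisons
# --------------------------------------------------------------------------

def compare_samples(a, b, paired: bool = True,
                    normality_alpha: float = 0.05) -> ComparisonResult:
    """Two-tailed comparison with a Shapiro-Wilk normality gate.

    Paired: Shapiro-Wilk on the differences decides between the paired
    t-test and the Wilcoxon signed-rank test.  Unpaired: both samples must
    pass for the t-test, else the rank-sum test.  For the rank tests a
    normal-approximation Z is reported alongside the exact-statistic p.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if paired and a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    direction = int(np.sign(a.mean() - b.mean()))

    if paired:
        d = a - b
        n = len(d)
        if np.allclose(d, 0):
            return ComparisonResult("paired-t", 0.0, 1.0, n,
                                    normality_p=None, direction=0)
        norm_p = float(sstats.shapiro(d).pvalue) if len(np.unique(d)) > 2 \
            else 0.0
        if norm_p > normality_alpha:
            t = sstats.ttest_rel(a, b)
            return ComparisonResult("paired-t", float(t.statistic),
                                    float(t.pvalue), n, norm_p, direction)
        w = sstats.wilcoxon(d, alternative="two-sided", method="auto")
        za = sstats.wilcoxon(d, alternative="two-sided", method="approx",
                             correction=False)
        return ComparisonResult("wilcoxon-signed-rank", float(w.statistic),
                                float(w.pvalue), n, norm_p, direction,
                                z=float(za.zstatistic))

    n = min(len(a), len(b))
    pa = float(sstats.shapiro(a).pvalue) if len(np.unique(a)) > 2 else 0.0
    pb = float(sstats.shapiro(b).pvalue) if len(np.unique(b)) > 2 else 0.0
    norm_p = min(pa, pb)
    if norm_p > normality_alpha:
        t = sstats.ttest_ind(a, b)
        return ComparisonResult("unpaired-t", float(t.statistic),
                                float(t.pvalue), n, norm_p, direction)
    rs = sstats.ranksums(a, b)
    return ComparisonResult("rank-sum", float(rs.statistic),
                            float(rs.pvalue), n, norm_p, direction,
                            z=float(rs.statistic))


def correlate(a, b) -> ComparisonResult:
    """Pearson correlation with a two-tailed p-value."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    res = sstats.pearsonr(a, b)
    return ComparisonResult("pearson-r", float(res.statistic),
                            float(res.pvalue), len(a),
                            r=float(res.statistic))
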