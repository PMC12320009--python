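# Methods

This note documents the models, parameter choices and numerical decisions
behind `neotag`, and what the synthetic-data tests do and do not establish
about real recordings.

## Synthetic recordings

The generator emulates 5-minute newborn OPM-MEG sessions: a cap of
`n_sensors` (default 27, up to 20 triaxial) magnetometers on the upper ~3/4
of a 65 mm sphere, 4 mm off the scalp (the thermal standoff of heated-cell
OPMs), none in the occipital patch where the infant rests. Placement uses a
Fibonacci spiral with farthest-point selection — the real caps only
constrain counts and regions, so the rule is ours. Triaxial housings go to
the most lateral positions, mirroring the practice of concentrating
triaxial sensors over temporal cortex. Each sensor contributes a radial
channel plus one or two tangential channels with a deterministic tangential
frame.

**Neural sources.** Two tangential current dipoles at the temporal
positions (0, ±42, 15) mm drive all responses through the same spherical
forward model the inverse stage uses. The evoked waveform is a
difference-of-Gammas biphasic bump whose positive peak is rescaled in time
to land exactly on `evoked_peak_latency` (default 260 ms); per-tone
steady-state responses are short Gamma bumps, with oddball tones receiving
`oddball_extra_amplitude` on top of `base_amplitude` — a period-4 amplitude
modulation of the 3 Hz train, which is what places spectral lines at
0.75 Hz and harmonics. Nothing is claimed about real newborn source depth
or waveform shape; these are minimal parametric forms with controllable
spectra.

**Noise and artifacts.** Defaults are chosen to sit in the ranges wearable
magnetometer data actually occupies: ~1 pT evoked fields at the best
channel, 0.5 pT/sample white sensor noise, and heartbeat artifacts of 3 pT
(newborn, rate drawn in 2.2–2.5 Hz) and 1.5 pT (parent, 1–1.5 Hz) as
rank-1 spatial patterns times a pseudo-ECG (sharp R-spike plus a broad
T-like lobe, sized so the spectral fundamental dominates the 0.8–3.5 Hz
band the heart-rate estimator searches). Ambient 1/f drift is injected as a
**rank-3 quasi-homogeneous vector field** coupling through each channel's
orientation, at 20 pT rms, plus a small (0.2 pT) per-channel 1/f floor and
linear drift. The rank-3 structure matters twice over: it is the physically
correct model of residual fields in a shielded room, and it is exactly the
structure the 3-PC spatial projection is designed to remove — with
spatially independent 1/f noise of similar power, the evoked field itself
becomes a leading principal component and the projection would delete the
signal. Movement bursts are sparse (2/min), large (300 pT), broadband
(smoothed-noise carrier under a Hanning envelope — a purely low-frequency
envelope would vanish in the 1–40 Hz band and be undetectable), with their
true windows recorded in `meta` for mask-recovery tests.

All randomness flows from one seed through `SeedSequence` spawning:
identical (config, seed) reproduces a recording bit for bit.

**What passing tests show.** The generator shares the forward model, the
spectral structure and the artifact taxonomy of the real recordings, so it
validates the analysis logic: epoch bookkeeping, SNR arithmetic, FWER
control, parameter recovery, localisation geometry. It does not emulate
sensor calibration errors, cross-axis talk, non-stationary heart rates,
cap movement relative to the head, or real cortical geometry — conclusions
about those require real data.

## Preprocessing chain

Order per paradigm: coarse robust-z mask → heartbeat ICA → artifact
interpolation → band-pass (1–40 Hz evoked; 0.2–40 Hz oddball, which must
keep 0.75 Hz) → notch at automatically detected 13–40 Hz noise peaks →
robust-z rejection → 1.5 s window extension → 3-PC projection. Choices:

* **Robust z-score rejection** uses |x| smoothed with a 1 s square window,
  standardised by median and 1.4826·MAD, threshold 5, masking samples that
  exceed it on any channel. The statistic is always computed on a 1–40 Hz
  view of the data: masking targets movement transients, which live in that
  band, while the oddball path's sub-hertz content is dominated by ambient
  drift whose slowly wandering amplitude would otherwise trigger large
  false rejections — drift removal is the PC projection's job, not the
  mask's. Replacing by-eye artifact marking with this automated first pass
  is a reproducibility decision; user-supplied windows can be unioned in.
* **Filters** are zero-phase Butterworth (forward–backward), split into a
  4th-order high-pass and a 12th-order low-pass: latencies are headline
  outputs, so zero phase is mandatory, and the asymmetric orders are the
  least filtering that both passes 3 Hz within 1% and attenuates 50 Hz
  mains by >40 dB under a 40 Hz passband edge. Padding is set to several
  filter time constants; scipy's default is far too short for sub-hertz
  corners. Notches are zero-phase IIR, Q = 30.
* **Artifact interpolation** (straight line between the last clean samples
  on either side; edge windows hold the nearest value) runs *before*
  filtering so filter ringing cannot spread artifact energy.
* **Heartbeat ICA**: FastICA fitted on artifact-free 1–40 Hz data. A
  component is cardiac when its power-spectrum SNR (same flanking-bin
  definition as the tagging analysis, computed from 20 s segment-averaged
  power — segment *coefficient* averaging would cancel anything not
  stimulus-locked, i.e. precisely the heartbeats) exceeds 7.5 inside a
  heart-rate range. Flagged components are subtracted from the full
  recording. Estimated heart ranges are the dominant 0.8–3.5 Hz component
  peak ± 0.15 Hz — the half-width that turns a 2.35 Hz newborn heart into
  the conventional 2.2–2.5 Hz band. In the oddball chain the stimulus
  harmonics (1.5 and 2.25 Hz) are exempt from the cardiac rule: a line
  exactly at a stimulus harmonic is stimulus-locked, which heartbeats are
  not, and without the exemption a cleanly separated neural component gets
  flagged through its 1.5 Hz oddball harmonic inside the parent heart-rate
  band. Convergence retries walk a schedule — symmetric (parallel) update,
  then one-unit deflation, then deflation at half the component count with
  relaxed tolerance — re-seeding each time: the symmetric update stalls
  when part of the whitened space is near-Gaussian sensor noise with no
  contrast gradient, while deflation converges reliably there, and the
  high-variance artifact components always survive the shrink.

## Evoked analysis

Epochs −70 to +500 ms around each tone, rejected when they intersect the
extended mask, baseline-corrected on the 70 ms prestimulus window, averaged
per participant, then across participants after matching each montage to a
template layout (azimuthal-equidistant 2D projection, global optimal
assignment per axis type — greedy nearest-neighbour matching can deadlock,
the assignment cannot). Triaxial responses are summarised as
`sqrt(t1² + t2²)` per sensor on the *individual* evoked response, before
group averaging.

Metrics: peak latency is the argmax of the across-channel RMS in
(0, 500] ms; the reported amplitude is the largest |channel| value at the
moment the first spatial principal component of the evoked matrix peaks
(configurable to the RMS peak instead — "the principal component of the
response" is genuinely ambiguous and we chose the spatial-PC reading);
SNR divides that amplitude by the same channel's baseline standard
deviation. An all-zero response returns explicit nulls.

## Frequency tagging

20 s epochs starting at oddball tones (greedy non-overlapping selection
from the recording start; overlap policy was unspecified, greedy is the
simplest deterministic rule), plain unnormalised FFT with no taper — the
epoch length is an exact multiple of every frequency of interest, so
leakage at those bins is nil. Complex coefficients are averaged across
epochs, power is the squared magnitude, and SNR uses flanks 0.1–0.4 Hz
away, endpoints inclusive: 7 bins per side at the 0.05 Hz grid. Bins whose
flanks leave the grid are flagged invalid (NaN), never extrapolated; a
zero flank gives +inf, kept distinct. Group spectra average SNR (not
power) across participants. A statistical caveat worth knowing: because
coefficient-averaged null power stays exponentially distributed for any
epoch count, null SNR exceeds 3 at a rate of about e⁻³ ≈ 5% per bin —
fixed SNR cut-offs are not significance tests here; the surrogate
machinery below is.

## Inference

Maximum statistics with the step-down refinement: per iteration, the
threshold is the 95th percentile ("higher" convention; an element is
significant when strictly above it — the inclusive/exclusive choice was
open and we test `observed > threshold`) of each surrogate map's maximum
over not-yet-significant elements; winners are masked and the loop repeats
until a fixed point. p-values are `(1 + #{max ≥ obs}) / (1 + n)` at the
iteration where each element's fate was decided, so p ≥ 1/(n+1) > 0 and
significant elements always have p ≤ α. Surrogate streams are seeded and
replayable, so every iteration sees the same draw and identical seeds give
bit-identical results.

* **Sign-flip** (evoked): one ±1 per epoch (individual level) or per
  participant (group level), applied to all channels and time points of
  that unit. Exhaustive enumeration (≤16 units) provides the oracle the
  Monte-Carlo path is tested against. Note that with P participants the
  smallest achievable group p is 2/2ᴾ and the observed map ties the
  ±identity surrogates, so group-level detection needs P ≥ 8 at α = 0.05.
* **Phase randomisation** (tagging): per surrogate, each epoch × bin gets a
  random phase factor applied to every channel (per-epoch granularity, one
  phase for all bins, is available behind a flag; the per-bin default also
  randomises within-epoch phase structure). Magnitudes are untouched, so
  every epoch's per-channel magnitude spectrum is conserved exactly. At the
  individual level the statistic is the SNR of the re-averaged
  coefficients; at the group level each participant's *epochs* are
  randomised, the participant's SNR recomputed, and SNRs averaged —
  rotating an already-averaged spectrum would leave its own SNR unchanged
  and produce a degenerate null. Frequencies of interest are tested
  separately (per-frequency correction; pooling is a flag away).
* **Scalar comparisons**: two-tailed t-tests gated by Shapiro–Wilk at 0.05
  (on differences when paired), falling back to Wilcoxon signed-rank /
  rank-sum with a normal-approximation Z reported alongside; Pearson r for
  correlations.

## Forward model and inverse

The forward solution is the analytic external field of a current dipole in
a homogeneous conducting sphere — chosen over a realistic boundary-element
head model deliberately: MEG is famously insensitive to conductor detail,
the sphere is exact and fast, and it gives the generator and the inverse a
shared, testable physics. Two independent oracles check the
implementation: the radial field component must equal the free-space
dipole's radial component (volume currents contribute none — exact), and
the full field must match a Geselowitz surface-integral evaluation built
from the single-sphere Legendre potential series (independent numerical
route, <1% on a coarse quadrature).

The inverse is `W = Lᵀ(LLᵀ + λC)⁻¹` (identity source covariance) with
λ from the standard heuristic `trace(LLᵀ)/trace(C)/SNR²`, SNR = 3.
Depth-bias correction defaults to **sLORETA-style** standardisation by the
per-source resolution block `(WL)ⱼⱼ` (pseudo-inverted, since the radial
direction is silent and the block has rank 2). We implemented the
dSPM-style variant (divide by projected noise SD) as an option but made
sLORETA the default after measuring dSPM's well-known intrinsic bias of
1–1.5 grid spacings on noiseless on-grid dipoles; sLORETA localises point
sources without bias. Free-orientation estimates are reported as
3-component norms. The source grid is cubic at 7.5 mm spacing within 85%
of the sphere radius (upper hemisphere); auditory ROIs are lateral wedges
around the interaural (±y) axis. Group oddball localisation inverts each
participant's epoch-averaged Fourier coefficients per bin, computes
source-level power and flanking-bin SNR, and averages the SNR spectra —
group-averaged sensor SNR cannot be source-projected because SNR is not
linear in the field.

## Pipelines and problem sizes

`run_evoked_pipeline` / `run_oddball_pipeline` chain the stages above for a
simulated cohort, log every removed component and mask window, test both
individual and group levels, and emit JSON reports with a manifest (config
snapshot, seeds, stage wall-clock, output hashes) that reproduces the run
bit for bit. Montage alignment to the template happens *before* the group
statistic and its surrogate stack are formed, so observed and null maps
correspond element by element.

The default generator parameters are the study-scale conditions (300 s at
1200 Hz, 27 sensors). The test suite and the acceptance script run
desk-scale versions of the same conditions — 10 participants, the full
300 s sequences at a reduced 300 Hz rate, 12 sensors, 500–1000 surrogates
(400 null runs at 500 surrogates for the FWER check) — sized so the whole
suite finishes in a couple of minutes. 300 Hz comfortably resolves the
40 Hz analysis band and the 0.05 Hz tagging grid. The 5-minute duration is
load-bearing for the oddball paradigm: phase randomisation attenuates the
stimulus line by 1/n_epochs, so a cohort with only a handful of 20 s
epochs has an overlapping null and no power. Two further cohort choices:
the acceptance cohort shares one cap layout (`array_seed`), because group
sign-flip inference assumes sign-consistent responses and channels near a
dipolar zero-crossing flip polarity between dissimilar layouts; and the
oddball chain exempts the stimulus harmonics (1.5, 2.25 Hz) from the
cardiac component rule — a cleanly separated neural component would
otherwise be flagged through its 1.5 Hz oddball harmonic, which sits
inside the parent heart-rate band, and deleted.

## Known limitations

* The sphere model cannot represent real cortical folding; localisation
  statements transfer to real data only at the "correct hemisphere,
  temporal region" level.
* FastICA on data whose minor subspace is near-Gaussian needs the
  component-shrinking retry; heavily rank-deficient inputs (after PC
  projection) should be decomposed before projecting.
* The tagging analysis evaluates the three named frequencies only; the
  second oddball harmonic (2.25 Hz) sits inside the newborn heart-rate band
  and is deliberately not scored.
* Group sign-flip inference is structurally underpowered below 8
  participants (see above); individual-level tests carry the evidence in
  small cohorts.
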