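# Methods

This note documents the models, estimators and numerical choices behind
`entosense`, in the order data flows through the pipeline.

## 1. Signal model and synthetic data

The instrument emulated here illuminates an air volume with two
near-infrared bands (808 nm and 980 nm) and records backscatter on a
four-segment quadrant photodiode, giving 8 synchronous channels at a
nominal 20 kHz after lock-in demodulation, with a 5 kHz low-pass cutoff
upstream.  Since wingbeat fundamentals stay below 1 kHz, the passband
holds at least five harmonic orders for any insect.

A synthetic transit is, per band `b` and quadrant `q`,

    s_qb(t) = E(t - t0 - delta_q) * [ B_b + W_b * w(t - t0) ]

* `E` is a unit-peak squared-cosine envelope with the configured FWHM
  (default 100 ms, the nominal transit time); it is smooth, compactly
  supported on twice the FWHM, and cheap to evaluate.
* `w` is the wing modulation: a harmonic sum
  `sum_k a_k cos(2 pi k f0 t + k phi)` rectified at zero and renormalised
  to unit peak over one period.  Rectification keeps backscatter
  non-negative, preserves spectral peaks at the harmonics of `f0`, and —
  important for the decomposition below — makes the waveform touch zero
  for a finite interval each period (the "wings closed" phase).  No
  published functional form exists for this waveform; the rectified
  harmonic sum is this package's modelling choice.  The default harmonic
  mix is a geometric decay `a_k = 0.6^(k-1)` with K = 5, which yields a
  clearly visible harmonic series; both are overridable.
* `B_b`, `W_b` are the body and peak-wing amplitudes per band.  Their
  ratio is, by construction, the designed body-to-wing ratio, and their
  808/980 ratios the designed melanisation indices.
* `delta_q` encodes crossing direction: each axis (left/right, bottom/top)
  shifts the quadrant envelope by `+- quad_lag / 2`, so opposite
  quadrant-pair envelope peaks are separated by exactly `quad_lag`.
  Complementary amplitude ramps were considered instead; they cannot
  guarantee an exact, parameter-equal peak separation without
  calibration, so the time-shift form was chosen as the simplest model
  with exactly controllable lags.

A full scene adds a quasi-static baseline (offset plus a slow sinusoid
and/or linear ramp), i.i.d. Gaussian noise per channel, and sub-500 µs
spike artefacts on random single channels; the sum is clipped at zero,
since a lock-in detector against a dark background cannot produce
negative output.  Everything is driven by one `numpy` generator seed, so
fixed seed means bit-identical output.

The packaged worked-example preset is a 160 Hz fundamental with the
default harmonic mix and amplitudes `B = 80`, `W = 200` in arbitrary
signal units (designed ratio 0.4, melanisation 1.0).  The absolute scale
was set large against the unit-SD scene noise because the body estimator
below is a windowed minimum, whose noise bias grows like
`sigma * sqrt(2 ln N)`; amplitudes of this size keep that bias to a few
per cent of the body amplitude.

The synthetic field study draws a latent daily activity
`lambda_d ~ LogNormal(-sigma^2/2, sigma)` (mean 1, default sigma = 1)
shared by all devices; sensor counts are Poisson with mean
`1122 * lambda_d * uptime` and trap catches Poisson with mean
`(1122 / 19) * lambda_d`, i.e. an observation-rate ratio of 19.  Uptime
is ~0.9 with small jitter.  Traps are emptied daily except Sundays, whose
catch pools into the next collection.  Defaults mirror a four-week,
six-sensor / six-trap deployment.

What the generator does **not** emulate: real insect size/species
mixtures, diurnal activity structure within a day, weather covariates
beyond a rain flag, sensor-to-sensor gain differences, or spatial
non-homogeneity between devices.  Passing tests therefore demonstrate
correctness of the algorithms under the stated signal model, not field
performance.

## 2. Event extraction

Per channel: the stream is block-mean downsampled to 2 kHz (no anti-alias
filter — cheap, and aliasing is irrelevant for a median/SD noise
estimate).  A rolling median boxcar, 2 s wide with 50 % overlap,
estimates the quasi-static baseline: a 2 s window makes the median
insensitive to ~100 ms transits.  An identical filter applied to the
samples strictly *below* each window's median estimates the noise SD;
restricting to the lower half keeps rare bright events from inflating the
noise estimate.  For Gaussian noise the below-median SD is
`sigma * sqrt(1 - 2/pi) ~= 0.603 sigma`, so the default threshold of
10 x SD sits near 6 sigma.  No correction toward true sigma is applied by
default (`sd_correction` enables the `1/0.603` rescale).

One scale subtlety is handled explicitly: block-averaging white noise
over N samples shrinks its SD by `sqrt(N)`.  The SD measured on the
block-mean 2 kHz stream is therefore rescaled by `sqrt(N)` before use, so
that it expresses the noise level of the full-resolution stream the
threshold is applied to; without this the effective threshold would be
~1.9 sigma instead of the intended ~6 sigma.

Median and SD tracks are valued at window centres and linearly
interpolated to the full-resolution time base (edges hold the nearest
value).  The detection condition is one-sided —
`residual > snr_factor * SD` — because insect backscatter can only add
signal.  Zero SDs are floored at machine epsilon.

The boolean mask is then eroded by 500 µs and dilated by 30 ms with flat,
centred structuring elements (scipy.ndimage; total widths, left-biased
centre for even lengths).  A true run of n samples survives erosion iff
`n >= erode_len`, so sub-500 µs spikes can never become events; each
surviving run grows by `dilate_len - 1` samples, recovering transit
flanks and merging the per-wingbeat threshold crossings of weak signals
into one run.  Masks are refined per channel and then OR-combined across
all 8 channels; maximal true runs of the combined mask are the events
(half-open 0-based sample intervals).  No minimum-duration cut is applied
beyond the erosion.  Each event carries the baseline-removed 8-channel
snippet, per-channel peak SNR, and the per-channel baseline/noise tracks
travel with the extraction as metadata.

## 3. Feature extraction

**Spectral density.** Welch estimate with Hann window, 50 % overlap,
segment length `min(n, 4096)`.  A 5 Hz grid on a ~100 ms event is
impossible; short events use a single segment zero-padded to >= 4096
points, which refines the evaluation grid (~4.9 Hz at 20 kHz) while the
physical resolution remains `sample_rate / nperseg = 1/duration`.  The
channel used for frequency estimation is the sum of all 8 channels
(maximum SNR); per-band quadrant sums are used for melanisation.

**Fundamental frequency.** Candidates are local PSD maxima; the search
band is 30-1000 Hz but peaks are located on the full grid so a band-edge
fundamental keeps its neighbours.  Each candidate is scored by the
harmonic sum `sum_k P(k f)` (k up to 5, capped at the passband), which
resists octave-up errors when the fundamental is weak; octave-down errors
cannot occur because a subharmonic is not a spectral peak.  The winner
must exceed the in-band median floor by a prominence factor (default 10 —
the same order as the detection factor; pure-noise spectra fall below
it), otherwise the event has no distinguishable wingbeat frequency.  The
returned value is refined by parabolic interpolation of log power.

**Body/wing decomposition.** The body (glint) track is the minimum
envelope: a rolling minimum over one wingbeat period `1/f0`, smoothed by
a rolling mean of the same width.  Because the rectified wing waveform
rests at zero once per period, the window minimum lands on the body
contribution.  The input is pre-smoothed over 1/8 period first: a raw
windowed minimum of noise is biased low by the extreme-value factor
`sqrt(2 ln N)`, and the short pre-smoothing suppresses this without
disturbing the flat wings-closed interval.  The wing track is defined as
`snippet - body`, so the decomposition reconstructs the signal exactly.

**Body-to-wing ratio.** Mean of the body track divided by the mean of the
wing track's upper envelope (rolling maximum over one period), both over
the central 50 % of the event, where the transit envelope cancels in the
ratio.  The published quantity gives no averaging definition; this is one
consistent choice, and the generator is built so its designed ratio
matches this definition.  A vanishing wing envelope (wingless transit)
yields an absent ratio rather than a division error.

**Melanisation.** Per component (body, wing separately):
`mean amplitude at 808 nm / mean amplitude at 980 nm`, quadrants summed
per band before decomposition, central 50 % of the event.  Absent when
the 980 nm denominator vanishes.

**Kinematics.** Left/right (and bottom/top) quadrant-pair sums over both
bands are smoothed over about one wingbeat period and cross-correlated;
the argmax lag gives a signed inter-quadrant delay, classified as
left-to-right / right-to-left (ascending / descending) when it exceeds
1 ms, "none" otherwise.  No mean subtraction is applied before the
correlation: the snippets are baseline-removed and near zero off-transit,
and subtracting a mean would create long matching negative plateaus that
drag the correlation peak toward zero lag.  Kinematics require at least
two quadrants with peak SNR at the detection level.

**Validity.** An event is invalid iff the rain flag is set or no
fundamental was found (reasons `rain` / `no-wbf`).  The rain flag is an
input from scene or weather metadata — no rain classifier is implemented,
as none is described for the original system.

## 4. Activity statistics

Valid events are binned per device and day (or hour) and divided by the
uptime fraction of the bin; bins with zero uptime are excluded rather
than zero-filled, and dates on an exclusion list (instrument malfunction)
are dropped.  Trap collections are normalised by the number of trapping
days covered: each collection's `days_covered` is the day gap since that
trap's previous collection, so a skipped Sunday makes the Monday
collection cover 2 days.  No rows are fabricated for un-emptied days.

The sensor-trap comparison pairs per-day means (across sensors, across
traps) on the intersection of days where both methods have data.
Spearman's rho uses average ranks for ties (scipy); the two-sided p-value
is an exact permutation enumeration for n <= 9 and the t-approximation
beyond.  An ordinary least-squares line of sensor on trap means is
reported alongside.  Constant series make rho undefined (reported
absent), and fewer than 3 common days is an error.

The study summary reports each method's mean daily count with its
standard error (SD across days / sqrt(n_days)) and the sensor/trap
ratio twice, labelled: once from the normalised means and once from the
raw means — the two differ whenever uptime is below 1 or collections
pool days, and the published "approximately 19 x" does not state which
convention it uses.

## 5. Problem sizes and tolerances

The test suite and the acceptance script run entirely on synthetic data
generated at call time.  Representative sizes, chosen as the smallest
that make the statistics stable: single-scene checks use 2.5-10 s
recordings at 20 kHz; the detection Monte-Carlo uses 200 transit scenes
plus 100 noise-only scenes of 2.6 s; wingbeat recovery sweeps 20
fundamentals x 20 seeded trials; the field-study recovery uses 100 seeded
four-week studies; morphology is checked exhaustively on all masks up to
length 16 and on 10^4 random masks up to length 64.  Numerical
tolerances in tests come from the quantity's own scale: spectral
estimates are held to one resolution step, closed-form statistics to
their sampling error (~3 %), constructions that are exact by design to
float precision.

## 6. Known limitations

* The below-median SD inflates when the baseline drifts appreciably
  within a 2 s window; this raises the threshold slightly (conservative).
* The body-track minimum filter biases the body estimate low in noise;
  the pre-smoothing mitigates but does not remove this, so body-to-wing
  ratios of faint events are biased toward small values.
* The harmonic-sum score assumes harmonics fall on multiples of the
  candidate within one grid step; strongly frequency-modulated wingbeats
  (chirps) would smear the score.
* Kinematic lags assume a single insect per event; overlapping transits
  produce a single merged event with mixed-lag correlation peaks.
* The exact permutation p-value is limited to n <= 9 pairs (9! ~ 3.6e5
  enumerated pairings); beyond that the t-approximation is used.
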