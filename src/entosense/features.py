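"""Per-event feature extraction.

From each baseline-removed transit snippet the pipeline derives:

* the fundamental wingbeat frequency (WBF) and its harmonic powers, from a
  Welch spectral density of the quadrant- and band-summed signal;
* a body/wing decomposition — the minimum envelope (wings at closed phase)
  is the body glint, the remainder the wing modulation — and from it the
  body-to-wing ratio;
* melanisation indices: 808 nm / 980 nm amplitude ratios of body and wing
  components (the bands index melanin absorption differentially);
* transit kinematics: signed inter-quadrant lags from cross-correlating
  left/right and bottom/top envelope pairs, classifying crossing
  direction;
* a validity flag — observations during heavy rain or without a
  distinguishable wingbeat frequency are removed downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import maximum_filter1d, minimum_filter1d, uniform_filter1d

from .errors import DataError
from .extract import InsectEvent
from .recording import (
    BANDS,
    BOTTOM_QUADRANTS,
    LEFT_QUADRANTS,
    RIGHT_QUADRANTS,
    TOP_QUADRANTS,
    band_indices,
    quadrant_indices,
)

__all__ = [
    "FeatureParams",
    "SpectralDensity",
    "EventFeatures",
    "estimate_psd",
    "fundamental_frequency",
    "harmonic_capacity",
    "body_wing_decompose",
    "wing_peak_envelope",
    "body_to_wing_ratio",
    "melanisation_index",
    "transit_kinematics",
    "validate_event",
    "extract_features",
    "features_table",
]


@dataclass
class FeatureParams:
    """Feature-extraction settings.

    ``passband_hz`` is the upstream hardware's anti-alias cutoff (5 kHz):
    with wingbeat fundamentals below 1 kHz it guarantees at least five
    harmonic orders in band.  The Welch segment length caps at 4096
    samples; shorter events use a single zero-padded segment, so the
    physical resolution is 1 / duration.
    """

    welch_nperseg: int = 4096
    welch_overlap: float = 0.5
    nfft_min: int = 4096
    search_band: tuple[float, float] = (30.0, 1000.0)
    prominence_factor: float = 10.0  # peak power over in-band median floor
    max_harmonics: int = 5
    passband_hz: float = 5000.0
    min_duration_s: float = 0.040    # two periods of a 50 Hz wingbeat
    central_fraction: float = 0.5
    min_lag_s: float = 1e-3          # below this a lag classifies as "none"
    kinematics_min_snr: float = 10.0  # quadrant peak SNR needed for lags


@dataclass
class SpectralDensity:
    """One-sided Welch power spectral density of an event channel."""

    frequency: np.ndarray     # Hz, 0 .. Nyquist
    power: np.ndarray         # signal^2 / Hz
    resolution: float         # Hz (segment-length limited)
    nperseg: int
    noverlap: int
    window: str = "hann"

    def power_at(self, f: float) -> float:
        """Power in the bin nearest to ``f`` (0 outside the grid)."""
        if f < self.frequency[0] or f > self.frequency[-1]:
            return 0.0
        idx = int(np.argmin(np.abs(self.frequency - f)))
        return float(self.power[idx])


@dataclass
class EventFeatures:
    """Derived features of one event; absent values are ``None``."""

    f0: float | None = None
    harmonic_amps: list[float] = field(default_factory=list)
    body_to_wing_ratio: float | None = None
    melanisation_body: float | None = None
    melanisation_wing: float | None = None
    horiz_lag_s: float | None = None
    vert_lag_s: float | None = None
    horiz_class: str | None = None   # left_to_right / right_to_left / none
    vert_class: str | None = None    # ascending / descending / none
    peak_snr: float = 0.0
    duration_s: float = 0.0
    start_time_s: float = 0.0
    device_id: str = ""
    valid: bool = True
    invalid_reason: str | None = None  # no-wbf / rain / other
    body_track: np.ndarray | None = None
    wing_track: np.ndarray | None = None

    _TABLE_FIELDS = (
        "device_id", "start_time_s", "duration_s", "peak_snr", "f0",
        "body_to_wing_ratio", "melanisation_body", "melanisation_wing",
        "horiz_lag_s", "vert_lag_s", "horiz_class", "vert_class",
        "valid", "invalid_reason",
    )

    def to_record(self) -> dict:
        rec = {k: getattr(self, k) for k in self._TABLE_FIELDS}
        for k, a in enumerate(self.harmonic_amps, start=1):
            rec[f"harmonic_{k}"] = a
        return rec


# --------------------------------------------------------------------------
# spectral estimation
# --------------------------------------------------------------------------

def estimate_psd(
    samples: np.ndarray,
    sample_rate: float,
    params: FeatureParams | None = None,
) -> SpectralDensity:
    """Welch power spectral density of one event channel.

    Hann window, 50 % overlap, segment length ``min(n, 4096)``; segments
    shorter than ``nfft_min`` are zero-padded so the frequency grid stays
    fine, but the physical resolution remains ``sample_rate / nperseg``.
    Satisfies Parseval within windowing tolerance: ``sum(power) * df``
    approximates the time-domain variance.
    """
    params = params or FeatureParams()
    samples = np.asarray(samples, dtype=float)
    if samples.size < 8:
        raise DataError("snippet too short for spectral estimation")
    nperseg = min(samples.size, params.welch_nperseg)
    noverlap = int(nperseg * params.welch_overlap)
    nfft = max(nperseg, params.nfft_min)
    freq, power = sps.welch(
        samples, fs=sample_rate, window="hann", nperseg=nperseg,
        noverlap=noverlap, nfft=nfft, detrend="constant",
    )
    return SpectralDensity(
        frequency=freq, power=power,
        resolution=sample_rate / nperseg,
        nperseg=nperseg, noverlap=noverlap,
    )


def harmonic_capacity(f0: float, passband_hz: float) -> int:
    """Number of harmonic orders (fundamental included) within the
    passband: ``floor(passband / f0)``.  A 5 kHz passband holds exactly
    five orders of a 1 kHz fundamental."""
    if f0 <= 0:
        raise DataError("f0 must be positive")
    return int(math.floor(passband_hz / f0 + 1e-9))


def _parabolic_refine(psd: SpectralDensity, idx: int) -> float:
    """Sub-bin peak refinement by parabolic interpolation of log power."""
    if idx <= 0 or idx >= psd.frequency.size - 1:
        return float(psd.frequency[idx])
    tiny = np.finfo(float).tiny
    a, b, c = np.log(psd.power[idx - 1: idx + 2] + tiny)
    denom = a - 2 * b + c
    if denom >= 0:
        return float(psd.frequency[idx])
    delta = 0.5 * (a - c) / denom
    df = psd.frequency[1] - psd.frequency[0]
    return float(psd.frequency[idx] + np.clip(delta, -1, 1) * df)


def fundamental_frequency(
    psd: SpectralDensity,
    params: FeatureParams | None = None,
) -> float | None:
    """Fundamental wingbeat frequency, or ``None`` if indistinguishable.

    Candidate frequencies are local PSD maxima inside the search band.
    Each candidate ``f`` is scored by the harmonic sum
    ``sum_k P(k f)`` (k up to ``max_harmonics``, capped at the passband),
    which keeps the estimate on the true fundamental even when the
    fundamental peak itself is weak, and cannot jump to a subharmonic
    because a subharmonic is not a spectral peak.  The winning candidate
    must rise above the in-band median floor by ``prominence_factor``;
    the returned value is refined by parabolic interpolation.
    """
    params = params or FeatureParams()
    lo, hi = params.search_band
    band = (psd.frequency >= lo) & (psd.frequency <= hi)
    if not band.any():
        return None
    floor = float(np.median(psd.power[band]))

    # peaks are found on the full grid so band-edge bins keep their
    # neighbours; candidates may sit one grid step outside the band
    df = psd.frequency[1] - psd.frequency[0]
    peaks, _ = sps.find_peaks(psd.power)
    f_peaks = psd.frequency[peaks]
    keep = (f_peaks >= lo - df) & (f_peaks <= hi + df)
    peaks = peaks[keep]
    if peaks.size == 0:
        return None

    best_idx, best_score = None, -np.inf
    for pk in peaks:
        f = psd.frequency[pk]
        k_max = min(params.max_harmonics,
                    harmonic_capacity(f, params.passband_hz))
        score = sum(psd.power_at(k * f) for k in range(1, max(k_max, 1) + 1))
        if score > best_score:
            best_score, best_idx = score, pk

    tiny = np.finfo(float).tiny
    if psd.power[best_idx] / max(floor, tiny) < params.prominence_factor:
        return None
    f_ref = _parabolic_refine(psd, best_idx)
    return float(np.clip(f_ref, lo, hi))


# --------------------------------------------------------------------------
# body / wing decomposition
# --------------------------------------------------------------------------

def body_wing_decompose(
    samples: np.ndarray,
    f0: float,
    sample_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Split a snippet into body (minimum-envelope) and wing tracks.

    The body track is a rolling minimum over one wingbeat period,
    smoothed by a rolling mean of the same width; the rectified wing
    waveform touches zero once per period, so within each window the
    minimum lands on the body glint.  A short pre-smoothing (1/8 period)
    suppresses the extreme-value bias that a windowed minimum of raw
    noise would otherwise carry.  The wing track is defined as
    ``samples - body_track``, so the two reconstruct the snippet exactly.
    """
    samples = np.asarray(samples, dtype=float)
    if f0 <= 0:
        raise DataError("f0 must be positive")
    win = max(3, int(round(sample_rate / f0)))
    pre = uniform_filter1d(samples, max(1, win // 8), mode="nearest")
    body = minimum_filter1d(pre, win, mode="nearest")
    body = uniform_filter1d(body, win, mode="nearest")
    wing = samples - body
    return body, wing


def wing_peak_envelope(
    wing_track: np.ndarray,
    f0: float,
    sample_rate: float,
) -> np.ndarray:
    """Upper envelope of the wing track: rolling maximum over one period."""
    win = max(3, int(round(sample_rate / f0)))
    return maximum_filter1d(np.asarray(wing_track, dtype=float), win,
                            mode="nearest")


def _central_slice(n: int, fraction: float) -> slice:
    lo = int(round(n * (1 - fraction) / 2))
    hi = int(round(n * (1 + fraction) / 2))
    return slice(lo, max(hi, lo + 1))


def body_to_wing_ratio(
    body_track: np.ndarray,
    wing_track: np.ndarray,
    f0: float,
    sample_rate: float,
    central_fraction: float = 0.5,
) -> float | None:
    """Mean body over mean wing-peak-envelope, central part of the event.

    Restricting to the central 50 % keeps the ratio stable under the
    transit envelope.  Returns ``None`` when the wing envelope vanishes
    (a wingless or non-oscillating transit).
    """
    body_track = np.asarray(body_track, dtype=float)
    wing_track = np.asarray(wing_track, dtype=float)
    if body_track.size == 0 or body_track.shape != wing_track.shape:
        raise DataError("tracks must be non-empty and of equal length")
    sl = _central_slice(body_track.size, central_fraction)
    env = wing_peak_envelope(wing_track, f0, sample_rate)[sl]
    wing_mean = float(env.mean())
    if wing_mean <= 0:
        return None
    return float(body_track[sl].mean() / wing_mean)


def melanisation_index(
    body_by_band: dict[int, np.ndarray],
    wing_by_band: dict[int, np.ndarray],
    f0: float,
    sample_rate: float,
    central_fraction: float = 0.5,
) -> tuple[float | None, float | None]:
    """808/980 amplitude ratios of the body and wing components.

    Inputs are quadrant-summed tracks per band.  Body uses the mean of
    the body track; wing uses the mean of the wing peak envelope — both
    over the central part of the event.  ``None`` where the 980 nm
    denominator vanishes.
    """
    def _mean(track: np.ndarray, env: bool) -> float:
        track = np.asarray(track, dtype=float)
        sl = _central_slice(track.size, central_fraction)
        if env:
            track = wing_peak_envelope(track, f0, sample_rate)
        return float(track[sl].mean())

    b808, b980 = _mean(body_by_band[808], False), _mean(body_by_band[980], False)
    w808, w980 = _mean(wing_by_band[808], True), _mean(wing_by_band[980], True)
    mel_body = b808 / b980 if b980 > 0 else None
    mel_wing = w808 / w980 if w980 > 0 else None
    return mel_body, mel_wing


# --------------------------------------------------------------------------
# kinematics
# --------------------------------------------------------------------------

def _pair_envelope(event: InsectEvent, quads: tuple[int, ...],
                   smooth_win: int) -> np.ndarray:
    rows = quadrant_indices(quads)
    summed = event.snippet[rows].sum(axis=0)
    return uniform_filter1d(summed, smooth_win, mode="nearest")

def _xcorr_lag(late: np.ndarray, early: np.ndarray) -> int:
    """Lag (samples) of ``late`` relative to ``early`` maximising their
    cross-correlation; positive = ``late`` peaks after ``early``.

    The inputs are baseline-removed envelopes, near zero away from the
    transit, so no mean subtraction is applied — removing the mean would
    turn the off-transit stretches into long matching plateaus that bias
    the correlation peak towards zero lag.
    """
    c = sps.correlate(np.clip(late, 0, None), np.clip(early, 0, None),
                      mode="full")
    return int(np.argmax(c)) - (early.size - 1)


def transit_kinematics(
    event: InsectEvent,
    f0: float | None,
    params: FeatureParams | None = None,
) -> tuple[float | None, float | None, str | None, str | None]:
    """Signed quadrant lags and direction classes of one transit.

    The left/right (and bottom/top) quadrant-pair envelopes are summed
    over both bands, smoothed over about one wingbeat period and
    cross-correlated; the lag maximising the correlation gives magnitude
    and sign.  Requires at least two quadrants with a detectable peak;
    lags below ``min_lag_s`` classify as ``"none"``.
    """
    params = params or FeatureParams()
    fs = event.sample_rate
    quad_peaks = {}
    for name, snr in event.peak_snr.items():
        q = int(name[1])
        quad_peaks[q] = max(quad_peaks.get(q, 0.0), snr)
    n_detectable = sum(
        1 for v in quad_peaks.values() if v >= params.kinematics_min_snr
    )
    if n_detectable < 2:
        return None, None, None, None

    smooth = max(3, int(round(fs / f0)) if f0 else int(round(0.010 * fs)))
    left = _pair_envelope(event, LEFT_QUADRANTS, smooth)
    right = _pair_envelope(event, RIGHT_QUADRANTS, smooth)
    top = _pair_envelope(event, TOP_QUADRANTS, smooth)
    bottom = _pair_envelope(event, BOTTOM_QUADRANTS, smooth)

    max_lag = event.duration
    h_lag = _xcorr_lag(right, left) / fs    # + : right later = left->right
    v_lag = _xcorr_lag(top, bottom) / fs    # + : top later   = ascending
    h_lag = float(np.clip(h_lag, -max_lag, max_lag))
    v_lag = float(np.clip(v_lag, -max_lag, max_lag))

    thresh = max(params.min_lag_s, 1.0 / fs)
    if abs(h_lag) < thresh:
        h_class = "none"
    else:
        h_class = "left_to_right" if h_lag > 0 else "right_to_left"
    if abs(v_lag) < thresh:
        v_class = "none"
    else:
        v_class = "ascending" if v_lag > 0 else "descending"
    return h_lag, v_lag, h_class, v_class


# --------------------------------------------------------------------------
# validity and orchestration
# --------------------------------------------------------------------------

def validate_event(
    features: EventFeatures,
    rain: bool = False,
) -> EventFeatures:
    """Apply the automatic removal rule: events during heavy rain or
    without a distinguishable wingbeat frequency are flagged invalid."""
    if rain:
        features.valid = False
        features.invalid_reason = "rain"
    elif features.f0 is None:
        features.valid = False
        features.invalid_reason = "no-wbf"
    else:
        features.valid = True
        features.invalid_reason = None
    return features


def extract_features(
    event: InsectEvent,
    params: FeatureParams | None = None,
    rain: bool = False,
) -> EventFeatures:
    """Compute all features of one event.

    The WBF is estimated from the sum of all 8 channels (maximum SNR);
    per-band quadrant sums feed the melanisation indices.
    """
    params = params or FeatureParams()
    fs = event.sample_rate
    feats = EventFeatures(
        peak_snr=max(event.peak_snr.values()) if event.peak_snr else 0.0,
        duration_s=event.duration,
        start_time_s=event.start_time_s,
        device_id=event.device_id,
    )

    combined = event.snippet.sum(axis=0)
    if event.duration >= params.min_duration_s and combined.size >= 8:
        psd = estimate_psd(combined, fs, params)
        feats.f0 = fundamental_frequency(psd, params)
    else:
        feats.f0 = None

    if feats.f0 is not None:
        f0 = feats.f0
        k_max = min(params.max_harmonics,
                    harmonic_capacity(f0, params.passband_hz))
        feats.harmonic_amps = [psd.power_at(k * f0)
                               for k in range(1, k_max + 1)]

        body, wing = body_wing_decompose(combined, f0, fs)
        feats.body_track, feats.wing_track = body, wing
        feats.body_to_wing_ratio = body_to_wing_ratio(
            body, wing, f0, fs, params.central_fraction
        )

        body_by_band, wing_by_band = {}, {}
        for band in BANDS:
            band_sum = event.snippet[band_indices(band)].sum(axis=0)
            b, w = body_wing_decompose(band_sum, f0, fs)
            body_by_band[band], wing_by_band[band] = b, w
        feats.melanisation_body, feats.melanisation_wing = melanisation_index(
            body_by_band, wing_by_band, f0, fs, params.central_fraction
        )

    (feats.horiz_lag_s, feats.vert_lag_s,
     feats.horiz_class, feats.vert_class) = transit_kinematics(
        event, feats.f0, params
    )
    return validate_event(feats, rain=rain)


def features_table(features: list[EventFeatures]) -> pd.DataFrame:
    """Tidy per-event feature table (tracks omitted; absent values NaN)."""
    if not features:
        return pd.DataFrame(columns=list(EventFeatures._TABLE_FIELDS))
    return pd.DataFrame([f.to_record() for f in features])
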