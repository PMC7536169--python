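"""Acoustic measurements used to verify rendered stimuli.

These routines recover the intended acoustic parameters from audio: spectral
centroid of the steady-state segment, attack time from the amplitude
envelope, the number of resolved spectral peaks, the mean harmonic-ratio
deviation (beta) summarising spectral flux, and an envelope-fluctuation proxy
for the beating introduced by detuned partials.
"""

from __future__ import annotations

import numpy as np
from scipy import signal
from scipy.ndimage import maximum_filter1d, uniform_filter1d

from .errors import UndefinedMeasurementError
from .synthesis import FLUX_BASE_RATIOS, FluxParams, RenderedAudio

__all__ = [
    "steady_state_segment",
    "magnitude_spectrum",
    "measured_spectral_centroid",
    "amplitude_envelope",
    "measured_attack_time",
    "harmonic_deviation_beta",
    "count_spectral_peaks",
    "envelope_fluctuation",
    "measured_filter_q",
]

#: Fraction of the tone treated as steady state: past the longest attack
#: (291 of 700 ms ~ 42%) and before the decay ramp.
STEADY_SEGMENT = (0.45, 0.90)

_SILENCE_RMS = 1e-9


def _require_signal(audio: RenderedAudio) -> np.ndarray:
    x = np.asarray(audio.samples, dtype=float)
    if x.size == 0 or np.sqrt(np.mean(x**2)) < _SILENCE_RMS:
        raise UndefinedMeasurementError("measurement undefined for silent audio")
    return x


def steady_state_segment(
    audio: RenderedAudio, segment: tuple[float, float] = STEADY_SEGMENT
) -> np.ndarray:
    """Extract the sustain portion of a tone as a sample array."""
    x = _require_signal(audio)
    lo, hi = segment
    return x[int(lo * len(x)) : int(hi * len(x))]


def magnitude_spectrum(
    samples: np.ndarray, sample_rate: int, min_fft: int = 2**15
) -> tuple[np.ndarray, np.ndarray]:
    """Flat-top-windowed magnitude spectrum, zero-padded to ``min_fft``."""
    n = len(samples)
    win = signal.windows.flattop(n)
    n_fft = max(min_fft, n)
    spec = np.abs(np.fft.rfft(samples * win, n_fft))
    freqs = np.fft.rfftfreq(n_fft, 1.0 / sample_rate)
    return freqs, spec


def measured_spectral_centroid(
    audio: RenderedAudio, segment: tuple[float, float] = STEADY_SEGMENT
) -> float:
    """Amplitude-weighted mean frequency of the steady-state spectrum (Hz)."""
    seg = steady_state_segment(audio, segment)
    freqs, spec = magnitude_spectrum(seg, audio.sample_rate_hz)
    total = spec.sum()
    if total <= 0:
        raise UndefinedMeasurementError("empty spectrum")
    return float(np.sum(freqs * spec) / total)


def amplitude_envelope(
    audio: RenderedAudio, smooth_ms: float = 1.0, window_ms: float = 6.0
) -> np.ndarray:
    """Macro amplitude envelope of a tone.

    The magnitude of the analytic signal still ripples at the waveform's
    crest rate; a causal (past-aligned) maximum filter of ``window_ms``
    flattens that ripple without delaying a rising ramp — for a window
    covering at least one fundamental period the sustain of a harmonic tone
    comes out flat.  A short moving average then removes the staircase.
    """
    x = _require_signal(audio).copy()
    # taper the end so an abruptly truncated signal does not produce a
    # Gibbs overshoot in the analytic-signal magnitude
    n_taper = min(int(round(5e-3 * audio.sample_rate_hz)), len(x) // 10)
    if n_taper > 1:
        x[-n_taper:] *= 0.5 * (1.0 + np.cos(np.linspace(0.0, np.pi, n_taper)))
    env = np.abs(signal.hilbert(x))
    if window_ms > 0:
        size = max(1, int(round(window_ms * audio.sample_rate_hz / 1000.0)))
        size += 1 - size % 2  # odd size so the causal origin is valid
        env = maximum_filter1d(env, size, origin=size // 2, mode="nearest")
    width = max(1, int(round(smooth_ms * audio.sample_rate_hz / 1000.0)))
    return uniform_filter1d(env, width)


def measured_attack_time(
    audio: RenderedAudio,
    low: float = 0.01,
    high: float = 0.99,
    smooth_ms: float = 1.0,
    window_ms: float = 6.0,
) -> float:
    """Attack time in ms: from the envelope crossing ``low``x peak until it
    first reaches ``high``x peak.

    The analytic-signal magnitude overshoots at an abrupt signal end, so the
    trailing edge is excluded when locating the peak.
    """
    env = amplitude_envelope(audio, smooth_ms=smooth_ms, window_ms=window_ms)
    margin = min(int(round(window_ms * audio.sample_rate_hz / 1000.0)) + 1, len(env) // 10)
    peak = env[: len(env) - margin].max()
    if peak <= 0:
        raise UndefinedMeasurementError("flat envelope")
    above_low = np.flatnonzero(env >= low * peak)
    above_high = np.flatnonzero(env >= high * peak)
    t0, t1 = above_low[0], above_high[0]
    return 1000.0 * (t1 - t0) / audio.sample_rate_hz


def harmonic_deviation_beta(flux: FluxParams) -> float:
    """Mean absolute deviation of the four detuned partial ratios from their
    whole-number bases (3, 4, 5, 6) — the beta summary of spectral flux."""
    return float(
        np.mean([abs(r - b) for r, b in zip(flux.ratios, FLUX_BASE_RATIOS)])
    )


def count_spectral_peaks(
    audio: RenderedAudio,
    threshold: float = 0.05,
    segment: tuple[float, float] = STEADY_SEGMENT,
) -> int:
    """Number of local maxima in the steady-state magnitude spectrum that
    exceed ``threshold`` x the global maximum."""
    seg = steady_state_segment(audio, segment)
    _, spec = magnitude_spectrum(seg, audio.sample_rate_hz)
    floor = threshold * spec.max()
    peaks, _ = signal.find_peaks(spec, height=floor, prominence=floor / 2)
    return int(len(peaks))


def envelope_fluctuation(
    audio: RenderedAudio,
    f0_hz: float | None = None,
    segment: tuple[float, float] = STEADY_SEGMENT,
    window_ms: float | None = None,
) -> float:
    """Relative standard deviation of the steady-state macro envelope.

    With the max-filter window at one fundamental period (pass ``f0_hz``, or
    a ``window_ms`` directly; default 6 ms), a harmonic tone's sustain
    envelope is flat while detuned partials leave slower beating residuals,
    so this index grows with the flux slider; it is a qualitative roughness
    proxy, not a calibrated psychoacoustic roughness model.
    """
    if window_ms is None:
        window_ms = 1000.0 / f0_hz if f0_hz else 6.0
    x = _require_signal(audio)
    lo, hi = segment
    env = amplitude_envelope(audio, smooth_ms=1.0, window_ms=window_ms)[
        int(lo * len(x)) : int(hi * len(x))
    ]
    return float(np.std(env) / np.mean(env))


def measured_filter_q(
    b: np.ndarray, a: np.ndarray, sample_rate: int, n_freq: int = 2**18
) -> tuple[float, float, float]:
    """Measure a band-pass filter's (centre_hz, bandwidth_hz, q) from its
    frequency response: the peak frequency and the -3 dB crossing points."""
    freqs, h = signal.freqz(b, a, worN=n_freq, fs=sample_rate)
    mag = np.abs(h)
    i_peak = int(np.argmax(mag))
    half = mag[i_peak] / np.sqrt(2.0)
    below_lo = np.flatnonzero(mag[:i_peak] <= half)
    below_hi = np.flatnonzero(mag[i_peak:] <= half)
    if below_lo.size == 0 or below_hi.size == 0:
        raise UndefinedMeasurementError("-3 dB points not bracketed")
    f_lo = freqs[below_lo[-1]]
    f_hi = freqs[i_peak + below_hi[0]]
    centre = float(freqs[i_peak])
    bandwidth = float(f_hi - f_lo)
    return centre, bandwidth, centre / bandwidth
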