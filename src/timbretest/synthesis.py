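"""Stimulus synthesis for the three timbre dimensions.

A stimulus is a complex tone built from eight sine partials (the fundamental
plus seven overtones at integer multiples 2..8 of f0).  Three slider-driven
link functions map a dimensionless 0-100 slider onto acoustic parameters:

* **envelope** — attack/decay times follow an exponential (base 1.03) curve,
  affinely calibrated so that attack runs 5 -> 291 ms and decay runs
  50 -> 5 ms across the slider; attack and decay are inversely coupled.
* **spectral flux** — four of the partials (base multiples 3, 4, 5 and 6 of
  f0) are detuned linearly from their integer ratios, two upward and two
  downward, producing beating between near-coincident partials.
* **spectral centroid** — a band-pass filter with constant quality factor
  Q = 1.8 whose centre frequency moves 600 -> 1000 Hz as the square of the
  normalised slider position (700 Hz at slider 50).

Trial audio repeats the tone three times with an 800 ms silent gap between
repetitions (offset-to-onset).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.io import wavfile

from .errors import AudioInputError, SliderRangeError

__all__ = [
    "SLIDER_MIN",
    "SLIDER_MAX",
    "ATTACK_RANGE_MS",
    "DECAY_RANGE_MS",
    "ENVELOPE_GROWTH_BASE",
    "FLUX_BASE_RATIOS",
    "FLUX_DETUNED_RATIOS",
    "CENTROID_RANGE_HZ",
    "Q_FACTOR",
    "N_PARTIALS",
    "DEFAULT_SAMPLE_RATE",
    "DEFAULT_TONE_DURATION_MS",
    "DEFAULT_REPETITION_INTERVAL_MS",
    "DEFAULT_N_REPETITIONS",
    "DEFAULT_PITCH_SET",
    "EnvelopeParams",
    "FluxParams",
    "CentroidParams",
    "StimulusSpec",
    "RenderedAudio",
    "note_to_hz",
    "envelope_link",
    "flux_link",
    "centroid_link",
    "bandpass_coefficients",
    "synthesize_tone",
    "render_trial",
    "write_audio",
    "read_audio",
]

SLIDER_MIN = 0.0
SLIDER_MAX = 100.0

ATTACK_RANGE_MS = (5.0, 291.0)
DECAY_RANGE_MS = (50.0, 5.0)
ENVELOPE_GROWTH_BASE = 1.03

FLUX_BASE_RATIOS = (3.0, 4.0, 5.0, 6.0)
FLUX_DETUNED_RATIOS = (3.3, 3.7, 5.2, 5.8)

CENTROID_RANGE_HZ = (600.0, 1000.0)
Q_FACTOR = 1.8

N_PARTIALS = 8
DEFAULT_SAMPLE_RATE = 44100
DEFAULT_TONE_DURATION_MS = 700.0
DEFAULT_REPETITION_INTERVAL_MS = 800.0
DEFAULT_N_REPETITIONS = 3

#: Five test pitches: named endpoints G3 and A#4 with three interior notes.
DEFAULT_PITCH_SET = ("G3", "C4", "E4", "G4", "A#4")

_NOTE_SEMITONES = {"C": -9, "D": -7, "E": -5, "F": -4, "G": -2, "A": 0, "B": 2}
_NOTE_RE = re.compile(r"^([A-Ga-g])([#b]?)(-?\d+)$")


def note_to_hz(note: str, a4_hz: float = 440.0) -> float:
    """Convert a note name such as ``'A#4'`` or ``'G3'`` to Hz (12-TET)."""
    m = _NOTE_RE.match(note.strip())
    if m is None:
        raise AudioInputError(f"cannot parse note name {note!r}")
    letter, accidental, octave = m.groups()
    semis = _NOTE_SEMITONES[letter.upper()]
    semis += {"#": 1, "b": -1, "": 0}[accidental]
    semis += 12 * (int(octave) - 4)
    return a4_hz * 2.0 ** (semis / 12.0)


def _check_slider(value: float) -> float:
    value = float(value)
    if not (SLIDER_MIN <= value <= SLIDER_MAX) or not np.isfinite(value):
        raise SliderRangeError(
            f"slider value {value} outside [{SLIDER_MIN}, {SLIDER_MAX}]"
        )
    return value


@dataclass(frozen=True)
class EnvelopeParams:
    """Attack and decay ramp durations in milliseconds."""

    attack_ms: float
    decay_ms: float


@dataclass(frozen=True)
class FluxParams:
    """Frequency ratios (multiples of f0) of the four detuned partials."""

    ratios: tuple[float, float, float, float]


@dataclass(frozen=True)
class CentroidParams:
    """Band-pass filter centre frequency and quality factor."""

    centre_hz: float
    q_factor: float = Q_FACTOR

    @property
    def bandwidth_hz(self) -> float:
        return self.centre_hz / self.q_factor


@dataclass(frozen=True)
class StimulusSpec:
    """Complete description of one trial's target tone."""

    f0_hz: float
    envelope_slider: float = 50.0
    flux_slider: float = 50.0
    centroid_slider: float = 50.0
    tone_duration_ms: float = DEFAULT_TONE_DURATION_MS
    n_repetitions: int = DEFAULT_N_REPETITIONS
    repetition_interval_ms: float = DEFAULT_REPETITION_INTERVAL_MS

    def __post_init__(self) -> None:
        if self.f0_hz <= 0:
            raise AudioInputError(f"f0 must be positive, got {self.f0_hz}")
        if self.tone_duration_ms <= 0:
            raise AudioInputError(
                f"tone duration must be positive, got {self.tone_duration_ms}"
            )
        if self.n_repetitions < 1:
            raise AudioInputError("need at least one repetition")
        for s in (self.envelope_slider, self.flux_slider, self.centroid_slider):
            _check_slider(s)

    def with_slider(self, dimension: str, value: float) -> "StimulusSpec":
        """Return a copy with the slider of ``dimension`` replaced."""
        key = {
            "envelope": "envelope_slider",
            "flux": "flux_slider",
            "centroid": "centroid_slider",
        }[dimension]
        return replace(self, **{key: value})


@dataclass(frozen=True)
class RenderedAudio:
    """A sampled mono waveform with samples in [-1, 1]."""

    sample_rate_hz: int
    samples: np.ndarray = field(repr=False)

    @property
    def duration_ms(self) -> float:
        return 1000.0 * len(self.samples) / self.sample_rate_hz


def envelope_link(s: float) -> EnvelopeParams:
    """Map a slider position to attack/decay times.

    Both ramps follow ``A * 1.03**s + B`` with (A, B) calibrated so the curve
    passes exactly through the endpoint values: attack 5 ms at slider 0 and
    291 ms at slider 100; decay 50 ms at slider 0 and 5 ms at slider 100.
    """
    s = _check_slider(s)
    return EnvelopeParams(
        attack_ms=_exp_affine(s, *ATTACK_RANGE_MS),
        decay_ms=_exp_affine(s, *DECAY_RANGE_MS),
    )


def _exp_affine(s: float, lo: float, hi: float) -> float:
    gain = ENVELOPE_GROWTH_BASE**SLIDER_MAX - 1.0
    a = (hi - lo) / gain
    return a * (ENVELOPE_GROWTH_BASE**s - 1.0) + lo


def flux_link(s: float) -> FluxParams:
    """Map a slider position to the four detuned partial ratios (linear)."""
    s = _check_slider(s)
    frac = s / SLIDER_MAX
    ratios = tuple(
        base + frac * (detuned - base)
        for base, detuned in zip(FLUX_BASE_RATIOS, FLUX_DETUNED_RATIOS)
    )
    return FluxParams(ratios=ratios)


def centroid_link(s: float) -> CentroidParams:
    """Map a slider position to the filter centre frequency.

    The centre follows 600 + 400 * (s/100)**2 Hz, i.e. a square-law link that
    places the reference 700 Hz at slider 50; Q is fixed at 1.8.
    """
    s = _check_slider(s)
    lo, hi = CENTROID_RANGE_HZ
    x = s / SLIDER_MAX
    return CentroidParams(centre_hz=lo + (hi - lo) * x * x, q_factor=Q_FACTOR)


def bandpass_coefficients(
    centre_hz: float, q_factor: float = Q_FACTOR, sample_rate: int = DEFAULT_SAMPLE_RATE
) -> tuple[np.ndarray, np.ndarray]:
    """Second-order resonator (b, a) with -3 dB bandwidth = centre / Q."""
    return signal.iirpeak(centre_hz, q_factor, fs=sample_rate)


def partial_multiples(flux: FluxParams) -> tuple[float, ...]:
    """The eight partial frequencies as multiples of f0.

    Partials at base multiples 1, 2, 7, 8 stay harmonic; those at base
    multiples 3, 4, 5, 6 take the flux-link ratios.
    """
    r = flux.ratios
    return (1.0, 2.0, r[0], r[1], r[2], r[3], 7.0, 8.0)


def _amplitude_envelope(
    n_samples: int, attack_ms: float, decay_ms: float, sample_rate: int
) -> np.ndarray:
    n_attack = int(round(attack_ms * sample_rate / 1000.0))
    n_decay = int(round(decay_ms * sample_rate / 1000.0))
    if n_attack + n_decay > n_samples:
        # compress both ramps proportionally for very short tones
        scale = n_samples / (n_attack + n_decay)
        n_attack = int(n_attack * scale)
        n_decay = n_samples - n_attack
    env = np.ones(n_samples)
    if n_attack > 0:
        env[:n_attack] = np.linspace(0.0, 1.0, n_attack, endpoint=False)
    if n_decay > 0:
        env[n_samples - n_decay :] = np.linspace(1.0, 0.0, n_decay, endpoint=False)
    return env


def synthesize_tone(
    spec: StimulusSpec,
    *,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    apply_filter: bool = True,
    apply_envelope: bool = True,
) -> RenderedAudio:
    """Render one complex tone for the given stimulus specification.

    Eight equal-amplitude sine partials are summed, band-pass filtered at the
    centroid-link centre frequency, shaped by a linear attack/sustain/decay
    amplitude envelope, and peak-normalised.  ``apply_filter=False`` and
    ``apply_envelope=False`` are analysis hooks that bypass those stages.
    """
    n = int(round(spec.tone_duration_ms * sample_rate / 1000.0))
    if n < 2:
        raise AudioInputError("tone duration shorter than two samples")
    t = np.arange(n) / sample_rate
    multiples = partial_multiples(flux_link(spec.flux_slider))
    x = np.zeros(n)
    for m in multiples:
        x += np.sin(2.0 * np.pi * spec.f0_hz * m * t)
    x /= N_PARTIALS

    if apply_filter:
        centroid = centroid_link(spec.centroid_slider)
        b, a = bandpass_coefficients(centroid.centre_hz, centroid.q_factor, sample_rate)
        x = signal.lfilter(b, a, x)

    if apply_envelope:
        env_params = envelope_link(spec.envelope_slider)
        x = x * _amplitude_envelope(
            n, env_params.attack_ms, env_params.decay_ms, sample_rate
        )

    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak
    return RenderedAudio(sample_rate_hz=sample_rate, samples=x)


def render_trial(
    spec: StimulusSpec,
    *,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    gap_mode: str = "offset_to_onset",
) -> RenderedAudio:
    """Render trial audio: the tone repeated with silent gaps.

    With the default ``offset_to_onset`` gap mode the repetition interval is
    an 800 ms silence between the end of one tone and the start of the next;
    ``onset_to_onset`` instead spaces tone onsets by the interval (the tone
    must then fit inside the interval).
    """
    tone = synthesize_tone(spec, sample_rate=sample_rate)
    if spec.n_repetitions == 1:
        return tone
    if gap_mode == "offset_to_onset":
        gap_ms = spec.repetition_interval_ms
    elif gap_mode == "onset_to_onset":
        gap_ms = spec.repetition_interval_ms - spec.tone_duration_ms
        if gap_ms < 0:
            raise AudioInputError(
                "tone longer than the onset-to-onset repetition interval"
            )
    else:
        raise AudioInputError(f"unknown gap mode {gap_mode!r}")
    n_gap = int(round(gap_ms * sample_rate / 1000.0))
    silence = np.zeros(n_gap)
    parts = []
    for i in range(spec.n_repetitions):
        if i:
            parts.append(silence)
        parts.append(tone.samples)
    return RenderedAudio(sample_rate_hz=sample_rate, samples=np.concatenate(parts))


def write_audio(audio: RenderedAudio, path) -> None:
    """Write a rendered waveform as 16-bit PCM mono WAV."""
    x = np.clip(audio.samples, -1.0, 1.0)
    pcm = np.round(x * 32767.0).astype(np.int16)
    wavfile.write(path, audio.sample_rate_hz, pcm)


def read_audio(path) -> RenderedAudio:
    """Read a WAV file back into a float waveform in [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32767.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483647.0
    else:
        samples = data.astype(np.float64)
    return RenderedAudio(sample_rate_hz=int(rate), samples=samples)
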