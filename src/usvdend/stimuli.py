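"""Synthesis and manipulation of ultrasonic-vocalization-like stimuli.

Mouse ultrasonic vocalizations (USVs) are near-pure frequency-modulated
whistles confined to roughly 30-120 kHz.  This module generates syllable
stand-ins (~100 ms FM tones with cosine onset/offset ramps) and provides the
stimulus constructions used throughout the pipeline: superposition of two
syllables at a controlled time lag, pitch shifting by semitones,
concatenation into adaptation trains with silent gaps, and calibration of
the peak level in dB SPL re 20 uPa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import ShortTimeFFT, resample
from scipy.signal.windows import hann

logger = logging.getLogger(__name__)

#: Reference sound pressure for dB SPL, in pascals.
P_REF = 20e-6

#: Frequency band of mouse USV content handled by the pipeline, in kHz.
USV_BAND_KHZ = (30.0, 120.0)

#: Default sampling rate, Hz.  Nyquist-safe for 120 kHz content.
DEFAULT_RATE = 250_000.0


@dataclass
class AudioClip:
    """A calibrated mono pressure waveform.

    Parameters
    ----------
    samples : ndarray
        Sound pressure in pascals.
    rate : float
        Sampling rate in Hz.
    label : str
        Free-text identifier.
    """

    samples: np.ndarray
    rate: float = DEFAULT_RATE
    label: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("AudioClip requires a mono (1-D) waveform")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("AudioClip samples must all be finite")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_samples / self.rate

    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * (1000.0 / self.rate)


@dataclass(frozen=True)
class SyllableSpec:
    """Parameters of one synthetic USV-like syllable.

    ``contour`` selects how the instantaneous frequency moves from
    ``f_start`` to ``f_end``: ``constant`` holds ``f_start``, ``linear``
    sweeps linearly, and ``sinusoidal`` follows a smooth half-cosine sweep
    (slow at the endpoints, fast in the middle), loosely mimicking the
    arched contours of natural syllables.
    """

    f_start: float  # kHz
    f_end: float  # kHz
    duration_ms: float = 100.0
    contour: str = "linear"  # constant | linear | sinusoidal
    amplitude_db_spl: float = 85.0
    seed: int = 0
    rate: float = DEFAULT_RATE
    #: "flat" keeps the energy uniform over the syllable; "bumps"
    #: concentrates it in a few randomly placed humps, emulating the
    #: amplitude modulation that makes natural syllables temporally
    #: distinct from one another.
    envelope: str = "flat"

    def validate(self) -> None:
        lo, hi = USV_BAND_KHZ
        for f in (self.f_start, self.f_end):
            if not (lo <= f <= hi):
                raise ValueError(
                    f"syllable frequency {f} kHz outside USV band "
                    f"[{lo}, {hi}] kHz"
                )
        if self.contour not in ("constant", "linear", "sinusoidal"):
            raise ValueError(f"unknown contour {self.contour!r}")
        if self.envelope not in ("flat", "bumps"):
            raise ValueError(f"unknown envelope {self.envelope!r}")
        if self.duration_ms <= 2 * 5.0:
            raise ValueError("syllable must be longer than twice the 5-ms ramp")
        if self.rate < 2 * USV_BAND_KHZ[1] * 1000:
            raise ValueError("sampling rate undersamples the USV band")


def synth_syllable(spec: SyllableSpec) -> AudioClip:
    """Synthesize one FM-tone syllable from its spec.

    The waveform is a single-component tone whose instantaneous frequency
    follows the requested contour; a 5-ms cosine ramp is applied to each
    end and the peak level is calibrated to ``spec.amplitude_db_spl``.
    Deterministic given ``spec.seed`` (the seed sets the carrier's start
    phase).
    """
    spec.validate()
    n = int(round(spec.duration_ms * 1e-3 * spec.rate))
    t = np.arange(n) / spec.rate  # seconds
    f0 = spec.f_start * 1e3
    f1 = spec.f_end * 1e3
    if spec.contour == "constant":
        f_inst = np.full(n, f0)
    elif spec.contour == "linear":
        f_inst = f0 + (f1 - f0) * t / t[-1]
    else:  # sinusoidal: half-cosine sweep between the endpoints
        f_inst = f0 + (f1 - f0) * 0.5 * (1 - np.cos(np.pi * t / t[-1]))
    rng = np.random.default_rng(spec.seed)
    phi0 = rng.uniform(0, 2 * np.pi)
    phase = phi0 + 2 * np.pi * np.cumsum(f_inst) / spec.rate
    samples = np.sin(phase)
    if spec.envelope == "bumps":
        # one or two narrow energy humps at random positions; the deep
        # modulation survives the encoder's cube-root compression
        n_bumps = int(rng.integers(1, 3))
        centers = rng.uniform(0.15, 0.85, n_bumps) * t[-1]
        width = 0.04 * t[-1]
        env = np.zeros(n)
        for c in centers:
            env += np.exp(-0.5 * ((t - c) / width) ** 2)
        samples = samples * (0.02 + env / env.max())
    clip = AudioClip(
        samples,
        rate=spec.rate,
        label=f"syl_{spec.contour}_{spec.f_start:g}-{spec.f_end:g}kHz",
    )
    clip = apply_cosine_ramp(clip)
    return calibrate_level(clip, spec.amplitude_db_spl)


def apply_cosine_ramp(clip: AudioClip, ramp_ms: float = 5.0) -> AudioClip:
    """Apply raised-cosine onset/offset ramps of ``ramp_ms`` to a clip."""
    n_ramp = int(round(ramp_ms * 1e-3 * clip.rate))
    if clip.n_samples <= 2 * n_ramp:
        raise ValueError(
            f"clip of {clip.duration_ms:.1f} ms too short for "
            f"{ramp_ms:.1f}-ms ramps"
        )
    env = np.ones(clip.n_samples)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    env[:n_ramp] = ramp
    env[-n_ramp:] = ramp[::-1]
    return replace(clip, samples=clip.samples * env)


def calibrate_level(clip: AudioClip, peak_db_spl: float = 85.0) -> AudioClip:
    """Scale the clip so its peak absolute pressure is ``peak_db_spl``.

    Peak pressure is ``10**(peak_db_spl / 20) * 20 uPa``; 85 dB SPL is the
    ceiling used for stimulus presentation.
    """
    peak = np.max(np.abs(clip.samples))
    if peak == 0:
        raise ValueError("cannot calibrate an all-zero clip")
    target = 10.0 ** (peak_db_spl / 20.0) * P_REF
    return replace(clip, samples=clip.samples * (target / peak))


def peak_frequency_khz(clip: AudioClip, nfft: int = 4096) -> float:
    """Frequency (kHz) of the largest magnitude bin of the clip's spectrum."""
    spec = np.abs(np.fft.rfft(clip.samples, n=max(nfft, clip.n_samples)))
    freqs = np.fft.rfftfreq(max(nfft, clip.n_samples), d=1.0 / clip.rate)
    return freqs[int(np.argmax(spec))] / 1e3


def _phase_vocoder_stretch(x: np.ndarray, rate: float, factor: float,
                           n_fft: int = 1024) -> np.ndarray:
    """Time-stretch ``x`` by ``factor`` (>1 lengthens) at constant pitch."""
    hop = n_fft // 4
    win = hann(n_fft, sym=False)
    stft = ShortTimeFFT(win, hop=hop, fs=rate, fft_mode="onesided")
    S = stft.stft(x)
    n_bins, n_frames = S.shape
    # Fractional analysis-frame positions for each synthesis frame.
    steps = np.arange(0, n_frames - 1, 1.0 / factor)
    omega = 2 * np.pi * hop * np.arange(n_bins) / n_fft  # expected advance
    out = np.empty((n_bins, steps.size), dtype=complex)
    phase = np.angle(S[:, 0])
    for i, step in enumerate(steps):
        j = int(step)
        frac = step - j
        mag = (1 - frac) * np.abs(S[:, j]) + frac * np.abs(S[:, j + 1])
        out[:, i] = mag * np.exp(1j * phase)
        dphi = np.angle(S[:, j + 1]) - np.angle(S[:, j]) - omega
        dphi -= 2 * np.pi * np.round(dphi / (2 * np.pi))
        phase = phase + omega + dphi
    return stft.istft(out, k1=int(round(x.size * factor)))


def pitch_shift(clip: AudioClip, semitones: float) -> AudioClip:
    """Shift all spectral components by ``2**(semitones / 12)`` in frequency.

    Duration is preserved: the waveform is phase-vocoder time-stretched by
    the frequency ratio and then resampled back to the original length,
    which scales every component's frequency by the ratio.  If the shifted
    peak frequency leaves the 30-120 kHz band a warning is logged and the
    clip is returned anyway.
    """
    if semitones == 0:
        return replace(clip, samples=clip.samples.copy())
    ratio = 2.0 ** (semitones / 12.0)
    stretched = _phase_vocoder_stretch(clip.samples, clip.rate, ratio)
    shifted = resample(stretched, clip.n_samples)
    out = AudioClip(
        shifted, rate=clip.rate,
        label=f"{clip.label}_shift{semitones:+g}st" if clip.label else "",
    )
    peak = peak_frequency_khz(out)
    lo, hi = USV_BAND_KHZ
    if not (lo <= peak <= hi):
        logger.warning(
            "pitch shift by %+g semitones moved the peak frequency to "
            "%.1f kHz, outside [%g, %g] kHz", semitones, peak, lo, hi,
        )
    return out


def superimpose(a: AudioClip, b: AudioClip, lag_ms: float = 0.0) -> AudioClip:
    """Sample-wise sum of two clips with ``b``'s onset delayed by ``lag_ms``.

    Negative lags advance ``b``; the common time origin shifts so that no
    samples are discarded.  The output spans the union of both clips'
    supports, zero-padded elsewhere.
    """
    if a.rate != b.rate:
        raise ValueError("cannot superimpose clips with different rates")
    shift = int(round(lag_ms * 1e-3 * a.rate))
    a_start = max(0, -shift)
    b_start = max(0, shift)
    n = max(a_start + a.n_samples, b_start + b.n_samples)
    out = np.zeros(n)
    out[a_start:a_start + a.n_samples] += a.samples
    out[b_start:b_start + b.n_samples] += b.samples
    return AudioClip(out, rate=a.rate,
                     label=f"({a.label})+({b.label})@{lag_ms:g}ms")


def adaptation_train(adapter: AudioClip, deviant: AudioClip, n_adapt: int,
                     gap_ms: float = 15.0) -> tuple[AudioClip, list[float]]:
    """Concatenate ``n_adapt`` adapter repeats then the deviant syllable.

    Consecutive syllables are separated by ``gap_ms`` of silence (15 ms in
    the cross-adaptation protocol).  Returns the waveform and the onset
    time (ms) of every syllable, the deviant last.
    """
    if n_adapt < 1:
        raise ValueError("n_adapt must be >= 1")
    if adapter.rate != deviant.rate:
        raise ValueError("rate mismatch between adapter and deviant")
    gap = np.zeros(int(round(gap_ms * 1e-3 * adapter.rate)))
    pieces, onsets = [], []
    pos = 0
    for _ in range(n_adapt):
        onsets.append(1000.0 * pos / adapter.rate)
        pieces.append(adapter.samples)
        pos += adapter.n_samples
        pieces.append(gap)
        pos += gap.size
    onsets.append(1000.0 * pos / adapter.rate)
    pieces.append(deviant.samples)
    clip = AudioClip(np.concatenate(pieces), rate=adapter.rate,
                     label=f"train_{n_adapt}x({adapter.label})+({deviant.label})")
    return clip, onsets


# ---------------------------------------------------------------------------
# Pair-set generation for the in-silico surveys

_CONTOURS = ("constant", "linear", "sinusoidal")


def _draw_spec(rng: np.random.Generator, f_lo: float, f_hi: float,
               duration_ms: float, amplitude_db_spl: float,
               envelope: str = "flat") -> SyllableSpec:
    """One random syllable spec with both endpoints inside [f_lo, f_hi]."""
    contour = _CONTOURS[rng.integers(len(_CONTOURS))]
    f_start = rng.uniform(f_lo, f_hi)
    if contour == "constant":
        f_end = f_start
    else:
        # Sweep of at least 5 kHz but staying inside the band.
        span = rng.uniform(5.0, min(20.0, f_hi - f_lo))
        direction = 1 if rng.random() < 0.5 else -1
        f_end = np.clip(f_start + direction * span, f_lo, f_hi)
    return SyllableSpec(
        f_start=float(f_start), f_end=float(f_end),
        duration_ms=duration_ms, contour=contour,
        amplitude_db_spl=amplitude_db_spl,
        seed=int(rng.integers(2**31)),
        envelope=envelope,
    )


def generate_pair_set(
    n_pairs: int,
    spectral_separation: str = "mixed",
    seed: int = 0,
    duration_ms: float = 100.0,
    amplitude_db_spl: float = 85.0,
) -> list[tuple[AudioClip, AudioClip]]:
    """Generate a reproducible set of syllable pairs for the surveys.

    ``spectral_separation`` controls the within-pair spectral-feature
    distance: ``low`` draws both syllables from the same narrow frequency
    region (overlapping bands), ``high`` draws them from disjoint low/high
    halves of the USV band, and ``mixed`` alternates between the two
    regimes pair by pair.

    The temporal structure covaries the way it does in natural pairs of
    co-occurring syllables: same-band pairs get independent bumpy
    amplitude envelopes (so their energy time courses decorrelate), while
    disjoint-band pairs keep flat envelopes (temporally coincident
    energy).  This yields both clustered-and-uncorrelated and
    dispersed-and-correlated synaptic input patterns on a tonotopically
    wired dendritic tree.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if spectral_separation not in ("low", "mixed", "high"):
        raise ValueError(f"unknown spectral_separation {spectral_separation!r}")
    rng = np.random.default_rng(seed)
    lo, hi = USV_BAND_KHZ
    pairs = []
    for i in range(n_pairs):
        if spectral_separation == "high" or (
                spectral_separation == "mixed" and i % 2 == 0):
            spec_a = _draw_spec(rng, lo + 5, 55.0, duration_ms,
                                amplitude_db_spl, envelope="flat")
            spec_b = _draw_spec(rng, 85.0, hi - 5, duration_ms,
                                amplitude_db_spl, envelope="flat")
        else:
            center = rng.uniform(lo + 15, hi - 15)
            spec_a = _draw_spec(rng, center - 10, center + 10, duration_ms,
                                amplitude_db_spl, envelope="bumps")
            spec_b = _draw_spec(rng, center - 10, center + 10, duration_ms,
                                amplitude_db_spl, envelope="bumps")
        a = synth_syllable(spec_a)
        b = synth_syllable(spec_b)
        a.label = f"pair{i}_a_{a.label}"
        b.label = f"pair{i}_b_{b.label}"
        pairs.append((a, b))
    return pairs
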