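"""Stimulus dissimilarity and synaptic-input overlap metrics.

Two stimulus distances are provided: the Euclidean distance between
flattened magnitude spectrograms, and the Euclidean distance between
spectral feature vectors (mean, quartiles, bandwidth of the power
spectrum in a 55-ms window around the firing response).  A temporal
correlation between the stimuli's power profiles complements them.

On the model side, spatial and temporal profiles of AMPA conductance
across the dendritic tree quantify how much two stimuli overlap in where
and when they deliver synaptic input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal import ShortTimeFFT, periodogram
from scipy.signal.windows import hann

from .neuron import SimResult
from .stimuli import AudioClip


@dataclass(frozen=True)
class SpectrogramConfig:
    nfft: int = 1024
    overlap: float = 0.75  # fraction of nfft

    def validate(self) -> None:
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must lie in [0, 1)")

    @property
    def hop(self) -> int:
        return max(1, int(round(self.nfft * (1 - self.overlap))))


def spectrogram(clip: AudioClip,
                config: SpectrogramConfig = SpectrogramConfig()
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hann-window STFT magnitude -> (S, freqs_hz, times_ms)."""
    config.validate()
    if clip.n_samples < config.nfft:
        raise ValueError("clip shorter than one FFT window")
    win = hann(config.nfft, sym=False)
    stft = ShortTimeFFT(win, hop=config.hop, fs=clip.rate,
                        fft_mode="onesided")
    S = np.abs(stft.stft(clip.samples))
    times_ms = stft.t(clip.n_samples) * 1e3
    return S, stft.f, times_ms


def _matched_spectrograms(a: AudioClip, b: AudioClip,
                          config: SpectrogramConfig
                          ) -> tuple[np.ndarray, np.ndarray]:
    if a.rate != b.rate:
        raise ValueError("rate mismatch")
    sa, _, _ = spectrogram(a, config)
    sb, _, _ = spectrogram(b, config)
    n = max(sa.shape[1], sb.shape[1])
    sa = np.pad(sa, ((0, 0), (0, n - sa.shape[1])))
    sb = np.pad(sb, ((0, 0), (0, n - sb.shape[1])))
    return sa, sb


def spectrogram_distance(a: AudioClip, b: AudioClip,
                         config: SpectrogramConfig = SpectrogramConfig(),
                         db_scale: bool = False) -> float:
    """Euclidean distance between flattened (onset-aligned) spectrograms.

    The shorter clip is zero-padded to the longer one's frame count.
    ``db_scale`` switches from magnitude to dB magnitudes.
    """
    sa, sb = _matched_spectrograms(a, b, config)
    if db_scale:
        floor = 1e-12
        sa = 20 * np.log10(np.maximum(sa, floor))
        sb = 20 * np.log10(np.maximum(sb, floor))
    return float(np.linalg.norm(sa.ravel() - sb.ravel()))


@dataclass(frozen=True)
class SpectralFeatures:
    """Moments and quartiles of the power spectrum (kHz)."""

    mean_khz: float
    q1_khz: float
    q2_khz: float
    q3_khz: float
    sd_khz: float

    def vector(self) -> np.ndarray:
        return np.array([self.mean_khz, self.q1_khz, self.q2_khz,
                         self.q3_khz, self.sd_khz])


def spectral_features(clip: AudioClip, center_ms: float | None = None,
                      window_ms: float = 55.0) -> SpectralFeatures:
    """Spectral mean, quartiles and bandwidth of a windowed segment.

    The window (default 55 ms) is centered on ``center_ms`` — typically
    the PSTH peak of the response — and clipped at the clip's edges.
    Features are moments of the normalized power spectral density from a
    single periodogram of the segment.
    """
    if center_ms is None:
        center_ms = clip.duration_ms / 2
    half = window_ms / 2
    i0 = int(round(max(0.0, center_ms - half) * 1e-3 * clip.rate))
    i1 = int(round(min(clip.duration_ms, center_ms + half) * 1e-3 * clip.rate))
    seg = clip.samples[i0:i1]
    if seg.size < 16 or not np.any(seg):
        raise ValueError("silent or empty analysis window")
    freqs, psd = periodogram(seg, fs=clip.rate)
    total = psd.sum()
    p = psd / total
    f_khz = freqs / 1e3
    mean = float(np.sum(f_khz * p))
    sd = float(np.sqrt(np.sum((f_khz - mean) ** 2 * p)))
    cum = np.cumsum(p)
    q1, q2, q3 = np.interp([0.25, 0.5, 0.75], cum, f_khz)
    return SpectralFeatures(mean_khz=mean, q1_khz=float(q1),
                            q2_khz=float(q2), q3_khz=float(q3), sd_khz=sd)


def spectral_feature_distance(fa: SpectralFeatures,
                              fb: SpectralFeatures) -> float:
    """Euclidean distance between (mean, q1, q2, q3, sd) feature vectors."""
    return float(np.linalg.norm(fa.vector() - fb.vector()))


def power_profile(clip: AudioClip,
                  config: SpectrogramConfig = SpectrogramConfig()
                  ) -> np.ndarray:
    """Frequency-averaged spectrogram: the stimulus energy time course."""
    S, _, _ = spectrogram(clip, config)
    return S.mean(axis=0)


def temporal_correlation(a: AudioClip, b: AudioClip,
                         window_ms: tuple[float, float] | None = None,
                         config: SpectrogramConfig = SpectrogramConfig()
                         ) -> float:
    """Pearson correlation between the two clips' power profiles."""
    sa, sb = _matched_spectrograms(a, b, config)
    pa, pb = sa.mean(axis=0), sb.mean(axis=0)
    if window_ms is not None:
        frame_ms = 1e3 * config.hop / a.rate
        i0 = max(0, int(window_ms[0] / frame_ms))
        i1 = min(pa.size, int(np.ceil(window_ms[1] / frame_ms)))
        pa, pb = pa[i0:i1], pb[i0:i1]
    if pa.size < 3:
        raise ValueError("need at least 3 profile points")
    if np.std(pa) == 0 or np.std(pb) == 0:
        raise ValueError("correlation undefined for a constant power profile")
    return float(stats.pearsonr(pa, pb).statistic)


@dataclass
class BranchProfiles:
    """Where (spatial) and when (temporal) AMPA input arrives.

    ``spatial`` is the per-dendrite time integral of the summed AMPA
    gating variable; ``temporal`` its per-step sum across dendrites.
    """

    spatial: np.ndarray  # (n_dendrites,)
    temporal: np.ndarray  # (n_steps,)
    dt_ms: float


def branch_profiles(result: SimResult) -> BranchProfiles:
    return BranchProfiles(spatial=result.s_ampa.sum(axis=0) * result.dt_ms,
                          temporal=result.s_ampa.sum(axis=1),
                          dt_ms=result.dt_ms)


def overlap_category(profiles_a: BranchProfiles, profiles_b: BranchProfiles,
                     temporal_threshold: float = 0.3,
                     spatial_threshold: float = 0.1
                     ) -> tuple[float, float, str]:
    """Correlate two stimuli's input profiles and label the input pattern.

    Returns ``(r_spatial, r_temporal, label)``.  Inputs dispersed across
    different branches but coincident in time ("dispersed-and-correlated",
    r_temporal above / r_spatial below threshold) contrast with inputs
    hitting the same branches at different times
    ("clustered-and-uncorrelated"); other combinations are unlabeled.
    The default thresholds can be replaced by dataset medians.
    """
    n = max(profiles_a.temporal.size, profiles_b.temporal.size)
    ta = np.pad(profiles_a.temporal, (0, n - profiles_a.temporal.size))
    tb = np.pad(profiles_b.temporal, (0, n - profiles_b.temporal.size))
    for v in (profiles_a.spatial, profiles_b.spatial, ta, tb):
        if np.std(v) == 0:
            raise ValueError("overlap undefined for a constant profile")
    r_spatial = float(stats.pearsonr(profiles_a.spatial,
                                     profiles_b.spatial).statistic)
    r_temporal = float(stats.pearsonr(ta, tb).statistic)
    if r_temporal > temporal_threshold and r_spatial < spatial_threshold:
        label = "dispersed-and-correlated"
    elif r_temporal < temporal_threshold and r_spatial > spatial_threshold:
        label = "clustered-and-uncorrelated"
    else:
        label = "unlabeled"
    return r_spatial, r_temporal, label
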