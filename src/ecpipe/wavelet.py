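"""Continuous-wavelet instantaneous phase in the two analysis bands.

The analytic Morlet wavelet (centre frequency 1 Hz, i.e. omega0 = 2*pi in
the angular convention) is applied in the frequency domain: the signal is
FFT'd once and multiplied by the wavelet's spectrum at each scale.  The
instantaneous phase of a band is the angle of the complex coefficients
averaged over the band's frequency bins (averaging complex values, not
angles, is safe under phase wrapping), unwrapped by cumulative
principal-value increments.  Samples inside the cone of influence (COI) -
the edge region where the stretched wavelet overlaps the record boundary -
are trimmed symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, ResolutionError
from .io_fnirs import Recording

OMEGA0 = 2.0 * np.pi  # Morlet angular centre frequency (1 Hz)

#: scale <-> frequency factor, spectral-peak convention: the wavelet
#: spectrum exp(-(s*w - omega0)^2 / 2) at scale_for_freq(f) peaks exactly
#: at f, so a pure tone's response is maximal at its own frequency
_FOURIER_FACTOR = 2 * np.pi / OMEGA0


@dataclass(frozen=True)
class FrequencyBand:
    """A named physiological frequency interval (Hz)."""

    name: str
    f_lo: float
    f_hi: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ConfigError("need 0 < f_lo < f_hi")


#: interval I: myogenic activity; interval II: neurogenic activity
BAND_I = FrequencyBand("I", 0.052, 0.145, "myogenic")
BAND_II = FrequencyBand("II", 0.021, 0.052, "neurogenic")
DEFAULT_BANDS = (BAND_I, BAND_II)


@dataclass
class PhaseSeries:
    """Unwrapped per-channel instantaneous phases in one band.

    ``offset`` is the number of COI samples trimmed from the start of the
    original record (the same count is trimmed from the end).
    """

    phases: np.ndarray  # (n_channels, n_samples), radians
    band: FrequencyBand
    fs: float
    offset: int = 0

    def __post_init__(self) -> None:
        self.phases = np.atleast_2d(np.asarray(self.phases, dtype=float))
        if not np.all(np.isfinite(self.phases)):
            raise ValueError("phases contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.phases.shape[0]

    @property
    def n_samples(self) -> int:
        return self.phases.shape[1]


def scale_for_freq(freq: float | np.ndarray) -> np.ndarray:
    """Wavelet scale (seconds) whose Fourier-equivalent frequency is freq."""
    return 1.0 / (_FOURIER_FACTOR * np.asarray(freq, dtype=float))


def coi_samples(freq: float | np.ndarray, fs: float) -> np.ndarray:
    """Edge width (samples) of the cone of influence at each frequency.

    Uses the e-folding time sqrt(2)*scale of the Morlet envelope.
    """
    return np.ceil(np.sqrt(2.0) * scale_for_freq(freq) * fs).astype(int)


def band_freq_grid(
    band: FrequencyBand, voices: int = 20
) -> np.ndarray:
    """Logarithmic frequency grid spanning the band (>= 20 voices)."""
    if voices < 3:
        raise ConfigError("need at least 3 voices per band")
    return np.geomspace(band.f_lo, band.f_hi, voices)


def cwt(
    signal: np.ndarray, fs: float, freqs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic Morlet CWT at the given frequencies.

    Returns (coeffs, coi_mask): complex coefficients of shape
    (n_freqs, n_samples) and a boolean mask of the same shape, True where
    the coefficient is edge-contaminated (inside the cone of influence).
    """
    x = np.asarray(signal, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0.005) or np.any(freqs >= 2.0):
        raise ConfigError(
            "analysis frequencies must lie strictly inside the filtered "
            "0.005-2 Hz range"
        )
    n = x.size
    n_fft = int(2 ** np.ceil(np.log2(2 * n)))
    xf = np.fft.fft(x - x.mean(), n_fft)
    omega = 2 * np.pi * np.fft.fftfreq(n_fft, d=1.0 / fs)
    scales = scale_for_freq(freqs)  # seconds
    coeffs = np.empty((freqs.size, n), dtype=complex)
    pos = omega > 0
    for i, s in enumerate(scales):
        # amplitude normalization: a unit sinusoid at the matched
        # frequency yields |W| = 1, independent of scale
        psi_hat = np.zeros(n_fft)
        psi_hat[pos] = 2.0 * np.exp(-0.5 * (s * omega[pos] - OMEGA0) ** 2)
        coeffs[i] = np.fft.ifft(xf * psi_hat)[:n]
    edges = coi_samples(freqs, fs)
    idx = np.arange(n)
    coi_mask = (idx[None, :] < edges[:, None]) | (
        idx[None, :] >= n - edges[:, None]
    )
    return coeffs, coi_mask


def band_phase(
    coeffs: np.ndarray,
    freqs: np.ndarray,
    band: FrequencyBand,
    fs: float,
    trim: bool = True,
) -> tuple[np.ndarray, int]:
    """Unwrapped band phase from CWT coefficients (single channel).

    Complex coefficients are averaged over the band's frequency bins at
    each time point before taking the angle.  Returns (phase, offset):
    ``offset`` COI samples were removed from each end when ``trim``.
    """
    freqs = np.asarray(freqs, dtype=float)
    sel = (freqs >= band.f_lo) & (freqs <= band.f_hi)
    if sel.sum() < 3:
        raise ResolutionError(
            f"band {band.name} covered by only {int(sel.sum())} frequency "
            "bins (need >= 3)"
        )
    mean_coeff = coeffs[sel].mean(axis=0)
    phase = np.unwrap(np.angle(mean_coeff))
    n = phase.size
    offset = int(coi_samples(band.f_lo, fs))
    if not trim:
        return phase, 0
    if 2 * offset >= n:
        raise ResolutionError(
            f"record of {n} samples lies entirely inside the cone of "
            f"influence for band {band.name} (edge = {offset} samples)"
        )
    return phase[offset:n - offset], offset


def extract_all_phases(
    recording: Recording,
    bands: tuple[FrequencyBand, ...] = DEFAULT_BANDS,
    voices: int = 20,
) -> dict[str, PhaseSeries]:
    """Per-band unwrapped phases for every channel of a (preprocessed)
    recording, on a common COI-trimmed time support per band."""
    out: dict[str, PhaseSeries] = {}
    for band in bands:
        freqs = band_freq_grid(band, voices)
        phases = []
        offset = 0
        for k in range(recording.n_channels):
            coeffs, _ = cwt(recording.data[k], recording.fs, freqs)
            ph, offset = band_phase(coeffs, freqs, band, recording.fs)
            phases.append(ph)
        out[band.name] = PhaseSeries(
            phases=np.vstack(phases), band=band, fs=recording.fs,
            offset=offset,
        )
    return out


def band_phase_single(
    signal: np.ndarray, fs: float, band: FrequencyBand, voices: int = 20
) -> tuple[np.ndarray, int]:
    """Convenience: CWT + band phase for one channel."""
    freqs = band_freq_grid(band, voices)
    coeffs, _ = cwt(signal, fs, freqs)
    return band_phase(coeffs, freqs, band, fs)
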