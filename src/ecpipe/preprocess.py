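"""Despiking and zero-phase band-pass filtering of dHbO2 recordings.

Movement artifacts and ambient-light pickup appear as abrupt spikes; they
are detected against a moving average / moving SD and replaced by cubic
spline interpolation over clean neighbours.  A zero-phase Butterworth
band-pass (0.005-2 Hz) then removes slow drifts and uncorrelated
high-frequency noise before phase extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import butter, sosfiltfilt

from .errors import ConfigError, LengthError
from .io_fnirs import Recording


@dataclass(frozen=True)
class PreprocessConfig:
    """Despike + band-pass parameters.

    spike_window_s / spike_z have no published values; the defaults (4 s
    window, 5 moving-SD threshold) follow common fNIRS practice.  The band
    edges are the standard 0.005-2 Hz hemodynamic range and the Butterworth
    order (4, applied forward-backward) balances rolloff against ringing.
    """

    spike_window_s: float = 4.0
    spike_z: float = 5.0
    band_lo: float = 0.005
    band_hi: float = 2.0
    filter_order: int = 4

    def validate(self, fs: float) -> None:
        if self.spike_window_s <= 0:
            raise ConfigError("spike_window_s must be positive")
        if not 0 < self.band_lo < self.band_hi < fs / 2:
            raise ConfigError(
                f"need 0 < band_lo < band_hi < fs/2, got "
                f"({self.band_lo}, {self.band_hi}) at fs={fs}"
            )


def despike(
    signal: np.ndarray, fs: float, config: PreprocessConfig | None = None
) -> tuple[np.ndarray, int]:
    """Replace moving-SD outliers by cubic-spline interpolation.

    Returns (cleaned signal, number of samples replaced).  Output length
    always equals input length.
    """
    config = config or PreprocessConfig()
    x = np.asarray(signal, dtype=float)
    n = x.size
    win = int(round(config.spike_window_s * fs))
    win += 1 - win % 2  # centered odd window
    if win > n:
        raise ConfigError(
            f"spike window of {win} samples exceeds signal length {n}"
        )
    s = pd.Series(x)
    mov_mean = s.rolling(win, center=True, min_periods=1).mean().to_numpy()
    mov_sd = s.rolling(win, center=True, min_periods=2).std().to_numpy()
    mov_sd = np.nan_to_num(mov_sd, nan=0.0)
    dev = np.abs(x - mov_mean)
    floor = 1e-12 * max(1.0, float(np.max(np.abs(x))))
    bad = dev > config.spike_z * np.maximum(mov_sd, floor)
    n_bad = int(bad.sum())
    if n_bad == 0 or n_bad >= n - 1:
        return x.copy(), n_bad
    good = ~bad
    idx = np.arange(n)
    spline = CubicSpline(idx[good], x[good])
    out = x.copy()
    inner = bad & (idx >= idx[good][0]) & (idx <= idx[good][-1])
    out[inner] = spline(idx[inner])
    # leading/trailing outliers: hold the nearest clean value
    lead = bad & (idx < idx[good][0])
    trail = bad & (idx > idx[good][-1])
    out[lead] = x[good][0]
    out[trail] = x[good][-1]
    return out, n_bad


def bandpass(
    signal: np.ndarray, fs: float, config: PreprocessConfig | None = None
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass."""
    config = config or PreprocessConfig()
    config.validate(fs)
    x = np.asarray(signal, dtype=float)
    sos = butter(
        config.filter_order, [config.band_lo, config.band_hi],
        btype="bandpass", fs=fs, output="sos",
    )
    min_len = 3 * (2 * sos.shape[0] + 1)
    n = x.shape[-1]
    if n <= min_len:
        raise LengthError(
            f"signal of {n} samples too short for stable filtering "
            f"(needs > {min_len})"
        )
    # pad over ~3 periods of the low corner so its slow transient settles
    padlen = int(min(n - 1, 3 * fs / config.band_lo))
    return sosfiltfilt(sos, x, axis=-1, padlen=padlen)


def preprocess_recording(
    recording: Recording, config: PreprocessConfig | None = None
) -> tuple[Recording, np.ndarray]:
    """Despike then band-pass every channel.

    Returns (filtered Recording, per-channel despiked-sample fraction).
    """
    config = config or PreprocessConfig()
    out = np.empty_like(recording.data)
    frac = np.empty(recording.n_channels)
    for k in range(recording.n_channels):
        clean, n_bad = despike(recording.data[k], recording.fs, config)
        out[k] = clean
        frac[k] = n_bad / recording.n_samples
    out = bandpass(out, recording.fs, config)
    rec = Recording(
        data=out, fs=recording.fs, subject_id=recording.subject_id,
        group=recording.group, state=recording.state,
    )
    return rec, frac


def qc_exclude(
    despike_fractions: dict[str, np.ndarray],
    max_fraction: float = 0.10,
    min_channels: int = 3,
) -> pd.DataFrame:
    """Flag subjects with excessive artifact contamination.

    A subject is flagged (never silently dropped) when strictly more than
    ``max_fraction`` of samples were despiked on at least ``min_channels``
    channels.  ``despike_fractions`` maps subject id -> per-channel despiked
    fractions (one recording or the worst state).
    """
    rows = []
    for sid, frac in despike_fractions.items():
        frac = np.asarray(frac, dtype=float)
        n_contam = int(np.sum(frac > max_fraction))
        excluded = n_contam >= min_channels
        reason = (
            f">{max_fraction:.0%} samples despiked on {n_contam} channels"
            if excluded else ""
        )
        rows.append(
            dict(
                subject_id=sid, excluded=excluded,
                n_contaminated_channels=n_contam,
                worst_fraction=float(frac.max()), reason=reason,
            )
        )
    return pd.DataFrame(rows)
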