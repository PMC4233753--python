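"""Morlet wavelet spectral features of postural time series.

Each postural mode time series ``y_k(t)`` is converted into per-frame
amplitudes ``S(k, f; t)`` of a Morlet continuous wavelet transform on a
dyadic (log2-uniform) grid of frequency channels between a minimum
frequency and the Nyquist frequency.  Concatenating all modes gives a
per-frame spectral feature vector; normalizing each frame to unit sum
turns it into a probability distribution over mode-frequency channels,
which is the object all downstream embedding distances are computed on.

The amplitude normalization is chosen so that a unit-amplitude sinusoid
at a channel's centre frequency produces the same peak response (1.0) at
every channel, making channels directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrequencyChannels",
    "FeatureSeries",
    "dyadic_channels",
    "morlet_amplitude",
    "build_features",
]


@dataclass(frozen=True)
class FrequencyChannels:
    """A dyadically spaced set of frequency channels.

    Attributes
    ----------
    freqs : ndarray
        Strictly increasing channel centre frequencies in Hz;
        ``freqs[0] == f_min`` and ``freqs[-1] == f_max``.
    f_min, f_max : float
        Band edges in Hz. ``f_max`` is conventionally the Nyquist
        frequency of the recording.
    """

    freqs: np.ndarray
    f_min: float
    f_max: float

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.ndim != 1 or f.size < 2:
            raise ValueError("need at least two channels")
        if np.any(np.diff(f) <= 0):
            raise ValueError("channel frequencies must be strictly increasing")
        object.__setattr__(self, "freqs", f)

    def __len__(self) -> int:
        return self.freqs.size


@dataclass
class FeatureSeries:
    """Per-frame spectral feature vectors.

    Attributes
    ----------
    S : ndarray, shape (T, m*F)
        Wavelet amplitudes, mode-major: column ``k*F + j`` is mode ``k``,
        channel ``j``.
    amplitude : ndarray, shape (T,)
        Per-frame total amplitude ``A(t) = sum_{k,f} S(k,f;t)``.
    s_hat : ndarray, shape (T, m*F)
        Normalized features, each retained row summing to one.
    valid : ndarray of bool, shape (T,)
        False where ``A(t) == 0`` (degenerate frames, excluded downstream).
    edge_valid : ndarray of bool, shape (T,)
        False inside the cone of influence of the lowest-frequency
        channel, where zero padding contaminates amplitudes. Frames are
        retained but flagged.
    channels : FrequencyChannels
    n_modes : int
    frame_rate : float
    """

    S: np.ndarray
    amplitude: np.ndarray
    s_hat: np.ndarray
    valid: np.ndarray
    edge_valid: np.ndarray
    channels: FrequencyChannels
    n_modes: int
    frame_rate: float
    mode_index: np.ndarray = field(default=None)  # type: ignore[assignment]
    channel_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        F = len(self.channels)
        if self.mode_index is None:
            self.mode_index = np.repeat(np.arange(self.n_modes), F)
        if self.channel_index is None:
            self.channel_index = np.tile(np.arange(F), self.n_modes)


def dyadic_channels(n: int = 25, f_min: float = 1.0, f_max: float = 50.0) -> FrequencyChannels:
    """Build ``n`` frequency channels uniformly spaced in log2 between
    ``f_min`` and ``f_max`` (inclusive at both ends).

    ``f_i = 2 ** (log2 f_min + (i-1)/(n-1) * log2(f_max/f_min))``.
    """
    if not (0 < f_min < f_max):
        raise ValueError("require 0 < f_min < f_max")
    if n < 2:
        raise ValueError("need n >= 2 channels")
    freqs = np.exp2(np.linspace(np.log2(f_min), np.log2(f_max), n))
    # pin the endpoints exactly (linspace guarantees them up to rounding)
    freqs[0], freqs[-1] = f_min, f_max
    return FrequencyChannels(freqs=freqs, f_min=float(f_min), f_max=float(f_max))


def _morlet_scale(freq_hz: float, frame_rate: float, omega0: float) -> float:
    """Wavelet scale (in samples) whose response peaks at ``freq_hz``.

    Uses the standard centre-frequency relation for the Morlet wavelet,
    ``f = (omega0 + sqrt(2 + omega0**2)) / (4 pi s)``.
    """
    f_cyc = freq_hz / frame_rate  # cycles per sample
    return (omega0 + np.sqrt(2.0 + omega0**2)) / (4.0 * np.pi * f_cyc)


def morlet_amplitude(
    y: np.ndarray,
    channels: FrequencyChannels,
    frame_rate: float,
    omega0: float = 5.0,
) -> np.ndarray:
    """Morlet continuous-wavelet amplitudes of one time series.

    Parameters
    ----------
    y : ndarray, shape (T,)
        Finite time series (one postural mode).
    channels : FrequencyChannels
    frame_rate : float
        Sampling rate in Hz.
    omega0 : float
        Morlet centre frequency (admissibility/resolution trade-off).

    Returns
    -------
    ndarray, shape (T, F)
        Non-negative amplitudes. A unit-amplitude sinusoid at a channel's
        centre frequency yields peak amplitude 1.0 at that channel.

    Notes
    -----
    Computed in the Fourier domain with zero padding at both ends. The
    phase of the transform is discarded: only moduli are returned, which
    makes the features invariant to the temporal alignment of
    oscillations within the analysis window.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("y must be 1-D")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in input series")
    T = y.size
    scales = np.array([_morlet_scale(f, frame_rate, omega0) for f in channels.freqs])
    # pad by 4x the largest scale so circular wrap never reaches the data
    pad = int(np.ceil(4.0 * scales.max()))
    n = T + 2 * pad
    yp = np.zeros(n)
    yp[pad : pad + T] = y
    yf = np.fft.fft(yp)
    omega = 2.0 * np.pi * np.fft.fftfreq(n)  # rad / sample
    out = np.empty((T, len(channels)))
    # frequency response of the (analytic) Morlet wavelet at scale s:
    # psi_hat(s w) = pi^{-1/4} sqrt(2 pi) exp(-(s w - omega0)^2 / 2), w > 0.
    # A unit cosine splits into two exponentials of amplitude 1/2; the
    # negative-frequency lobe is negligible, so dividing by psi_hat(omega0)/2
    # gives unit peak response at the matched channel for every channel.
    peak = np.pi ** (-0.25) * np.sqrt(2.0 * np.pi)
    for j, s in enumerate(scales):
        h = np.where(omega > 0, peak * np.exp(-0.5 * (s * omega - omega0) ** 2), 0.0)
        w = np.fft.ifft(yf * h)
        out[:, j] = (2.0 / peak) * np.abs(w[pad : pad + T])
    return out


def build_features(
    y: np.ndarray,
    channels: FrequencyChannels,
    frame_rate: float,
    omega0: float = 5.0,
) -> FeatureSeries:
    """Concatenate per-mode wavelet amplitudes into per-frame feature vectors.

    Parameters
    ----------
    y : ndarray, shape (m, T)
        Postural time series, one row per mode.
    channels : FrequencyChannels
        Must satisfy ``f_max == frame_rate / 2`` (Nyquist).
    frame_rate : float
    omega0 : float

    Returns
    -------
    FeatureSeries
        With ``S`` of shape (T, m*F) in mode-major column order, the total
        amplitude ``A(t)`` and normalized ``s_hat`` rows summing to one
        wherever ``A(t) > 0``.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if not np.isclose(channels.f_max, frame_rate / 2.0, rtol=1e-9):
        raise ValueError(
            f"channel f_max={channels.f_max} Hz must equal the Nyquist "
            f"frequency {frame_rate / 2.0} Hz"
        )
    m, T = y.shape
    F = len(channels)
    S = np.empty((T, m * F))
    for k in range(m):
        S[:, k * F : (k + 1) * F] = morlet_amplitude(y[k], channels, frame_rate, omega0)
    A = S.sum(axis=1)
    valid = A > 0
    s_hat = np.zeros_like(S)
    s_hat[valid] = S[valid] / A[valid, None]
    # cone of influence of the lowest channel (e-folding time sqrt(2)*s)
    s_max = _morlet_scale(channels.f_min, frame_rate, omega0)
    coi = int(np.ceil(np.sqrt(2.0) * s_max))
    edge_valid = np.ones(T, dtype=bool)
    edge_valid[: min(coi, T)] = False
    edge_valid[max(T - coi, 0) :] = False
    return FeatureSeries(
        S=S,
        amplitude=A,
        s_hat=s_hat,
        valid=valid,
        edge_valid=edge_valid,
        channels=channels,
        n_modes=m,
        frame_rate=float(frame_rate),
    )
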