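"""Phase reconstruction of periodic behavioural bouts.

Within a bout of periodic behaviour the postural modes trace a limit
cycle.  Time is mapped onto a cyclic phase variable: each mode's Hilbert
analytic signal provides a raw "protophase"; each protophase is
corrected to a uniformly rotating genuine phase by a Fourier-series
transform of its empirical distribution; the corrected phases are
combined across modes by a weighted circular mean, weighting modes by
the inverse circular variance of their residuals so uninformative modes
contribute little.  Phase-averaged orbits (mean mode value per phase
bin, with SEM) summarize the stereotyped cycle of a behaviour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "PhaseSeries",
    "PhaseOrbit",
    "NoOscillationError",
    "protophase_hilbert",
    "combine_phases",
    "reconstruct_phase",
    "phase_average",
    "bout_spectrum",
]


class NoOscillationError(ValueError):
    """Raised when a series carries no usable oscillation."""


@dataclass
class PhaseSeries:
    """A reconstructed cyclic phase for one bout."""

    phase: np.ndarray  # wrapped to [0, 2pi)
    unwrapped: np.ndarray
    mean_frequency: float  # Hz, slope of unwrapped phase / 2pi
    weights: np.ndarray  # per-mode combination weights (sum to 1)


@dataclass
class PhaseOrbit:
    """Phase-averaged limit cycle of a behaviour."""

    bin_centers: np.ndarray  # (B,) in [0, 2pi)
    mean: np.ndarray  # (m, B)
    sem: np.ndarray  # (m, B)
    n_bouts: int
    mean_frequency: float  # Hz
    frequency_sem: float
    interpolated_bins: np.ndarray  # bool (B,), True where bins were empty


def protophase_hilbert(
    y: np.ndarray, reliability_dip: float = 0.1
) -> tuple[np.ndarray, bool]:
    """Raw phase estimate of one mode: the angle of the analytic signal
    of the mean-subtracted series.

    Returns ``(protophase, reliable)``; the estimate is flagged
    unreliable when the amplitude envelope dips below ``reliability_dip``
    times its median (phase slips become likely there).

    Raises
    ------
    NoOscillationError
        For a constant series.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("y must be 1-D")
    yc = y - y.mean()
    if np.allclose(yc, 0.0, atol=1e-15):
        raise NoOscillationError("no oscillation: constant series")
    a = hilbert(yc)
    env = np.abs(a)
    reliable = bool(env.min() >= reliability_dip * np.median(env))
    return np.angle(a), reliable


def _fourier_correct(theta_unwrapped: np.ndarray, order: int = 4) -> np.ndarray:
    """Map a protophase to a genuine phase whose distribution is uniform.

    Uses the empirical Fourier coefficients of the protophase density:
    ``phi = theta + sum_{n=1..order} 2 Im[ S_n (e^{i n theta} - 1) / n ]``
    with ``S_n = <e^{-i n theta}>``, which flattens the density to first
    order and keeps the map smooth and monotone for modest deviations.
    """
    theta = theta_unwrapped
    phi = theta.astype(float).copy()
    for n in range(1, order + 1):
        Sn = np.mean(np.exp(-1j * n * theta))
        phi += 2.0 * np.imag(Sn * (np.exp(1j * n * theta) - 1.0) / n)
    return phi


def combine_phases(
    protophases: list[np.ndarray],
    frame_rate: float,
    reliable: list[bool] | None = None,
    fourier_order: int = 4,
) -> PhaseSeries:
    """Combine per-mode protophases into one genuine phase.

    Each protophase is unwrapped (sign-flipped if it advances backwards),
    Fourier-corrected to uniform rotation, and the corrected phases are
    averaged with weights proportional to the inverse circular variance
    of each mode's residual about its own linear trend.  Absolute phase
    offsets are retained, so phase values refer to a fixed position on
    the cycle and orbits can be pooled across bouts.

    Raises
    ------
    NoOscillationError
        If no reliable protophase remains.
    """
    if reliable is None:
        reliable = [True] * len(protophases)
    keep = [i for i, r in enumerate(reliable) if r]
    if not keep:
        raise NoOscillationError("all protophases unreliable")
    T = len(protophases[keep[0]])
    t = np.arange(T)
    corrected: dict[int, np.ndarray] = {}
    weights = np.zeros(len(protophases))
    for i in range(len(protophases)):
        th = np.unwrap(np.asarray(protophases[i], dtype=float))
        if th[-1] < th[0]:  # mode rotating the other way
            th = -th
        phi = _fourier_correct(th, order=fourier_order)
        corrected[i] = phi
        if i in keep:
            slope, icept = np.polyfit(t, phi, 1)
            resid = phi - (slope * t + icept)
            circ_var = 1.0 - np.abs(np.mean(np.exp(1j * resid)))
            weights[i] = 1.0 / max(circ_var, 1e-6)
    weights = weights / weights.sum()
    # align every mode's constant offset to the lowest-index mode
    # (reliability gates the weights only, never the reference), so the
    # combined offset is an intrinsic property of the signal and orbits
    # from different bouts of one behaviour share a phase reference
    ref = corrected[min(corrected)]
    combined = np.zeros(T)
    two_pi = 2.0 * np.pi
    for i in keep:
        phi = corrected[i]
        delta = np.angle(np.mean(np.exp(1j * (ref - phi))))
        phi = phi + delta
        # snap to the reference 2*pi branch before averaging unwrapped phases
        phi += two_pi * np.round(np.mean(ref - phi) / two_pi)
        combined += weights[i] * phi
    # median slope is robust to residual phase slips at low SNR
    freq = float(np.median(np.gradient(combined)) * frame_rate / (2.0 * np.pi))
    unwrapped = np.maximum.accumulate(combined)
    return PhaseSeries(
        phase=np.mod(unwrapped, 2.0 * np.pi),
        unwrapped=unwrapped,
        mean_frequency=freq,
        weights=weights,
    )


def reconstruct_phase(
    y: np.ndarray,
    frame_rate: float,
    fourier_order: int = 4,
    bandpass: bool = True,
) -> PhaseSeries:
    """Reconstruct the cyclic phase of one multi-mode bout.

    Estimates the bout's dominant frequency from the summed mode
    periodograms, band-passes each mode around it (half to double the
    dominant frequency, zero-phase), extracts Hilbert protophases and
    combines them via :func:`combine_phases`.  The band-pass suppresses
    the broadband-noise phase slips that otherwise bias the unwrapped
    phase at low signal-to-noise.
    """
    from scipy.signal import butter, periodogram, sosfiltfilt

    y = np.atleast_2d(np.asarray(y, dtype=float))
    if bandpass:
        psd_sum = None
        for k in range(y.shape[0]):
            f, p = periodogram(y[k], fs=frame_rate, window="hann", detrend="linear")
            psd_sum = p if psd_sum is None else psd_sum + p
        f0 = f[int(np.argmax(psd_sum[1:])) + 1]
        lo = max(f0 / 2.0, f[1])
        hi = min(2.0 * f0, 0.9 * frame_rate / 2.0)
        if hi <= lo:
            raise NoOscillationError("dominant frequency out of band")
        sos = butter(2, [lo, hi], btype="bandpass", fs=frame_rate, output="sos")
        y = np.array([sosfiltfilt(sos, yk) for yk in y])
    protos, flags = [], []
    for yk in y:
        try:
            th, ok = protophase_hilbert(yk)
        except NoOscillationError:
            continue
        protos.append(th)
        flags.append(ok)
    if not protos:
        raise NoOscillationError("no oscillating mode")
    if not any(flags):
        warnings.warn(
            "all protophases have envelope dips; combining them anyway",
            stacklevel=2,
        )
        flags = [True] * len(flags)
    return combine_phases(protos, frame_rate, flags, fourier_order=fourier_order)


def phase_average(
    bouts: list[tuple[np.ndarray, PhaseSeries]],
    n_bins: int = 50,
) -> PhaseOrbit:
    """Phase-averaged orbit over bouts of one behaviour.

    Parameters
    ----------
    bouts : list of ``(y, phase)`` with ``y`` of shape (m, T).

    Returns per-mode mean and SEM of ``y`` in each of ``n_bins`` phase
    bins.  Bin means are computed per bout first and then averaged, so
    the SEM reflects between-bout variability (including phase-estimation
    wobble) rather than the optimistic pooled-frame scatter.  Empty bins
    are filled by circular linear interpolation and flagged.
    """
    if not bouts:
        raise ValueError("need at least one bout")
    m = np.atleast_2d(bouts[0][0]).shape[0]
    edges = np.linspace(0.0, 2.0 * np.pi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    per_bout = np.full((len(bouts), m, n_bins), np.nan)
    freqs = []
    for b, (y, ps) in enumerate(bouts):
        y = np.atleast_2d(np.asarray(y, dtype=float))
        idx = np.clip(np.digitize(ps.phase, edges) - 1, 0, n_bins - 1)
        cnt_b = np.zeros(n_bins)
        np.add.at(cnt_b, idx, 1)
        filled = cnt_b > 0
        for k in range(m):
            s = np.zeros(n_bins)
            np.add.at(s, idx, y[k])
            per_bout[b, k, filled] = s[filled] / cnt_b[filled]
        freqs.append(ps.mean_frequency)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n_eff = np.sum(~np.isnan(per_bout[:, 0, :]), axis=0)  # bouts per bin
        mean = np.nanmean(per_bout, axis=0)
        sd = np.nanstd(per_bout, axis=0, ddof=1) if len(bouts) > 1 else np.zeros((m, n_bins))
    sem = np.where(n_eff > 0, sd / np.sqrt(np.maximum(n_eff, 1)), np.nan)
    sem = np.nan_to_num(sem, nan=0.0)
    empty = n_eff == 0
    if empty.any() and not empty.all():
        good = ~empty
        for k in range(m):
            mean[k, empty] = np.interp(
                centers[empty], centers[good], mean[k, good], period=2.0 * np.pi
            )
            sem[k, empty] = np.interp(
                centers[empty], centers[good], sem[k, good], period=2.0 * np.pi
            )
    freqs_arr = np.array(freqs)
    f_sem = float(freqs_arr.std(ddof=1) / np.sqrt(len(freqs_arr))) if len(freqs_arr) > 1 else 0.0
    return PhaseOrbit(
        bin_centers=centers,
        mean=mean,
        sem=sem,
        n_bouts=len(bouts),
        mean_frequency=float(freqs_arr.mean()),
        frequency_sem=f_sem,
        interpolated_bins=empty,
    )


def bout_spectrum(
    bouts: list[np.ndarray],
    frame_rate: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Average power spectral density over bouts of one behaviour.

    Each bout is detrended, Hann-tapered and zero-padded to a common FFT
    length; periodograms are averaged and the peak frequency is located
    with parabolic interpolation.

    Returns ``(freqs, mean_psd, peak_freq_hz)``.
    """
    from scipy.signal import periodogram

    if not bouts:
        raise ValueError("need at least one bout")
    nfft = int(2 ** np.ceil(np.log2(max(len(b) for b in bouts))))
    nfft = max(nfft, 64)
    psds = []
    for b in bouts:
        b = np.asarray(b, dtype=float)
        f, p = periodogram(
            b, fs=frame_rate, window="hann", nfft=nfft, detrend="linear"
        )
        psds.append(p)
    mean_psd = np.mean(psds, axis=0)
    k = int(np.argmax(mean_psd[1:])) + 1  # skip DC
    if 1 <= k < len(mean_psd) - 1:
        cm, c0, cp = mean_psd[k - 1], mean_psd[k], mean_psd[k + 1]
        denom = cm - 2 * c0 + cp
        frac = 0.0 if denom == 0 else 0.5 * (cm - cp) / denom
    else:
        frac = 0.0
    df = f[1] - f[0]
    return f, mean_psd, float((k + frac) * df)
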