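"""Synthetic behaving-agent generators with known ground truth.

Two levels of fixture are produced:

* **Movies** — an anti-aliased dark elliptical body on a light
  background undergoing rigid rotation/translation, with appendage-like
  oscillating Gaussian blobs, plus additive Gaussian pixel noise.  The
  true per-frame pose (heading, position) is returned alongside, so
  registration can be validated against ground truth.

* **Postural time series** — a Markov chain over K behavioural states,
  each state a multi-mode limit cycle with its own frequency, amplitude
  and mode-loading vectors (a cosine and a sine loading, so each state
  traces a genuine closed orbit), plus additive Gaussian noise.  True
  per-frame state labels are returned.  Cohorts add per-individual
  parameter jitter and optional group effects (e.g. one extra active
  mode in a chosen state for one group).

Defaults emulate a 100 Hz recording with state frequencies spread in
log-frequency between 2 and 32 Hz (well inside the 1-50 Hz analysis
band), mean dwell times of about a second, and signal-to-noise around
ten - periodic within-state dynamics interleaved with pause-move
switching, the statistical structure the mapping pipeline assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imagery import RawMovie
from .postural import PosturalTimeSeries

__all__ = [
    "Appendage",
    "AgentSpec",
    "StateModelSpec",
    "synth_movie",
    "synth_state_timeseries",
    "synth_cohort",
    "default_state_model",
]


# ---------------------------------------------------------------------------
# Movie-level generator
# ---------------------------------------------------------------------------

@dataclass
class Appendage:
    """An oscillating blob attached to the body (body-frame coordinates)."""

    attach: tuple[float, float]  # (x, y) px in body frame
    frequency: float  # Hz
    amplitude: float  # px, oscillation amplitude
    radius: float = 3.0  # px, blob size
    phase: float = 0.0
    intensity: float = 1.0  # relative to body contrast
    axis: tuple[float, float] = (1.0, 0.0)  # oscillation direction, body frame


@dataclass
class AgentSpec:
    """A rigid elliptical body with oscillating appendages and a rigid
    motion trajectory."""

    body_axes: tuple[float, float] = (22.0, 9.0)  # semi-axes, px
    body_intensity: float = 0.65  # contrast against the background
    head_intensity: float = 0.25  # extra blob marking the head (asymmetry)
    appendages: list[Appendage] = field(default_factory=list)
    position: np.ndarray | None = None  # (T, 2) centre per frame
    heading: np.ndarray | None = None  # (T,) degrees per frame
    background: float = 0.9
    noise_sigma: float = 0.02
    dark_body: bool = True  # body darker than background


def _aa_ellipse(xg, yg, cx, cy, a, b, theta_rad):
    """Anti-aliased ellipse indicator via a smooth edge ~1 px wide."""
    dx = xg - cx
    dy = yg - cy
    c, s = np.cos(theta_rad), np.sin(theta_rad)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    r = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    # signed distance approx in px near the boundary
    grad = np.sqrt((u / a**2) ** 2 + (v / b**2) ** 2)
    d = (r - 1.0) / np.maximum(grad, 1e-9) / np.maximum(r, 1e-9)
    return np.clip(0.5 - d, 0.0, 1.0)


def synth_movie(
    spec: AgentSpec,
    T: int = 200,
    frame_rate: float = 100.0,
    frame_size: int = 128,
    seed: int = 0,
) -> tuple[RawMovie, np.ndarray]:
    """Render a synthetic single-agent movie.

    Returns ``(movie, truth)`` with ``truth`` an array of shape (T, 3)
    holding the true per-frame (heading_deg, x, y).  Deterministic given
    the seed.
    """
    rng = np.random.default_rng(seed)
    if spec.position is None:
        pos = np.tile([frame_size / 2.0, frame_size / 2.0], (T, 1))
    else:
        pos = np.asarray(spec.position, dtype=float)
    if spec.heading is None:
        head = np.zeros(T)
    else:
        head = np.asarray(spec.heading, dtype=float)
    a, b = spec.body_axes
    margin = max(
        max(a, b),
        max(
            [np.hypot(*ap.attach) + ap.amplitude + 3 * ap.radius
             for ap in spec.appendages],
            default=0.0,
        ),
    )
    if np.any(pos - margin < 0) or np.any(pos + margin >= frame_size):
        raise ValueError("agent trajectory leaves the frame")
    ys, xs = np.mgrid[0:frame_size, 0:frame_size].astype(float)
    frames = np.empty((T, frame_size, frame_size))
    t_axis = np.arange(T) / frame_rate
    for t in range(T):
        th = np.deg2rad(head[t])
        cx, cy = pos[t]
        body = _aa_ellipse(xs, ys, cx, cy, a, b, th)
        # head marker: brighter blob towards +x of the body frame
        hx = cx + 0.6 * a * np.cos(th)
        hy = cy + 0.6 * a * np.sin(th)
        headblob = spec.head_intensity * np.exp(
            -((xs - hx) ** 2 + (ys - hy) ** 2) / (2 * (0.35 * b) ** 2)
        )
        img = spec.body_intensity * body + headblob * body
        c, s = np.cos(th), np.sin(th)
        for ap in spec.appendages:
            osc = ap.amplitude * np.sin(2 * np.pi * ap.frequency * t_axis[t] + ap.phase)
            bx = ap.attach[0] + osc * ap.axis[0]
            by = ap.attach[1] + osc * ap.axis[1]
            wx = cx + c * bx - s * by
            wy = cy + s * bx + c * by
            img += ap.intensity * spec.body_intensity * np.exp(
                -((xs - wx) ** 2 + (ys - wy) ** 2) / (2 * ap.radius**2)
            )
        img = np.clip(img, 0.0, 1.0)
        frame = spec.background - img if spec.dark_body else img
        frame = frame + rng.normal(0.0, spec.noise_sigma, img.shape)
        frames[t] = np.clip(frame, 0.0, 1.0)
    truth = np.column_stack([head, pos])
    return RawMovie(frames=frames, frame_rate=frame_rate), truth


# ---------------------------------------------------------------------------
# Time-series-level generator
# ---------------------------------------------------------------------------

@dataclass
class StateModelSpec:
    """A Markov-switching multi-mode limit-cycle model.

    Each state k has a frequency, an amplitude and two orthogonal
    loading vectors (cosine and sine components over the m modes), so a
    dwell in state k traces a closed orbit in mode space.
    """

    n_states: int
    n_modes: int
    frequencies: np.ndarray  # (K,) Hz
    amplitudes: np.ndarray  # (K,)
    loadings_cos: np.ndarray  # (K, m)
    loadings_sin: np.ndarray  # (K, m)
    transition: np.ndarray  # (K, K) row-stochastic switching matrix
    noise_sigma: float = 0.1

    def __post_init__(self) -> None:
        P = np.asarray(self.transition, dtype=float)
        if not np.allclose(P.sum(axis=1), 1.0):
            raise ValueError("switching matrix rows must sum to 1")
        if np.any(np.asarray(self.frequencies) <= 0):
            raise ValueError("frequencies must be positive")


def default_state_model(
    n_states: int = 6,
    n_modes: int = 8,
    frame_rate: float = 100.0,
    mean_dwell_s: float = 1.0,
    noise_sigma: float = 0.1,
    f_lo: float = 2.0,
    f_hi: float = 32.0,
    seed: int = 0,
) -> StateModelSpec:
    """A K-state model with log-spaced frequencies and random orthogonal
    mode loadings; dwell times are geometric with the given mean."""
    rng = np.random.default_rng(seed)
    freqs = np.exp2(np.linspace(np.log2(f_lo), np.log2(f_hi), n_states))
    amps = np.ones(n_states)
    Lc = rng.standard_normal((n_states, n_modes))
    Ls = rng.standard_normal((n_states, n_modes))
    for k in range(n_states):
        Lc[k] /= np.linalg.norm(Lc[k])
        Ls[k] -= (Ls[k] @ Lc[k]) * Lc[k]
        Ls[k] /= np.linalg.norm(Ls[k])
    p_stay = 1.0 - 1.0 / (mean_dwell_s * frame_rate)
    K = n_states
    P = np.full((K, K), (1.0 - p_stay) / (K - 1)) if K > 1 else np.ones((1, 1))
    if K > 1:
        np.fill_diagonal(P, p_stay)
    return StateModelSpec(
        n_states=K,
        n_modes=n_modes,
        frequencies=freqs,
        amplitudes=amps,
        loadings_cos=Lc,
        loadings_sin=Ls,
        transition=P,
        noise_sigma=noise_sigma,
    )


def synth_state_timeseries(
    spec: StateModelSpec,
    T: int = 20_000,
    frame_rate: float = 100.0,
    seed: int = 0,
) -> tuple[PosturalTimeSeries, np.ndarray]:
    """Simulate the Markov-switching limit-cycle model.

    Returns ``(series, labels)``; the phase of a state's oscillator
    advances continuously within a dwell and restarts at a random phase
    on each entry.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    K, m = spec.n_states, spec.n_modes
    states = np.empty(T, dtype=int)
    s = int(rng.integers(K))
    cum = np.cumsum(spec.transition, axis=1)
    u = rng.random(T)
    for t in range(T):
        states[t] = s
        s = int(np.searchsorted(cum[s], u[t]))
    y = np.zeros((m, T))
    phase = rng.uniform(0, 2 * np.pi)
    prev = states[0]
    for t in range(T):
        k = states[t]
        if k != prev:
            phase = rng.uniform(0, 2 * np.pi)
            prev = k
        phase += 2 * np.pi * spec.frequencies[k] / frame_rate
        y[:, t] = spec.amplitudes[k] * (
            np.cos(phase) * spec.loadings_cos[k] + np.sin(phase) * spec.loadings_sin[k]
        )
    y += rng.normal(0.0, spec.noise_sigma, y.shape)
    return PosturalTimeSeries(y=y, frame_rate=float(frame_rate)), states


def synth_cohort(
    spec: StateModelSpec,
    n_per_group: tuple[int, int] = (3, 3),
    T: int = 20_000,
    frame_rate: float = 100.0,
    seed: int = 0,
    jitter: float = 0.05,
    group_effect_state: int | None = None,
    group_effect_mode: int | None = None,
    group_effect_amplitude: float = 1.0,
) -> tuple[list[PosturalTimeSeries], list[np.ndarray], np.ndarray]:
    """Simulate a two-group cohort of individuals.

    Each individual gets multiplicative jitter (lognormal scale
    ``jitter``) on its state amplitudes and frequencies.  If a group
    effect is requested, individuals of group 1 gain an extra active
    mode (``group_effect_mode``) oscillating in state
    ``group_effect_state`` with the given amplitude.

    Returns ``(series_list, labels_list, group_labels)``.
    """
    if len(n_per_group) < 1 or min(n_per_group) < 1:
        raise ValueError("need at least one individual per group")
    rng = np.random.default_rng(seed)
    series, labels, groups = [], [], []
    for g, n in enumerate(n_per_group):
        for _ in range(n):
            sub = StateModelSpec(
                n_states=spec.n_states,
                n_modes=spec.n_modes,
                frequencies=spec.frequencies
                * np.exp(rng.normal(0, jitter, spec.n_states)),
                amplitudes=spec.amplitudes
                * np.exp(rng.normal(0, jitter, spec.n_states)),
                loadings_cos=spec.loadings_cos.copy(),
                loadings_sin=spec.loadings_sin.copy(),
                transition=spec.transition,
                noise_sigma=spec.noise_sigma,
            )
            if g == 1 and group_effect_state is not None and group_effect_mode is not None:
                k, j = group_effect_state, group_effect_mode
                lc = sub.loadings_cos[k].copy()
                lc[j] += group_effect_amplitude
                sub.loadings_cos[k] = lc / np.linalg.norm(lc)
            ind_seed = int(rng.integers(2**31 - 1))
            ts, lab = synth_state_timeseries(sub, T=T, frame_rate=frame_rate, seed=ind_seed)
            series.append(ts)
            labels.append(lab)
            groups.append(g)
    return series, labels, np.array(groups)
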