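"""Behavioural maps: density estimation, watershed regions and dynamics.

The embedded trajectory z(t) is turned into a behavioural map by kernel
density estimation on a regular grid followed by a watershed transform
of the negated density: every grid cell is assigned to the density peak
reached by gradient ascent, so each region holds exactly one local
maximum.  Trajectory speed |dz/dt| follows a two-state pause-move
pattern; a two-component lognormal mixture fitted to the speeds defines
a pause threshold, and maximal runs of paused frames inside one region
are the dwells — the bouts of stereotyped behaviour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "BehaviorDensity",
    "RegionMap",
    "SpeedMixture",
    "StateSequence",
    "estimate_density",
    "watershed_regions",
    "trajectory_speed",
    "fit_speed_mixture",
    "assign_states",
    "dwell_statistics",
]


@dataclass
class BehaviorDensity:
    """Gaussian-smoothed probability density over the embedded plane.

    ``grid[i, j]`` is the density at x = xs[j], y = ys[i]; the density
    integrates to one over the extent (sum times cell area).
    """

    grid: np.ndarray
    extent: tuple[float, float, float, float]  # (xmin, xmax, ymin, ymax)
    sigma: float

    @property
    def cell_size(self) -> tuple[float, float]:
        ny, nx = self.grid.shape
        x0, x1, y0, y1 = self.extent
        return (x1 - x0) / nx, (y1 - y0) / ny

    def cell_of(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Grid indices (row, col) of coordinates; -1 where outside."""
        z = np.atleast_2d(z)
        x0, x1, y0, y1 = self.extent
        dx, dy = self.cell_size
        col = np.floor((z[:, 0] - x0) / dx).astype(int)
        row = np.floor((z[:, 1] - y0) / dy).astype(int)
        ny, nx = self.grid.shape
        bad = (col < 0) | (col >= nx) | (row < 0) | (row >= ny)
        col[bad] = -1
        row[bad] = -1
        return row, col


@dataclass
class RegionMap:
    """Watershed-labelled behavioural regions.

    ``labels`` holds integer region ids (1..n_regions, ordered by
    descending peak density); 0 marks boundaries and background.
    """

    labels: np.ndarray
    n_regions: int
    peaks: np.ndarray  # (n_regions, 2) peak coordinates (x, y)
    density: BehaviorDensity


@dataclass
class SpeedMixture:
    """Two-component lognormal mixture over embedded-space speeds."""

    log_means: np.ndarray  # natural-log means, ascending
    log_sds: np.ndarray
    weights: np.ndarray
    threshold: float  # pause/move speed threshold (equal posterior)
    degenerate: bool = False

    @property
    def pause_weight(self) -> float:
        return float(self.weights[0])


@dataclass
class StateSequence:
    """Per-frame behavioural annotation of one individual."""

    region: np.ndarray  # per-frame region id (0 = outside/boundary)
    speed: np.ndarray
    moving: np.ndarray  # bool
    dwells: pd.DataFrame  # columns: region, start, duration_s
    frame_rate: float


def estimate_density(
    z: np.ndarray,
    sigma: float = 1.5,
    grid_size: int = 501,
    extent: tuple[float, float, float, float] | None = None,
) -> BehaviorDensity:
    """Kernel density estimate of embedded points on a regular grid.

    A 2D histogram over the data extent plus a 3-sigma margin is
    convolved with an isotropic Gaussian of width ``sigma`` (in embedding
    units) and normalized to unit integral.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if len(z) < 1:
        raise ValueError("need at least one point")
    if extent is None:
        x0, x1 = z[:, 0].min(), z[:, 0].max()
        y0, y1 = z[:, 1].min(), z[:, 1].max()
        pad = 3.0 * sigma
        extent = (x0 - pad, x1 + pad, y0 - pad, y1 + pad)
    x0, x1, y0, y1 = extent
    H, _, _ = np.histogram2d(
        z[:, 1], z[:, 0], bins=grid_size, range=[[y0, y1], [x0, x1]]
    )
    dx = (x1 - x0) / grid_size
    dy = (y1 - y0) / grid_size
    H = ndimage.gaussian_filter(H, sigma=(sigma / dy, sigma / dx), mode="constant")
    total = H.sum() * dx * dy
    if total > 0:
        H /= total
    return BehaviorDensity(grid=H, extent=extent, sigma=float(sigma))


def watershed_regions(
    density: BehaviorDensity,
    background_threshold: float = 1e-6,
    min_distance: int = 1,
) -> RegionMap:
    """Segment the density into regions, one per local maximum.

    The watershed transform of the negated density is restricted to cells
    whose density exceeds ``background_threshold`` times the maximum;
    watershed lines (and background) are labelled 0.  Region ids are
    assigned in order of descending peak density for reproducibility.
    """
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed

    b = density.grid
    if b.max() <= 0:
        raise ValueError("empty density")
    mask = b > background_threshold * b.max()
    coords = peak_local_max(
        b, min_distance=min_distance, labels=mask, exclude_border=False
    )
    if len(coords) == 0:
        raise ValueError("no density maxima above the background threshold")
    # order markers by descending peak density so labels are reproducible
    order = np.argsort(-b[coords[:, 0], coords[:, 1]], kind="stable")
    coords = coords[order]
    markers = np.zeros_like(b, dtype=np.int32)
    markers[coords[:, 0], coords[:, 1]] = np.arange(1, len(coords) + 1)
    labels = watershed(-b, markers=markers, mask=mask, watershed_line=True)
    x0, x1, y0, y1 = density.extent
    dx, dy = density.cell_size
    peaks_xy = np.column_stack(
        [x0 + (coords[:, 1] + 0.5) * dx, y0 + (coords[:, 0] + 0.5) * dy]
    )
    return RegionMap(
        labels=labels,
        n_regions=int(len(coords)),
        peaks=peaks_xy,
        density=density,
    )


def trajectory_speed(
    z: np.ndarray,
    frame_rate: float,
    smooth_window: float = 0.05,
) -> np.ndarray:
    """Speed |dz/dt| in embedding units per second, by central differences
    with optional Gaussian temporal smoothing (``smooth_window`` in s)."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if len(z) < 3:
        raise ValueError("need at least 3 frames")
    v = np.gradient(z, 1.0 / frame_rate, axis=0)
    speed = np.linalg.norm(v, axis=1)
    if smooth_window and smooth_window > 0:
        speed = ndimage.gaussian_filter1d(speed, sigma=smooth_window * frame_rate)
    return speed


def fit_speed_mixture(
    speeds: np.ndarray,
    seed: int = 0,
    degenerate_weight: float = 0.05,
) -> SpeedMixture:
    """Fit a two-component Gaussian mixture to log speeds by EM.

    Zero speeds are floored at one tenth of the smallest positive value.
    The pause threshold is the speed of equal posterior probability
    between the two components, searched between the two log-means.  If
    one component collapses (weight below ``degenerate_weight`` or
    near-identical means) the fit is flagged degenerate.
    """
    from sklearn.mixture import GaussianMixture

    s = np.asarray(speeds, dtype=float).ravel()
    s = s[np.isfinite(s)]
    pos = s[s > 0]
    if pos.size == 0:
        raise ValueError("all speeds are zero")
    floor = pos.min() / 10.0
    x = np.log(np.maximum(s, floor))[:, None]
    gm = GaussianMixture(
        n_components=2, covariance_type="diag", random_state=seed,
        n_init=3, reg_covar=1e-6,
    ).fit(x)
    mu = gm.means_.ravel()
    sd = np.sqrt(gm.covariances_.ravel())
    w = gm.weights_.ravel()
    order = np.argsort(mu)
    mu, sd, w = mu[order], sd[order], w[order]

    # unimodal if the two log-means sit closer than their combined widths
    degenerate = bool(w.min() < degenerate_weight or (mu[1] - mu[0]) < sd[0] + sd[1])
    if degenerate:
        warnings.warn("speed mixture is effectively single-component", stacklevel=2)

    # equal-posterior crossing between the two log-means
    def post_diff(t: float) -> float:
        lo = np.log(w) - np.log(sd) - 0.5 * ((t - mu) / sd) ** 2
        return lo[0] - lo[1]

    from scipy.optimize import brentq

    if post_diff(mu[0]) > 0 and post_diff(mu[1]) < 0:
        t_star = brentq(post_diff, mu[0], mu[1])
    else:  # no crossing inside the bracket; fall back to the midpoint
        t_star = 0.5 * (mu[0] + mu[1])
    return SpeedMixture(
        log_means=mu,
        log_sds=sd,
        weights=w,
        threshold=float(np.exp(t_star)),
        degenerate=degenerate,
    )


def assign_states(
    z: np.ndarray,
    regions: RegionMap,
    mixture: SpeedMixture,
    frame_rate: float,
    smooth_window: float = 0.05,
    min_dwell: float = 0.05,
) -> StateSequence:
    """Annotate each frame with its region, speed and pause/move state,
    and extract dwells: maximal runs of paused frames within one region,
    lasting at least ``min_dwell`` seconds."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    row, col = regions.density.cell_of(z)
    inside = row >= 0
    region = np.zeros(len(z), dtype=int)
    region[inside] = regions.labels[row[inside], col[inside]]
    speed = trajectory_speed(z, frame_rate, smooth_window)
    moving = speed > mixture.threshold

    recs = []
    run_start = None
    for t in range(len(z) + 1):
        ok = t < len(z) and not moving[t] and region[t] > 0
        if ok and run_start is None:
            run_start = t
        elif run_start is not None and (
            not ok or region[t] != region[run_start]
        ):
            dur = (t - run_start) / frame_rate
            if dur >= min_dwell:
                recs.append((int(region[run_start]), int(run_start), dur))
            run_start = t if ok else None
    dwells = pd.DataFrame(recs, columns=["region", "start", "duration_s"])
    return StateSequence(
        region=region,
        speed=speed,
        moving=moving,
        dwells=dwells,
        frame_rate=float(frame_rate),
    )


def dwell_statistics(
    states: list[StateSequence],
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Pool dwell statistics across individuals.

    Returns
    -------
    occupancy : DataFrame indexed by region with per-individual columns
        (fraction of that individual's frames spent in the region) and a
        pooled ``total`` column.
    durations : ndarray of all dwell durations (s), pooled.
    visitation : DataFrame with, per region, the number of individuals
        having at least one dwell there.
    """
    if len(states) == 0:
        raise ValueError("need at least one individual")
    all_regions = sorted(
        set().union(*[set(np.unique(s.region[s.region > 0])) for s in states])
        | set().union(*[set(s.dwells["region"]) for s in states])
    )
    occ = pd.DataFrame(index=pd.Index(all_regions, name="region"))
    for i, s in enumerate(states):
        counts = pd.Series(s.region).value_counts()
        occ[f"ind_{i}"] = [counts.get(r, 0) / len(s.region) for r in all_regions]
    occ["total"] = occ.mean(axis=1)
    durations = np.concatenate(
        [s.dwells["duration_s"].to_numpy() for s in states]
    ) if any(len(s.dwells) for s in states) else np.empty(0)
    visits = pd.DataFrame(
        {
            "n_individuals": [
                sum(1 for s in states if (s.dwells["region"] == r).any())
                for r in all_regions
            ]
        },
        index=pd.Index(all_regions, name="region"),
    )
    return occ, durations, visits
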