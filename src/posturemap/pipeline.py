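"""End-to-end orchestration: postural series -> behavioural map.

`map_cohort` chains the standard stages for a set of individuals'
postural time series: wavelet feature construction, importance-sampled
training set, t-SNE over KL divergences, re-embedding of held-out
frames, pooled density estimation, watershed segmentation, the
pause-move speed mixture and per-individual state sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import behaviormap as bm
from . import embedding as emb
from . import spectral
from .postural import PosturalTimeSeries

__all__ = ["CohortMap", "map_cohort"]


@dataclass
class CohortMap:
    """Everything produced by a cohort mapping run."""

    features: list[spectral.FeatureSeries]
    model: emb.EmbeddingModel
    z: list[np.ndarray]  # per-individual embedded trajectories
    is_train: list[np.ndarray]
    density: bm.BehaviorDensity
    regions: bm.RegionMap
    mixture: bm.SpeedMixture
    states: list[bm.StateSequence]
    frame_rate: float
    coordinate_scale: float = 1.0  # raw t-SNE units per map unit


def map_cohort(
    series: list[PosturalTimeSeries],
    n_train: int = 5000,
    H: float = 5.0,
    dim: int = 2,
    seed: int = 0,
    n_channels: int = 25,
    f_min: float = 1.0,
    sigma: float = 1.5,
    grid_size: int = 301,
    n_iter: int = 1000,
    background_threshold: float = 1e-3,
    smooth_window: float = 0.05,
    min_dwell: float = 0.05,
    map_radius: float = 6.5,
) -> CohortMap:
    """Build a behavioural map for a cohort of postural time series.

    All randomness (training-set sampling, t-SNE initialization) derives
    from ``seed``.  ``background_threshold`` is relative to the density
    maximum and controls where the watershed stops.

    ``map_radius`` fixes the coordinate units of the final map: embedded
    coordinates are rescaled so the pooled RMS radius equals it.  The raw
    span of a t-SNE solution is arbitrary (it grows with training-set
    size and iteration count), so this normalization is what gives the
    smoothing width ``sigma`` a stable meaning; the default puts the
    standard sigma range (1-2.5) between over-segmentation of single
    behaviours and merging of distinct ones.  Set ``map_radius=None`` to
    keep raw embedding units.
    """
    frame_rate = series[0].frame_rate
    channels = spectral.dyadic_channels(n_channels, f_min, frame_rate / 2.0)
    feats = [spectral.build_features(s.y, channels, frame_rate) for s in series]

    valid_feats = [f.s_hat[f.valid] for f in feats]
    picks = emb.select_training_set(valid_feats, n_train, seed=seed)
    train = np.vstack([vf[p] for vf, p in zip(valid_feats, picks)])
    model = emb.tsne_embed(train, H=H, d=dim, seed=seed, n_iter=n_iter)

    z_list: list[np.ndarray] = []
    train_flags: list[np.ndarray] = []
    offset = 0
    for f, vf, p in zip(feats, valid_feats, picks):
        T = f.S.shape[0]
        valid_idx = np.flatnonzero(f.valid)
        z = np.full((T, dim), np.nan)
        is_train = np.zeros(T, dtype=bool)
        n_p = len(p)
        # training frames keep their trained coordinates
        z[valid_idx[p]] = model.train_coords[offset : offset + n_p]
        is_train[valid_idx[p]] = True
        offset += n_p
        rest = np.setdiff1d(np.arange(len(valid_idx)), p)
        if rest.size:
            z[valid_idx[rest]] = emb.reembed_points(vf[rest], model)
        # degenerate frames: hold the previous coordinate (no dynamics info)
        bad = np.flatnonzero(~f.valid)
        for t in bad:
            z[t] = z[t - 1] if t > 0 else z[np.flatnonzero(f.valid)[0]]
        z_list.append(z)
        train_flags.append(is_train)

    pooled = np.vstack(z_list)
    coordinate_scale = 1.0
    if map_radius is not None:
        rms = float(np.sqrt((pooled**2).sum(axis=1)).mean())
        if rms > 0:
            coordinate_scale = rms / map_radius
            z_list = [z / coordinate_scale for z in z_list]
            pooled = pooled / coordinate_scale
    density = bm.estimate_density(pooled, sigma=sigma, grid_size=grid_size)
    regions = bm.watershed_regions(density, background_threshold=background_threshold)
    speeds = np.concatenate(
        [bm.trajectory_speed(z, frame_rate, smooth_window) for z in z_list]
    )
    mixture = bm.fit_speed_mixture(speeds, seed=seed)
    states = [
        bm.assign_states(z, regions, mixture, frame_rate, smooth_window, min_dwell)
        for z in z_list
    ]
    return CohortMap(
        features=feats,
        model=model,
        z=z_list,
        is_train=train_flags,
        density=density,
        regions=regions,
        mixture=mixture,
        states=states,
        frame_rate=frame_rate,
        coordinate_scale=coordinate_scale,
    )
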