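"""Postural decomposition: PCA eigenmodes of Radon-transformed images.

Aligned egocentric frames are Radon-transformed (line-integral
projections over a fixed angle set) and the resulting pixel vectors are
decomposed by principal component analysis.  The eigenvectors of the
data covariance matrix are the postural modes; projecting each frame
onto the leading m modes converts a movie into an m-dimensional postural
time series y_k(t).

The number of retained modes can be chosen automatically by comparing
the eigenvalue spectrum against that of shuffled data (each coordinate
independently permuted across time, destroying correlations while
preserving marginals): modes whose eigenvalues exceed the shuffled
spectrum carry correlations larger than finite-sampling error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RadonFeatures",
    "ModeBasis",
    "PosturalTimeSeries",
    "radon_transform",
    "radon_features",
    "fit_modes",
    "variance_explained",
    "project_frames",
]

DEFAULT_ANGLES = np.arange(0.0, 180.0, 1.0)


@dataclass
class RadonFeatures:
    """Radon-space feature vectors of an image stack."""

    vectors: np.ndarray  # (T, R)
    angle_set: np.ndarray  # degrees
    image_shape: tuple[int, int]


@dataclass
class ModeBasis:
    """Eigenmodes of the Radon-space pixel covariance matrix C."""

    mean: np.ndarray  # (R,)
    eigenvectors: np.ndarray  # (R, m), orthonormal columns
    eigenvalues: np.ndarray  # descending, length >= m
    m: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-9 * max(self.eigenvalues[0], 1.0)):
            raise ValueError("eigenvalues must be non-increasing")
        if self.m > self.eigenvectors.shape[1]:
            raise ValueError("m exceeds available eigenvectors")


@dataclass
class PosturalTimeSeries:
    """Projections y_k(t) of frames onto the leading postural modes."""

    y: np.ndarray  # (m, T)
    frame_rate: float

    @property
    def n_modes(self) -> int:
        return self.y.shape[0]

    @property
    def n_frames(self) -> int:
        return self.y.shape[1]


def radon_transform(frame: np.ndarray, angles: np.ndarray | None = None) -> np.ndarray:
    """Line-integral projections of one square masked frame over the
    configured angle set, flattened angle-major."""
    from skimage.transform import radon

    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.shape[0] != frame.shape[1]:
        raise ValueError("frame must be square")
    angles = DEFAULT_ANGLES if angles is None else np.asarray(angles, dtype=float)
    sino = radon(frame, theta=angles, circle=True)  # (bins, n_angles)
    return sino.T.ravel()  # angle-major


def radon_features(
    frames: np.ndarray, angles: np.ndarray | None = None
) -> RadonFeatures:
    """Radon-transform a stack of frames into a (T, R) feature matrix."""
    angles = DEFAULT_ANGLES if angles is None else np.asarray(angles, dtype=float)
    frames = np.asarray(frames, dtype=float)
    first = radon_transform(frames[0], angles)
    out = np.empty((len(frames), first.size))
    out[0] = first
    for t in range(1, len(frames)):
        out[t] = radon_transform(frames[t], angles)
    return RadonFeatures(
        vectors=out, angle_set=angles, image_shape=frames.shape[1:]
    )


def _covariance_eigs(X: np.ndarray, chunk: int = 100_000) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean, descending eigenvalues and eigenvectors of the covariance of
    the rows of X, accumulated in chunks along time."""
    T, R = X.shape
    mean = X.mean(axis=0)
    C = np.zeros((R, R))
    for start in range(0, T, chunk):
        B = X[start : start + chunk] - mean
        C += B.T @ B
    C /= T - 1
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    return mean, evals, evecs


def fit_modes(
    features: RadonFeatures | np.ndarray,
    m: int | None = 50,
    seed: int = 0,
    n_shuffles: int = 3,
    max_subsample: int = 500_000,
) -> ModeBasis:
    """Fit postural modes by eigendecomposition of the mean-centred data
    covariance.

    Parameters
    ----------
    features : RadonFeatures or (T, R) array
    m : int or None
        Number of modes to retain. If None, m is chosen automatically as
        the number of eigenvalues exceeding the rank-matched maximum over
        ``n_shuffles`` shuffled-data spectra (each column independently
        permuted across time).
    seed : int
        Seed for the shuffles and any subsampling.
    max_subsample : int
        If T exceeds this, the covariance is estimated from a uniformly
        strided subsample.
    """
    X = features.vectors if isinstance(features, RadonFeatures) else np.asarray(features, dtype=float)
    T, R = X.shape
    if T < 2:
        raise ValueError("need at least two frames")
    if T > max_subsample:
        stride = int(np.ceil(T / max_subsample))
        X = X[::stride]
        T = len(X)
    mean, evals, evecs = _covariance_eigs(X)
    if evals[0] <= 0:
        raise ValueError("zero covariance: input is constant")

    if m is None:
        rng = np.random.default_rng(seed)
        shuf_max = np.zeros_like(evals)
        for _ in range(n_shuffles):
            Xs = X.copy()
            for j in range(R):
                rng.shuffle(Xs[:, j])
            _, ev_s, _ = _covariance_eigs(Xs)
            shuf_max = np.maximum(shuf_max, ev_s)
        m = int(np.sum(evals > shuf_max))
        m = max(m, 1)
    m = min(m, R, T - 1 if T - 1 > 0 else R)
    return ModeBasis(
        mean=mean, eigenvectors=evecs[:, :m], eigenvalues=evals, m=int(m)
    )


def variance_explained(basis: ModeBasis, m: int) -> float:
    """Fraction of total variance captured by the top-m modes."""
    if m > basis.eigenvalues.size:
        raise ValueError("m exceeds the number of eigenvalues")
    total = basis.eigenvalues.sum()
    if total == 0:
        return 0.0
    return float(basis.eigenvalues[:m].sum() / total)


def project_frames(
    features: RadonFeatures | np.ndarray,
    basis: ModeBasis,
    frame_rate: float = 100.0,
) -> PosturalTimeSeries:
    """Project feature vectors onto the postural modes:
    ``y_k(t) = <mode_k, x_t - mean>``."""
    X = features.vectors if isinstance(features, RadonFeatures) else np.asarray(features, dtype=float)
    if X.shape[1] != basis.mean.size:
        raise ValueError("feature dimension does not match the basis")
    y = (X - basis.mean) @ basis.eigenvectors[:, : basis.m]
    return PosturalTimeSeries(y=y.T, frame_rate=float(frame_rate))
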