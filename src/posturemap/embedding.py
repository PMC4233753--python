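"""Low-dimensional embedding of spectral feature distributions.

Per-frame normalized wavelet spectra are treated as probability
distributions over mode-frequency channels and compared with the
Kullback-Leibler (KL) divergence.  Transition probabilities between
frames use a Gaussian kernel of that divergence, with a per-point kernel
width calibrated so every point has the same transition entropy H
(perplexity 2**H, i.e. the same effective neighbour count).  A
t-distributed stochastic neighbour embedding then places points in 2D
(or 3D) so that Cauchy-kernel transition probabilities in the embedded
space match the calibrated ones as closely as possible.

Because the embedding scales as O(N^2) in memory, a training set is
chosen by inverse-density importance sampling so rare behaviours are
represented, the map is built from the training set only, and all
remaining frames are re-embedded one by one against the fixed training
coordinates.

All entropies and divergences use base-2 logarithms: an entropy of
H = 5 bits corresponds to a perplexity of 2**5 = 32 neighbours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TransitionModel",
    "EmbeddingModel",
    "EmbeddedTrajectory",
    "kl_distance",
    "pairwise_kl",
    "calibrate_transitions",
    "tsne_embed",
    "select_training_set",
    "reembed_points",
]

_EPS = 1e-12  # floor on q-channels in KL (zeros only arise from degenerate input)


# ---------------------------------------------------------------------------
# KL divergence distances
# ---------------------------------------------------------------------------

def _check_normalized(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError(f"{name} has negative entries")
    sums = p.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError(f"{name} rows must sum to 1 (got {np.atleast_1d(sums)[:3]}...)")
    return p


def kl_distance(p: np.ndarray, q: np.ndarray, base: float = 2.0) -> float:
    """KL divergence ``sum_c p_c log(p_c / q_c)`` between two normalized
    spectra, with the convention 0*log(0) = 0 and a floor of 1e-12 on q.

    Asymmetric by construction: ``kl_distance(p, q) != kl_distance(q, p)``
    in general.
    """
    p = _check_normalized(p, "p")
    q = _check_normalized(q, "q")
    mask = p > 0
    terms = p[mask] * (np.log(p[mask]) - np.log(np.maximum(q[mask], _EPS)))
    return float(terms.sum() / np.log(base))


def pairwise_kl(P: np.ndarray, Q: np.ndarray | None = None, base: float = 2.0) -> np.ndarray:
    """All-pairs KL divergences d(p_i, q_j) between rows of two stacks of
    normalized spectra, computed as a matrix product:

    ``d(p, q) = sum p log p - p . log q``.

    Returns an (n_p, n_q) matrix; note the asymmetry d(i,j) != d(j,i).
    """
    P = _check_normalized(P, "P")
    Q = P if Q is None else _check_normalized(Q, "Q")
    logQ = np.log(np.maximum(Q, _EPS))
    Pl = np.where(P > 0, P * np.log(np.maximum(P, _EPS)), 0.0)
    neg_entropy = Pl.sum(axis=1)
    D = neg_entropy[:, None] - P @ logQ.T
    np.maximum(D, 0.0, out=D)  # clip numerical negatives
    return D / np.log(base)


# ---------------------------------------------------------------------------
# Entropy-calibrated transition probabilities
# ---------------------------------------------------------------------------

@dataclass
class TransitionModel:
    """Row-stochastic transition probabilities with per-point kernel widths.

    ``P[i, j]`` is the probability of transitioning from point i to point
    j, proportional to ``exp(-D[i,j]**2 / (2 sigma_i**2))`` with
    ``P[i, i] = 0``; each ``sigma_i`` is set so that the base-2 entropy of
    row i equals ``target_entropy`` bits (perplexity ``2**H``).
    """

    sigma: np.ndarray
    P: np.ndarray
    target_entropy: float

    @property
    def perplexity(self) -> float:
        return float(2.0**self.target_entropy)


def _row_entropy_bits(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log2(p), 0.0)
    return -t.sum(axis=-1)


def _calibrate_rows(
    D2: np.ndarray,
    H: float,
    tol: float = 1e-3,
    max_iter: int = 80,
    self_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-row bisection on beta = 1/(2 sigma^2).

    Parameters
    ----------
    D2 : (n, k) squared distances from each of n points to its k candidates.
    self_mask : optional (n, k) bool, True where the candidate is the point
        itself (transition excluded).

    Returns (P rows, sigma).
    """
    n, k = D2.shape
    if 2.0**H > (k - (0 if self_mask is None else 1)):
        raise ValueError("perplexity 2**H exceeds the number of neighbours")
    # scale-aware initial bracket
    scale = np.median(D2[D2 > 0]) if np.any(D2 > 0) else 1.0
    beta = np.full(n, 1.0 / max(scale, _EPS))
    lo = np.zeros(n)
    hi = np.full(n, np.inf)

    def rows_for(beta_: np.ndarray) -> np.ndarray:
        logits = -beta_[:, None] * D2
        if self_mask is not None:
            logits = np.where(self_mask, -np.inf, logits)
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        return p

    # rows whose non-self distances are all identical: entropy is flat in
    # sigma; the uniform row is returned (its entropy may differ from H)
    D2m = np.where(self_mask, np.nan, D2) if self_mask is not None else D2
    with np.errstate(invalid="ignore"):
        flat = ~(np.nanmax(D2m, axis=1) > np.nanmin(D2m, axis=1) + 1e-15)

    for _ in range(max_iter):
        p = rows_for(beta)
        Hrow = _row_entropy_bits(p)
        err = Hrow - H
        done = np.abs(err) < tol
        if np.all(done | flat):
            break
        too_high = err > 0  # entropy too high -> sharpen (increase beta)
        lo = np.where(too_high & ~done, beta, lo)
        hi = np.where(~too_high & ~done, beta, hi)
        beta = np.where(
            too_high & ~done,
            np.where(np.isinf(hi), beta * 2.0, 0.5 * (beta + hi)),
            beta,
        )
        beta = np.where(
            ~too_high & ~done,
            np.where(lo == 0, beta / 2.0, 0.5 * (beta + lo)),
            beta,
        )
    p = rows_for(beta)
    off_target = flat & (np.abs(_row_entropy_bits(p) - H) >= tol)
    if np.any(off_target):
        warnings.warn(
            f"{int(off_target.sum())} row(s) with all-identical distances; "
            "uniform transition rows used",
            stacklevel=2,
        )
    sigma = np.sqrt(1.0 / (2.0 * beta))
    return p, sigma


def calibrate_transitions(D: np.ndarray, H: float = 5.0, tol: float = 1e-3) -> TransitionModel:
    """Calibrate per-point Gaussian kernel widths on a pairwise distance
    matrix so every row of transition probabilities has entropy ``H`` bits.

    Parameters
    ----------
    D : (n, n) ndarray
        Non-negative distances with zero diagonal (need not be symmetric).
    H : float
        Target transition entropy in bits; perplexity is ``2**H``.
    tol : float
        Entropy tolerance in bits.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("D must be square")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("diagonal of D must be zero")
    self_mask = np.eye(n, dtype=bool)
    P, sigma = _calibrate_rows(D**2, H, tol=tol, self_mask=self_mask)
    P[self_mask] = 0.0
    P /= P.sum(axis=1, keepdims=True)
    return TransitionModel(sigma=sigma, P=P, target_entropy=float(H))


# ---------------------------------------------------------------------------
# t-SNE on KL divergences
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingModel:
    """A trained embedding: training spectra, their coordinates and the
    calibration parameters needed to re-embed new points."""

    train_features: np.ndarray
    train_coords: np.ndarray
    target_entropy: float
    seed: int
    n_iter: int
    final_cost: float
    dim: int = 2
    train_indices: np.ndarray | None = None


@dataclass
class EmbeddedTrajectory:
    """Per-frame embedded coordinates with training/re-embedded provenance."""

    z: np.ndarray
    is_train: np.ndarray
    frame_rate: float
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(len(self.z), dtype=bool)


def _q_matrix(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cauchy-kernel joint probabilities in the embedded space."""
    d2 = np.sum(Y**2, axis=1)
    num = d2[:, None] + d2[None, :]
    num -= 2.0 * (Y @ Y.T)
    num += 1.0
    np.reciprocal(num, out=num)
    np.fill_diagonal(num, 0.0)
    Q = num / num.sum()
    return Q, num


def tsne_embed(
    train: np.ndarray,
    H: float = 5.0,
    d: int = 2,
    seed: int = 0,
    n_iter: int = 1000,
    early_exaggeration: float = 12.0,
    exaggeration_iter: int = 250,
    learning_rate: float | None = None,
    distances: np.ndarray | None = None,
    verbose: bool = False,
) -> EmbeddingModel:
    """Embed normalized spectra into ``d`` dimensions by t-SNE over KL
    divergences.

    Conditional transition probabilities are calibrated to entropy ``H``
    bits, symmetrized to joints ``p_ij = (p_{j|i} + p_{i|j}) / 2N``, and
    the embedded coordinates minimize ``KL(P || Q)`` where Q uses a
    Cauchy (Student-t, one degree of freedom) kernel of embedded
    Euclidean distances.  Gradient descent uses momentum, adaptive gains
    and an early-exaggeration phase, and is deterministic given ``seed``.

    Parameters
    ----------
    train : (N, C) normalized spectra (rows sum to 1).
    distances : optional precomputed (N, N) distance matrix; computed as
        pairwise KL if omitted.
    learning_rate : defaults to ``N / early_exaggeration``.
    """
    train = np.asarray(train, dtype=float)
    N = train.shape[0]
    rng = np.random.default_rng(seed)
    if N == 1:
        return EmbeddingModel(
            train_features=train,
            train_coords=np.zeros((1, d)),
            target_entropy=H,
            seed=seed,
            n_iter=0,
            final_cost=0.0,
            dim=d,
        )
    D = pairwise_kl(train) if distances is None else np.asarray(distances, dtype=float)
    model = calibrate_transitions(D, H=H)
    P = (model.P + model.P.T) / (2.0 * N)
    P = np.maximum(P, 1e-30)

    if learning_rate is None:
        learning_rate = max(N / early_exaggeration, 50.0)
    # float32 throughout the descent: halves memory traffic at no cost to
    # the embedding (the objective is optimized to far lower precision)
    P32 = P.astype(np.float32)
    Y = (1e-4 * rng.standard_normal((N, d))).astype(np.float32)
    dY = np.zeros_like(Y)
    gains = np.ones_like(Y)
    Pex = (P * early_exaggeration).astype(np.float32)
    momentum = np.float32(0.5)
    num = np.empty((N, N), np.float32)
    G = np.empty((N, N), np.float32)
    W = np.empty((N, N), np.float32)
    for it in range(n_iter):
        Pt = Pex if it < exaggeration_iter else P32
        if it == exaggeration_iter:
            momentum = np.float32(0.8)
        d2 = np.sum(Y**2, axis=1)
        np.matmul(Y, Y.T, out=G)
        np.add(d2[:, None], d2[None, :], out=num)
        G *= 2.0
        num -= G
        num += 1.0
        np.reciprocal(num, out=num)
        np.fill_diagonal(num, 0.0)
        s = num.sum()
        np.multiply(num, np.float32(-1.0 / s), out=W)  # W = Pt - Q
        W += Pt
        W *= num
        grad = W.sum(axis=1)[:, None] * Y - W @ Y
        grad *= 4.0
        sign_agree = np.sign(grad) == np.sign(dY)
        gains = np.where(sign_agree, gains * np.float32(0.8), gains + np.float32(0.2))
        np.maximum(gains, np.float32(0.01), out=gains)
        dY = momentum * dY - np.float32(learning_rate) * gains * grad
        Y += dY
        Y -= Y.mean(axis=0)
        if verbose and (it + 1) % 100 == 0:
            Q = num / s
            cost = float(np.sum(P * np.log(P / np.maximum(Q, 1e-30))))
            print(f"iter {it + 1}: KL(P||Q) = {cost:.4f}")
    Y = Y.astype(float)
    Q, _ = _q_matrix(Y)
    cost = float(np.sum(P * np.log(P / np.maximum(Q, 1e-30))))
    return EmbeddingModel(
        train_features=train,
        train_coords=Y,
        target_entropy=H,
        seed=seed,
        n_iter=n_iter,
        final_cost=cost,
        dim=d,
    )


# ---------------------------------------------------------------------------
# Importance-sampled training set
# ---------------------------------------------------------------------------

def select_training_set(
    features_per_movie: list[np.ndarray],
    n_total: int,
    seed: int = 0,
    k: int = 32,
) -> list[np.ndarray]:
    """Select training frames across movies by inverse-density importance
    sampling, so rare behaviours are represented.

    Each movie receives a quota proportional to its length (largest
    remainder rounding, so quotas sum exactly to ``n_total``).  Within a
    movie, frames are sampled without replacement with probability
    proportional to their k-th nearest-neighbour distance in feature
    space (an inverse local-density estimate).

    Returns a list of index arrays, one per movie.
    """
    lengths = np.array([len(f) for f in features_per_movie])
    if n_total > lengths.sum():
        raise ValueError("n_total exceeds the number of available frames")
    raw = n_total * lengths / lengths.sum()
    quotas = np.floor(raw).astype(int)
    rem = n_total - quotas.sum()
    if rem > 0:
        order = np.argsort(-(raw - quotas))
        quotas[order[:rem]] += 1
    quotas = np.minimum(quotas, lengths)
    short = n_total - quotas.sum()
    while short > 0:  # redistribute if a movie saturated
        room = lengths - quotas
        i = int(np.argmax(room))
        add = min(short, room[i])
        quotas[i] += add
        short -= add

    from sklearn.neighbors import NearestNeighbors

    rng = np.random.default_rng(seed)
    picks: list[np.ndarray] = []
    max_ref = 2048  # kNN radii against a subsampled reference for long movies
    for f, q in zip(features_per_movie, quotas):
        f = np.asarray(f, dtype=float)
        if q == len(f):
            picks.append(np.arange(len(f)))
            continue
        if len(f) > max_ref:
            ref = f[rng.choice(len(f), size=max_ref, replace=False)]
        else:
            ref = f
        kk = min(k, len(ref) - 1)
        nn = NearestNeighbors(n_neighbors=kk + 1).fit(ref)
        dist, _ = nn.kneighbors(f)
        w = dist[:, -1]  # k-NN radius ~ 1 / local density
        if w.sum() <= 0:
            w = np.ones(len(f))
        w = w / w.sum()
        picks.append(np.sort(rng.choice(len(f), size=q, replace=False, p=w)))
    return picks


# ---------------------------------------------------------------------------
# Re-embedding of held-out points
# ---------------------------------------------------------------------------

def reembed_points(
    new: np.ndarray,
    model: EmbeddingModel,
    n_iter: int = 80,
    learning_rate: float = 0.5,
    momentum: float = 0.8,
    block_size: int = 4000,
    n_candidates: int = 256,
    return_cost: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Place new points into a trained map without moving it.

    For each new point: KL divergences to all training spectra are
    computed, a transition row is calibrated to the model's target
    entropy, and the point's coordinate minimizes the KL objective
    between that row and the Cauchy-kernel distribution over the fixed
    training coordinates, by gradient descent initialized at the nearest
    training neighbour.

    Returns the (n, d) coordinates (and per-point final objectives if
    ``return_cost``).
    """
    new = np.atleast_2d(np.asarray(new, dtype=float))
    if new.shape[1] != model.train_features.shape[1]:
        raise ValueError("feature dimension mismatch with the trained model")
    Yt = model.train_coords
    H = model.target_entropy
    n = new.shape[0]
    out = np.empty((n, model.dim))
    costs = np.empty(n)
    N = len(Yt)
    k = min(n_candidates, N)
    Yt32 = Yt.astype(np.float32)
    yt2 = np.sum(Yt32**2, axis=1)
    mom = np.float32(momentum)
    lr = np.float32(learning_rate)
    for start in range(0, n, block_size):
        sl = slice(start, min(start + block_size, n))
        block = new[sl]
        B = len(block)
        D2 = pairwise_kl(block, model.train_features) ** 2
        # the Gaussian kernel at perplexity 2**H is numerically zero beyond
        # the nearest few hundred candidates; calibrate on those only
        if k < N:
            idx = np.argpartition(D2, k - 1, axis=1)[:, :k]
            D2k = np.take_along_axis(D2, idx, axis=1)
        else:
            idx = np.broadcast_to(np.arange(N), (B, N))
            D2k = D2
        Pk, _ = _calibrate_rows(D2k, H)
        P = np.zeros((B, N), dtype=np.float32)
        np.put_along_axis(P, idx, Pk.astype(np.float32), axis=1)
        z = Yt32[np.argmin(D2, axis=1)].copy()
        vel = np.zeros_like(z)

        def _wq(z_: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            d2 = np.sum(z_**2, axis=1)[:, None] + yt2[None, :] - 2.0 * (z_ @ Yt32.T)
            w = 1.0 / (1.0 + np.maximum(d2, 0.0))
            return w, w / w.sum(axis=1, keepdims=True)

        for _ in range(n_iter):
            w, Q = _wq(z)
            # grad_b = 2 sum_n c_bn (z_b - Y_n), c = (P - Q) * w
            c = P - Q
            c *= w
            grad = z * c.sum(axis=1, keepdims=True) - c @ Yt32
            vel = mom * vel - (2.0 * lr) * grad
            z = z + vel
        _, Q = _wq(z)
        Pf = P.astype(float)
        costs[sl] = np.sum(
            np.where(Pf > 0, Pf * np.log(np.maximum(Pf, 1e-30) / np.maximum(Q, 1e-30)), 0.0),
            axis=1,
        )
        out[sl] = z.astype(float)
    if return_cost:
        return out, costs
    return out
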