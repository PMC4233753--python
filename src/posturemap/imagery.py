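"""Segmentation and egocentric registration of single-animal video.

Each frame is segmented by edge detection plus morphological closing to
produce a binary mask of the animal; masked frames are rescaled so the
body covers a reference area, rotationally aligned by polar
cross-correlation against a template image, and translationally aligned
by sub-pixel phase correlation.  The result is an image stack in the
co-moving, co-rotating frame of the animal, with background pixels
exactly zero.

The animal may be darker or lighter than the background: polarity is
detected from the first segmented frame and intensities are inverted if
needed so the registered foreground is bright on a zero background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "RawMovie",
    "SegmentationParams",
    "RegistrationResult",
    "AlignedFrameStack",
    "NoAnimalError",
    "segment_fly",
    "align_rotation",
    "align_translation",
    "rescale_to_reference",
    "process_movie",
]


class NoAnimalError(ValueError):
    """Raised when no sufficiently large foreground component is found."""

    def __init__(self, frame_index: int | None = None, message: str | None = None):
        self.frame_index = frame_index
        super().__init__(
            message
            or f"no animal found{'' if frame_index is None else f' in frame {frame_index}'}"
        )


@dataclass
class RawMovie:
    """A grayscale movie of a single behaving animal."""

    frames: np.ndarray  # (T, H, W)
    frame_rate: float
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, H, W)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class SegmentationParams:
    """Edge-detection and morphology parameters for body segmentation.

    Hysteresis thresholds are fractions of the frame's intensity range.
    """

    edge_low: float = 0.1
    edge_high: float = 0.3
    dilate_radius: int = 3
    erode_radius: int = 3
    min_area: int = 300
    canny_sigma: float = 1.5

    def __post_init__(self) -> None:
        if not self.edge_low < self.edge_high:
            raise ValueError("edge_low must be < edge_high")
        if self.dilate_radius < 0 or self.erode_radius < 0:
            raise ValueError("morphology radii must be >= 0")


@dataclass
class RegistrationResult:
    """Per-frame rigid registration parameters."""

    angle: float  # degrees in [-180, 180)
    shift: tuple[float, float]  # (dx, dy), sub-pixel
    scale: float
    ok: bool = True


@dataclass
class AlignedFrameStack:
    """Masked, registered, rescaled egocentric image stack."""

    frames: np.ndarray  # (T, H, W), background exactly zero
    registration_log: pd.DataFrame  # frame, angle_deg, dx, dy, scale, ok
    template: np.ndarray
    frame_rate: float = 100.0
    excluded: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_fly(
    frame: np.ndarray,
    params: SegmentationParams | None = None,
    frame_index: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Isolate the animal in one frame.

    Canny edge detection, morphological dilation, hole filling and
    erosion produce candidate components; the largest closed component of
    at least ``min_area`` pixels is kept as the mask.

    Returns ``(mask, masked_frame)`` with ``masked_frame = frame * mask``.

    Raises
    ------
    NoAnimalError
        If no component reaches ``min_area`` (e.g. a blank frame).
    """
    from skimage.feature import canny
    from skimage.morphology import dilation, disk, erosion

    params = params or SegmentationParams()
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise NoAnimalError(frame_index, "empty frame")
    rng_ = frame.max() - frame.min()
    if rng_ <= 0:
        raise NoAnimalError(frame_index)
    norm = (frame - frame.min()) / rng_
    edges = canny(
        norm,
        sigma=params.canny_sigma,
        low_threshold=params.edge_low,
        high_threshold=params.edge_high,
    )
    m = dilation(edges, disk(params.dilate_radius))
    m = ndimage.binary_fill_holes(m)
    if params.erode_radius:
        m = erosion(m, disk(params.erode_radius))
    labels, n = ndimage.label(m)
    if n == 0:
        raise NoAnimalError(frame_index)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(areas)) + 1
    if areas[best - 1] < params.min_area:
        raise NoAnimalError(frame_index)
    mask = labels == best
    return mask, frame * mask


# ---------------------------------------------------------------------------
# Rotational alignment
# ---------------------------------------------------------------------------

def _skew_x(img: np.ndarray) -> float:
    """Third moment of intensity along x about the centroid; the sign
    encodes which half of the body (head vs tail) is heavier."""
    total = img.sum()
    if total <= 0:
        return 0.0
    ys, xs = np.indices(img.shape)
    cx = (img * xs).sum() / total
    sx = np.sqrt((img * (xs - cx) ** 2).sum() / total)
    if sx == 0:
        return 0.0
    return float((img * ((xs - cx) / sx) ** 3).sum() / total)


def _rotate(img: np.ndarray, angle_deg: float) -> np.ndarray:
    from skimage.transform import rotate

    return rotate(img, angle_deg, order=1, preserve_range=True)


def align_rotation(
    masked_frame: np.ndarray,
    template: np.ndarray,
    angular_bins: int = 720,
) -> tuple[float, np.ndarray]:
    """Rotationally align a masked frame to a template by polar
    cross-correlation about the centroid.

    Both images must be the same shape and centred on their foreground
    centroid.  The recovered angle (degrees, in [-180, 180)) maximizes
    the angular cross-correlation of the polar-unwrapped images, with
    parabolic sub-bin interpolation; a remaining 180-degree head/tail
    ambiguity is resolved by requiring the intensity skewness along the
    body's major axis to match the template's.

    Returns ``(angle, rotated_frame)`` where ``rotated_frame`` is the
    input rotated by ``-angle``.
    """
    from skimage.transform import warp_polar

    if masked_frame.shape != template.shape:
        raise ValueError("frame and template must have the same shape")
    radius = min(masked_frame.shape) // 2
    pf = warp_polar(masked_frame, radius=radius, output_shape=(angular_bins, radius))
    pt = warp_polar(template, radius=radius, output_shape=(angular_bins, radius))
    F = np.fft.rfft(pf, axis=0)
    G = np.fft.rfft(pt, axis=0)
    corr = np.fft.irfft(F * np.conj(G), n=angular_bins, axis=0).sum(axis=1)

    # near-flat angular correlation = rotationally symmetric foreground
    # (a rasterized disc ripples at ~1% of its correlation level)
    spread = corr.max() - corr.min()
    if spread <= 0.03 * max(abs(corr).max(), 1e-12):
        warnings.warn("rotationally symmetric foreground; angle set to 0", stacklevel=2)
        return 0.0, masked_frame.copy()

    k = int(np.argmax(corr))
    cm, c0, cp = corr[(k - 1) % angular_bins], corr[k], corr[(k + 1) % angular_bins]
    denom = cm - 2 * c0 + cp
    frac = 0.0 if denom == 0 else 0.5 * (cm - cp) / denom
    # the polar correlation peak sits at the template->frame angular lag;
    # report the frame's rotation relative to the template
    angle = -(k + frac) * (360.0 / angular_bins)

    def wrap(a: float) -> float:
        return (a + 180.0) % 360.0 - 180.0

    angle = wrap(angle)
    rotated = _rotate(masked_frame, -angle)

    s_t = _skew_x(template)
    s_f = _skew_x(rotated)
    scale = max(abs(s_t), abs(s_f))
    if scale > 1e-3 and s_t * s_f < 0:
        angle = wrap(angle + 180.0)
        rotated = _rotate(masked_frame, -angle)
    return float(angle), rotated


# ---------------------------------------------------------------------------
# Translational alignment
# ---------------------------------------------------------------------------

def align_translation(
    frame: np.ndarray,
    template: np.ndarray,
    upsample_factor: int = 20,
) -> tuple[tuple[float, float], np.ndarray]:
    """Sub-pixel translational alignment by upsampled phase correlation.

    Returns ``((dx, dy), shifted_frame)`` where ``(dx, dy)`` is the
    displacement of the frame relative to the template (default
    precision 1/upsample_factor = 0.05 px) and ``shifted_frame`` is the
    frame translated by ``-(dx, dy)`` via Fourier shift, with the
    wrapped boundary zeroed.
    """
    from skimage.registration import phase_cross_correlation

    frame = np.asarray(frame, dtype=float)
    if frame.shape != template.shape:
        raise ValueError("frame and template must have the same shape")
    shift_rc, _, _ = phase_cross_correlation(
        template, frame, upsample_factor=upsample_factor, normalization=None
    )
    dy, dx = -shift_rc[0], -shift_rc[1]  # displacement of frame vs template
    shifted = np.fft.ifftn(ndimage.fourier_shift(np.fft.fftn(frame), shift_rc)).real
    # zero the band that wrapped around
    ry, rx = int(np.ceil(abs(shift_rc[0]))), int(np.ceil(abs(shift_rc[1])))
    if ry:
        if shift_rc[0] > 0:
            shifted[:ry, :] = 0.0
        else:
            shifted[-ry:, :] = 0.0
    if rx:
        if shift_rc[1] > 0:
            shifted[:, :rx] = 0.0
        else:
            shifted[:, -rx:] = 0.0
    return (float(dx), float(dy)), shifted


# ---------------------------------------------------------------------------
# Size normalization
# ---------------------------------------------------------------------------

def rescale_to_reference(
    frames: np.ndarray,
    masks: np.ndarray,
    reference_area: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Rescale every frame of a movie by a single isotropic factor so the
    movie's median foreground area equals ``reference_area``.

    ``scale = sqrt(reference_area / median_area)``; output frames are
    centre-cropped or zero-padded back to the input shape.

    Returns ``(frames, masks, scale)``.
    """
    from skimage.transform import rescale

    areas = np.array([int(m.sum()) for m in masks], dtype=float)
    med = float(np.median(areas))
    if med <= 0:
        raise ValueError("zero median foreground area")
    scale = float(np.sqrt(reference_area / med))
    if abs(scale - 1.0) < 1e-12:
        return np.asarray(frames, dtype=float), np.asarray(masks, bool), 1.0
    out_f = np.zeros((len(frames),) + frames[0].shape)
    out_m = np.zeros((len(masks),) + masks[0].shape, dtype=bool)
    for i, (f, m) in enumerate(zip(frames, masks)):
        rf = rescale(np.asarray(f, dtype=float), scale, order=1, preserve_range=True)
        rm = rescale(m.astype(float), scale, order=1, preserve_range=True) > 0.5
        out_f[i] = _fit_to_shape(rf, f.shape)
        out_m[i] = _fit_to_shape(rm.astype(float), m.shape) > 0.5
    return out_f, out_m, scale


def _fit_to_shape(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Centre-crop or zero-pad an image to a target shape."""
    out = np.zeros(shape, dtype=img.dtype)
    h, w = img.shape
    H, W = shape
    sy, ty = (h - H) // 2 if h > H else 0, (H - h) // 2 if h < H else 0
    sx, tx = (w - W) // 2 if w > W else 0, (W - w) // 2 if w < W else 0
    ch, cw = min(h, H), min(w, W)
    out[ty : ty + ch, tx : tx + cw] = img[sy : sy + ch, sx : sx + cw]
    return out


def _center_on_centroid(masked: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Shift (integer pixels) so the intensity centroid sits at the image
    centre. Returns the shifted image and the applied (dx, dy)."""
    total = masked.sum()
    if total <= 0:
        return masked, (0.0, 0.0)
    cy, cx = ndimage.center_of_mass(masked)
    H, W = masked.shape
    dy = int(round(H / 2 - cy))
    dx = int(round(W / 2 - cx))
    out = np.zeros_like(masked)
    ys = slice(max(dy, 0), H + min(dy, 0))
    yd = slice(max(-dy, 0), H + min(-dy, 0))
    out[ys, :] = masked[yd, :]
    out2 = np.zeros_like(out)
    xs = slice(max(dx, 0), W + min(dx, 0))
    xd = slice(max(-dx, 0), W + min(-dx, 0))
    out2[:, xs] = out[:, xd]
    return out2, (float(dx), float(dy))


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def process_movie(
    movie: RawMovie,
    params: SegmentationParams | None = None,
    reference_area: float | None = None,
    template: np.ndarray | None = None,
    n_template_frames: int = 100,
    template_iterations: int = 2,
) -> AlignedFrameStack:
    """Segment, rescale, rotationally and translationally align a movie.

    Frames failing segmentation are excluded and their indices reported
    in ``AlignedFrameStack.excluded``.  If no template is supplied it is
    built as the mean of the first ``n_template_frames`` successfully
    segmented, centred frames, iteratively re-aligned
    ``template_iterations`` times.
    """
    params = params or SegmentationParams()
    T = len(movie)
    masks: list[np.ndarray] = []
    maskeds: list[np.ndarray] = []
    good_idx: list[int] = []
    excluded: list[int] = []
    for t in range(T):
        try:
            mask, _ = segment_fly(movie.frames[t], params, frame_index=t)
        except NoAnimalError:
            excluded.append(t)
            continue
        masks.append(mask)
        maskeds.append(np.asarray(movie.frames[t], dtype=float))
        good_idx.append(t)
    if not good_idx:
        raise NoAnimalError(message="no frame contains an animal")

    # polarity: make the foreground bright so correlations are mass-driven
    f0, m0 = maskeds[0], masks[0]
    invert = np.median(f0[m0]) < np.median(f0[~m0])
    frames_arr = np.stack(
        [(f.max() - f if invert else f) * m for f, m in zip(maskeds, masks)]
    )
    masks_arr = np.stack(masks)

    scale = 1.0
    if reference_area is not None:
        frames_arr, masks_arr, scale = rescale_to_reference(
            frames_arr, masks_arr, reference_area
        )

    centered = []
    cshifts = []
    for f in frames_arr:
        c, sh = _center_on_centroid(f)
        centered.append(c)
        cshifts.append(sh)

    if template is None:
        n0 = min(n_template_frames, len(centered))
        template = np.mean(centered[:n0], axis=0)
        for _ in range(template_iterations):
            aligned0 = []
            for f in centered[:n0]:
                _, rot = align_rotation(f, template)
                _, shifted = align_translation(rot, template)
                aligned0.append(shifted)
            template = np.mean(aligned0, axis=0)

    out = np.empty_like(np.stack(centered))
    recs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, f in enumerate(centered):
            angle, rot = align_rotation(f, template)
            (ddx, ddy), shifted = align_translation(rot, template)
            out[i] = shifted
            recs.append(
                {
                    "frame": good_idx[i],
                    "angle_deg": angle,
                    "dx": -cshifts[i][0] + ddx,
                    "dy": -cshifts[i][1] + ddy,
                    "scale": scale,
                    "ok": True,
                }
            )
    for t in excluded:
        recs.append(
            {"frame": t, "angle_deg": np.nan, "dx": np.nan, "dy": np.nan,
             "scale": scale, "ok": False}
        )
    log = pd.DataFrame(recs).sort_values("frame").reset_index(drop=True)
    return AlignedFrameStack(
        frames=out,
        registration_log=log,
        template=template,
        frame_rate=movie.frame_rate,
        excluded=np.array(excluded, dtype=int),
    )
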