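"""Reading and writing the pipeline's on-disk formats.

Movies come in as multi-page TIFF (or AVI where imageio can decode it);
intermediate products (aligned stacks, mode bases, postural series,
features, embeddings, maps) are stored in HDF5.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .behaviormap import BehaviorDensity, RegionMap
from .embedding import EmbeddingModel
from .imagery import AlignedFrameStack, RawMovie
from .postural import ModeBasis, PosturalTimeSeries

__all__ = [
    "read_movie",
    "write_movie_tiff",
    "write_aligned",
    "read_aligned",
    "write_modes",
    "read_modes",
    "write_embedding",
    "read_embedding",
    "write_map",
]


def read_movie(path: str | Path, frame_rate: float = 100.0) -> RawMovie:
    """Read a grayscale movie from multi-page TIFF (or AVI via imageio)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        frames = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        frames = iio.imread(path)
        if frames.ndim == 4:  # colour -> luminance
            frames = frames.mean(axis=-1)
    frames = np.asarray(frames)
    if frames.dtype.kind in "ui":
        frames = frames.astype(float) / np.iinfo(frames.dtype).max
    return RawMovie(frames=frames, frame_rate=frame_rate)


def write_movie_tiff(path: str | Path, movie: RawMovie) -> None:
    import tifffile

    data = np.clip(movie.frames * 255, 0, 255).astype(np.uint8)
    tifffile.imwrite(path, data)


def write_aligned(path: str | Path, stack: AlignedFrameStack) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=stack.frames, compression="gzip")
        f.create_dataset("template", data=stack.template)
        f.attrs["frame_rate"] = stack.frame_rate
        g = f.create_group("registration")
        for col in ("frame", "angle_deg", "dx", "dy", "scale", "ok"):
            g.create_dataset(col, data=stack.registration_log[col].to_numpy())
        f.create_dataset("excluded", data=stack.excluded)


def read_aligned(path: str | Path) -> AlignedFrameStack:
    with h5py.File(path, "r") as f:
        log = pd.DataFrame(
            {col: f["registration"][col][:] for col in
             ("frame", "angle_deg", "dx", "dy", "scale", "ok")}
        )
        return AlignedFrameStack(
            frames=f["frames"][:],
            registration_log=log,
            template=f["template"][:],
            frame_rate=float(f.attrs["frame_rate"]),
            excluded=f["excluded"][:],
        )


def write_modes(
    path: str | Path,
    basis: ModeBasis,
    series: PosturalTimeSeries | None = None,
    radon: np.ndarray | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("modes")
        g.create_dataset("mean", data=basis.mean)
        g.create_dataset("vectors", data=basis.eigenvectors)
        g.create_dataset("eigenvalues", data=basis.eigenvalues)
        g.attrs["m"] = basis.m
        if radon is not None:
            f.create_dataset("radon", data=radon, compression="gzip")
        if series is not None:
            ts = f.create_group("timeseries")
            ts.create_dataset("y", data=series.y)
            ts.attrs["frame_rate"] = series.frame_rate


def read_modes(path: str | Path) -> tuple[ModeBasis | None, PosturalTimeSeries | None]:
    with h5py.File(path, "r") as f:
        basis = None
        if "modes" in f:
            basis = ModeBasis(
                mean=f["modes/mean"][:],
                eigenvectors=f["modes/vectors"][:],
                eigenvalues=f["modes/eigenvalues"][:],
                m=int(f["modes"].attrs["m"]),
            )
        series = None
        if "timeseries" in f:
            series = PosturalTimeSeries(
                y=f["timeseries/y"][:],
                frame_rate=float(f["timeseries"].attrs["frame_rate"]),
            )
        return basis, series


def write_embedding(path: str | Path, model: EmbeddingModel,
                    z: np.ndarray | None = None) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("embedding")
        g.create_dataset("train_features", data=model.train_features,
                         compression="gzip")
        g.create_dataset("train_coords", data=model.train_coords)
        if model.train_indices is not None:
            g.create_dataset("train_idx", data=model.train_indices)
        if z is not None:
            g.create_dataset("z", data=z)
        g.attrs["H"] = model.target_entropy
        g.attrs["seed"] = model.seed
        g.attrs["n_iter"] = model.n_iter
        g.attrs["final_cost"] = model.final_cost
        g.attrs["dim"] = model.dim


def read_embedding(path: str | Path) -> tuple[EmbeddingModel, np.ndarray | None]:
    with h5py.File(path, "r") as f:
        g = f["embedding"]
        model = EmbeddingModel(
            train_features=g["train_features"][:],
            train_coords=g["train_coords"][:],
            target_entropy=float(g.attrs["H"]),
            seed=int(g.attrs["seed"]),
            n_iter=int(g.attrs["n_iter"]),
            final_cost=float(g.attrs["final_cost"]),
            dim=int(g.attrs["dim"]),
            train_indices=g["train_idx"][:] if "train_idx" in g else None,
        )
        z = g["z"][:] if "z" in g else None
        return model, z


def write_map(path: str | Path, density: BehaviorDensity,
              regions: RegionMap | None = None) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("map")
        g.create_dataset("density", data=density.grid, compression="gzip")
        g.create_dataset("extent", data=np.array(density.extent))
        g.attrs["sigma"] = density.sigma
        if regions is not None:
            g.create_dataset("labels", data=regions.labels, compression="gzip")
            g.create_dataset("peaks", data=regions.peaks)
            g.attrs["n_regions"] = regions.n_regions
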