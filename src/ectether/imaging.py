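"""Image containers, TIFF I/O, focus selection and projection.

Images are held as 2-D float arrays of nonnegative intensities regardless
of on-disk bit depth; the original dtype is remembered for round-trip
writing. Focus scoring uses the variance of the 3x3 four-neighbour
Laplacian stencil with mirrored borders (reflect-101, the default border
of the common CV implementations), so a constant image scores exactly 0
and the score is invariant to adding a constant offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "FluorImage",
    "ZStack",
    "laplacian_variance",
    "select_best_focus",
    "max_project",
    "read_tiff_stack",
    "write_tiff_stack",
]

# 4-neighbour discrete Laplacian
_LAPLACIAN = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)


@dataclass
class FluorImage:
    """One channel's 2-D intensity grid.

    Parameters
    ----------
    pixels : ndarray
        2-D array of nonnegative intensities (arbitrary units).
    channel : str
        Channel label, e.g. ``"DAPI"``, ``"FISH"``, ``"IF"``.
    z_index : int, optional
        Plane index when the image came from a z-stack.
    source_dtype : numpy dtype, optional
        On-disk dtype of the original file, used when writing back.
    """

    pixels: np.ndarray
    channel: str = ""
    z_index: int | None = None
    source_dtype: np.dtype | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be a 2-D grid with both dimensions >= 1")
        if not np.isfinite(px).all():
            raise ValueError("image intensities must be finite")
        if (px < 0).any():
            raise ValueError("image intensities must be nonnegative")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ZStack:
    """Ordered planes of identical shape and channel.

    ``step_um`` is the axial spacing between planes (0.5 um is the
    acquisition default this pipeline assumes).
    """

    planes: list[FluorImage] = field(default_factory=list)
    step_um: float = 0.5

    def __post_init__(self) -> None:
        if self.step_um <= 0:
            raise ValueError("step_um must be > 0")
        if self.planes:
            shape = self.planes[0].shape
            channel = self.planes[0].channel
            for i, plane in enumerate(self.planes):
                if plane.shape != shape:
                    raise ValueError("all planes must share one shape")
                if plane.channel != channel:
                    raise ValueError("all planes must share one channel")
                plane.z_index = i

    def __len__(self) -> int:
        return len(self.planes)


def laplacian_variance(image: FluorImage) -> float:
    """Population variance of the 3x3 Laplacian response (mirrored borders).

    A constant image scores exactly 0; sharper texture scores higher.
    """
    response = ndimage.convolve(image.pixels, _LAPLACIAN, mode="mirror")
    return float(np.var(response))


def select_best_focus(stack: ZStack) -> tuple[int, FluorImage]:
    """Pick the plane maximizing :func:`laplacian_variance`.

    Ties are broken toward the lowest z index so the choice is
    deterministic.
    """
    if len(stack) == 0:
        raise ValueError("cannot select focus from an empty stack")
    scores = [laplacian_variance(p) for p in stack.planes]
    best = int(np.argmax(scores))  # argmax returns the first maximum
    return best, stack.planes[best]


def max_project(stack: ZStack) -> FluorImage:
    """Per-pixel maximum-intensity projection across planes."""
    if len(stack) == 0:
        raise ValueError("cannot project an empty stack")
    projected = np.max([p.pixels for p in stack.planes], axis=0)
    first = stack.planes[0]
    return FluorImage(projected, channel=first.channel, source_dtype=first.source_dtype)


def read_tiff_stack(path, channel: str = "") -> ZStack:
    """Read a single- or multi-page TIFF into a :class:`ZStack`.

    Pages are taken as z planes in file order. A 2-D file yields a
    one-plane stack.
    """
    data = tifffile.imread(path)
    arr = np.asarray(data)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected 2-D or 3-D TIFF, got shape {arr.shape}")
    dtype = arr.dtype
    planes = [
        FluorImage(plane.astype(float), channel=channel, z_index=i, source_dtype=dtype)
        for i, plane in enumerate(arr)
    ]
    return ZStack(planes=planes)


def write_tiff_stack(path, images: Sequence[FluorImage] | FluorImage) -> None:
    """Write one or more images as TIFF pages, restoring the source dtype."""
    if isinstance(images, FluorImage):
        images = [images]
    if not images:
        raise ValueError("nothing to write")
    dtype = images[0].source_dtype or np.dtype("float32")
    arr = np.stack([im.pixels for im in images]).astype(dtype)
    tifffile.imwrite(
        path, arr if arr.shape[0] > 1 else arr[0], photometric="minisblack"
    )
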