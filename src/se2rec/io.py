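"""Readers and writers for images, transform stacks, maps and traces.

Formats are deliberately plain: 8-bit grayscale PNG for images and feature
maps (with a JSON sidecar for the map's recipe), 32-bit-float TIFF for
float images, multi-page 32-bit-float TIFF for complex stacks (pages
interleaved: orientation 0 real, orientation 0 imag, orientation 1 real,
...; the page order is echoed to a sidecar text header), and CSV for error
traces.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .exceptions import DimensionError, StorageError
from .maps import FeatureMap
from .reconstruct import ReconstructionTrace

__all__ = [
    "read_image",
    "write_image",
    "write_float_image",
    "save_stack",
    "load_stack",
    "save_trace",
    "save_feature_map",
    "load_feature_map",
]

logger = logging.getLogger("se2rec")


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image as a float array.

    Color inputs are converted to grayscale by channel averaging, with a
    logged warning; non-square images are rejected.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise StorageError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        logger.warning("converting non-grayscale image %s by channel averaging", path)
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise DimensionError(f"image {path} is not square: shape {arr.shape}")
    return arr.astype(float)


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit grayscale PNG (values clipped to [0, 255] and rounded)."""
    path = Path(path)
    data = np.rint(np.clip(np.asarray(image), 0.0, 255.0)).astype(np.uint8)
    try:
        iio.imwrite(path, data)
    except OSError as exc:
        raise StorageError(f"cannot write image {path}: {exc}") from exc


def write_float_image(image: np.ndarray, path: str | Path) -> None:
    """Write a lossless 32-bit-float TIFF."""
    try:
        tifffile.imwrite(Path(path), np.asarray(image, dtype=np.float32))
    except OSError as exc:
        raise StorageError(f"cannot write image {path}: {exc}") from exc


def save_stack(stack: np.ndarray, path: str | Path) -> None:
    """Persist a complex ``(n, n, m)`` stack as interleaved float32 TIFF pages."""
    path = Path(path)
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise DimensionError(f"expected an (n, n, m) stack, got shape {stack.shape}")
    m = stack.shape[2]
    pages = np.empty((2 * m, stack.shape[0], stack.shape[1]), dtype=np.float32)
    pages[0::2] = np.moveaxis(stack.real, -1, 0)
    pages[1::2] = np.moveaxis(stack.imag, -1, 0)
    try:
        tifffile.imwrite(path, pages)
        Path(str(path) + ".meta.txt").write_text(
            f"se2rec transform stack, shape (n, n, m) = {stack.shape}\n"
            "pages: orientation 0 real, orientation 0 imag, orientation 1 real, "
            "orientation 1 imag, ...\n"
            "dtype: float32 per page (complex64 stack on load)\n"
        )
    except OSError as exc:
        raise StorageError(f"cannot write stack {path}: {exc}") from exc


def load_stack(path: str | Path) -> np.ndarray:
    """Load a stack written by :func:`save_stack` (complex64, ``(n, n, m)``)."""
    path = Path(path)
    try:
        pages = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise StorageError(f"cannot read stack {path}: {exc}") from exc
    if pages.ndim != 3 or pages.shape[0] % 2 != 0:
        raise DimensionError(f"{path} does not hold interleaved real/imag pages")
    stack = pages[0::2] + 1j * pages[1::2]
    return np.moveaxis(stack.astype(np.complex64), 0, -1)


def save_trace(trace: ReconstructionTrace, path: str | Path) -> None:
    """Write the recorded error trace as CSV (iteration, delta_percent)."""
    path = Path(path)
    try:
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["iteration", "delta_percent"])
            for i, it in enumerate(trace.iterations):
                delta = "" if trace.deltas is None else repr(float(trace.deltas[i]))
                writer.writerow([int(it), delta])
    except OSError as exc:
        raise StorageError(f"cannot write trace {path}: {exc}") from exc


def save_feature_map(fmap: FeatureMap, path: str | Path) -> None:
    """Write a feature map as an index-valued PNG plus a JSON sidecar."""
    path = Path(path)
    if fmap.m > 256:
        raise DimensionError(f"cannot store {fmap.m} orientation indices in 8 bits")
    try:
        iio.imwrite(path, fmap.values.astype(np.uint8))
        Path(str(path) + ".json").write_text(
            json.dumps(
                {
                    "kind": fmap.kind,
                    "n": int(fmap.n),
                    "m": int(fmap.m),
                    "rho": fmap.rho,
                    "seed": fmap.seed,
                },
                indent=2,
            )
        )
    except OSError as exc:
        raise StorageError(f"cannot write feature map {path}: {exc}") from exc


def load_feature_map(path: str | Path) -> FeatureMap:
    """Load a feature map written by :func:`save_feature_map`."""
    path = Path(path)
    try:
        values = np.asarray(iio.imread(path)).astype(np.int64)
        meta = json.loads(Path(str(path) + ".json").read_text())
    except (OSError, ValueError, json.JSONDecodeError) as exc:
        raise StorageError(f"cannot read feature map {path}: {exc}") from exc
    return FeatureMap(
        values=values,
        m=int(meta["m"]),
        kind=meta["kind"],
        rho=meta["rho"],
        seed=meta["seed"],
    )
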