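"""Readers and writers: multi-page TIFF stacks, label maps, region masks.

Image stacks are stored one channel per TIFF page with the channel names in
the TIFF's shaped metadata, so a stack round-trips with its naming intact.
Operation is strictly 2D (single optical planes); pages with extra
dimensions are rejected rather than silently projected.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .images import ChannelImage

__all__ = [
    "write_image_stack",
    "read_image_stack",
    "write_label_map",
    "read_label_map",
    "read_region_masks",
]


def write_image_stack(path, stack: np.ndarray, channel_names) -> None:
    """Write (C, H, W) stack as a multi-page TIFF, channel names in metadata."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"expected a (C, H, W) stack, got shape {stack.shape}")
    names = list(channel_names)
    if len(names) != stack.shape[0]:
        raise ValueError(f"{len(names)} channel names for {stack.shape[0]} pages")
    tifffile.imwrite(
        path, stack, photometric="minisblack", metadata={"channel_names": names}
    )


def read_image_stack(path, channel_names=None) -> dict:
    """Read a multi-page TIFF into {channel name: ChannelImage}.

    Channel names come from the file's metadata unless overridden; the
    number of names must match the page count.  Each page must be a single
    2D plane — multi-Z or multi-timepoint input is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image stack not found: {path}")
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
        meta_names = None
        if tif.shaped_metadata:
            meta_names = tif.shaped_metadata[0].get("channel_names")
    for i, page in enumerate(pages):
        if np.asarray(page).ndim != 2:
            raise ValueError(
                f"{path}: page {i} has shape {np.asarray(page).shape}; only "
                "single 2D optical planes are supported (no Z stacks)"
            )
    names = list(channel_names) if channel_names is not None else meta_names
    if names is None:
        raise ValueError(f"{path}: no channel names in metadata and none supplied")
    if len(names) != len(pages):
        raise ValueError(
            f"{path}: {len(names)} channel names for {len(pages)} TIFF pages"
        )
    return {
        name: ChannelImage(np.asarray(page), name) for name, page in zip(names, pages)
    }


def write_label_map(path, labels: np.ndarray) -> None:
    """Write an integer label image (16-bit when it fits, else 32-bit)."""
    labels = np.asarray(labels)
    dtype = np.uint16 if labels.max() < 2**16 else np.uint32
    tifffile.imwrite(path, labels.astype(dtype))


def read_label_map(path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: label map must be 2D, got shape {arr.shape}")
    return arr.astype(np.int32)


def read_region_masks(mask_paths: dict) -> dict:
    """Read named binary mask TIFFs into {region name: boolean array}."""
    out = {}
    for name, path in mask_paths.items():
        arr = tifffile.imread(path)
        if arr.ndim != 2:
            raise ValueError(f"region {name!r} ({path}): mask must be 2D")
        out[name] = np.asarray(arr) > 0
    return out
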