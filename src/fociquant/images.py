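"""Shared raster container for single-channel fluorescence images."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ChannelImage:
    """One 2D intensity grid for one labelled stain/probe channel.

    Pixels are non-negative finite intensities on an arbitrary scale
    (the assay leaves per-sample intensity calibration to the user).
    ``bit_depth_note`` records the dtype of the source data so that
    integer inputs of any bit depth can be carried through unchanged.
    """

    pixels: np.ndarray
    channel_name: str = ""
    bit_depth_note: str = field(default="")

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError(
                f"channel {self.channel_name!r}: expected a non-empty 2D image, "
                f"got shape {px.shape}"
            )
        if not np.issubdtype(px.dtype, np.number):
            raise ValueError(f"channel {self.channel_name!r}: non-numeric pixels")
        if not np.all(np.isfinite(px)):
            raise ValueError(f"channel {self.channel_name!r}: non-finite pixel values")
        if px.min() < 0:
            raise ValueError(f"channel {self.channel_name!r}: negative pixel values")
        object.__setattr__(self, "pixels", px)
        if not self.bit_depth_note:
            object.__setattr__(self, "bit_depth_note", str(px.dtype))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape
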